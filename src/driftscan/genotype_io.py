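"""Genotype data model and readers/writers for PLINK text and VCF.

The internal model is a samples x SNPs dosage matrix counting copies of
``allele_b`` (0/1/2), with ``MISSING = -1`` as the sentinel for uncalled
genotypes.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype.  Never participates in arithmetic.
MISSING: int = -1

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "population"]

#: Strand-ambiguous allele pairs dropped when merging across chips.
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype input files."""


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering (1..n before non-numeric names)."""
    num = pd.to_numeric(chrom, errors="coerce")
    return pd.Series(
        list(zip(num.isna(), num.fillna(0), chrom.astype(str))), index=chrom.index
    )


def make_variant_table(records) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)
    return df


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with linked variant and sample tables.

    ``dosage[i, j]`` counts copies of ``variants.allele_b[j]`` carried by
    ``samples.sample_id[i]``; ``MISSING`` marks uncalled cells.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        n, m = self.dosage.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.samples["sample_id"].duplicated().any():
            dups = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise ValueError(f"duplicated sample ids: {sorted(set(dups))}")
        if self.variants["snp_id"].duplicated().any():
            raise ValueError("duplicated snp ids")
        if (self.variants["allele_a"] == self.variants["allele_b"]).any():
            raise ValueError("allele_a == allele_b at some locus")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values outside {0,1,2,MISSING}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of called cells."""
        return self.dosage != MISSING

    def population_index(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no samples in population {population!r}")
        return idx

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.samples["population"]))

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.samples.iloc[index], self.variants, self.dosage[index, :]
        )

    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.samples, self.variants.iloc[index], self.dosage[:, index]
        )

    def sort_variants(self) -> "GenotypeMatrix":
        order = (
            self.variants.assign(_key=_chrom_sort_key(self.variants["chrom"]))
            .sort_values(["_key", "pos"], kind="stable")
            .index.to_numpy()
        )
        return self.take_variants(order)

    # -- per-axis summaries ---------------------------------------------
    def snp_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=1)

    def allele_b_frequency(self) -> np.ndarray:
        """Pooled frequency of allele_b per SNP (nan where uncalled)."""
        called = self.called()
        n = called.sum(axis=0)
        tot = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_b_frequency()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP counts of (aa, ab, bb) genotypes, shape (M, 3)."""
        return np.stack(
            [(self.dosage == k).sum(axis=0) for k in (0, 1, 2)], axis=1
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes (2N x M) for a single chromosome."""

    variants: pd.DataFrame
    haplos: np.ndarray
    sample_of_haplotype: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.haplos = np.asarray(self.haplos, dtype=np.uint8)
        if self.haplos.shape[0] != len(self.sample_of_haplotype):
            raise ValueError("haplotype rows do not match sample_of_haplotype")
        if self.haplos.shape[1] != len(self.variants):
            raise ValueError("haplotype columns do not match variants")
        if len(self.variants["chrom"].unique()) > 1:
            raise ValueError("HaplotypeSet must span a single chromosome")
        counts = pd.Series(self.sample_of_haplotype).value_counts()
        if (counts != 2).any():
            raise ValueError("each sample must contribute exactly 2 haplotypes")

    @property
    def n_haplotypes(self) -> int:
        return self.haplos.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.sample_of_haplotype))

    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    def dosage(self) -> tuple[list[str], np.ndarray]:
        """Collapse haplotype pairs to sample dosages (allele_b copies)."""
        ids = self.sample_ids
        rows = {s: [] for s in ids}
        for h, s in enumerate(self.sample_of_haplotype):
            rows[s].append(h)
        d = np.stack([self.haplos[rows[s][0]] + self.haplos[rows[s][1]] for s in ids])
        return ids, d.astype(np.int8)

    def subset_samples(self, sample_ids) -> "HaplotypeSet":
        keep = set(sample_ids)
        idx = [h for h, s in enumerate(self.sample_of_haplotype) if s in keep]
        return HaplotypeSet(
            self.variants,
            self.haplos[idx, :],
            [self.sample_of_haplotype[h] for h in idx],
        )


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    ``allele_a``/``allele_b`` are assigned lexicographically (so the read
    is invariant to sample order); dosage counts ``allele_b``.
    Monomorphic loci get ``allele_b`` = ``"0"``.  Variants are sorted by
    (chrom, pos) on return.
    """
    variants = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise GenotypeFormatError(
                    f"{map_path}:{lineno}: MAP line must have 4 columns"
                )
            chrom, snp_id, _cm, pos = fields
            variants.append((snp_id, chrom, int(pos)))
    m = len(variants)

    sample_ids, populations, rows = [], [], []
    alleles: list[list[str]] = [[] for _ in range(m)]
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise GenotypeFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(fields)}"
                )
            fid, iid = fields[0], fields[1]
            sample_ids.append(iid)
            populations.append(fid)
            row = np.full(m, MISSING, dtype=np.int8)
            for j in range(m):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    continue
                d = 0
                for a in (a1, a2):
                    if a not in alleles[j]:
                        alleles[j].append(a)
                        if len(alleles[j]) > 2:
                            raise GenotypeFormatError(
                                f"{ped_path}:{lineno}: >2 alleles at "
                                f"{variants[j][0]}: {alleles[j]}"
                            )
                    d += alleles[j].index(a)
                row[j] = d
            rows.append(row)

    dosage = (
        np.stack(rows) if rows else np.empty((0, m), dtype=np.int8)
    )
    var_records = []
    for j, ((snp_id, chrom, pos), al) in enumerate(zip(variants, alleles)):
        if len(al) == 2 and al[0] > al[1]:  # orient lexicographically
            al = [al[1], al[0]]
            col = dosage[:, j]
            dosage[:, j] = np.where(col == MISSING, MISSING, 2 - col)
        a = al[0] if len(al) > 0 else "N"
        b = al[1] if len(al) > 1 else "0"
        var_records.append((snp_id, chrom, pos, a, b))

    g = GenotypeMatrix(
        pd.DataFrame({"sample_id": sample_ids, "population": populations}),
        make_variant_table(var_records),
        dosage,
    )
    return g.sort_variants()


def write_plink_text(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text files; inverse of :func:`read_plink_text`."""
    with open(map_path, "w") as fh:
        for v in g.variants.itertuples():
            fh.write(f"{v.chrom}\t{v.snp_id}\t0\t{v.pos}\n")
    a = g.variants["allele_a"].to_numpy()
    b = g.variants["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, s in enumerate(g.samples.itertuples()):
            parts = [s.population, s.sample_id, "0", "0", "0", "-9"]
            for j, d in enumerate(g.dosage[i]):
                if d == MISSING:
                    parts += ["0", "0"]
                elif d == 0:
                    parts += [a[j], a[j]]
                elif d == 1:
                    parts += [a[j], b[j]]
                else:
                    parts += [b[j], b[j]]
            fh.write(" ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, require_phased: bool = False, population_of=None):
    """Read a VCF into a GenotypeMatrix, or HaplotypeSets when phased.

    Only biallelic SNP records are kept (others are skipped and counted).
    With ``require_phased=True`` the return value is a dict chrom ->
    :class:`HaplotypeSet`; any ``/``-separated genotype is an error.

    ``population_of`` optionally maps sample_id -> population label
    (default: one population ``"pop"``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    records, dosage_rows, haplo_rows = [], [], []
    skipped = 0
    unphased_records = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        gts = rec.genotypes  # [allele0, allele1, phased]
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        records.append((snp_id, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        dos = np.full(n, MISSING, dtype=np.int8)
        hap = np.zeros(2 * n, dtype=np.uint8)
        for i, gt in enumerate(gts):
            a0, a1 = gt[0], gt[1]
            if a0 >= 0 and a1 >= 0:
                dos[i] = a0 + a1
                hap[2 * i], hap[2 * i + 1] = a0, a1
                if require_phased and not gt[2]:
                    unphased_records.append((rec.CHROM, rec.POS, sample_ids[i]))
            elif require_phased:
                unphased_records.append((rec.CHROM, rec.POS, sample_ids[i]))
        dosage_rows.append(dos)
        haplo_rows.append(hap)
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if require_phased and unphased_records:
        preview = ", ".join(f"{c}:{p} ({s})" for c, p, s in unphased_records[:5])
        raise GenotypeFormatError(
            f"{len(unphased_records)} unphased/missing genotypes where phased "
            f"data is required, e.g. {preview}"
        )

    variants = make_variant_table(records)
    if population_of is None:
        population_of = {}
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": [population_of.get(s, "pop") for s in sample_ids],
        }
    )
    if not require_phased:
        dosage = (
            np.stack(dosage_rows, axis=1)
            if dosage_rows
            else np.empty((n, 0), dtype=np.int8)
        )
        return GenotypeMatrix(samples, variants, dosage).sort_variants()

    haplos = np.stack(haplo_rows, axis=1)  # 2N x M
    sample_of_hap = [s for s in sample_ids for _ in range(2)]
    out = {}
    for chrom in pd.unique(variants["chrom"]):
        idx = np.flatnonzero((variants["chrom"] == chrom).to_numpy())
        idx = idx[np.argsort(variants["pos"].to_numpy()[idx], kind="stable")]
        out[chrom] = HaplotypeSet(variants.iloc[idx], haplos[:, idx], sample_of_hap)
    return out


def write_vcf(path, g: GenotypeMatrix, haplotypes: dict | None = None) -> None:
    """Write a minimal VCF 4.2.  With ``haplotypes`` (chrom -> HaplotypeSet)
    genotypes are written phased; otherwise unphased from dosage."""
    g = g.sort_variants()
    ids = list(g.samples["sample_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        if haplotypes is not None:
            for chrom, hs in haplotypes.items():
                order = {s: [] for s in hs.sample_ids}
                for h, s in enumerate(hs.sample_of_haplotype):
                    order[s].append(h)
                for j, v in enumerate(hs.variants.itertuples()):
                    gts = "\t".join(
                        f"{hs.haplos[order[s][0], j]}|{hs.haplos[order[s][1], j]}"
                        for s in ids
                    )
                    fh.write(
                        f"{v.chrom}\t{v.pos}\t{v.snp_id}\t{v.allele_a}\t"
                        f"{v.allele_b}\t.\tPASS\t.\tGT\t{gts}\n"
                    )
        else:
            code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for j, v in enumerate(g.variants.itertuples()):
                gts = "\t".join(code[int(d)] for d in g.dosage[:, j])
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.snp_id}\t{v.allele_a}\t"
                    f"{v.allele_b}\t.\tPASS\t.\tGT\t{gts}\n"
                )


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_datasets(datasets: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge datasets on the intersection of their loci.

    Alleles are harmonized to the first dataset's orientation (dosage
    flipped ``d -> 2 - d`` where the pair is swapped).  Strand-ambiguous
    (A/T, C/G) loci and loci with irreconcilable allele sets are dropped
    with logged counts.
    """
    if len(datasets) < 2:
        raise ValueError("merge_datasets needs at least 2 datasets")
    all_ids = pd.concat([d.samples["sample_id"] for d in datasets])
    if all_ids.duplicated().any():
        raise ValueError(
            f"duplicated sample ids across datasets: "
            f"{sorted(set(all_ids[all_ids.duplicated()]))}"
        )

    shared = set(datasets[0].variants["snp_id"])
    for d in datasets[1:]:
        shared &= set(d.variants["snp_id"])

    ref = datasets[0]
    ref_idx = {s: j for j, s in enumerate(ref.variants["snp_id"])}
    n_ambiguous = n_irreconcilable = 0
    keep_ids = []
    flips = []  # per dataset: set of snp_ids to flip
    for _ in datasets:
        flips.append(set())
    for snp_id in ref.variants["snp_id"]:
        if snp_id not in shared:
            continue
        j0 = ref_idx[snp_id]
        a0 = ref.variants["allele_a"].iat[j0]
        b0 = ref.variants["allele_b"].iat[j0]
        if frozenset((a0, b0)) in AMBIGUOUS_PAIRS:
            n_ambiguous += 1
            continue
        ok = True
        ds_flip = []
        for k, d in enumerate(datasets[1:], start=1):
            jk = d.variants.index[d.variants["snp_id"] == snp_id][0]
            a, b = d.variants["allele_a"].iat[jk], d.variants["allele_b"].iat[jk]
            observed = {x for x in (a, b) if x != "0"}
            if observed <= {a0, b0}:
                ds_flip.append((k, a == b0 and b != b0))
            else:
                ok = False
                break
        if not ok:
            n_irreconcilable += 1
            continue
        keep_ids.append(snp_id)
        for k, fl in ds_flip:
            if fl:
                flips[k].add(snp_id)
    if n_ambiguous:
        logger.info("merge: dropped %d strand-ambiguous loci", n_ambiguous)
    if n_irreconcilable:
        logger.warning("merge: dropped %d irreconcilable loci", n_irreconcilable)

    keep_set = set(keep_ids)
    ref_keep = [ref_idx[s] for s in ref.variants["snp_id"] if s in keep_set]
    variants = ref.variants.iloc[ref_keep].reset_index(drop=True)
    order = list(variants["snp_id"])

    blocks, sample_frames = [], []
    for k, d in enumerate(datasets):
        idx_of = {s: j for j, s in enumerate(d.variants["snp_id"])}
        cols = [idx_of[s] for s in order]
        block = d.dosage[:, cols].copy()
        flip_mask = np.array([s in flips[k] for s in order])
        if flip_mask.any():
            sub = block[:, flip_mask]
            sub = np.where(sub == MISSING, MISSING, 2 - sub)
            block[:, flip_mask] = sub
        blocks.append(block)
        sample_frames.append(d.samples)

    return GenotypeMatrix(
        pd.concat(sample_frames, ignore_index=True),
        variants,
        np.concatenate(blocks, axis=0),
    ).sort_variants()
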