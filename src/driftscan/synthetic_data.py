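"""Forward Wright-Fisher simulator with recombination, drift and sweeps.

Populations diverge from a single ancestral allele-frequency pool by pure
drift (no mutation, no migration).  Haplotypes recombine within
chromosomes (Haldane map, configurable cM/Mb) and assort freely between
chromosomes.  An optional locus under positive selection (genotype fitness
1 : 1+s : 1+2s) can be placed in one population.  Output is a phased
:class:`~driftscan.genotype_io.HaplotypeSet` per chromosome plus the
collapsed :class:`~driftscan.genotype_io.GenotypeMatrix` with i.i.d.
missingness, together with a ground-truth record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from driftscan.genotype_io import (
    MISSING,
    GenotypeMatrix,
    HaplotypeSet,
    make_variant_table,
    write_plink_text,
    write_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class SweepSpec:
    """A single positively selected locus in one population."""

    population: int  # index of the target population
    chrom: str
    pos: int  # target position in bp; the nearest simulated SNP is used
    s: float  # selection coefficient per allele copy
    start_generation: int = 0
    initial_freq: float | None = None  # overrides the ancestral draw
    condition_on_fixation: bool = False
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_populations: int = 2
    ne_per_population: int | list[int] = 100
    generations_divergence: int = 20
    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000_000
    n_snps_per_chrom: int = 500
    recomb_rate_cm_per_mb: float = 1.0
    ancestral_freq_distribution: tuple = ("beta", 0.5, 0.5)
    sweep: SweepSpec | None = None
    sample_sizes: list[int] | None = None
    missing_rate: float = 0.0
    population_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.ne_per_population, int):
            self.ne_per_population = [self.ne_per_population] * self.n_populations
        if len(self.ne_per_population) != self.n_populations:
            raise ValueError("ne_per_population length mismatch")
        if self.sample_sizes is None:
            self.sample_sizes = [
                min(30, ne) for ne in self.ne_per_population
            ]
        if len(self.sample_sizes) != self.n_populations:
            raise ValueError("sample_sizes length mismatch")
        for s, ne in zip(self.sample_sizes, self.ne_per_population):
            if s > ne:
                raise ValueError("sample size exceeds Ne")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.population_labels is None:
            self.population_labels = [
                f"pop{k + 1}" for k in range(self.n_populations)
            ]

    @property
    def chrom_names(self) -> list[str]:
        return [str(c + 1) for c in range(self.n_chromosomes)]


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    haplotypes: dict[str, HaplotypeSet]
    truth: dict = field(default_factory=dict)

    @property
    def config(self) -> SimulationConfig:
        return self.truth["config"]


# ---------------------------------------------------------------------------


def _draw_positions(rng: np.random.Generator, cfg: SimulationConfig):
    """Uniform, unique, sorted SNP positions per chromosome."""
    variants = []
    for chrom in cfg.chrom_names:
        want = cfg.n_snps_per_chrom
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp + 1, size=2 * want))
        while pos.size < want:  # collisions are rare at these densities
            extra = rng.integers(1, cfg.chrom_length_bp + 1, size=2 * want)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=want, replace=False))
        for k, p in enumerate(pos):
            variants.append((f"snp_{chrom}_{k}", chrom, int(p), "A", "C"))
    return make_variant_table(variants)


def _ancestral_freqs(rng: np.random.Generator, cfg: SimulationConfig, m: int):
    kind, *params = cfg.ancestral_freq_distribution
    if kind == "beta":
        return rng.beta(params[0], params[1], size=m)
    if kind == "uniform":
        lo, hi = params if params else (0.0, 1.0)
        return rng.uniform(lo, hi, size=m)
    raise ValueError(f"unknown ancestral frequency distribution {kind!r}")


@dataclass
class _GeneticMap:
    """Concatenated genetic map: cumulative Morgans per SNP, chromosome
    index per SNP, and the chromosome count (for free assortment)."""

    cum_morgans: np.ndarray
    chrom_idx: np.ndarray
    n_chrom: int

    @property
    def total_morgans(self) -> float:
        return float(self.cum_morgans[-1])


def _genetic_map(variants: pd.DataFrame, rate_cm_per_mb: float) -> _GeneticMap:
    pos = variants["pos"].to_numpy(dtype=float)
    chrom = variants["chrom"].to_numpy()
    d_bp = np.diff(pos, prepend=pos[0])
    morgans = d_bp * rate_cm_per_mb / 1e8
    new_chrom = np.empty(len(pos), dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    morgans[new_chrom] = 0.0  # chromosome junctions carry no map length
    chrom_idx = np.cumsum(new_chrom) - 1
    return _GeneticMap(np.cumsum(morgans), chrom_idx, int(chrom_idx[-1]) + 1)


def _make_gametes(rng, parent_haps: np.ndarray, parent_idx: np.ndarray,
                  gmap: _GeneticMap):
    """One recombinant gamete per entry of ``parent_idx``.

    ``parent_haps`` is (2*Ne, M); gamete g recombines rows 2*p, 2*p+1.
    Crossovers are Poisson on the genetic map (Haldane model, exact
    interval parity), chromosomes assort freely via independent phases.
    """
    h0 = parent_haps[2 * parent_idx]
    h1 = parent_haps[2 * parent_idx + 1]
    g = len(parent_idx)
    m = parent_haps.shape[1]
    counts = np.zeros((g, m), dtype=np.uint8)
    total = gmap.total_morgans
    if total > 0:
        n_x = rng.poisson(total, size=g)
        u = rng.random(n_x.sum()) * total
        idx = np.searchsorted(gmap.cum_morgans, u, side="left")
        rows = np.repeat(np.arange(g), n_x)
        keep = idx < m
        np.add.at(counts, (rows[keep], idx[keep]), 1)
    phases = rng.integers(0, 2, size=(g, gmap.n_chrom), dtype=np.uint8)
    # uint8 cumsum wraps mod 256 (even), so crossover parity is preserved
    switch = counts.cumsum(axis=1, dtype=np.uint8)
    switch += phases[:, gmap.chrom_idx]
    switch &= 1
    return (h0 ^ ((h0 ^ h1) & switch)).astype(np.uint8)


def _evolve_population(
    rng, haps: np.ndarray, ne: int, generations: int, gmap: _GeneticMap,
    sweep_col: int | None, s: float, start_generation: int,
) -> np.ndarray:
    for gen in range(generations):
        if sweep_col is not None and gen >= start_generation and s > 0:
            dosage = haps[0::2, sweep_col].astype(float) + haps[1::2, sweep_col]
            w = 1.0 + s * dosage
            p = w / w.sum()
            parents = rng.choice(ne, size=2 * ne, p=p)
        else:
            parents = rng.integers(0, ne, size=2 * ne)
        haps = _make_gametes(rng, haps, parents, gmap)
    return haps


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the forward simulation described in the module docstring."""
    attempt = 0
    while True:
        # widely spaced retry seeds so replicate series (seed, seed+1, ...)
        # cannot collide on the same successful attempt
        ds = _simulate_once(config, config.seed + attempt * 1_000_003)
        if config.sweep is None or not config.sweep.condition_on_fixation:
            return ds
        if ds.truth["sweep"]["final_freq_target_pop"] == 1.0:
            if attempt:
                logger.info("sweep fixed after %d resimulations", attempt)
            return ds
        attempt += 1
        if attempt > config.sweep.max_retries:
            raise RuntimeError(
                f"sweep failed to fix in {config.sweep.max_retries} retries"
            )


def _simulate_once(cfg: SimulationConfig, seed: int) -> SimulatedDataset:
    rng = np.random.default_rng(seed)
    variants = _draw_positions(rng, cfg)
    m = len(variants)
    freqs = _ancestral_freqs(rng, cfg, m)

    sweep_col = None
    if cfg.sweep is not None:
        on_chrom = np.flatnonzero((variants["chrom"] == cfg.sweep.chrom).to_numpy())
        if on_chrom.size == 0:
            raise ValueError(f"sweep chromosome {cfg.sweep.chrom!r} not simulated")
        pos = variants["pos"].to_numpy()[on_chrom]
        sweep_col = int(on_chrom[np.argmin(np.abs(pos - cfg.sweep.pos))])
        if cfg.sweep.initial_freq is not None:
            freqs[sweep_col] = cfg.sweep.initial_freq

    gmap = _genetic_map(variants, cfg.recomb_rate_cm_per_mb)

    sample_frames, dosage_blocks = [], []
    hap_blocks = []  # (haplos 2S x M, sample ids)
    sweep_final = {}
    for k in range(cfg.n_populations):
        ne = cfg.ne_per_population[k]
        # founders drawn from the shared ancestral pool (linkage equilibrium)
        haps = (rng.random((2 * ne, m)) < freqs[None, :]).astype(np.uint8)
        is_target = cfg.sweep is not None and cfg.sweep.population == k
        haps = _evolve_population(
            rng, haps, ne, cfg.generations_divergence, gmap,
            sweep_col if is_target else None,
            cfg.sweep.s if is_target else 0.0,
            cfg.sweep.start_generation if is_target else 0,
        )
        if sweep_col is not None:
            sweep_final[cfg.population_labels[k]] = float(
                haps[:, sweep_col].mean()
            )
        chosen = np.sort(rng.choice(ne, size=cfg.sample_sizes[k], replace=False))
        ids = [f"{cfg.population_labels[k]}_{i:03d}" for i in range(len(chosen))]
        hap_idx = np.stack([2 * chosen, 2 * chosen + 1], axis=1).ravel()
        sampled = haps[hap_idx]
        hap_blocks.append((sampled, ids))
        dosage_blocks.append(
            (sampled[0::2].astype(np.int8) + sampled[1::2]).astype(np.int8)
        )
        sample_frames.append(
            pd.DataFrame(
                {"sample_id": ids, "population": cfg.population_labels[k]}
            )
        )

    dosage = np.concatenate(dosage_blocks, axis=0)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage = np.where(mask, MISSING, dosage).astype(np.int8)

    samples = pd.concat(sample_frames, ignore_index=True)
    genotypes = GenotypeMatrix(samples, variants, dosage)

    all_haps = np.concatenate([h for h, _ in hap_blocks], axis=0)
    sample_of_hap = [s for _, ids in hap_blocks for s in ids for _ in range(2)]
    haplotypes = {}
    for chrom in cfg.chrom_names:
        idx = np.flatnonzero((variants["chrom"] == chrom).to_numpy())
        haplotypes[chrom] = HaplotypeSet(
            variants.iloc[idx], all_haps[:, idx], sample_of_hap
        )

    truth = {
        "config": cfg,
        "seed_used": seed,
        "true_ne": list(cfg.ne_per_population),
        "divergence_generations": cfg.generations_divergence,
        "pedigree": {},
        "sweep": None,
    }
    if cfg.sweep is not None:
        truth["sweep"] = {
            "snp_id": variants["snp_id"].iat[sweep_col],
            "chrom": cfg.sweep.chrom,
            "pos": int(variants["pos"].iat[sweep_col]),
            "s": cfg.sweep.s,
            "population": cfg.population_labels[cfg.sweep.population],
            "final_freq_target_pop": sweep_final[
                cfg.population_labels[cfg.sweep.population]
            ],
            "final_freqs": sweep_final,
        }
    return SimulatedDataset(genotypes, haplotypes, truth)


# ---------------------------------------------------------------------------
# Planted relatives
# ---------------------------------------------------------------------------


def plant_relatives(
    dataset: SimulatedDataset, specs: list[dict], seed: int = 0
) -> SimulatedDataset:
    """Add individuals by Mendelian transmission from named parents.

    Each spec is ``{"child_id": ..., "parent1": ..., "parent2": ...}``.
    With ``parent2`` absent or None the child is an exact copy of
    ``parent1`` (a planted duplicate).  Children may themselves be parents
    of later specs, so e.g. full-sib matings can be composed.
    """
    rng = np.random.default_rng(seed)
    g = dataset.genotypes
    cfg = dataset.config
    known = set(g.samples["sample_id"])
    haplotypes = {c: hs for c, hs in dataset.haplotypes.items()}
    new_samples = []
    pedigree = dict(dataset.truth.get("pedigree", {}))

    variants = g.variants
    gmap = _genetic_map(variants, cfg.recomb_rate_cm_per_mb)

    # current haplotypes as one 2N x M array in variant order
    order_cols = {c: np.flatnonzero((variants["chrom"] == c).to_numpy())
                  for c in haplotypes}
    hap_rows = {}
    for c, hs in haplotypes.items():
        for h, s in enumerate(hs.sample_of_haplotype):
            hap_rows.setdefault(s, {}).setdefault(c, []).append(h)

    def sample_haps(sample_id):
        out = np.empty((2, len(variants)), dtype=np.uint8)
        for c, hs in haplotypes.items():
            rows = hap_rows[sample_id][c]
            out[:, order_cols[c]] = hs.haplos[rows, :]
        return out

    added = {}
    for spec in specs:
        child = spec["child_id"]
        p1 = spec["parent1"]
        p2 = spec.get("parent2")
        if child in known:
            raise ValueError(f"child id {child!r} already present")
        for p in (p1, p2):
            if p is not None and p not in known and p not in added:
                raise ValueError(f"unknown parent id {p!r}")

        def get(sid):
            return added[sid] if sid in added else sample_haps(sid)

        if p2 is None:
            child_haps = get(p1).copy()
        else:
            g1 = _make_gametes(rng, get(p1), np.array([0]), gmap)[0]
            g2 = _make_gametes(rng, get(p2), np.array([0]), gmap)[0]
            child_haps = np.stack([g1, g2])
        added[child] = child_haps
        known.add(child)
        pedigree[child] = {"parent1": p1, "parent2": p2}
        pop = g.samples.loc[g.samples["sample_id"] == p1, "population"]
        pop_label = pop.iloc[0] if len(pop) else "planted"
        new_samples.append({"sample_id": child, "population": pop_label})

    if not added:
        return dataset

    new_ids = [s["sample_id"] for s in new_samples]
    new_haps = np.concatenate([added[s] for s in new_ids], axis=0)
    new_dosage = (new_haps[0::2].astype(np.int8) + new_haps[1::2]).astype(np.int8)

    genotypes = GenotypeMatrix(
        pd.concat([g.samples, pd.DataFrame(new_samples)], ignore_index=True),
        variants,
        np.concatenate([g.dosage, new_dosage], axis=0),
    )
    new_hapsets = {}
    for c, hs in haplotypes.items():
        extra_sample_of = [s for s in new_ids for _ in range(2)]
        new_hapsets[c] = HaplotypeSet(
            hs.variants,
            np.concatenate([hs.haplos, new_haps[:, order_cols[c]]], axis=0),
            hs.sample_of_haplotype + extra_sample_of,
        )
    truth = dict(dataset.truth)
    truth["pedigree"] = pedigree
    return SimulatedDataset(genotypes, new_hapsets, truth)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export(dataset: SimulatedDataset, out_dir, fmt: str = "plink_text",
           prefix: str = "sim") -> dict:
    """Write the dataset to disk; returns the path map.

    Formats: ``plink_text`` (PED/MAP) and ``vcf_phased``.  A truth JSON is
    always written alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if fmt == "plink_text":
        ped, mp = out_dir / f"{prefix}.ped", out_dir / f"{prefix}.map"
        write_plink_text(dataset.genotypes, ped, mp)
        paths.update(ped=str(ped), map=str(mp))
    elif fmt == "vcf_phased":
        if (dataset.genotypes.dosage == MISSING).any():
            raise ValueError(
                "phased VCF export requires fully called genotypes "
                "(missing_rate must be 0)"
            )
        vcf = out_dir / f"{prefix}.vcf"
        write_vcf(vcf, dataset.genotypes, haplotypes=dataset.haplotypes)
        paths["vcf"] = str(vcf)
    else:
        raise ValueError(f"unknown export format {fmt!r}")

    truth = {k: v for k, v in dataset.truth.items() if k != "config"}
    cfg = dataset.config
    truth["parameters"] = {
        "seed": cfg.seed,
        "n_populations": cfg.n_populations,
        "ne_per_population": cfg.ne_per_population,
        "generations_divergence": cfg.generations_divergence,
        "n_chromosomes": cfg.n_chromosomes,
        "chrom_length_bp": cfg.chrom_length_bp,
        "n_snps_per_chrom": cfg.n_snps_per_chrom,
        "recomb_rate_cm_per_mb": cfg.recomb_rate_cm_per_mb,
        "sample_sizes": cfg.sample_sizes,
        "missing_rate": cfg.missing_rate,
    }
    truth_path = out_dir / f"{prefix}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    paths["truth"] = str(truth_path)
    return paths
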