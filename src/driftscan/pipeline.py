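"""End-to-end orchestration of the analysis workflow.

Stages: simulate/load -> QC -> diversity -> structure -> Ne -> ROH ->
pairwise selection scans -> annotation, driven by one config with a
single master seed fanned out per stage by stable hashing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from driftscan import annotation as annot
from driftscan import diversity, ne_estimation, qc, roh, structure
from driftscan import selection_scan as scan
from driftscan import synthetic_data as synth
from driftscan.genotype_io import GenotypeMatrix, HaplotypeSet

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass
class PipelineConfig:
    out_dir: str = "driftscan_out"
    seed: int = 0
    # input: either files or a simulation block
    ped: str | None = None
    map: str | None = None
    vcf: str | None = None
    simulate: dict | None = None
    # QC thresholds (paper defaults)
    min_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6
    max_pi_hat: float = 0.25
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_pca: float = 0.5
    ld_r2_relatedness: float = 0.3
    roh_params: dict = field(default_factory=dict)
    lof_threshold: float = 1.5
    lof_neighbors: int = 20
    flank_bp: int = 40_000
    fdr_q: float = 0.05
    features: str | None = None
    gene_sets: str | None = None
    scan_both_orientations: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        has_files = (self.ped and self.map) or self.vcf
        if not has_files and self.simulate is None:
            raise ValueError(
                "config must define input files (ped+map or vcf) or a "
                "'simulate' block"
            )
        for key in ("ped", "map", "vcf", "features", "gene_sets"):
            path = getattr(self, key)
            if path and not Path(path).exists():
                raise ValueError(f"config field {key!r}: {path} does not exist")


def _load_input(cfg: PipelineConfig):
    """Returns (GenotypeMatrix, haplotypes-or-None)."""
    if cfg.simulate is not None:
        sim_cfg_kwargs = dict(cfg.simulate)
        sweep = sim_cfg_kwargs.pop("sweep", None)
        if sweep is not None:
            sweep = synth.SweepSpec(**sweep)
        sim_cfg_kwargs.setdefault("seed", stage_seed(cfg.seed, "simulate"))
        sim = synth.simulate(
            synth.SimulationConfig(sweep=sweep, **sim_cfg_kwargs)
        )
        return sim.genotypes, sim.haplotypes
    if cfg.vcf:
        from driftscan.genotype_io import read_vcf

        try:
            haps = read_vcf(cfg.vcf, require_phased=True)
            variants = pd.concat([h.variants for h in haps.values()])
            first = next(iter(haps.values()))
            ids, _ = first.dosage()
            dosages = [h.dosage()[1] for h in haps.values()]
            g = GenotypeMatrix(
                pd.DataFrame({"sample_id": ids, "population": "pop"}),
                variants,
                np.concatenate(dosages, axis=1),
            )
            return g, haps
        except Exception:
            return read_vcf(cfg.vcf, require_phased=False), None
    from driftscan.genotype_io import read_plink_text

    return read_plink_text(cfg.ped, cfg.map), None


def _subset_haplotypes(haplotypes, g: GenotypeMatrix):
    if haplotypes is None:
        return None
    ids = set(g.samples["sample_id"])
    snp_keep = set(g.variants["snp_id"])
    out = {}
    for chrom, hs in haplotypes.items():
        cols = np.flatnonzero(hs.variants["snp_id"].isin(snp_keep).to_numpy())
        if cols.size == 0:
            continue
        sub = hs.subset_samples([s for s in hs.sample_ids if s in ids])
        out[chrom] = HaplotypeSet(
            sub.variants.iloc[cols], sub.haplos[:, cols], sub.sample_of_haplotype
        )
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; writes tables under ``cfg.out_dir`` and returns
    the manifest (also written as JSON)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "seed": cfg.seed, "config": asdict(cfg)}

    def stage(name):
        manifest["stages"].append({"name": name, "t_start": time.time()})
        logger.info("stage: %s", name)

    def done(**info):
        manifest["stages"][-1]["t_elapsed"] = (
            time.time() - manifest["stages"][-1].pop("t_start")
        )
        manifest["stages"][-1].update(info)

    stage("load")
    g, haplotypes = _load_input(cfg)
    done(n_samples=g.n_samples, n_snps=g.n_variants)

    stage("qc")
    g_qc, reports = qc.run_qc(
        g, cfg.min_call_rate, cfg.min_maf, cfg.hwe_alpha, cfg.max_pi_hat
    )
    pd.concat([r.to_frame() for r in reports]).to_csv(
        out / "qc_report.tsv", sep="\t", index=False
    )
    done(n_samples=g_qc.n_samples, n_snps=g_qc.n_variants)

    stage("diversity")
    pops = g_qc.populations
    for metric in ("chord", "reynolds", "afd_mean", "fst"):
        diversity.distance_matrix(g_qc, metric=metric).to_csv(
            out / f"distance_{metric}.tsv", sep="\t"
        )
    fst_rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            theta, lo, hi = diversity.pairwise_fst_multilocus(
                g_qc, a, b, seed=stage_seed(cfg.seed, f"fst:{a}:{b}")
            )
            fst_rows.append(
                {"pop1": a, "pop2": b, "fst": theta, "ci_low": lo, "ci_high": hi}
            )
    pd.DataFrame(fst_rows).to_csv(out / "pairwise_fst.tsv", sep="\t", index=False)
    curve = diversity.ld_decay_curve(g_qc, max_pairs_per_chrom=200_000,
                                     seed=stage_seed(cfg.seed, "ld_decay"))
    curve.to_csv(out / "ld_decay.tsv", sep="\t", index=False)
    done(n_pairs=len(fst_rows))

    stage("structure")
    g_pruned, _ = qc.ld_prune(g_qc, cfg.ld_window, cfg.ld_step, cfg.ld_r2_pca)
    g_clean, outliers = structure.remove_outliers(
        g_pruned, k_neighbors=cfg.lof_neighbors, threshold=cfg.lof_threshold
    )
    outliers.to_csv(out / "outliers.tsv", sep="\t", index=False)
    k = min(10, g_clean.n_samples - 1, g_clean.n_variants)
    pca_res = structure.pca(g_clean, k=k)
    pd.DataFrame(
        pca_res.scores,
        index=pca_res.sample_ids,
        columns=[f"PC{i + 1}" for i in range(pca_res.scores.shape[1])],
    ).to_csv(out / "pca_scores.tsv", sep="\t")
    diss = structure.ibs_dissimilarity(g_clean)
    tree = structure.hierarchical_tree(diss, list(g_clean.samples["sample_id"]))
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    # drop flagged outliers from the full matrix for downstream stages
    flagged = set(outliers.loc[outliers["flagged"], "sample_id"])
    keep = ~g_qc.samples["sample_id"].isin(flagged).to_numpy()
    g_qc = g_qc.take_samples(np.flatnonzero(keep))
    haplotypes = _subset_haplotypes(haplotypes, g_qc)
    done(n_outliers=int(outliers["flagged"].sum()))

    stage("ne")
    ne_frames = []
    for pop in pops:
        try:
            ne_frames.append(ne_estimation.ldne_maf_screens(g_qc, pop))
        except ValueError as exc:
            logger.warning("Ne for %s skipped: %s", pop, exc)
    if ne_frames:
        pd.concat(ne_frames).to_csv(out / "ne_contemporary.tsv", sep="\t",
                                    index=False)
    hist_rows = []
    for pop in pops:
        for pt in ne_estimation.historical_ne(g_qc, pop):
            hist_rows.append({"population": pop, **asdict(pt)})
    pd.DataFrame(hist_rows).to_csv(out / "ne_historical.tsv", sep="\t",
                                   index=False)
    done()

    stage("roh")
    params = roh.ROHParams(**cfg.roh_params)
    all_segments = []
    peak_rows = []
    for pop in pops:
        g_pop = g_qc.take_samples(g_qc.population_index(pop))
        segments = roh.detect_roh_all(g_pop, params)
        all_segments.extend(segments)
        res = roh.roh_incidence_peaks(
            segments, g_pop.variants, list(g_pop.samples["sample_id"])
        )
        for pk in res.peaks:
            peak_rows.append({"population": pop, **asdict(pk)})
    roh.segments_to_frame(all_segments).to_csv(
        out / "roh_segments.tsv", sep="\t", index=False
    )
    roh.froh_per_sample(g_qc, all_segments).to_csv(
        out / "froh.tsv", sep="\t", index=False
    )
    roh.length_class_summary(all_segments).to_csv(
        out / "roh_length_classes.tsv", sep="\t", index=False
    )
    pd.DataFrame(peak_rows).to_csv(out / "roh_peaks.tsv", sep="\t", index=False)
    done(n_segments=len(all_segments))

    stage("scan")
    scan_info = {}
    if haplotypes is not None and len(pops) >= 2:
        ordered_pairs = []
        for i, a in enumerate(pops):
            for b in pops[i + 1 :]:
                ordered_pairs.append((a, b))
                if cfg.scan_both_orientations:
                    ordered_pairs.append((b, a))
        for a, b in ordered_pairs:
            ids_a = set(
                g_qc.samples.loc[g_qc.samples["population"] == a, "sample_id"]
            )
            ids_b = set(
                g_qc.samples.loc[g_qc.samples["population"] == b, "sample_id"]
            )
            haps_a = {
                c: h.subset_samples([s for s in h.sample_ids if s in ids_a])
                for c, h in haplotypes.items()
            }
            haps_b = {
                c: h.subset_samples([s for s in h.sample_ids if s in ids_b])
                for c, h in haplotypes.items()
            }
            result = scan.run_pairwise_scan(
                g_qc, haps_a, haps_b, a, b,
                scan.ScanConfig(
                    seed=stage_seed(cfg.seed, f"scan:{a}:{b}"),
                    fdr_q=cfg.fdr_q,
                ),
            )
            name = f"scan_{a}_vs_{b}"
            result.table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
            scan_info[name] = int(result.table["significant"].sum())
            if cfg.features:
                feats = (
                    annot.read_gff3(cfg.features)
                    if str(cfg.features).endswith((".gff", ".gff3"))
                    else annot.read_bed(cfg.features)
                )
                hits = annot.annotate_scan(result.table, feats, cfg.flank_bp)
                hits.to_csv(out / f"{name}_annotation.tsv", sep="\t", index=False)
    else:
        logger.warning("scan skipped: phased haplotypes unavailable")
    done(**scan_info)

    manifest["parameter_hash"] = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    return manifest


def make_demo(out_dir, seed: int = 0) -> dict:
    """Generate the documented 4-population tutorial dataset (sample sizes
    21/29/67/52) plus its truth record; returns export paths."""
    cfg = synth.SimulationConfig(
        seed=seed,
        n_populations=4,
        ne_per_population=[80, 80, 100, 100],
        generations_divergence=30,
        n_chromosomes=3,
        chrom_length_bp=30_000_000,
        n_snps_per_chrom=400,
        sample_sizes=[21, 29, 67, 52],
        missing_rate=0.01,
    )
    sim = synth.simulate(cfg)
    return synth.export(sim, out_dir, fmt="plink_text", prefix="demo")
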