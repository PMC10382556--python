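"""Interval annotation of significant SNPs and gene-set enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

FEATURE_COLUMNS = ["feature_id", "chrom", "start_bp", "end_bp", "feature_class"]


def read_bed(path, feature_class: str = "gene") -> pd.DataFrame:
    """Read BED (0-based half-open) into 1-based inclusive features."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            rows.append((name, f[0], int(f[1]) + 1, int(f[2]), feature_class))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def read_gff3(path, feature_types=("gene",)) -> pd.DataFrame:
    """Read GFF3 (already 1-based inclusive); keeps the listed types."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("Name") or f"{f[0]}:{f[3]}-{f[4]}"
            rows.append((name, f[0], int(f[3]), int(f[4]), f[2]))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def merge_significant_intervals(
    variants: pd.DataFrame, significant: np.ndarray
) -> pd.DataFrame:
    """Merge runs of map-consecutive significant SNPs into intervals.

    ``variants`` must be (chrom, pos)-sorted as produced by the scan;
    singleton significant SNPs become point intervals.
    """
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    sig = np.asarray(significant, dtype=bool)
    rows = []
    j = 0
    while j < len(sig):
        if not sig[j]:
            j += 1
            continue
        k = j
        while k + 1 < len(sig) and sig[k + 1] and chroms[k + 1] == chroms[j]:
            k += 1
        rows.append(
            {
                "chrom": str(chroms[j]),
                "start_bp": int(pos[j]),
                "end_bp": int(pos[k]),
                "n_snps": k - j + 1,
            }
        )
        j = k + 1
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_snps"])


def overlap_features(
    intervals: pd.DataFrame, features: pd.DataFrame, flank_bp: int = 40_000
) -> pd.DataFrame:
    """Intervals x features hits with a symmetric flank on the features.

    An interval hits a feature iff it intersects
    [start - flank, end + flank] (1-based inclusive).
    """
    rows = []
    for iv in intervals.itertuples():
        on_chrom = features[features["chrom"].astype(str) == str(iv.chrom)]
        lo = on_chrom["start_bp"].to_numpy() - flank_bp
        hi = on_chrom["end_bp"].to_numpy() + flank_bp
        hit = (iv.end_bp >= lo) & (iv.start_bp <= hi)
        for _, feat in on_chrom[hit].iterrows():
            rows.append(
                {
                    "chrom": iv.chrom,
                    "interval_start": iv.start_bp,
                    "interval_end": iv.end_bp,
                    "feature_id": feat["feature_id"],
                    "feature_class": feat["feature_class"],
                    "feature_start": feat["start_bp"],
                    "feature_end": feat["end_bp"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "interval_start", "interval_end", "feature_id",
            "feature_class", "feature_start", "feature_end",
        ],
    )


def annotate_scan(
    scan_table: pd.DataFrame, features: pd.DataFrame, flank_bp: int = 40_000
) -> pd.DataFrame:
    """Convenience wrapper: merge significant SNPs then overlap features."""
    intervals = merge_significant_intervals(
        scan_table[["chrom", "pos"]],
        scan_table["significant"].fillna(False).to_numpy(dtype=bool),
    )
    return overlap_features(intervals, features, flank_bp)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment(
    hit_genes: set[str],
    universe_genes: set[str],
    gene_sets: dict[str, set[str]],
    min_hits: int = 2,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per gene set with BH FDR.

    Sets are intersected with the universe; sets with fewer than
    ``min_hits`` hit genes are skipped.
    """
    from driftscan.selection_scan import bh_fdr

    if not universe_genes:
        raise ValueError("empty universe")
    if not hit_genes <= universe_genes:
        raise ValueError("hit genes must be a subset of the universe")
    m = len(universe_genes)
    n_draw = len(hit_genes)
    rows = []
    for set_id, genes in gene_sets.items():
        genes = genes & universe_genes
        if not genes:
            continue
        k = len(hit_genes & genes)
        if k < min_hits:
            continue
        p = float(hypergeom.sf(k - 1, m, len(genes), n_draw))
        rows.append(
            {
                "set_id": set_id,
                "set_size": len(genes),
                "n_hits": k,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows, columns=["set_id", "set_size", "n_hits", "p_value"]
    )
    if len(result):
        q, sig = bh_fdr(result["p_value"].to_numpy(), q_threshold)
        result["q_value"] = q
        result["significant"] = sig
    else:
        result["q_value"] = []
        result["significant"] = []
    return result


def read_gene_sets(path) -> dict[str, set[str]]:
    """Two-column TSV (set_id, gene_id) -> mapping of sets to genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            set_id, gene_id = line.split()[:2]
            sets.setdefault(set_id, set()).add(gene_id)
    return sets
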