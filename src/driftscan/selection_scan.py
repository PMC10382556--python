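"""Composite selection scan: FST, FLK, xp-EHH combined by DCMS.

Pipeline per population pair: per-SNP Weir-Cockerham theta; FLK against a
tree-derived kinship (neighbor-joining on coancestry distances); xp-EHH
from phased haplotypes; right-tailed fractional-rank p-values; a robust
(MCD) correlation of the three statistics; the de-correlated composite
DCMS; robust-normal calibration of the composite to p-values; and
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from driftscan.diversity import (
    AlleleFrequencyTable,
    allele_frequencies,
    per_snp_wc_fst,
    reynolds_distance,
    zfst,
)
from driftscan.genotype_io import GenotypeMatrix, HaplotypeSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Population tree and kinship
# ---------------------------------------------------------------------------

@dataclass
class PopulationTree:
    """Rooted population tree; kinship is derived from root-to-leaf paths."""

    labels: list[str]
    #: root-to-leaf shared branch length for each pair (the kinship core);
    #: diagonal holds the full root-to-leaf path length.
    shared_path: np.ndarray
    newick: str = ""


def build_population_tree(
    distances: pd.DataFrame, drift_scale: float = 2.0
) -> PopulationTree:
    """Neighbor-joining tree from a population distance matrix.

    ``drift_scale`` multiplies the distances before branch apportioning:
    a pairwise coancestry distance estimates the *mean* of the two
    root-to-leaf drift branches, so recovering additive per-branch drift
    requires a factor 2 (the default).  With ``drift_scale=1`` two
    populations at distance d get two branches of d/2.

    For two populations the single edge is split equally at a midpoint
    root; larger trees are midpoint-rooted after standard NJ with negative
    branch lengths clipped to zero.
    """
    labels = list(distances.index)
    d = np.asarray(distances, dtype=float) * drift_scale
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 populations")
    if n == 2:
        half = d[0, 1] / 2.0
        shared = np.array([[half, 0.0], [0.0, half]])
        newick = f"({labels[0]}:{half:.10g},{labels[1]}:{half:.10g});"
        return PopulationTree(labels, shared, newick)

    import io

    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    tree = nj(SkbioDM(d, ids=labels))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            logger.info("clipping negative branch length %.4g", node.length)
            node.length = 0.0
    tree = tree.root_at_midpoint()
    leaves = {leaf.name: leaf for leaf in tree.tips()}

    def depth_to_root(node):
        total = 0.0
        while node.parent is not None:
            total += node.length or 0.0
            node = node.parent
        return total

    shared = np.zeros((n, n))
    for i, a in enumerate(labels):
        shared[i, i] = depth_to_root(leaves[a])
        for j in range(i + 1, n):
            lca = tree.lowest_common_ancestor([labels[i], labels[j]])
            shared[i, j] = shared[j, i] = depth_to_root(lca)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return PopulationTree(labels, shared, buf.getvalue().strip())


def kinship_from_tree(
    tree: PopulationTree, transform: str = "linear"
) -> pd.DataFrame:
    """Kinship F per population pair from shared root-to-leaf paths.

    ``linear``: F_ij is the shared branch length itself.  ``drift``:
    F_ij = 1 - exp(-shared length) — branch lengths built from
    -ln(1 - theta) distances are additive on the log scale, so this maps
    them back to the coancestry (variance) scale; the FLK null requires
    it for calibration.
    """
    path = tree.shared_path
    if transform == "drift":
        path = 1.0 - np.exp(-path)
    elif transform != "linear":
        raise ValueError(f"unknown transform {transform!r}")
    f = pd.DataFrame(path, index=tree.labels, columns=tree.labels)
    eig = np.linalg.eigvalsh(f.to_numpy())
    if eig.min() < -1e-8:
        raise ValueError("kinship matrix is not positive semidefinite")
    return f


# ---------------------------------------------------------------------------
# FLK
# ---------------------------------------------------------------------------

def flk_test(p: np.ndarray, kinship: pd.DataFrame):
    """FLK statistic and chi-square p-value for one SNP.

    ``p`` holds the allele frequency per population in kinship order.
    Returns (nan, nan) when the ancestral estimate p0 is 0 or 1.
    """
    stat, pval = flk_scan(np.asarray(p, dtype=float)[:, None], kinship)
    return float(stat[0]), float(pval[0])


def flk_scan(p: np.ndarray, kinship: pd.DataFrame):
    """Vectorized FLK over SNP columns of ``p`` (n_pop x M)."""
    f = kinship.to_numpy()
    n_pop = f.shape[0]
    try:
        finv = np.linalg.inv(f)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular kinship (cond={np.linalg.cond(f):.3g})"
        ) from exc
    ones = np.ones(n_pop)
    w = finv @ ones
    denom = ones @ w
    p0 = (w @ p) / denom
    d = p - p0[None, :]
    quad = np.einsum("im,ij,jm->m", d, finv, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = quad / (p0 * (1.0 - p0))
    bad = ~np.isfinite(p).all(axis=0) | (p0 <= 0) | (p0 >= 1)
    stat = np.where(bad, np.nan, stat)
    pval = np.where(np.isnan(stat), np.nan, chi2.sf(stat, df=n_pop - 1))
    return stat, pval


def flk_kinship_for_pair(
    freqs: AlleleFrequencyTable, pop1: str, pop2: str
) -> pd.DataFrame:
    """2x2 kinship for a pairwise FLK from the plug-in coancestry distance.

    The plug-in (no sample-size correction) variant is used so that the
    binomial sampling noise of the observed frequencies is absorbed into
    the kinship, keeping the null statistic chi-square calibrated.
    """
    d = reynolds_distance(freqs, pop1, pop2, sample_correction=False)
    tree = build_population_tree(
        pd.DataFrame(
            [[0.0, d], [d, 0.0]], index=[pop1, pop2], columns=[pop1, pop2]
        ),
        drift_scale=2.0,
    )
    return kinship_from_tree(tree, transform="drift")


# ---------------------------------------------------------------------------
# EHH / iHH / xp-EHH
# ---------------------------------------------------------------------------

def ehh(haplos: np.ndarray, core: int, direction: int):
    """EHH profile from a core marker outwards over phased haplotypes.

    ``haplos`` is n x M binary; ``direction`` +1 (right) or -1 (left).
    Entry k of the result is EHH at the k-th marker from the core
    (entry 0 = 1 at the core itself); haplotypes are grouped by identity
    over the closed interval core..x, unpolarized.
    """
    n, m = haplos.shape
    if n < 4:
        raise ValueError("need >= 4 haplotypes")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    pair_total = n * (n - 1) / 2.0
    groups = np.zeros(n, dtype=np.int64)
    out = [1.0]
    idx = core
    while True:
        idx += direction
        if idx < 0 or idx >= m:
            break
        key = groups * 2 + haplos[:, idx]
        if idx == core + direction:  # first step also splits on the core allele
            key = key * 2 + haplos[:, core]
        _, groups = np.unique(key, return_inverse=True)
        counts = np.bincount(groups)
        out.append(float((counts * (counts - 1) / 2.0).sum() / pair_total))
    return np.array(out)


def _ihh_one_side(haplos, positions, core, direction, cutoff, max_gap_bp):
    """Trapezoidal integral of EHH to the truncation point on one side.

    Returns (ihh, reason); reason is None on success, otherwise a string
    ('no_truncation' when EHH never drops below the cutoff before the
    chromosome end, 'gap' when consecutive markers are too far apart).
    """
    n, m = haplos.shape
    pair_total = n * (n - 1) / 2.0
    groups = np.zeros(n, dtype=np.int64)
    prev_ehh = 1.0
    total = 0.0
    idx = core
    first = True
    while True:
        nxt = idx + direction
        if nxt < 0 or nxt >= m:
            return None, "no_truncation"
        gap = abs(positions[nxt] - positions[idx])
        if gap > max_gap_bp:
            return None, "gap"
        key = groups * 2 + haplos[:, nxt]
        if first:
            key = key * 2 + haplos[:, core]
            first = False
        _, groups = np.unique(key, return_inverse=True)
        counts = np.bincount(groups)
        cur = float((counts * (counts - 1) / 2.0).sum() / pair_total)
        total += 0.5 * (prev_ehh + cur) * gap
        if cur < cutoff:
            return total, None
        prev_ehh = cur
        idx = nxt


def ihh(haplos, positions, core, cutoff=0.05, max_gap_bp=200_000):
    """Integrated EHH (both sides); (value, None) or (nan, reason)."""
    left, why_l = _ihh_one_side(haplos, positions, core, -1, cutoff, max_gap_bp)
    if left is None:
        return float("nan"), why_l
    right, why_r = _ihh_one_side(haplos, positions, core, +1, cutoff, max_gap_bp)
    if right is None:
        return float("nan"), why_r
    return left + right, None


def xpehh(
    hap_a: HaplotypeSet,
    hap_b: HaplotypeSet,
    core: int,
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
) -> float:
    """Raw xp-EHH = ln(iHH_A / iHH_B) at one core SNP (nan if excluded)."""
    pos = hap_a.positions()
    ihh_a, _ = ihh(hap_a.haplos, pos, core, cutoff, max_gap_bp)
    ihh_b, _ = ihh(hap_b.haplos, hap_b.positions(), core, cutoff, max_gap_bp)
    if not np.isfinite(ihh_a) or not np.isfinite(ihh_b):
        return float("nan")
    if ihh_a <= 0 or ihh_b <= 0:
        return float("nan")
    return float(np.log(ihh_a / ihh_b))


def xpehh_scan(
    haplotypes_a: dict[str, HaplotypeSet],
    haplotypes_b: dict[str, HaplotypeSet],
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
) -> pd.DataFrame:
    """Raw xp-EHH for every SNP of every shared chromosome."""
    rows = []
    for chrom, ha in haplotypes_a.items():
        hb = haplotypes_b.get(chrom)
        if hb is None:
            continue
        if not ha.variants["snp_id"].equals(hb.variants["snp_id"]):
            raise ValueError(f"variant maps differ on chromosome {chrom}")
        for core in range(len(ha.variants)):
            rows.append(
                {
                    "snp_id": ha.variants["snp_id"].iat[core],
                    "xpehh_raw": xpehh(ha, hb, core, cutoff, max_gap_bp),
                }
            )
    return pd.DataFrame(rows)


def standardize_xpehh(raw: np.ndarray) -> np.ndarray:
    """Genomewide z-standardization over defined scores."""
    return zfst(np.asarray(raw, dtype=float))


# ---------------------------------------------------------------------------
# DCMS machinery
# ---------------------------------------------------------------------------

def fractional_rank_pvalues(stat: np.ndarray, tail: str = "right") -> np.ndarray:
    """p_i = descending-rank/(n+1); strictly inside (0, 1), ties averaged."""
    x = np.asarray(stat, dtype=float)
    if np.isnan(x).any():
        raise ValueError("undefined statistics must be excluded before ranking")
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 values")
    if tail == "right":
        ranks = rankdata(-x, method="average")
    elif tail == "left":
        ranks = rankdata(x, method="average")
    else:
        raise ValueError("tail must be 'right' or 'left'")
    return ranks / (n + 1.0)


def mcd_covariance(
    stats: np.ndarray, alpha: float = 0.75, subsample: int = 30_000,
    seed: int = 0,
) -> np.ndarray:
    """Robust (FAST-MCD) correlation matrix of the statistic columns.

    Rows with undefined entries are excluded; at most ``subsample`` rows
    (seeded draw) enter the fit.  A degenerate fit falls back to the
    classical correlation with a warning.
    """
    x = np.asarray(stats, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 3:
        raise ValueError("need >= 3 complete rows")
    rng = np.random.default_rng(seed)
    if x.shape[0] > subsample:
        x = x[rng.choice(x.shape[0], size=subsample, replace=False)]
    from sklearn.covariance import MinCovDet

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MinCovDet(
                support_fraction=alpha, random_state=int(seed)
            ).fit(x)
        cov = fit.covariance_
        if np.linalg.det(cov) <= 0:
            raise np.linalg.LinAlgError("degenerate MCD covariance")
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("MCD degenerate; falling back to classical covariance")
        cov = np.cov(x, rowvar=False)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return corr


def dcms(frac_p: np.ndarray, correlation: np.ndarray) -> np.ndarray:
    """DCMS_i = sum_k ln((1-p_ik)/p_ik) / sum_l |r_kl| (self term included)."""
    p = np.asarray(frac_p, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    r = np.atleast_2d(np.asarray(correlation, dtype=float))
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("fractional p-values must be strictly in (0, 1)")
    if r.shape[0] != p.shape[1]:
        raise ValueError("correlation size does not match statistic count")
    if not np.allclose(r, r.T, atol=1e-8) or not np.allclose(np.diag(r), 1.0):
        raise ValueError("correlation must be symmetric with unit diagonal")
    weights = 1.0 / np.abs(r).sum(axis=0)
    return (np.log((1.0 - p) / p) * weights[None, :]).sum(axis=1)


def calibrate_dcms(values: np.ndarray, tol: float = 1e-8):
    """Robust-normal upper-tail p-values for the DCMS composite.

    Location by intercept-only Huber M-estimation (c = 1.345), scale by
    MAD, IRLS to the given tolerance.  Returns (p, mu, sigma).
    """
    import statsmodels.api as sm

    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 values")
    mad_scale = sm.robust.scale.mad(x)
    if mad_scale == 0:
        raise ValueError("MAD is zero; cannot calibrate")
    model = sm.RLM(
        x, np.ones((len(x), 1)), M=sm.robust.norms.HuberT(t=1.345)
    )
    res = model.fit(conv="coefs", tol=tol, scale_est="mad", maxiter=200)
    mu = float(res.params[0])
    sigma = float(res.scale)
    return norm.sf(x, loc=mu, scale=sigma), mu, sigma


def bh_fdr(p: np.ndarray, q_threshold: float = 0.05):
    """Benjamini-Hochberg step-up q-values and the significant set."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    q[order] = p[order] * m / np.arange(1, m + 1)
    q[order] = np.minimum.accumulate(q[order][::-1])[::-1]
    q = np.minimum(q, 1.0)
    return q, q < q_threshold


# ---------------------------------------------------------------------------
# Full pairwise scan
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    seed: int = 0
    ehh_cutoff: float = 0.05
    ehh_max_gap_bp: int = 200_000
    mcd_alpha: float = 0.75
    mcd_subsample: int = 30_000
    fdr_q: float = 0.05


@dataclass
class ScanResult:
    table: pd.DataFrame
    kinship: pd.DataFrame
    correlation: np.ndarray
    calibration: tuple[float, float]  # (mu, sigma)
    n_excluded: int = 0

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]


def run_pairwise_scan(
    g: GenotypeMatrix,
    haplotypes_a: dict[str, HaplotypeSet],
    haplotypes_b: dict[str, HaplotypeSet],
    pop_a: str,
    pop_b: str,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Compose FST -> FLK -> xp-EHH -> DCMS -> calibrated p -> BH q.

    ``haplotypes_a``/``haplotypes_b`` are per-chromosome phased sets for
    the two populations (pop_a is the xp-EHH numerator, so the right tail
    detects sweeps in pop_a).  SNPs undefined in any statistic are
    excluded from the composite and carry NaN in the output.
    """
    cfg = config or ScanConfig()
    theta = per_snp_wc_fst(g, pop_a, pop_b)
    freqs = allele_frequencies(g, [pop_a, pop_b])
    kinship = flk_kinship_for_pair(freqs, pop_a, pop_b)
    flk_stat, flk_p = flk_scan(freqs.p, kinship)

    xp = xpehh_scan(
        haplotypes_a, haplotypes_b, cfg.ehh_cutoff, cfg.ehh_max_gap_bp
    ).set_index("snp_id")["xpehh_raw"]
    xp_raw = (
        xp.reindex(g.variants["snp_id"]).to_numpy()
        if len(xp)
        else np.full(g.n_variants, np.nan)
    )

    table = pd.DataFrame(
        {
            "snp_id": g.variants["snp_id"],
            "chrom": g.variants["chrom"],
            "pos": g.variants["pos"],
            "fst_theta": theta,
            "flk_stat": flk_stat,
            "flk_p": flk_p,
            "xpehh_raw": xp_raw,
        }
    )
    defined = (
        ~np.isnan(theta) & ~np.isnan(flk_stat) & ~np.isnan(xp_raw)
    )
    n_excluded = int((~defined).sum())
    if defined.sum() < 10:
        raise ValueError("too few SNPs with all three statistics defined")

    for col in ("zfst", "xpehh_z", "p_frac_fst", "p_frac_flk", "p_frac_xpehh",
                "dcms", "dcms_p", "q_value"):
        table[col] = np.nan
    table["significant"] = pd.array([None] * len(table), dtype="boolean")

    idx = np.flatnonzero(defined)
    table.loc[idx, "zfst"] = zfst(theta[idx])
    table.loc[idx, "xpehh_z"] = standardize_xpehh(xp_raw[idx])

    p_fst = fractional_rank_pvalues(theta[idx])
    p_flk = fractional_rank_pvalues(flk_stat[idx])
    p_xp = fractional_rank_pvalues(xp_raw[idx])
    table.loc[idx, "p_frac_fst"] = p_fst
    table.loc[idx, "p_frac_flk"] = p_flk
    table.loc[idx, "p_frac_xpehh"] = p_xp

    stats = np.column_stack(
        [theta[idx], flk_stat[idx], table["xpehh_z"].to_numpy()[idx]]
    )
    corr = mcd_covariance(
        stats, alpha=cfg.mcd_alpha, subsample=cfg.mcd_subsample, seed=cfg.seed
    )
    composite = dcms(np.column_stack([p_fst, p_flk, p_xp]), corr)
    table.loc[idx, "dcms"] = composite
    dcms_p, mu, sigma = calibrate_dcms(composite)
    q, sig = bh_fdr(dcms_p, cfg.fdr_q)
    table.loc[idx, "dcms_p"] = dcms_p
    table.loc[idx, "q_value"] = q
    table.loc[idx, "significant"] = sig

    _assert_scan_invariants(table, idx)
    return ScanResult(
        table=table,
        kinship=kinship,
        correlation=corr,
        calibration=(mu, sigma),
        n_excluded=n_excluded,
    )


def _assert_scan_invariants(table: pd.DataFrame, idx: np.ndarray) -> None:
    sub = table.iloc[idx]
    for col in ("p_frac_fst", "p_frac_flk", "p_frac_xpehh"):
        v = sub[col].to_numpy()
        assert ((v > 0) & (v < 1)).all(), f"{col} not strictly interior"
    q = sub["q_value"].to_numpy()
    p = sub["dcms_p"].to_numpy()
    assert (q >= p - 1e-12).all(), "q < p"
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all(), "q not monotone in p"
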