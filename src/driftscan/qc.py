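"""Quality-control cascade: call rate, MAF/HWE, IBD relatedness, LD pruning.

The intended order mirrors a single merged-QC pass: call-rate filtering
(SNPs then samples), then MAF/HWE on the pooled sample, then greedy
within-population relatedness pruning, with LD pruning as a separate
subsetting step for structure analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from driftscan.genotype_io import MISSING, GenotypeMatrix


class EmptyDatasetError(ValueError):
    """All SNPs or all samples were removed by a filter."""


@dataclass
class QCReport:
    step: str
    params: dict = field(default_factory=dict)
    n_snps_removed: int = 0
    n_samples_removed: int = 0
    removed_snp_ids: list = field(default_factory=list)
    removed_sample_ids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": self.step,
                    "n_snps_removed": self.n_snps_removed,
                    "n_samples_removed": self.n_samples_removed,
                    "params": repr(self.params),
                }
            ]
        )


@dataclass
class IBDPair:
    sample_i: str
    sample_j: str
    p_ibd0: float
    p_ibd1: float
    p_ibd2: float

    @property
    def pi_hat(self) -> float:
        return self.p_ibd2 + 0.5 * self.p_ibd1


def _check_nonempty(g: GenotypeMatrix, step: str) -> None:
    if g.n_samples == 0 or g.n_variants == 0:
        raise EmptyDatasetError(f"{step}: all data removed")


# ---------------------------------------------------------------------------
# Call rate
# ---------------------------------------------------------------------------

def filter_call_rate(
    g: GenotypeMatrix, min_rate: float = 0.90
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs, then samples, with call rate below ``min_rate``.

    The sample pass is computed on the SNP-filtered matrix.
    """
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    snp_keep = g.snp_call_rate() >= min_rate
    removed_snps = list(g.variants["snp_id"][~snp_keep])
    g1 = g.take_variants(np.flatnonzero(snp_keep))
    _check_nonempty(g1, "call-rate (SNPs)")
    samp_keep = g1.sample_call_rate() >= min_rate
    removed_samples = list(g1.samples["sample_id"][~samp_keep])
    g2 = g1.take_samples(np.flatnonzero(samp_keep))
    _check_nonempty(g2, "call-rate (samples)")
    report = QCReport(
        step="call_rate",
        params={"min_rate": min_rate},
        n_snps_removed=len(removed_snps),
        n_samples_removed=len(removed_samples),
        removed_snp_ids=removed_snps,
        removed_sample_ids=removed_samples,
    )
    return g2, report


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact HWE p-value (sum of configurations no more probable
    than the observed heterozygote count, margins fixed).

    Monomorphic SNPs return 1 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    # log-probability of each heterozygote count with the same parity
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.array(
        [
            _log_hwe_prob(n, n_a, h)
            for h in hets
        ]
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.flatnonzero(hets == n_ab)[0]]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _log_hwe_prob(n: int, n_a: int, n_ab: int) -> float:
    """Log P(het count = n_ab | n individuals, n_a copies of allele a)."""
    n_aa = (n_a - n_ab) // 2
    n_bb = n - n_aa - n_ab
    lg = math.lgamma
    return (
        lg(n + 1)
        - lg(n_aa + 1)
        - lg(n_ab + 1)
        - lg(n_bb + 1)
        + n_ab * math.log(2.0)
        + lg(n_a + 1)
        + lg(2 * n - n_a + 1)
        - lg(2 * n + 1)
    )


def filter_maf_hwe(
    g: GenotypeMatrix, min_maf: float = 0.01, hwe_alpha: float = 1e-6
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with MAF < ``min_maf`` (strict) or pooled HWE p < ``hwe_alpha``."""
    if not (0 < min_maf < 1 and 0 < hwe_alpha < 1):
        raise ValueError("thresholds must be in (0, 1)")
    maf = g.maf()
    counts = g.genotype_counts()
    hwe_p = np.array(
        [hwe_exact_test(*row) if row.sum() > 0 else 1.0 for row in counts]
    )
    low_maf = maf < min_maf
    bad_hwe = hwe_p < hwe_alpha
    drop = low_maf | bad_hwe | np.isnan(maf)
    g1 = g.take_variants(np.flatnonzero(~drop))
    _check_nonempty(g1, "maf/hwe")
    report = QCReport(
        step="maf_hwe",
        params={
            "min_maf": min_maf,
            "hwe_alpha": hwe_alpha,
            "n_low_maf": int(low_maf.sum()),
            "n_hwe": int(bad_hwe.sum()),
        },
        n_snps_removed=int(drop.sum()),
        removed_snp_ids=list(g.variants["snp_id"][drop]),
    )
    return g1, report


# ---------------------------------------------------------------------------
# IBD (PLINK-style method of moments)
# ---------------------------------------------------------------------------

def estimate_ibd(g: GenotypeMatrix) -> list[IBDPair]:
    """Method-of-moments P(IBD=0,1,2) for every sample pair.

    Uses pooled sample allele frequencies and observed identity-by-state
    counts; probabilities are bounded into [0, 1] and renormalized.
    """
    if g.n_samples < 2:
        raise ValueError("IBD estimation needs at least 2 samples")
    p = g.allele_b_frequency()
    usable = ~np.isnan(p) & (p > 0) & (p < 1)
    if not usable.any():
        raise ValueError("no polymorphic SNPs with called genotypes")
    p = p[usable]
    q = 1.0 - p
    dos = g.dosage[:, usable]
    called = dos != MISSING

    # expected P(IBS=i | IBD=z) per SNP
    e0_0 = 2 * p**2 * q**2
    e1_0 = 4 * p**3 * q + 4 * p * q**3
    e2_0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_1 = 2 * p**2 * q + 2 * p * q**2
    e2_1 = p**3 + q**3 + p**2 * q + p * q**2

    ids = list(g.samples["sample_id"])
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            joint = called[i] & called[j]
            nj = joint.sum()
            if nj == 0:
                continue
            diff = np.abs(dos[i, joint] - dos[j, joint])
            ibs0 = int((diff == 2).sum())  # opposite homozygotes
            ibs1 = int((diff == 1).sum())  # one shared allele
            ibs2 = int(nj - ibs0 - ibs1)
            s0_0, s1_0, s2_0 = e0_0[joint].sum(), e1_0[joint].sum(), e2_0[joint].sum()
            s1_1, s2_1 = e1_1[joint].sum(), e2_1[joint].sum()
            z0 = ibs0 / s0_0 if s0_0 > 0 else 0.0
            z1 = (ibs1 - z0 * s1_0) / s1_1 if s1_1 > 0 else 0.0
            z2 = (ibs2 - z0 * s2_0 - z1 * s2_1) / nj
            z = np.clip([z0, z1, z2], 0.0, 1.0)
            tot = z.sum()
            z = z / tot if tot > 0 else np.array([1.0, 0.0, 0.0])
            out.append(IBDPair(ids[i], ids[j], *map(float, z)))
    return out


def prune_related(
    g: GenotypeMatrix, pairs: list[IBDPair], max_pi_hat: float = 0.25
) -> tuple[GenotypeMatrix, QCReport]:
    """Greedy within-population relatedness pruning.

    While any within-population pair exceeds ``max_pi_hat``, remove the
    individual involved in the most such pairs (ties broken by lower call
    rate, then lexicographic id).
    """
    pop_of = dict(
        zip(g.samples["sample_id"], g.samples["population"])
    )
    call_rate = dict(zip(g.samples["sample_id"], g.sample_call_rate()))
    edges = {
        (pr.sample_i, pr.sample_j)
        for pr in pairs
        if pr.pi_hat > max_pi_hat
        and pop_of.get(pr.sample_i) == pop_of.get(pr.sample_j)
    }
    removed = []
    while edges:
        degree: dict[str, int] = {}
        for a, b in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        victim = min(
            degree, key=lambda s: (-degree[s], call_rate.get(s, 0.0), s)
        )
        removed.append(victim)
        edges = {e for e in edges if victim not in e}
    keep = ~g.samples["sample_id"].isin(removed).to_numpy()
    g1 = g.take_samples(np.flatnonzero(keep))
    _check_nonempty(g1, "ibd")
    report = QCReport(
        step="ibd_prune",
        params={"max_pi_hat": max_pi_hat},
        n_samples_removed=len(removed),
        removed_sample_ids=removed,
    )
    return g1, report


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(g: GenotypeMatrix, snp_i: int, snp_j: int) -> float:
    """Squared Pearson correlation of dosages over jointly called samples.

    Returns NaN when either SNP is monomorphic in the joint sample.
    """
    x, y = g.dosage[:, snp_i], g.dosage[:, snp_j]
    joint = (x != MISSING) & (y != MISSING)
    x, y = x[joint].astype(float), y[joint].astype(float)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _window_r2(dos: np.ndarray) -> np.ndarray:
    """Pairwise r^2 among the columns of a small dosage block (no missing
    masking refinement: missing cells are excluded pairwise)."""
    m = dos.shape[1]
    out = np.full((m, m), np.nan)
    valid = dos != MISSING
    x = dos.astype(float)
    for a in range(m):
        for b in range(a + 1, m):
            joint = valid[:, a] & valid[:, b]
            if joint.sum() < 2:
                continue
            xa, xb = x[joint, a], x[joint, b]
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            out[a, b] = out[b, a] = r * r
    return out


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> tuple[GenotypeMatrix, QCReport]:
    """Sliding-window LD pruning (indep-pairwise semantics).

    Within each window, while any surviving pair has r^2 > ``r2_max`` the
    pair with the largest r^2 is found and its lower-MAF member removed
    (tie: the later-positioned SNP).  Windows advance by ``step_snps``.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    maf = g.maf()
    removed_mask = np.zeros(g.n_variants, dtype=bool)
    chroms = g.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        start = 0
        while True:
            window = cols[start : start + window_snps]
            live = [c for c in window if not removed_mask[c]]
            if len(live) >= 2:
                r2 = _window_r2(g.dosage[:, live])
                while True:
                    with np.errstate(invalid="ignore"):
                        over = np.argwhere(np.triu(r2 > r2_max, k=1))
                    if over.size == 0:
                        break
                    vals = r2[over[:, 0], over[:, 1]]
                    a, b = over[np.argmax(vals)]
                    ca, cb = live[a], live[b]
                    if maf[ca] < maf[cb] or (maf[ca] == maf[cb] and ca > cb):
                        drop_local = a
                    else:
                        drop_local = b
                    removed_mask[live[drop_local]] = True
                    r2[drop_local, :] = np.nan
                    r2[:, drop_local] = np.nan
            if start + window_snps >= len(cols):
                break
            start += step_snps
    g1 = g.take_variants(np.flatnonzero(~removed_mask))
    _check_nonempty(g1, "ld_prune")
    report = QCReport(
        step="ld_prune",
        params={
            "window_snps": window_snps,
            "step_snps": step_snps,
            "r2_max": r2_max,
        },
        n_snps_removed=int(removed_mask.sum()),
        removed_snp_ids=list(g.variants["snp_id"][removed_mask]),
    )
    return g1, report


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_qc(
    g: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-6,
    max_pi_hat: float = 0.25,
) -> tuple[GenotypeMatrix, list[QCReport]]:
    """Call rate -> MAF/HWE -> IBD pruning, returning all reports."""
    reports = []
    g, rep = filter_call_rate(g, min_call_rate)
    reports.append(rep)
    g, rep = filter_maf_hwe(g, min_maf, hwe_alpha)
    reports.append(rep)
    pairs = estimate_ibd(g)
    g, rep = prune_related(g, pairs, max_pi_hat)
    reports.append(rep)
    return g, reports
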