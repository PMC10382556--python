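"""Population differentiation and diversity statistics.

Allele frequencies per population, absolute allele frequency difference
(AFD), Cavalli-Sforza & Edwards chord distance, Reynolds-type coancestry
distance, Weir & Cockerham FST (per SNP and multilocus ratio-of-sums with
a bootstrap CI over loci), Z(FST), and the LD-decay curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from driftscan.genotype_io import MISSING, GenotypeMatrix


@dataclass
class AlleleFrequencyTable:
    """Per-population allele_b frequencies and called diploid counts."""

    populations: list[str]
    snp_ids: list[str]
    p: np.ndarray          # n_pop x M, NaN where undefined
    n_called: np.ndarray   # n_pop x M
    het_obs: np.ndarray    # n_pop x M observed heterozygote frequency

    def row(self, population: str) -> int:
        return self.populations.index(population)


def allele_frequencies(g: GenotypeMatrix, populations=None) -> AlleleFrequencyTable:
    if populations is None:
        populations = g.populations
    p_rows, n_rows, h_rows = [], [], []
    for pop in populations:
        idx = g.population_index(pop)
        dos = g.dosage[idx, :]
        called = dos != MISSING
        n = called.sum(axis=0)
        tot = np.where(called, dos, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, tot / (2.0 * n), np.nan)
            h = np.where(n > 0, (dos == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        p_rows.append(p)
        n_rows.append(n)
        h_rows.append(h)
    return AlleleFrequencyTable(
        list(populations),
        list(g.variants["snp_id"]),
        np.stack(p_rows),
        np.stack(n_rows),
        np.stack(h_rows),
    )


# ---------------------------------------------------------------------------
# AFD and distances
# ---------------------------------------------------------------------------

def afd(freqs: AlleleFrequencyTable, pop1: str, pop2: str):
    """Per-SNP absolute allele frequency difference and its mean +/- SD.

    For biallelic loci the half-sum of per-allele absolute differences
    reduces to |p1 - p2|.
    """
    p1 = freqs.p[freqs.row(pop1)]
    p2 = freqs.p[freqs.row(pop2)]
    per_snp = 0.5 * (np.abs(p1 - p2) + np.abs((1 - p1) - (1 - p2)))
    defined = ~np.isnan(per_snp)
    mean = float(np.nanmean(per_snp)) if defined.any() else float("nan")
    sd = float(np.nanstd(per_snp, ddof=1)) if defined.sum() > 1 else float("nan")
    return per_snp, mean, sd


def chord_distance(freqs: AlleleFrequencyTable, pop1: str, pop2: str) -> float:
    """Cavalli-Sforza & Edwards chord distance averaged over usable loci."""
    x = freqs.p[freqs.row(pop1)]
    y = freqs.p[freqs.row(pop2)]
    ok = ~np.isnan(x) & ~np.isnan(y)
    if not ok.any():
        raise ValueError("no loci with defined frequencies in both populations")
    x, y = x[ok], y[ok]
    cos_theta = np.sqrt(x * y) + np.sqrt((1 - x) * (1 - y))
    per_locus = np.sqrt(np.maximum(2.0 * (1.0 - cos_theta), 0.0))
    return float(2.0 / (np.pi * ok.sum()) * per_locus.sum())


def reynolds_distance(
    freqs: AlleleFrequencyTable, pop1: str, pop2: str,
    sample_correction: bool = True,
) -> float:
    """Coancestry distance -ln(1 - theta), theta by ratio-of-sums.

    With ``sample_correction`` the Weir-Cockerham variance components are
    used (theta estimates the drift component only).  Without it a plug-in
    estimator is used whose expectation includes the sampling variance of
    the observed frequencies; the FLK kinship uses that variant so finite
    sample noise is absorbed into the kinship.
    """
    theta = _pairwise_theta(freqs, pop1, pop2, sample_correction)
    if theta >= 1.0:
        raise ValueError(f"theta >= 1 ({theta}); cannot take -ln(1-theta)")
    return float(max(0.0, -np.log(1.0 - theta)))


def _pairwise_theta(freqs, pop1, pop2, sample_correction=True) -> float:
    i, j = freqs.row(pop1), freqs.row(pop2)
    p1, p2 = freqs.p[i], freqs.p[j]
    n1, n2 = freqs.n_called[i].astype(float), freqs.n_called[j].astype(float)
    ok = ~np.isnan(p1) & ~np.isnan(p2) & (n1 > 0) & (n2 > 0)
    if sample_correction:
        h1, h2 = freqs.het_obs[i], freqs.het_obs[j]
        a, b, c = _wc_components(p1[ok], p2[ok], n1[ok], n2[ok], h1[ok], h2[ok])
        denom = (a + b + c).sum()
        return float(a.sum() / denom) if denom != 0 else float("nan")
    # plug-in: between-population variance over total, no sampling removal
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    nbar = (n1 + n2) / 2.0
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    denom = (pbar * (1 - pbar) + s2 / 2.0).sum()
    return float(s2.sum() / denom) if denom != 0 else float("nan")


def _wc_components(p1, p2, n1, n2, h1, h2):
    """Weir & Cockerham (1984) a, b, c for two populations, vectorized."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2.0
    return a, b, c


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def per_snp_wc_fst(g: GenotypeMatrix, pop1: str, pop2: str) -> np.ndarray:
    """Weir-Cockerham theta-hat per SNP; NaN where a+b+c == 0."""
    freqs = allele_frequencies(g, [pop1, pop2])
    p1, p2 = freqs.p
    n1, n2 = freqs.n_called.astype(float)
    h1, h2 = freqs.het_obs
    out = np.full(g.n_variants, np.nan)
    ok = ~np.isnan(p1) & ~np.isnan(p2) & (n1 > 1) & (n2 > 1)
    a, b, c = _wc_components(p1[ok], p2[ok], n1[ok], n2[ok], h1[ok], h2[ok])
    denom = a + b + c
    theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    out[ok] = theta
    return out


def pairwise_fst_multilocus(
    g: GenotypeMatrix, pop1: str, pop2: str, n_boot: int = 1000, seed: int = 0
):
    """Multilocus theta (ratio of summed WC components) with a 95%
    percentile bootstrap CI over loci."""
    freqs = allele_frequencies(g, [pop1, pop2])
    p1, p2 = freqs.p
    n1, n2 = freqs.n_called.astype(float)
    h1, h2 = freqs.het_obs
    ok = ~np.isnan(p1) & ~np.isnan(p2) & (n1 > 1) & (n2 > 1)
    a, b, c = _wc_components(p1[ok], p2[ok], n1[ok], n2[ok], h1[ok], h2[ok])
    denom_sum = (a + b + c).sum()
    theta = float(a.sum() / denom_sum) if denom_sum != 0 else float("nan")
    m = int(ok.sum())
    if m < 2 or n_boot < 1:
        return theta, float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    tot = a + b + c
    reps = np.empty(n_boot)
    for k in range(n_boot):
        pick = rng.integers(0, m, size=m)
        d = tot[pick].sum()
        reps[k] = a[pick].sum() / d if d != 0 else np.nan
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return theta, float(lo), float(hi)


def zfst(theta: np.ndarray) -> np.ndarray:
    """Z-transform of per-SNP theta over defined values (mean 0, SD 1)."""
    defined = ~np.isnan(theta)
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined values")
    mu = theta[defined].mean()
    sd = theta[defined].std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in theta")
    out = np.full_like(theta, np.nan, dtype=float)
    out[defined] = (theta[defined] - mu) / sd
    return out


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay_curve(
    g: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    bin_width_bp: int = 50_000,
    population: str | None = None,
    max_pairs_per_chrom: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean within-chromosome dosage r^2 binned by physical distance.

    Returns a frame (bin_start, bin_end, mean_r2, n_pairs); empty bins get
    NaN.  ``max_pairs_per_chrom`` optionally subsamples pairs for speed.
    """
    if population is not None:
        g = g.take_samples(g.population_index(population))
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    chroms = g.variants["chrom"].to_numpy()
    pos_all = g.variants["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        pos = pos_all[cols]
        ii, jj = np.triu_indices(len(cols), k=1)
        dist = pos[jj] - pos[ii]
        keep = (dist > 0) & (dist <= max_dist_bp)
        ii, jj, dist = ii[keep], jj[keep], dist[keep]
        if max_pairs_per_chrom is not None and len(ii) > max_pairs_per_chrom:
            pick = rng.choice(len(ii), size=max_pairs_per_chrom, replace=False)
            ii, jj, dist = ii[pick], jj[pick], dist[pick]
        if len(ii) == 0:
            continue
        r2 = _pairwise_r2(g.dosage[:, cols], ii, jj)
        ok = ~np.isnan(r2)
        b = np.minimum(((dist[ok] - 1) // bin_width_bp).astype(int), n_bins - 1)
        np.add.at(sums, b, r2[ok])
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_width_bp + 1,
            "bin_end": (np.arange(n_bins) + 1) * bin_width_bp,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def _pairwise_r2(dos: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """r^2 for the requested column pairs, masking missing pairwise."""
    if (dos == MISSING).any():
        out = np.empty(len(ii))
        x = dos.astype(float)
        valid = dos != MISSING
        for k, (a, b) in enumerate(zip(ii, jj)):
            joint = valid[:, a] & valid[:, b]
            xa, xb = x[joint, a], x[joint, b]
            if joint.sum() < 2 or xa.std() == 0 or xb.std() == 0:
                out[k] = np.nan
            else:
                r = np.corrcoef(xa, xb)[0, 1]
                out[k] = r * r
        return out
    x = dos.astype(float)
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    n = x.shape[0]
    cov = (xc[:, ii] * xc[:, jj]).sum(axis=0) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sd[ii] * sd[jj])
    r[(sd[ii] == 0) | (sd[jj] == 0)] = np.nan
    return r * r


def ld_at_distance(curve: pd.DataFrame, dist_bp: int = 100_000) -> float:
    """Mean r^2 of the bin containing ``dist_bp``."""
    hit = curve[(curve["bin_start"] <= dist_bp) & (curve["bin_end"] >= dist_bp)]
    if hit.empty:
        return float("nan")
    return float(hit["mean_r2"].iloc[0])


def distance_matrix(
    g: GenotypeMatrix, metric: str = "reynolds", **kwargs
) -> pd.DataFrame:
    """Symmetric population distance matrix for the chosen metric
    (``chord`` | ``reynolds`` | ``afd_mean`` | ``fst``)."""
    pops = g.populations
    freqs = allele_frequencies(g, pops)
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "chord":
                v = chord_distance(freqs, pops[i], pops[j])
            elif metric == "reynolds":
                v = reynolds_distance(freqs, pops[i], pops[j], **kwargs)
            elif metric == "afd_mean":
                v = afd(freqs, pops[i], pops[j])[1]
            elif metric == "fst":
                v = _pairwise_theta(freqs, pops[i], pops[j])
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = v
    return pd.DataFrame(d, index=pops, columns=pops)
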