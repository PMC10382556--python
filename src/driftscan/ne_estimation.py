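"""Effective population size from linkage disequilibrium.

Contemporary Ne: mean squared Burrows-composite (dosage) correlation over
inter-chromosomal SNP pairs, corrected for the expected sampling
contribution (Waples-style, random mating, S >= 30 regime:
E[r2_sample] = 1/S + 3.19/S^2), inverted to Ne through the drift
expectation.  A leave-one-chromosome-out jackknife gives the CI.

Historical Ne: within-chromosome pairs binned by recombination distance c
(Morgans); per bin Ne = (1/(4 f(c))) * (1/r2_adj - alpha) at time
t = 1/(2 f(c)) generations ago.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from driftscan.genotype_io import MISSING, GenotypeMatrix


@dataclass
class NeEstimate:
    ne_point: float
    ci_low: float
    ci_high: float
    maf_screen: float
    n_pairs: int
    mean_r2: float
    r2_drift: float
    n_samples: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class HistoricalNePoint:
    generations_ago: float
    ne: float
    bin_low_morgans: float
    bin_high_morgans: float
    mean_r2_adj: float
    n_pairs: int


def expected_sample_r2(s: int, estimator: str = "pearson") -> float:
    """Expected squared correlation from finite sampling alone.

    ``pearson``: 1/(S-1), the independence expectation of the squared
    Pearson correlation of dosages used here (verified by simulation).
    ``waples``: 1/S + 3.19/S^2, the S >= 30 random-mating constant derived
    for the Burrows-delta-based estimator of the cited method.
    """
    if estimator == "pearson":
        return 1.0 / (s - 1)
    if estimator == "waples":
        return 1.0 / s + 3.19 / s**2
    raise ValueError(f"unknown estimator {estimator!r}")


def ne_from_drift_r2(r2_drift: float, method: str = "waples") -> float:
    """Invert the drift component of r^2 to Ne.

    ``linear``: Ne = 1/(3 r2'), the first-order E[r2'] = 1/(3Ne)
    inversion.  ``waples``: the second-order inversion
    Ne = (1/3 + sqrt(1/9 - 2.76 r2')) / (2 r2').
    Non-positive r2' yields infinity.
    """
    if r2_drift <= 0:
        return float("inf")
    if method == "linear":
        return 1.0 / (3.0 * r2_drift)
    if method == "waples":
        disc = 1.0 / 9.0 - 2.76 * r2_drift
        if disc < 0:
            disc = 0.0
        return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2_drift)
    raise ValueError(f"unknown inversion method {method!r}")


def _dosage_r2_matrix(dos: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between all dosage columns (no missing)."""
    x = dos.astype(float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / x.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = c / np.outer(sd, sd)
    return r * r


def contemporary_ldne(
    g: GenotypeMatrix,
    population: str | None = None,
    maf_screen: float = 0.0,
    sampling_correction: bool = True,
    inversion: str = "waples",
) -> NeEstimate:
    """LD-based single-sample Ne from inter-chromosomal pairs."""
    if population is not None:
        g = g.take_samples(g.population_index(population))
    s = g.n_samples
    if s < 10:
        raise ValueError(f"need >= 10 samples, got {s}")
    chroms = g.variants["chrom"].to_numpy()
    if len(pd.unique(chroms)) < 2:
        raise ValueError("need >= 2 chromosomes for inter-chromosomal LD")

    maf = g.maf()
    keep = ~np.isnan(maf) & (maf > maf_screen) & ((g.dosage != MISSING).all(axis=0))
    cols = np.flatnonzero(keep)
    sub = g.dosage[:, cols]
    chrom_sub = chroms[cols]
    r2 = _dosage_r2_matrix(sub)
    inter = chrom_sub[:, None] != chrom_sub[None, :]
    iu = np.triu(inter, k=1) & ~np.isnan(r2)

    warnings = []
    n_pairs = int(iu.sum())
    if n_pairs == 0:
        raise ValueError("no usable inter-chromosomal pairs")
    if n_pairs < 100:
        warnings.append(f"only {n_pairs} usable pairs")

    sample_r2 = expected_sample_r2(s) if sampling_correction else 0.0

    def point(mask):
        mean = r2[mask].mean()
        drift = mean - sample_r2
        return mean, drift, ne_from_drift_r2(drift, inversion)

    mean_r2, r2_drift, ne = point(iu)

    # leave-one-chromosome-out jackknife on the drift r2 scale
    uniq = pd.unique(chrom_sub)
    jack = []
    for c in uniq:
        m = iu.copy()
        on_c = chrom_sub == c
        m[on_c, :] = False
        m[:, on_c] = False
        if m.any():
            jack.append(r2[m].mean() - sample_r2)
    k = len(jack)
    if k >= 2:
        jack = np.array(jack)
        theta_bar = jack.mean()
        se = np.sqrt((k - 1) / k * ((jack - theta_bar) ** 2).sum())
        lo_r2, hi_r2 = r2_drift - 1.96 * se, r2_drift + 1.96 * se
        ci_high = ne_from_drift_r2(lo_r2, inversion)
        ci_low = ne_from_drift_r2(hi_r2, inversion)
        if np.isfinite(ne):
            ci_low = min(ci_low, ne)
            ci_high = max(ci_high, ne)
    else:
        ci_low, ci_high = float("nan"), float("nan")
        warnings.append("too few chromosomes for jackknife")
    return NeEstimate(
        ne_point=float(ne),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        maf_screen=maf_screen,
        n_pairs=n_pairs,
        mean_r2=float(mean_r2),
        r2_drift=float(r2_drift),
        n_samples=s,
        warnings=warnings,
    )


def ldne_maf_screens(
    g: GenotypeMatrix,
    population: str | None = None,
    screens=(0.0, 0.02, 0.05, 0.1),
    **kwargs,
) -> pd.DataFrame:
    """Batch of contemporary estimates over the standard MAF screens."""
    rows = []
    for screen in screens:
        est = contemporary_ldne(g, population, maf_screen=screen, **kwargs)
        rows.append(
            {
                "population": population or "all",
                "maf_screen": screen,
                "ne": est.ne_point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_pairs": est.n_pairs,
                "mean_r2": est.mean_r2,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Historical Ne
# ---------------------------------------------------------------------------

def historical_ne(
    g: GenotypeMatrix,
    population: str | None = None,
    max_dist_bp: int = 4_000_000,
    n_bins: int = 20,
    cm_per_mb: float = 1.0,
    alpha: float = 2.0,
    mapping: str = "linear",
    sample_correction: bool = True,
) -> list[HistoricalNePoint]:
    """Distance-binned within-chromosome LD converted to an Ne trajectory.

    ``mapping='linear'`` uses f(c) = c; ``'sved'`` uses
    f(c) = c(1 - c/2)/(1 - c)^2.  ``alpha`` absorbs the mutation
    correction (2 without, 2.2 with).
    """
    if population is not None:
        g = g.take_samples(g.population_index(population))
    s = g.n_samples
    chroms = g.variants["chrom"].to_numpy()
    pos_all = g.variants["pos"].to_numpy()
    maf = g.maf()
    usable = ~np.isnan(maf) & (maf > 0) & ((g.dosage != MISSING).all(axis=0))

    max_c = max_dist_bp * cm_per_mb / 1e8
    edges = np.linspace(0.0, max_c, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero((chroms == chrom) & usable)
        if len(cols) < 2:
            continue
        r2 = _dosage_r2_matrix(g.dosage[:, cols])
        pos = pos_all[cols]
        ii, jj = np.triu_indices(len(cols), k=1)
        c = (pos[jj] - pos[ii]) * cm_per_mb / 1e8
        vals = r2[ii, jj]
        ok = (c > 0) & (c <= max_c) & ~np.isnan(vals)
        b = np.minimum(np.searchsorted(edges, c[ok], side="right") - 1, n_bins - 1)
        np.add.at(sums, b, vals[ok])
        np.add.at(counts, b, 1)

    sample_r2 = (1.0 / s) if sample_correction else 0.0
    points = []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        mean_adj = sums[b] / counts[b] - sample_r2
        if mean_adj <= 0:
            continue
        c_mid = 0.5 * (edges[b] + edges[b + 1])
        if mapping == "linear":
            fc = c_mid
        elif mapping == "sved":
            fc = c_mid * (1 - c_mid / 2) / (1 - c_mid) ** 2
        else:
            raise ValueError(f"unknown mapping {mapping!r}")
        inv = 1.0 / mean_adj - alpha
        if inv <= 0 or fc <= 0:
            continue
        points.append(
            HistoricalNePoint(
                generations_ago=1.0 / (2.0 * fc),
                ne=inv / (4.0 * fc),
                bin_low_morgans=float(edges[b]),
                bin_high_morgans=float(edges[b + 1]),
                mean_r2_adj=float(mean_adj),
                n_pairs=int(counts[b]),
            )
        )
    return points
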