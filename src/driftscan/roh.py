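"""Sliding-window runs of homozygosity, F_ROH, and shared-ROH peaks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from driftscan.genotype_io import MISSING, GenotypeMatrix

#: Length-class edges in Mb: [0,4), [4,8), [8,16), [16,32), >=32.
LENGTH_CLASS_EDGES_MB = (0, 4, 8, 16, 32)


@dataclass
class ROHParams:
    window_size_snps: int = 15
    min_snp: int = 20
    overlap_threshold: float = 0.05
    min_density_bp_per_snp: int = 168_000  # >= 1 SNP per 168 kbps of span
    max_gap_bp: int = 1_000_000
    min_length_bp: int = 500_000
    max_het_per_window: int = 1
    max_miss_per_window: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0, 1]")
        for name in ("window_size_snps", "min_snp", "min_density_bp_per_snp",
                     "max_gap_bp", "min_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def detect_roh(
    g: GenotypeMatrix, sample_id: str, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Sliding-window ROH detection for one individual.

    A window is homozygous when it holds at most ``max_het_per_window``
    heterozygotes and ``max_miss_per_window`` missing calls.  A SNP is
    in-run when the fraction of windows covering it that are homozygous is
    at least ``overlap_threshold``.  Runs are split at physical gaps above
    ``max_gap_bp`` and filtered on SNP count, length, and density.
    """
    params = params or ROHParams()
    row = np.flatnonzero((g.samples["sample_id"] == sample_id).to_numpy())
    if row.size != 1:
        raise KeyError(f"sample {sample_id!r} not found")
    dosage = g.dosage[row[0]]
    chroms = g.variants["chrom"].to_numpy()
    pos_all = g.variants["pos"].to_numpy()

    segments: list[ROHSegment] = []
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        segments.extend(
            _detect_chrom(
                str(chrom), dosage[cols], pos_all[cols], sample_id, params
            )
        )
    return segments


def _detect_chrom(chrom, dos, pos, sample_id, p: ROHParams):
    m = len(dos)
    w = p.window_size_snps
    if m < w:
        return []
    het = (dos == 1).astype(np.int32)
    mis = (dos == MISSING).astype(np.int32)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - w + 1
    starts = np.arange(n_win)
    win_ok = (
        (chet[starts + w] - chet[starts] <= p.max_het_per_window)
        & (cmis[starts + w] - cmis[starts] <= p.max_miss_per_window)
    )
    # windows covering SNP j start in [j-w+1, j]
    c_ok = np.concatenate([[0], np.cumsum(win_ok)])
    lo = np.maximum(np.arange(m) - w + 1, 0)
    hi = np.minimum(np.arange(m), n_win - 1)
    n_cover = hi - lo + 1
    n_hom = c_ok[hi + 1] - c_ok[lo]
    in_run = (n_hom / n_cover) >= p.overlap_threshold

    segments = []
    j = 0
    while j < m:
        if not in_run[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and in_run[k + 1]:
            k += 1
        # split the candidate [j, k] at large physical gaps
        cut_points = [j]
        for t in range(j, k):
            if pos[t + 1] - pos[t] > p.max_gap_bp:
                cut_points.append(t + 1)
        cut_points.append(k + 1)
        for a, b in zip(cut_points[:-1], cut_points[1:]):
            n_snps = b - a
            start, end = int(pos[a]), int(pos[b - 1])
            length = end - start + 1
            if (
                n_snps >= p.min_snp
                and length >= p.min_length_bp
                and n_snps * p.min_density_bp_per_snp >= length
            ):
                segments.append(ROHSegment(sample_id, chrom, start, end, n_snps))
        j = k + 1
    return segments


def detect_roh_all(
    g: GenotypeMatrix, params: ROHParams | None = None
) -> list[ROHSegment]:
    params = params or ROHParams()
    out = []
    for sid in g.samples["sample_id"]:
        out.extend(detect_roh(g, sid, params))
    return out


# ---------------------------------------------------------------------------


def genome_length_from_map(variants: pd.DataFrame) -> int:
    """Sum over chromosomes of (last - first SNP position)."""
    total = 0
    for _, grp in variants.groupby("chrom", sort=False):
        total += int(grp["pos"].max() - grp["pos"].min())
    return total


def froh(segments: list[ROHSegment], genome_length_bp: int) -> float:
    """F_ROH = total ROH length / genome length, for one individual."""
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    by_chrom: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start_bp)
        for a, b in zip(segs[:-1], segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(
                    f"overlapping segments on {a.chrom}: "
                    f"{a.start_bp}-{a.end_bp} and {b.start_bp}-{b.end_bp}"
                )
    return sum(s.length_bp for s in segments) / genome_length_bp


def froh_per_sample(
    g: GenotypeMatrix, segments: list[ROHSegment],
    genome_length_bp: int | None = None,
) -> pd.DataFrame:
    if genome_length_bp is None:
        genome_length_bp = genome_length_from_map(g.variants)
    by_sample: dict[str, list[ROHSegment]] = {
        s: [] for s in g.samples["sample_id"]
    }
    for seg in segments:
        by_sample[seg.sample_id].append(seg)
    rows = [
        {
            "sample_id": sid,
            "population": pop,
            "n_segments": len(by_sample[sid]),
            "froh": froh(by_sample[sid], genome_length_bp),
        }
        for sid, pop in zip(g.samples["sample_id"], g.samples["population"])
    ]
    return pd.DataFrame(rows)


def length_class_summary(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segment counts per length class [0,4), [4,8), [8,16), [16,32), >=32 Mb."""
    edges = [e * 1_000_000 for e in LENGTH_CLASS_EDGES_MB[1:]]
    labels = ["0-4Mb", "4-8Mb", "8-16Mb", "16-32Mb", ">=32Mb"]
    counts = [0] * 5
    for seg in segments:
        counts[int(np.searchsorted(edges, seg.length_bp, side="right"))] += 1
    return pd.DataFrame({"length_class": labels, "n_segments": counts})


@dataclass
class ROHPeak:
    chrom: str
    start_bp: int
    end_bp: int
    max_incidence: float


@dataclass
class IncidenceResult:
    incidence: np.ndarray  # per SNP, fraction of individuals covered
    peaks: list[ROHPeak] = field(default_factory=list)


def roh_incidence_peaks(
    segments: list[ROHSegment],
    variants: pd.DataFrame,
    sample_ids: list[str],
    threshold: float = 0.7,
) -> IncidenceResult:
    """Per-SNP fraction of individuals whose ROH covers the SNP, with
    maximal runs of SNPs strictly above ``threshold`` reported as peaks."""
    n = len(sample_ids)
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    covered = np.zeros((n, len(variants)), dtype=bool)
    row_of = {s: i for i, s in enumerate(sample_ids)}
    for seg in segments:
        if seg.sample_id not in row_of:
            continue
        mask = (chroms == seg.chrom) & (pos >= seg.start_bp) & (pos <= seg.end_bp)
        covered[row_of[seg.sample_id]] |= mask
    incidence = covered.mean(axis=0)

    peaks = []
    above = incidence > threshold
    j = 0
    while j < len(variants):
        if not above[j] :
            j += 1
            continue
        k = j
        while (
            k + 1 < len(variants)
            and above[k + 1]
            and chroms[k + 1] == chroms[j]
        ):
            k += 1
        peaks.append(
            ROHPeak(
                chrom=str(chroms[j]),
                start_bp=int(pos[j]),
                end_bp=int(pos[k]),
                max_incidence=float(incidence[j : k + 1].max()),
            )
        )
        j = k + 1
    return IncidenceResult(incidence=incidence, peaks=peaks)


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
                "length_bp": s.length_bp,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"],
    )
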