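"""Population structure: PCA, LOF outlier removal, IBS clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.neighbors import LocalOutlierFactor

from driftscan.genotype_io import MISSING, GenotypeMatrix


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray             # N x k
    explained_variance: np.ndarray  # k fractions of total variance
    loadings: np.ndarray | None = None  # M' x k (non-constant SNPs only)


def pca(g: GenotypeMatrix, k: int = 10, keep_loadings: bool = False) -> PCAResult:
    """PCA of centered, unit-variance dosage columns (SVD based).

    Missing cells are mean-imputed per SNP; zero-variance SNPs are dropped
    before scaling.  Sign convention: the largest-magnitude loading of
    each component is positive.
    """
    x = g.dosage.astype(float)
    x[g.dosage == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    x = (x[:, keep] - col_mean[keep]) / sd[keep]
    if k > min(x.shape):
        raise ValueError(f"k={k} exceeds rank bound {min(x.shape)}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic orientation: dominant loading positive per component
    for comp in range(len(s)):
        j = np.argmax(np.abs(vt[comp]))
        if vt[comp, j] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    scores = u[:, :k] * s[:k]
    lam = s**2
    explained = lam[:k] / lam.sum()
    return PCAResult(
        list(g.samples["sample_id"]),
        scores,
        explained,
        vt[:k].T if keep_loadings else None,
    )


def lof_outliers(
    scores: np.ndarray,
    sample_ids: list[str],
    populations: list[str] | None = None,
    k_neighbors: int = 20,
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Local outlier factor on the leading PCs, applied per population.

    Returns a frame (sample_id, population, lof_score, flagged); flagged
    iff lof_score > threshold.
    """
    scores = np.asarray(scores, dtype=float)
    if populations is None:
        populations = ["all"] * len(sample_ids)
    out = []
    frame = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    for pop, grp in frame.groupby("population", sort=False):
        idx = grp.index.to_numpy()
        n = len(idx)
        if n <= 2:
            for i in idx:
                out.append((sample_ids[i], pop, 1.0, False))
            continue
        kn = min(k_neighbors, n - 1)
        lof = LocalOutlierFactor(n_neighbors=kn)
        lof.fit(scores[idx])
        score = -lof.negative_outlier_factor_
        score = np.maximum(score, 1e-12)
        for i, s in zip(idx, score):
            out.append((sample_ids[i], pop, float(s), bool(s > threshold)))
    return pd.DataFrame(
        out, columns=["sample_id", "population", "lof_score", "flagged"]
    )


def remove_outliers(
    g: GenotypeMatrix,
    n_pcs: int = 3,
    k_neighbors: int = 20,
    threshold: float = 1.5,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Fit PCA, flag LOF outliers on the first ``n_pcs`` PCs per
    population, and drop them."""
    res = pca(g, k=min(n_pcs, g.n_samples - 1, g.n_variants))
    report = lof_outliers(
        res.scores,
        res.sample_ids,
        list(g.samples["population"]),
        k_neighbors=k_neighbors,
        threshold=threshold,
    )
    keep = ~report["flagged"].to_numpy()
    return g.take_samples(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# IBS dissimilarity and hierarchical clustering
# ---------------------------------------------------------------------------

def ibs_dissimilarity(g: GenotypeMatrix) -> np.ndarray:
    """d(i,j) = 1 - mean(IBS/2) over jointly called SNPs.

    IBS = 2 - |dosage_i - dosage_j|.  Pairs with no jointly called SNP get
    NaN.
    """
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    n = g.n_samples
    x = g.dosage.astype(float)
    valid = g.dosage != MISSING
    d = np.zeros((n, n))
    for i in range(n):
        joint = valid[i] & valid[i + 1 :]
        diff = np.abs(x[i] - x[i + 1 :])
        diff[~joint] = 0.0
        counts = joint.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(counts > 0, diff.sum(axis=1) / (2.0 * counts), np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


@dataclass
class Dendrogram:
    labels: list[str]
    linkage_matrix: np.ndarray  # scipy format; heights non-decreasing

    def to_newick(self) -> str:
        """Newick with branch lengths; merge heights are halved so leaf-to-
        leaf path lengths reproduce the cophenetic distances."""
        if len(self.labels) == 1:
            return f"{self.labels[0]}:0;"
        root = to_tree(self.linkage_matrix)

        def height(node):
            return 0.0 if node.is_leaf() else node.dist / 2.0

        def walk(node, parent_height):
            length = parent_height - height(node)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, height(node))
            right = walk(node.right, height(node))
            return f"({left},{right}):{length:.10g}"

        left = walk(root.left, height(root))
        right = walk(root.right, height(root))
        return f"({left},{right});"

    def cophenetic(self) -> np.ndarray:
        from scipy.cluster.hierarchy import cophenet

        return squareform(cophenet(self.linkage_matrix))


def hierarchical_tree(dissimilarity: np.ndarray, labels: list[str]) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric dissimilarity matrix."""
    d = np.asarray(dissimilarity, dtype=float)
    if len(labels) == 1:
        return Dendrogram(list(labels), np.empty((0, 4)))
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains undefined entries")
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(list(labels), z)
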