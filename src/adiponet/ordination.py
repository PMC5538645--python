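"""Condition-signature views: expression filtering, sample PCA on
log2(FPKM+1), and Ward hierarchical clustering on Spearman-correlation
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix


def filter_expressed(em: ExpressionMatrix,
                     min_fpkm: float = 5.0,
                     aggregate: str = "max") -> ExpressionMatrix:
    """Retain genes whose max (or mean) FPKM across samples is strictly above
    ``min_fpkm``."""
    if aggregate == "max":
        stat = em.values.max(axis=1)
    elif aggregate == "mean":
        stat = em.values.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    keep = stat > min_fpkm
    if not keep.any():
        raise ValueError(
            f"no gene exceeds FPKM {min_fpkm}; lower the threshold"
        )
    return ExpressionMatrix(em.values.loc[keep].copy(), em.meta.copy())


@dataclass
class OrdinationResult:
    scores: pd.DataFrame              # samples x components
    variance_fractions: np.ndarray    # per-component, non-increasing
    loadings: pd.DataFrame            # genes x components
    mean: pd.Series                   # per-gene centering offsets


def pca_samples(em: ExpressionMatrix) -> OrdinationResult:
    """Exact PCA of samples on gene-centered log2(FPKM+1).

    Sign convention: for each component the gene with the largest absolute
    loading carries a positive loading, making the decomposition
    deterministic.
    """
    if em.values.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = np.log2(em.values.to_numpy(dtype=float) + 1.0).T  # samples x genes
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    n = x.shape[0]
    var = s ** 2 / (n - 1)
    total = var.sum()
    fractions = var / total if total > 0 else var
    # deterministic sign: largest-|loading| gene positive per component
    for j in range(vt.shape[0]):
        g = int(np.argmax(np.abs(vt[j])))
        if vt[j, g] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=em.sample_ids, columns=comp_names),
        variance_fractions=fractions,
        loadings=pd.DataFrame(vt.T, index=em.gene_ids, columns=comp_names),
        mean=pd.Series(mean, index=em.gene_ids),
    )


def spearman_distance(em: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise d(i,j) = 1 - Spearman rho between sample profiles."""
    x = em.values.to_numpy(dtype=float)
    for j, sid in enumerate(em.sample_ids):
        if np.all(x[:, j] == x[0, j]):
            raise ValueError(
                f"sample {sid!r} has a constant profile; Spearman undefined"
            )
    rho = stats.spearmanr(x).statistic
    if np.isscalar(rho):  # two samples
        rho = np.array([[1.0, rho], [rho, 1.0]])
    d = 1.0 - np.asarray(rho)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return pd.DataFrame(d, index=em.sample_ids, columns=em.sample_ids)


def hcluster_samples(em: ExpressionMatrix, *, linkage: str = "ward",
                     metric: str = "spearman") -> tuple[np.ndarray, list[str]]:
    """Ward agglomeration (Lance-Williams on squared distances) of samples on
    1 - Spearman rho.  Returns (scipy linkage matrix, leaf sample ids)."""
    if metric != "spearman":
        raise ValueError("only the spearman metric is implemented")
    if em.values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    d = spearman_distance(em)
    condensed = squareform(d.to_numpy(), checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return z, em.sample_ids


def cut_tree(z: np.ndarray, sample_ids: list[str], k: int) -> dict[str, int]:
    """Flat cluster labels for a k-group cut of the linkage tree."""
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return {sid: int(lab) for sid, lab in zip(sample_ids, labels)}
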