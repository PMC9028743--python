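"""Count filtering, normalization and replicate-similarity diagnostics.

Median-of-ratios size factors, log2 normalized expression, pairwise Pearson
correlation with hierarchical clustering, PCA on top-variable genes, and the
top-k abundance-overlap comparison between sample groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .data import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "PcaResult",
    "drop_unexpressed",
    "size_factors",
    "normalize",
    "sample_correlation",
    "pca",
    "abundance_overlap",
]


@dataclass
class NormalizedMatrix:
    """Counts divided columnwise by per-sample size factors."""

    gene_ids: list[str]
    sample_ids: list[str]
    normalized: np.ndarray  # genes x samples, float
    factors: np.ndarray  # per-sample size factors, > 0

    @property
    def log2(self) -> np.ndarray:
        """log2(normalized + 1) view used for correlation/PCA diagnostics."""
        return np.log2(self.normalized + 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.normalized, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PcaResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    variance_fraction: np.ndarray  # per component, non-increasing

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.variance_fraction) <= 1e-12)
        assert self.variance_fraction.sum() <= 1.0 + 1e-9


def drop_unexpressed(counts: CountMatrix) -> CountMatrix:
    """Remove genes with zero counts in every sample.

    Mirrors the standard pre-filter for bulk RNA-seq differential
    expression; idempotent.
    """
    keep = counts.counts.sum(axis=1) > 0
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("all genes have zero counts in every sample")
    if n_removed:
        logger.info("drop_unexpressed: removed %d all-zero genes", n_removed)
    gene_ids = [g for g, k in zip(counts.gene_ids, keep) if k]
    return CountMatrix(gene_ids, list(counts.sample_ids), counts.counts[keep, :])


def size_factors(counts: CountMatrix, allow_pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over reference genes of
    count / geometric mean of that gene across samples.  Reference genes are
    rows with no zero count.  If none exist, either raise (default) or — with
    ``allow_pseudo_reference`` — fall back to rows whose geometric mean over
    the positive entries is finite, zeros excluded per gene.
    """
    mat = counts.counts.astype(float)
    reference = np.all(mat > 0, axis=1)
    if not reference.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has positive counts in every sample; re-run with "
                "allow_pseudo_reference=True to use a positive-entry pseudo-reference"
            )
        # geometric mean over positive entries only
        ref_rows = mat.sum(axis=1) > 0
        logmat = np.where(mat > 0, np.log(np.where(mat > 0, mat, 1.0)), np.nan)
        geo = np.exp(np.nanmean(logmat[ref_rows], axis=1))
        ratios = np.where(mat[ref_rows] > 0, mat[ref_rows] / geo[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        ref = mat[reference, :]
        geo = np.exp(np.mean(np.log(ref), axis=1))
        ratios = ref / geo[:, None]
        factors = np.median(ratios, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("size factor estimation produced a non-positive factor")
    return factors


def normalize(counts: CountMatrix, factors: np.ndarray | None = None, **kw) -> NormalizedMatrix:
    if factors is None:
        factors = size_factors(counts, **kw)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,) or np.any(factors <= 0):
        raise ValueError("size factors must be positive, one per sample")
    return NormalizedMatrix(
        list(counts.gene_ids),
        list(counts.sample_ids),
        counts.counts / factors[None, :],
        factors,
    )


def sample_correlation(
    norm: NormalizedMatrix, linkage_method: str = "average"
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation of log2 expression with a dendrogram ordering.

    Hierarchical clustering uses distance 1 - r with average linkage (the
    linkage is configurable).  Returns the symmetric correlation matrix and
    the leaf order of the dendrogram.
    """
    if norm.normalized.shape[1] < 2:
        raise ValueError("sample correlation requires at least 2 samples")
    logmat = norm.log2
    stds = logmat.std(axis=0)
    zero_var = np.where(stds == 0)[0]
    if zero_var.size:
        raise ValueError(
            f"sample {norm.sample_ids[zero_var[0]]!r} has zero variance; "
            "Pearson correlation undefined"
        )
    corr = np.corrcoef(logmat.T)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    link = sch.linkage(ssd.squareform(dist, checks=False), method=linkage_method)
    order = sch.leaves_list(link)
    corr_df = pd.DataFrame(corr, index=norm.sample_ids, columns=norm.sample_ids)
    return corr_df, [norm.sample_ids[i] for i in order]


def pca(norm: NormalizedMatrix, n_top_genes: int = 500, n_components: int | None = None) -> PcaResult:
    """PCA of samples on the log2 expression of the most variable genes.

    Genes are ranked by variance of log2 expression; the top ``n_top_genes``
    are centered per gene and decomposed by SVD.  Variance fractions are
    relative to the total variance of the selected, centered submatrix.
    """
    if norm.normalized.shape[1] < 3:
        raise ValueError("PCA requires at least 3 samples")
    if n_top_genes < 2:
        raise ValueError("n_top_genes must be >= 2")
    logmat = norm.log2
    variances = logmat.var(axis=1)  # per-gene variance across samples
    k = min(n_top_genes, logmat.shape[0])
    top = np.argsort(-variances, kind="stable")[:k]
    X = logmat[top, :].T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = (S**2).sum()
    if total_var == 0:
        raise ValueError("selected genes have zero variance; PCA undefined")
    if n_components is None:
        n_components = min(X.shape) - 1 or 1
    n_components = min(n_components, len(S))
    scores = U[:, :n_components] * S[:n_components]
    var_frac = (S[:n_components] ** 2) / total_var
    return PcaResult(list(norm.sample_ids), scores, var_frac)


def abundance_overlap(
    norm_a: NormalizedMatrix, norm_b: NormalizedMatrix, k: int = 1000
) -> dict:
    """Shared fraction of the k most abundant genes between two groups.

    Genes are ranked by mean normalized count within each group; ties break
    lexicographically by gene id so the ranking is deterministic.
    """
    if norm_a.gene_ids != norm_b.gene_ids:
        raise ValueError("abundance_overlap requires the same gene universe in both groups")
    if k > len(norm_a.gene_ids):
        raise ValueError(f"k={k} exceeds the number of genes ({len(norm_a.gene_ids)})")

    def top_k(norm: NormalizedMatrix) -> set[str]:
        means = norm.normalized.mean(axis=1)
        ranked = sorted(zip(norm.gene_ids, means), key=lambda t: (-t[1], t[0]))
        return {g for g, _ in ranked[:k]}

    a, b = top_k(norm_a), top_k(norm_b)
    shared = a & b
    return {
        "k": k,
        "shared": sorted(shared),
        "n_shared": len(shared),
        "shared_fraction": len(shared) / k,
        "unique_a": sorted(a - b),
        "unique_b": sorted(b - a),
    }
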