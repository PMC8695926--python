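"""Ordination of sample methylomes, separation scoring and enrichment tests.

Samples are embedded from their gene-level methylation profiles either by
PCA (centered per gene, unscaled — all features already share the [0, 1]
methylation scale) or by classical metric MDS on Euclidean distances
(Torgerson double centering; for Euclidean input the two are equivalent up
to rotation and sign). Group separation in an embedding is quantified by
the mean silhouette coefficient, which turns a visual "the samples
separate" claim into a number in [-1, 1].

Annotation enrichment (housekeeping genes, transposable-element overlap)
uses the 2x2 Pearson chi-square without continuity correction; expression
comparisons use Welch's unequal-variance t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import t as _t
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .aggregate import MethylationMatrix

__all__ = [
    "Embedding",
    "pca_embed",
    "mds_embed",
    "separation_score",
    "chisq_enrichment",
    "welch_t_compare",
]

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """Sample coordinates in a low-dimensional ordination."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    variance_explained: np.ndarray | None
    method: str

    def __post_init__(self) -> None:
        if self.variance_explained is not None:
            ve = np.asarray(self.variance_explained, dtype=float)
            if ((ve < -1e-12) | (ve > 1 + 1e-12)).any():
                raise ValueError("variance_explained entries must lie in [0, 1]")
            if ve.sum() > 1 + 1e-9:
                raise ValueError("variance_explained must sum to <= 1")

    def to_frame(self, labels: Mapping[str, str] | None = None) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"dim{i + 1}" for i in range(k)],
        )
        if labels is not None:
            df["group"] = [labels[s] for s in self.sample_ids]
        return df


def _complete_sample_matrix(
    matrix: MethylationMatrix, gene_set: Iterable[str] | None
) -> np.ndarray:
    """Samples x genes array after dropping genes with any missing entry."""
    values = matrix.values
    if gene_set is not None:
        keep = set(gene_set)
        values = values.loc[[g for g in values.index if g in keep]]
    complete = values.dropna(axis=0)
    dropped = len(values) - len(complete)
    if dropped:
        logger.info("ordination: dropped %d gene(s) with missing values", dropped)
    if complete.empty:
        raise ValueError("no genes without missing values to ordinate on")
    return complete.to_numpy(dtype=float).T  # samples x genes


def pca_embed(
    matrix: MethylationMatrix,
    gene_set: Iterable[str] | None = None,
    k: int = 2,
    scale: bool = False,
) -> Embedding:
    """PCA of sample methylation profiles over a gene set.

    Genes carrying any missing value are dropped first (no imputation).
    Features (genes) are mean-centered; ``scale=True`` additionally divides
    by the per-gene standard deviation. Deterministic up to per-axis sign.
    """
    x = _complete_sample_matrix(matrix, gene_set)
    n_samples = x.shape[0]
    if n_samples < k + 1:
        raise ValueError(f"pca_embed: needs >= k+1 = {k + 1} samples, got {n_samples}")
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    centered = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if k > rank:
        raise ValueError(f"pca_embed: k={k} exceeds data rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    return Embedding(
        sample_ids=list(matrix.sample_ids),
        coordinates=coords,
        variance_explained=pca.explained_variance_ratio_,
        method="pca",
    )


def mds_embed(
    matrix: MethylationMatrix,
    gene_set: Iterable[str] | None = None,
    k: int = 2,
) -> Embedding:
    """Classical (Torgerson) metric MDS on Euclidean sample distances.

    Double-centers the squared distance matrix and takes the top-k
    eigenvectors scaled by the square roots of their eigenvalues. For
    Euclidean input this reproduces the PCA configuration up to rotation
    and sign, and the full-dimensional embedding reproduces the input
    distances exactly (up to numerical precision).
    """
    x = _complete_sample_matrix(matrix, gene_set)
    n = x.shape[0]
    if n < k + 1:
        raise ValueError(f"mds_embed: needs >= k+1 = {k + 1} samples, got {n}")
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    n_pos = int(positive.sum())
    if n_pos == 0:  # all samples coincide: a zero-distance configuration
        return Embedding(
            sample_ids=list(matrix.sample_ids),
            coordinates=np.zeros((n, k)),
            variance_explained=np.zeros(k),
            method="mds",
        )
    if k > n_pos:
        raise ValueError(f"mds_embed: k={k} exceeds embedding rank {n_pos}")
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    var_exp = eigvals[:k] / eigvals[positive].sum()
    return Embedding(
        sample_ids=list(matrix.sample_ids),
        coordinates=coords,
        variance_explained=var_exp,
        method="mds",
    )


def separation_score(embedding: Embedding, labels: Mapping[str, str] | pd.Series) -> float:
    """Mean silhouette coefficient of the group labeling in the embedding.

    Euclidean distances in the embedding space; +1 means tight, well
    separated groups, ~0 means no structure, negative means samples sit
    closer to another group than their own.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    y = np.asarray([labels[s] for s in embedding.sample_ids])
    if len(np.unique(y)) < 2:
        raise ValueError("separation_score: needs >= 2 groups")
    return float(silhouette_score(embedding.coordinates, y, metric="euclidean"))


class EnrichmentResult(NamedTuple):
    chi2: float
    p_value: float
    fold_enrichment: float


def chisq_enrichment(
    in_set_with_flag: int,
    in_set_without: int,
    background_with: int,
    background_without: int,
) -> EnrichmentResult:
    """Pearson chi-square (no continuity correction) for a 2x2 enrichment table.

    Rows: gene set vs. background; columns: flag present vs. absent.
    ``fold_enrichment`` is the flag proportion in the set divided by the
    flag proportion in the background.
    """
    a, b, c, d = in_set_with_flag, in_set_without, background_with, background_without
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(_chi2.sf(chi2, 1))
    set_prop, bg_prop = a / r1, c / r2
    fold = set_prop / bg_prop if bg_prop > 0 else float("inf")
    return EnrichmentResult(float(chi2), p, float(fold))


class TTestResult(NamedTuple):
    t: float
    p_value: float
    degenerate: bool = False


def welch_t_compare(values_a: Sequence[float], values_b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance two-sided t-test.

    Degrees of freedom by Welch-Satterthwaite. When both groups have zero
    variance and equal means the statistic is undefined; p = 1 is returned
    with the degenerate flag set.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_compare: each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, degenerate=True)
        return TTestResult(float(np.inf) * np.sign(a.mean() - b.mean()), 0.0, degenerate=True)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(_t.sf(abs(t), df))
    return TTestResult(float(t), min(1.0, p))
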