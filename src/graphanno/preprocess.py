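"""Feature processing: HVG selection, z-scoring, TF-IDF, gene activity, embeddings.

Conventions
-----------
* Highly variable genes are ranked by variance of log1p counts-per-10k.
* TF-IDF follows the Signac dialect ``log1p(1e4 * TF * IDF)`` with
  ``TF = x / rowsum`` and ``IDF = n_cells / (1 + df)``; zeros stay zero.
* Gene activity sums peak counts over the gene body plus a strand-aware
  upstream extension (default 2 kb).
* PCA / LSI components carry a fixed sign convention (largest-|loading|
  entry positive) so downstream graphs are bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from intervaltree import IntervalTree

from graphanno.io import FeatureMatrix, GeneTable, PeakTable, ValidationError

__all__ = [
    "EmbeddingMatrix",
    "select_hvg",
    "standardize",
    "tfidf",
    "gene_activity",
    "pca_embed",
    "lsi_embed",
    "log_normalize",
]

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingMatrix:
    """Low-dimensional cell coordinates with provenance."""

    coords: np.ndarray
    cell_ids: list[str]
    method: str  # pca | lsi | cca | latent

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValidationError("embedding coords must be 2-D")
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValidationError("embedding rows and cell ids mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("embedding contains non-finite values")

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def _row_sums(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.sum(axis=1)).ravel()
    return np.asarray(values).sum(axis=1)


def log_normalize(X: FeatureMatrix, scale: float = 1e4) -> FeatureMatrix:
    """log1p counts-per-``scale`` normalization (sparse-preserving)."""
    totals = _row_sums(X.values)
    totals = np.where(totals == 0, 1.0, totals)
    if sp.issparse(X.values):
        mat = X.values.tocsr().astype(float)
        scaled = sp.diags(scale / totals) @ mat
        scaled.data = np.log1p(scaled.data)
        out = scaled
    else:
        out = np.log1p(np.asarray(X.values, dtype=float) * (scale / totals)[:, None])
    return FeatureMatrix(out, list(X.cell_ids), list(X.feature_ids), X.modality)


def select_hvg(X: FeatureMatrix, g: int) -> FeatureMatrix:
    """Keep the ``g`` genes with highest variance of log1p CP10K counts.

    Returned genes are ordered by decreasing variance rank.
    """
    if g < 2:
        raise ValueError("need at least 2 highly variable genes")
    if g > X.n_features:
        raise ValueError(f"requested {g} genes but matrix has {X.n_features}")
    norm = log_normalize(X).dense()
    var = norm.var(axis=0)  # population variance
    order = np.argsort(-var, kind="stable")[:g]
    keep = [X.feature_ids[i] for i in order]
    return X.subset_features(keep)


def standardize(X: FeatureMatrix) -> FeatureMatrix:
    """Per-feature z-score over cells (population sd); zero-variance -> zeros."""
    dense = X.dense()
    mean = dense.mean(axis=0)
    sd = dense.std(axis=0)
    # features whose spread is pure floating-point residue count as constant
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    safe_sd = np.where(zero, 1.0, sd)
    out = (dense - mean) / safe_sd
    out[:, zero] = 0.0
    return FeatureMatrix(out, list(X.cell_ids), list(X.feature_ids), X.modality)


def tfidf(X: FeatureMatrix, scale: float = 1e4) -> FeatureMatrix:
    """TF-IDF normalize a peak count matrix: ``log1p(scale * TF * IDF)``.

    Cells with zero total counts are dropped with a warning (their TF term
    is undefined); all-zero peaks are allowed and stay zero columns.
    """
    mat = X.values.tocsr().astype(float) if sp.issparse(X.values) else sp.csr_matrix(
        np.asarray(X.values, dtype=float)
    )
    totals = np.asarray(mat.sum(axis=1)).ravel()
    keep = totals > 0
    cell_ids = list(X.cell_ids)
    if not np.all(keep):
        n_dropped = int((~keep).sum())
        warnings.warn(f"dropping {n_dropped} all-zero cells before TF-IDF")
        logger.info("tfidf: dropped %d all-zero cells", n_dropped)
        mat = mat[keep]
        cell_ids = [c for c, k in zip(cell_ids, keep) if k]
        totals = totals[keep]
    n_cells = mat.shape[0]
    df = np.asarray((mat > 0).sum(axis=0)).ravel()
    idf = n_cells / (1.0 + df)
    tf = sp.diags(1.0 / totals) @ mat
    out = tf @ sp.diags(idf)
    out.data = np.log1p(scale * out.data)
    return FeatureMatrix(out.tocsr(), cell_ids, list(X.feature_ids), X.modality)


def _gene_windows(genes: GeneTable, upstream: int) -> tuple[np.ndarray, np.ndarray]:
    """Gene body plus strand-aware 5' upstream extension, clipped at 0."""
    start = genes.start.copy()
    end = genes.end.copy()
    for i, s in enumerate(genes.strand):
        if s == "+":
            start[i] = max(0, start[i] - upstream)
        else:
            end[i] = end[i] + upstream
    return start, end


def gene_activity(
    X_atac: FeatureMatrix,
    peaks: PeakTable,
    genes: GeneTable,
    upstream: int = 2000,
    gene_subset: list[str] | None = None,
) -> FeatureMatrix:
    """Per-cell, per-gene sum of counts of peaks overlapping the gene window.

    The window is the gene body extended ``upstream`` bp 5' of the TSS
    (strand-aware).  Each peak contributes its full count to every gene
    window it overlaps (counted once per gene).  Genes without overlapping
    peaks — including genes absent from the annotation — yield zero columns.
    """
    peak_index = {p: i for i, p in enumerate(peaks.peak_ids)}
    missing = [f for f in X_atac.feature_ids if f not in peak_index]
    if missing:
        raise ValidationError(f"matrix peaks missing coordinates: {missing[:5]}")

    if gene_subset is None:
        gene_subset = list(genes.gene_ids)
    gene_pos = {gid: i for i, gid in enumerate(genes.gene_ids)}

    win_start, win_end = _gene_windows(genes, upstream)
    trees: dict[str, IntervalTree] = {}
    out_col = {gid: j for j, gid in enumerate(gene_subset)}
    n_absent = 0
    for gid in gene_subset:
        if gid not in gene_pos:
            n_absent += 1
            continue
        i = gene_pos[gid]
        trees.setdefault(genes.chrom[i], IntervalTree()).addi(
            win_start[i], win_end[i], gid
        )
    if n_absent:
        warnings.warn(f"{n_absent} genes absent from annotation; zero activity columns")

    # peak -> gene link matrix (p x g), then activity = X @ L
    rows, cols = [], []
    for j, pid in enumerate(X_atac.feature_ids):
        i = peak_index[pid]
        tree = trees.get(peaks.chrom[i])
        if tree is None:
            continue
        for hit in tree.overlap(peaks.start[i], peaks.end[i]):
            rows.append(j)
            cols.append(out_col[hit.data])
    links = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(X_atac.n_features, len(gene_subset)),
    )
    mat = X_atac.values if sp.issparse(X_atac.values) else sp.csr_matrix(X_atac.values)
    activity = (mat @ links).tocsr()
    return FeatureMatrix(activity, list(X_atac.cell_ids), list(gene_subset), "gene_activity")


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-|loading| entry of each component positive."""
    for j in range(loadings.shape[0]):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    return scores, loadings


def _svd(dense: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic truncated SVD (descending singular values)."""
    U, s, Vt = np.linalg.svd(dense, full_matrices=False)
    return U[:, :n], s[:n], Vt[:n]


def pca_embed(X: FeatureMatrix, n: int = 30) -> EmbeddingMatrix:
    """Top-``n`` principal components of the (already standardized) matrix.

    Deterministic up to the fixed sign rule: the largest-|loading| entry of
    every component is positive.
    """
    dense = X.dense()
    if n >= min(dense.shape):
        raise ValueError(
            f"n={n} must be < min(cells, features) = {min(dense.shape)}"
        )
    centered = dense - dense.mean(axis=0)
    U, s, Vt = _svd(centered, n)
    scores = U * s
    scores, _ = _fix_signs(scores, Vt.copy())
    return EmbeddingMatrix(scores, list(X.cell_ids), "pca")


def lsi_embed(
    X_tfidf: FeatureMatrix, n: int = 30, drop_first: bool = True
) -> EmbeddingMatrix:
    """Truncated SVD of the TF-IDF matrix (latent semantic indexing).

    With ``drop_first`` (the default) the first component — which tracks
    per-cell sequencing depth — is discarded and components 2..n are
    returned (``n - 1`` dimensions).
    """
    dense = X_tfidf.dense()
    if n > min(dense.shape):
        raise ValueError(
            f"n={n} exceeds min(cells, peaks) = {min(dense.shape)}; lower n"
        )
    U, s, Vt = _svd(dense, n)
    if s[-1] < 1e-10:
        raise ValueError(
            f"matrix rank below n={n} (singular value {s[-1]:.2e}); lower n"
        )
    scores = U * s
    scores, _ = _fix_signs(scores, Vt.copy())
    if drop_first:
        scores = scores[:, 1:]
    return EmbeddingMatrix(scores, list(X_tfidf.cell_ids), "lsi")
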