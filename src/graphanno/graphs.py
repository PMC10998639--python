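"""Cell graphs: mutual-kNN graphs, CCA anchors, the hybrid and merged graphs.

All adjacency matrices are symmetric, binary, zero-diagonal scipy sparse.
"Shared nearest neighbors" is read as mutual (reciprocal) kNN throughout:
an edge (i, j) exists iff i is among j's k nearest and vice versa, with
ties on distance broken by ascending index for determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from graphanno.io import ValidationError
from graphanno.preprocess import EmbeddingMatrix, _svd

__all__ = [
    "CellGraph",
    "AnchorSet",
    "HybridGraph",
    "mutual_knn_graph",
    "cca_shared_space",
    "detect_anchors",
    "build_hybrid_graph",
    "build_merged_graph",
]

logger = logging.getLogger(__name__)


@dataclass
class CellGraph:
    """Symmetric binary adjacency over identified cells."""

    adjacency: sp.spmatrix
    node_ids: list[str]
    node_modality: list[str]  # per-node: rna | atac

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency)
        A.eliminate_zeros()
        n = A.shape[0]
        if A.shape[0] != A.shape[1]:
            raise ValidationError("adjacency must be square")
        if n != len(self.node_ids) or n != len(self.node_modality):
            raise ValidationError("adjacency size and node metadata mismatch")
        if (A != A.T).nnz != 0:
            raise ValidationError("adjacency must be symmetric")
        if A.diagonal().sum() != 0:
            raise ValidationError("adjacency must have zero diagonal")
        if A.nnz and not np.all(A.data == 1):
            raise ValidationError("adjacency must be binary")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def n_isolated(self) -> int:
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        return int((deg == 0).sum())


@dataclass
class AnchorSet:
    """Reciprocal RNA-ATAC cell pairs found in the shared CCA space."""

    pairs: list[tuple[int, int]]  # (rna_index, atac_index)
    scores: np.ndarray  # cosine similarity per pair

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.pairs) != len(self.scores):
            raise ValidationError("pairs and scores length mismatch")

    @property
    def atac_anchors(self) -> list[int]:
        """Distinct ATAC anchor indices, ascending (the set A)."""
        return sorted({a for _, a in self.pairs})

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class HybridGraph:
    """RNA graph extended with ATAC anchor nodes, plus gene-level features.

    Node order: the ``n_rna`` RNA cells first, then the distinct ATAC
    anchors (ascending ATAC index).  ``features`` stacks the standardized
    RNA expression block over the standardized gene-activity rows of the
    anchors; both blocks share the same gene columns.
    """

    graph: CellGraph
    features: np.ndarray
    n_rna: int
    anchor_atac_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.graph.n_nodes != self.n_rna + len(self.anchor_atac_indices):
            raise ValidationError("hybrid node count != n_rna + n_anchors")
        if self.features.shape[0] != self.graph.n_nodes:
            raise ValidationError("hybrid features row count mismatch")


def _knn_lists(dist: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest columns per row; ties by ascending index."""
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :k]


def mutual_knn_graph(emb: EmbeddingMatrix, k: int, modality: str = "rna") -> CellGraph:
    """Mutual kNN graph under Euclidean distance (exact, all-pairs).

    Edge (i, j) iff ``j in kNN(i)`` and ``i in kNN(j)``, self excluded.
    Isolated nodes are permitted (counted in the log).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = emb.coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    dist = cdist(emb.coords, emb.coords)
    np.fill_diagonal(dist, np.inf)
    nn = _knn_lists(dist, k)
    member = np.zeros((n, n), dtype=bool)
    member[np.repeat(np.arange(n), k), nn.ravel()] = True
    adj = (member & member.T).astype(np.int8)
    graph = CellGraph(sp.csr_matrix(adj), list(emb.cell_ids), [modality] * n)
    logger.info(
        "mutual_knn_graph(k=%d): %d nodes, %d edges, %d isolated",
        k, graph.n_nodes, graph.n_edges, graph.n_isolated,
    )
    return graph


def cca_shared_space(
    X_rna_std, X_gam_std, n: int = 30
) -> tuple[EmbeddingMatrix, EmbeddingMatrix]:
    """Project both modalities into one space via SVD of the cross-product.

    Computes the SVD of ``X_rna_std @ X_gam_std.T`` over the shared gene
    columns (diagonal-free CCA as used in Seurat-style integration).  The
    top-``n`` left/right singular vectors, scaled by their singular values
    so that low-correlation components carry proportionally less weight,
    become the cell coordinates; each row is then L2-normalized.
    """
    if X_rna_std.feature_ids != X_gam_std.feature_ids:
        raise ValidationError("CCA inputs must share identical gene columns")
    K = X_rna_std.dense() @ X_gam_std.dense().T
    if n > min(K.shape):
        raise ValueError(f"n={n} exceeds rank bound {min(K.shape)}")
    U, s, Vt = _svd(K, n)
    V = Vt.T
    U = U * s
    V = V * s
    # sign rule keyed on the left singular vectors; the flip is shared so
    # the two modalities stay in the same half-space
    for j in range(n):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] *= -1
            V[:, j] *= -1
    def _l2(rows: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(rows, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return rows / norms
    return (
        EmbeddingMatrix(_l2(U), list(X_rna_std.cell_ids), "cca"),
        EmbeddingMatrix(_l2(V), list(X_gam_std.cell_ids), "cca"),
    )


def detect_anchors(U_rna: EmbeddingMatrix, U_gam: EmbeddingMatrix, k2: int) -> AnchorSet:
    """Cross-modality mutual-kNN pairs in the shared space (anchor cells).

    Pair (r, a) is kept iff ``a`` is among the ``k2`` ATAC cells nearest to
    ``r`` and ``r`` is among the ``k2`` RNA cells nearest to ``a``.  The
    score is the cosine similarity of the pair.
    """
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    n1, n2 = U_rna.coords.shape[0], U_gam.coords.shape[0]
    dist = cdist(U_rna.coords, U_gam.coords)
    k_r = min(k2, n2)
    k_a = min(k2, n1)
    nn_of_rna = _knn_lists(dist, k_r)  # per RNA cell: nearest ATAC cells
    nn_of_atac = _knn_lists(dist.T, k_a)  # per ATAC cell: nearest RNA cells
    in_rna_list = np.zeros((n1, n2), dtype=bool)
    in_rna_list[np.repeat(np.arange(n1), k_r), nn_of_rna.ravel()] = True
    in_atac_list = np.zeros((n2, n1), dtype=bool)
    in_atac_list[np.repeat(np.arange(n2), k_a), nn_of_atac.ravel()] = True
    mutual = in_rna_list & in_atac_list.T
    rs, as_ = np.nonzero(mutual)
    if len(rs) == 0:
        raise ValidationError(
            "no anchor cells detected; training is impossible without anchors "
            "- increase k2 or check that the modalities share cell types"
        )
    norm_r = np.linalg.norm(U_rna.coords[rs], axis=1)
    norm_a = np.linalg.norm(U_gam.coords[as_], axis=1)
    dots = np.einsum("ij,ij->i", U_rna.coords[rs], U_gam.coords[as_])
    denom = np.where(norm_r * norm_a == 0, 1.0, norm_r * norm_a)
    scores = dots / denom
    pairs = list(zip(rs.tolist(), as_.tolist()))
    anchors = AnchorSet(pairs, scores)
    logger.info(
        "detect_anchors(k2=%d): %d pairs over %d distinct ATAC anchors",
        k2, len(pairs), len(anchors.atac_anchors),
    )
    return anchors


def build_hybrid_graph(
    G_rna: CellGraph,
    anchors: AnchorSet,
    X_rna_std,
    X_gam_std,
) -> HybridGraph:
    """Extend the RNA graph with the ATAC anchor cells.

    Nodes are the RNA cells followed by the distinct ATAC anchors.  RNA-RNA
    edges are copied from ``G_rna``; each anchor node is connected to the
    RNA cells it forms reciprocal CCA pairs with (no ATAC-ATAC edges).
    Features stack standardized expression over the anchors' standardized
    gene-activity rows.
    """
    if len(anchors) == 0:
        raise ValidationError("anchor set is empty")
    n1 = G_rna.n_nodes
    atac_anchor = anchors.atac_anchors
    n2 = X_gam_std.n_cells
    for r, a in anchors.pairs:
        if not (0 <= r < n1) or not (0 <= a < n2):
            raise ValidationError(f"anchor pair ({r}, {a}) out of range")
    node_of = {a: n1 + j for j, a in enumerate(atac_anchor)}
    m = n1 + len(atac_anchor)
    A = sp.lil_matrix((m, m), dtype=np.int8)
    A[:n1, :n1] = G_rna.adjacency
    for r, a in anchors.pairs:
        A[r, node_of[a]] = 1
        A[node_of[a], r] = 1
    feats = np.vstack([X_rna_std.dense(), X_gam_std.dense()[atac_anchor]])
    node_ids = list(G_rna.node_ids) + [X_gam_std.cell_ids[a] for a in atac_anchor]
    modality = ["rna"] * n1 + ["atac"] * len(atac_anchor)
    graph = CellGraph(A.tocsr(), node_ids, modality)
    logger.info(
        "build_hybrid_graph: %d nodes (%d RNA + %d anchors), %d edges",
        m, n1, len(atac_anchor), graph.n_edges,
    )
    return HybridGraph(graph, feats, n1, atac_anchor)


def build_merged_graph(
    hybrid: HybridGraph, G_atac: CellGraph
) -> CellGraph:
    """Combine hybrid and ATAC graphs into one graph over all N = n1+n2 cells.

    Node order: all RNA cells, then all ATAC cells.  RNA-RNA edges come from
    the hybrid graph's RNA block, ATAC-ATAC edges from ``G_atac``, and each
    hybrid anchor node's cross-modality edges are remapped to the anchor's
    index within the full ATAC set.
    """
    n1 = hybrid.n_rna
    n2 = G_atac.n_nodes
    N = n1 + n2
    A = sp.lil_matrix((N, N), dtype=np.int8)
    H = hybrid.graph.adjacency
    A[:n1, :n1] = H[:n1, :n1]
    A[n1:, n1:] = G_atac.adjacency
    cross = H[:n1, n1:].tocoo()  # RNA x anchor-node block
    for r, j, v in zip(cross.row, cross.col, cross.data):
        if v:
            a = hybrid.anchor_atac_indices[j]
            A[r, n1 + a] = 1
            A[n1 + a, r] = 1
    node_ids = hybrid.graph.node_ids[:n1] + list(G_atac.node_ids)
    modality = ["rna"] * n1 + ["atac"] * n2
    merged = CellGraph(A.tocsr(), node_ids, modality)
    logger.info(
        "build_merged_graph: N=%d, %d edges (%d cross-modality)",
        N, merged.n_edges, int(cross.nnz),
    )
    return merged
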