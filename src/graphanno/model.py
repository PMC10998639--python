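"""Parallel variational graph auto-encoders with semi-supervised label transfer.

Two VGAE branches are trained jointly: a *hybrid* branch over the RNA graph
extended with ATAC anchor cells (gene-level features) and an *ATAC* branch
over the full ATAC cell graph (TF-IDF peak features).  Each branch is a
two-layer GCN encoder producing (mu, log sigma), reparameterized as
``Z = mu + exp(log sigma) * N(0,1)``.  The latent dimension equals the
number of cell types: the softmax of the merged latent doubles as the
label-probability matrix.

Four losses are combined: the VGAE KL term, a weighted binary cross-entropy
on the inner-product reconstruction of the merged reference-target graph,
an anchor alignment penalty tying the two views of every ATAC anchor cell
together, and a cross-entropy on the labeled reference cells:

    L = L_kl + L_recon + lambda * L_align + L_class

Everything — forward pass, analytic gradients and the Adam optimizer — is
implemented in NumPy; training is full-batch and deterministic under a
fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from graphanno.graphs import CellGraph, HybridGraph
from graphanno.io import FeatureMatrix

__all__ = [
    "ModelConfig",
    "LatentState",
    "VGAEModel",
    "TrainResult",
    "normalize_adjacency",
    "encode",
    "reparameterize",
    "kl_loss",
    "alignment_loss",
    "decode",
    "reconstruction_loss",
    "classification_loss",
    "total_loss",
    "train",
    "predict_labels",
    "peak_importance",
    "holdout_edges",
]

logger = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass
class ModelConfig:
    """Hyperparameters of the parallel VGAE.

    ``hidden_dim`` (d) and ``lr`` follow the robustness trade-off of the
    method (d=128, lr=1e-4); the latent dimension is always the number of
    cell types and is inferred from the label matrix.  ``lam`` weights the
    alignment loss (default 1).  Ablations: ``single_layer`` collapses each
    encoder to one GCN layer (input -> k); ``no_alignment`` sets lam to 0;
    ``no_reconstruction`` drops the reconstruction term.
    """

    hidden_dim: int = 128
    lr: float = 1e-4
    epochs: int = 500
    lam: float = 1.0
    seed: int = 0
    single_layer: bool = False
    no_alignment: bool = False
    no_reconstruction: bool = False
    bce_mode: str = "weighted"  # weighted | unweighted
    kl_mode: str = "element"  # element (per-entry mean) | mean (per-node) | sum
    align_norm: str = "l2"  # l2 | l1

    def __post_init__(self) -> None:
        if self.bce_mode not in ("weighted", "unweighted"):
            raise ValueError("bce_mode must be weighted|unweighted")
        if self.kl_mode not in ("element", "mean", "sum"):
            raise ValueError("kl_mode must be element|mean|sum")
        if self.align_norm not in ("l2", "l1"):
            raise ValueError("align_norm must be l2|l1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class LatentState:
    """Per-branch posterior parameters and the merged latent.

    ``Z_m`` stacks the RNA rows of the hybrid latent over the full ATAC
    latent (N = n1 + n2 rows, k columns); ``Z_hat`` is its row-softmax,
    the label indicator.
    """

    mu_h: np.ndarray
    logsig_h: np.ndarray
    Z_h: np.ndarray
    mu_a: np.ndarray
    logsig_a: np.ndarray
    Z_a: np.ndarray
    n1: int

    @property
    def Z_m(self) -> np.ndarray:
        return np.vstack([self.Z_h[: self.n1], self.Z_a])

    @property
    def Z_hat(self) -> np.ndarray:
        return _softmax_rows(self.Z_m)


@dataclass
class VGAEModel:
    """Fitted weights of both branches plus the configuration."""

    config: ModelConfig
    weights: dict  # {"h": {...}, "a": {...}}
    n_types: int
    feature_dims: dict = field(default_factory=dict)


@dataclass
class TrainResult:
    model: VGAEModel
    latent: LatentState  # evaluation mode (Z = mu)
    trace: pd.DataFrame
    G_hat: np.ndarray  # decoded merged graph from evaluation-mode Z_m


def _softmax_rows(Z: np.ndarray) -> np.ndarray:
    shifted = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


# ---------------------------------------------------------------------------
# building blocks


def normalize_adjacency(A) -> sp.csr_matrix:
    """Symmetric GCN propagation matrix ``D^-1/2 (A + I) D^-1/2``."""
    if isinstance(A, CellGraph):
        A = A.adjacency
    A = sp.csr_matrix(A, dtype=float)
    A_tilde = A + sp.eye(A.shape[0], format="csr")
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return (D @ A_tilde @ D).tocsr()


def encode(A_hat, X, weights: dict, single_layer: bool = False, P=None):
    """GCN encoder: shared first layer, separate mu / log-sigma heads.

    Two-layer: ``H = relu(A X W1)``, ``mu = A H Wmu``, ``logsig = A H Wls``.
    Single-layer: ``mu = A X Wmu`` (input connects directly to the latent).
    Returns ``(mu, logsig, cache)`` where the cache carries intermediates
    for backprop.  ``P`` may supply the precomputed propagated input
    ``A_hat @ X`` (it is constant across epochs).
    """
    if P is None:
        P = A_hat @ X
    if single_layer:
        mu = P @ weights["Wmu"]
        ls = P @ weights["Wls"]
        cache = {"P": P}
    else:
        pre = P @ weights["W1"]
        if sp.issparse(pre):  # sparse P with dense W1 stays dense in practice
            pre = np.asarray(pre.todense())
        H = np.maximum(pre, 0.0)
        M = A_hat @ H
        mu = M @ weights["Wmu"]
        ls = M @ weights["Wls"]
        cache = {"P": P, "pre": pre, "M": M}
    if sp.issparse(mu):
        mu = np.asarray(mu.todense())
        ls = np.asarray(ls.todense())
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(ls))):
        raise FloatingPointError("encoder produced non-finite output")
    return mu, ls, cache


def reparameterize(mu: np.ndarray, logsig: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """``Z = exp(logsig) * noise + mu`` (evaluation mode passes zero noise)."""
    if mu.shape != logsig.shape or mu.shape != noise.shape:
        raise ValueError("mu, logsig and noise must share a shape")
    return np.exp(logsig) * noise + mu


def kl_loss(mu_h, sigma_h, mu_a, sigma_a, mode: str = "element") -> float:
    """KL divergence of both branch posteriors from the standard normal.

    Per element ``0.5 * (mu^2 + sigma^2 - 1 - 2 log sigma)``; each branch is
    summed and then normalized: ``element`` divides by the full tensor size
    (nodes x latent dims, the framework-default mean reduction), ``mean``
    divides by the node count only, ``sum`` applies no normalization.
    """
    total = 0.0
    for mu, sigma in ((mu_h, sigma_h), (mu_a, sigma_a)):
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        term = 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma))
        if mode == "element":
            term /= mu.size
        elif mode == "mean":
            term /= mu.shape[0]
        total += term
    return float(total)


def alignment_loss(
    Z_h: np.ndarray,
    Z_a: np.ndarray,
    anchor_rows_h: np.ndarray,
    anchor_rows_a: np.ndarray,
    norm: str = "l2",
) -> float:
    """Mean distance between the two views of each ATAC anchor cell."""
    if len(anchor_rows_h) == 0:
        raise ValueError("alignment loss undefined without anchors")
    diff = Z_h[anchor_rows_h] - Z_a[anchor_rows_a]
    if norm == "l2":
        per = np.linalg.norm(diff, axis=1)
    else:
        per = np.abs(diff).sum(axis=1)
    return float(per.mean())


def decode(Z_m: np.ndarray) -> np.ndarray:
    """Inner-product decoder: ``sigmoid(Z Z^T)``, an N x N probability matrix."""
    return _sigmoid(Z_m @ Z_m.T)


def reconstruction_loss(G, G_hat: np.ndarray, mode: str = "weighted") -> float:
    """Binary cross-entropy between the merged graph and its reconstruction.

    ``weighted`` (default): standard VGAE class weighting — positives carry
    ``pos_weight = (N^2 - E) / E`` and the mean is scaled by
    ``N^2 / (2 (N^2 - E))``.  ``unweighted``: plain BCE summed over all
    entries and divided by N.
    """
    G = np.asarray(G.todense(), dtype=float) if sp.issparse(G) else np.asarray(G, dtype=float)
    if G.shape != G_hat.shape:
        raise ValueError("graph and reconstruction shape mismatch")
    N = G.shape[0]
    p = np.clip(G_hat, _EPS, 1.0 - _EPS)
    ce = -(G * np.log(p) + (1.0 - G) * np.log(1.0 - p))
    if mode == "unweighted":
        return float(ce.sum() / N)
    E = G.sum()
    if E == 0 or E == N * N:
        raise ValueError("weighted BCE undefined for empty or complete graphs")
    pos_weight = (N * N - E) / E
    norm = N * N / (2.0 * (N * N - E))
    weighted = -(pos_weight * G * np.log(p) + (1.0 - G) * np.log(1.0 - p))
    return float(norm * weighted.mean())


def classification_loss(Z_hat: np.ndarray, Y: np.ndarray, reference_rows: np.ndarray) -> float:
    """Cross-entropy of the label indicator against the reference one-hots.

    Averaged over the n1 reference cells; target rows do not contribute.
    """
    n1 = len(reference_rows)
    probs = np.clip(Z_hat[reference_rows], _EPS, 1.0)
    return float(-(Y * np.log(probs)).sum() / n1)


def total_loss(L_kl: float, L_recon: float, L_align: float, L_class: float, lam: float) -> float:
    return L_kl + L_recon + lam * L_align + L_class


# ---------------------------------------------------------------------------
# training


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_weights(rng, n_feat: int, d: int, k: int, single_layer: bool) -> dict:
    if single_layer:
        # zero init: the single-layer encoder exists for interpretability,
        # so |W| must reflect accumulated learning signal, not random init
        # (gradients differ per input feature, so zeros are trainable here)
        return {"Wmu": np.zeros((n_feat, k)), "Wls": np.zeros((n_feat, k))}
    return {
        "W1": _glorot(rng, n_feat, d),
        "Wmu": _glorot(rng, d, k),
        "Wls": _glorot(rng, d, k),
    }


class _Adam:
    def __init__(self, params: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            m_hat = self.m[key] / (1 - self.b1**self.t)
            v_hat = self.v[key] / (1 - self.b2**self.t)
            params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _branch_backward(dmu, dls, cache, weights, single_layer: bool) -> dict:
    P = cache["P"]
    if single_layer:
        return {"Wmu": P.T @ dmu, "Wls": P.T @ dls}
    M = cache["M"]
    grads = {"Wmu": M.T @ dmu, "Wls": M.T @ dls}
    dM = dmu @ weights["Wmu"].T + dls @ weights["Wls"].T
    dH = cache["A_hat"] @ dM  # A_hat symmetric
    dpre = dH * (cache["pre"] > 0)
    grads["W1"] = P.T @ dpre
    return grads


def train(
    hybrid: HybridGraph,
    G_atac: CellGraph,
    X_atac: FeatureMatrix,
    G_merged: CellGraph,
    Y: np.ndarray,
    config: ModelConfig,
    target_truth: np.ndarray | None = None,
) -> TrainResult:
    """Jointly train both VGAE branches with full-batch Adam.

    Parameters
    ----------
    hybrid
        Hybrid graph (RNA + anchor nodes) with gene-level features.
    G_atac, X_atac
        ATAC cell graph and its TF-IDF peak features.
    G_merged
        Merged reference-target graph over all N = n1 + n2 cells, the
        reconstruction objective.
    Y
        (n1, k) one-hot labels of the reference cells.
    target_truth
        Optional (n2,) integer truth for the target cells; only used for
        the per-epoch accuracy trace.
    """
    n1 = hybrid.n_rna
    n2 = G_atac.n_nodes
    N = n1 + n2
    k = Y.shape[1]
    if Y.shape[0] != n1:
        raise ValueError("Y row count must equal the number of reference cells")
    anchors_a = np.asarray(hybrid.anchor_atac_indices, dtype=int)
    if len(anchors_a) == 0:
        raise ValueError("cannot train without anchors")
    anchors_h = n1 + np.arange(len(anchors_a))
    lam = 0.0 if config.no_alignment else config.lam

    rng = np.random.default_rng(config.seed)
    A_h = normalize_adjacency(hybrid.graph)
    A_a = normalize_adjacency(G_atac)
    X_h = hybrid.features
    X_a = X_atac.values if sp.issparse(X_atac.values) else np.asarray(X_atac.values, float)
    G = np.asarray(G_merged.adjacency.todense(), dtype=float)
    E = G.sum()
    if config.bce_mode == "weighted":
        pos_weight = (N * N - E) / E
        bce_norm = N * N / (2.0 * (N * N - E))

    w_h = _init_weights(rng, X_h.shape[1], config.hidden_dim, k, config.single_layer)
    w_a = _init_weights(rng, X_a.shape[1], config.hidden_dim, k, config.single_layer)
    opt = _Adam({**{f"h_{k_}": v for k_, v in w_h.items()},
                 **{f"a_{k_}": v for k_, v in w_a.items()}}, config.lr)
    ref_rows = np.arange(n1)
    y_idx = Y.argmax(axis=1)
    records = []
    prev_weights = None

    # propagated inputs are constant across epochs; they densify heavily
    # (each row is a neighborhood union), so dense BLAS wins
    P_h = A_h @ X_h
    P_a = A_a @ X_a
    if sp.issparse(P_h):
        P_h = np.asarray(P_h.todense())
    if sp.issparse(P_a):
        P_a = np.asarray(P_a.todense())
    for epoch in range(config.epochs):
        mu_h, ls_h, cache_h = encode(A_h, X_h, w_h, config.single_layer, P=P_h)
        mu_a, ls_a, cache_a = encode(A_a, X_a, w_a, config.single_layer, P=P_a)
        cache_h["A_hat"], cache_a["A_hat"] = A_h, A_a
        eps_h = rng.standard_normal(mu_h.shape)
        eps_a = rng.standard_normal(mu_a.shape)
        sig_h, sig_a = np.exp(ls_h), np.exp(ls_a)
        Z_h = reparameterize(mu_h, ls_h, eps_h)
        Z_a = reparameterize(mu_a, ls_a, eps_a)
        Z_m = np.vstack([Z_h[:n1], Z_a])

        # ---- forward losses
        L_kl = kl_loss(mu_h, sig_h, mu_a, sig_a, config.kl_mode)
        S = Z_m @ Z_m.T
        p = _sigmoid(S)
        if config.no_reconstruction:
            L_recon = 0.0
        else:
            L_recon = reconstruction_loss(G, p, config.bce_mode)
        L_align = alignment_loss(Z_h, Z_a, anchors_h, anchors_a, config.align_norm)
        Q = _softmax_rows(Z_m)
        L_class = classification_loss(Q, Y, ref_rows)
        loss = total_loss(L_kl, L_recon, L_align, L_class, lam)

        if not np.isfinite(loss):
            logger.error("training diverged at epoch %d (loss=%r)", epoch, loss)
            if prev_weights is not None:
                w_h, w_a = prev_weights
                break
            raise FloatingPointError(f"loss diverged at epoch {epoch}")
        prev_weights = ({k_: v.copy() for k_, v in w_h.items()},
                        {k_: v.copy() for k_, v in w_a.items()})

        # ---- gradients w.r.t. the merged latent
        dZ_m = np.zeros_like(Z_m)
        if not config.no_reconstruction:
            if config.bce_mode == "weighted":
                dS = bce_norm / (N * N) * (p * (1.0 - G + pos_weight * G) - pos_weight * G)
            else:
                dS = (p - G) / N
            # the forward loss clips probabilities to [eps, 1-eps]; the
            # clipped regions are flat, so their (sub)gradient is zero
            dS[(p <= _EPS) | (p >= 1.0 - _EPS)] = 0.0
            dZ_m += (dS + dS.T) @ Z_m
        dQ_rows = (Q[ref_rows] - Y) / n1
        dZ_m[ref_rows] += dQ_rows

        dZ_h = np.zeros_like(Z_h)
        dZ_a = np.zeros_like(Z_a)
        dZ_h[:n1] = dZ_m[:n1]
        dZ_a += dZ_m[n1:]
        if lam > 0:
            diff = Z_h[anchors_h] - Z_a[anchors_a]
            if config.align_norm == "l2":
                norms = np.linalg.norm(diff, axis=1, keepdims=True)
                norms = np.maximum(norms, 1e-12)
                dd = diff / norms / len(anchors_a)
            else:
                dd = np.sign(diff) / len(anchors_a)
            dZ_h[anchors_h] += lam * dd
            np.add.at(dZ_a, anchors_a, -lam * dd)

        # ---- through the reparameterization and the KL term
        if config.kl_mode == "element":
            scale_h, scale_a = 1.0 / mu_h.size, 1.0 / mu_a.size
        elif config.kl_mode == "mean":
            scale_h, scale_a = 1.0 / mu_h.shape[0], 1.0 / mu_a.shape[0]
        else:
            scale_h = scale_a = 1.0
        dmu_h = dZ_h + scale_h * mu_h
        dls_h = dZ_h * eps_h * sig_h + scale_h * (sig_h**2 - 1.0)
        dmu_a = dZ_a + scale_a * mu_a
        dls_a = dZ_a * eps_a * sig_a + scale_a * (sig_a**2 - 1.0)

        g_h = _branch_backward(dmu_h, dls_h, cache_h, w_h, config.single_layer)
        g_a = _branch_backward(dmu_a, dls_a, cache_a, w_a, config.single_layer)
        params = {**{f"h_{k_}": v for k_, v in w_h.items()},
                  **{f"a_{k_}": v for k_, v in w_a.items()}}
        grads = {**{f"h_{k_}": v for k_, v in g_h.items()},
                 **{f"a_{k_}": v for k_, v in g_a.items()}}
        opt.step(params, grads)

        # ---- per-epoch trace (evaluation mode: Z = mu)
        Zm_eval = np.vstack([mu_h[:n1], mu_a])
        pred = Zm_eval.argmax(axis=1)
        ref_acc = float((pred[:n1] == y_idx).mean())
        rec = {
            "epoch": epoch, "loss": loss, "kl": L_kl, "recon": L_recon,
            "align": L_align, "class": L_class, "ref_acc": ref_acc,
        }
        if target_truth is not None:
            rec["target_acc"] = float((pred[n1:] == np.asarray(target_truth)).mean())
        records.append(rec)

    # final evaluation-mode state
    mu_h, ls_h, _ = encode(A_h, X_h, w_h, config.single_layer, P=P_h)
    mu_a, ls_a, _ = encode(A_a, X_a, w_a, config.single_layer, P=P_a)
    latent = LatentState(mu_h, ls_h, mu_h.copy(), mu_a, ls_a, mu_a.copy(), n1)
    model = VGAEModel(
        config=config,
        weights={"h": w_h, "a": w_a},
        n_types=k,
        feature_dims={"h": X_h.shape[1], "a": X_a.shape[1]},
    )
    G_hat = decode(latent.Z_m)
    return TrainResult(model, latent, pd.DataFrame(records), G_hat)


def predict_labels(Z_hat: np.ndarray, rows: np.ndarray | None = None):
    """Argmax label per cell plus the max probability and the 0.5-rule flag.

    The predicted label is the argmax of the label indicator row (lowest
    index on ties); ``meets_threshold`` records whether the winning
    probability reaches 0.5, as the decision rule requires.
    """
    if rows is not None:
        Z_hat = Z_hat[rows]
    labels = Z_hat.argmax(axis=1)
    max_prob = Z_hat.max(axis=1)
    ties = (Z_hat == max_prob[:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("predict_labels: %d argmax ties resolved to lowest index", int(ties.sum()))
    return labels, max_prob, max_prob >= 0.5


def peak_importance(model: VGAEModel) -> np.ndarray:
    """Peak-to-type importance scores from a single-layer ATAC encoder.

    Returns a (peaks, k) matrix of absolute weight magnitudes connecting
    each peak input to each latent/label dimension.  Only defined when the
    ATAC branch is one layer deep (input wired directly to the latent).
    """
    if not model.config.single_layer:
        raise ValueError("peak importance requires a single-layer ATAC encoder")
    return np.abs(model.weights["a"]["Wmu"])


def holdout_edges(
    G: CellGraph, fraction: float, seed: int
) -> tuple[CellGraph, np.ndarray, np.ndarray]:
    """Remove a fraction of edges for link-prediction evaluation.

    Returns the pruned graph, the held-out edges as an (m, 2) index array
    and an equal number of sampled non-edges.
    """
    rng = np.random.default_rng(seed)
    coo = sp.triu(G.adjacency, k=1).tocoo()
    edges = np.column_stack([coo.row, coo.col])
    m = max(1, int(round(fraction * len(edges))))
    held = edges[rng.choice(len(edges), size=m, replace=False)]
    A = G.adjacency.tolil(copy=True)
    for i, j in held:
        A[i, j] = 0
        A[j, i] = 0
    n = G.n_nodes
    dense = G.adjacency.toarray()
    negatives = []
    while len(negatives) < m:
        i, j = rng.integers(0, n, size=2)
        if i != j and dense[i, j] == 0:
            negatives.append((min(i, j), max(i, j)))
    return (
        CellGraph(A.tocsr(), list(G.node_ids), list(G.node_modality)),
        held,
        np.asarray(negatives),
    )
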