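"""Prediction-reliability scoring on the reconstructed reference-target graph.

For each target (ATAC) cell c and each reference label group K, the edge
density is ``d_c^K = e_c^K / |K|`` and the edge weight is the mean decoded
probability over the kept edges (``w_c^K = 0`` when there is no edge).
A prediction is *confident* when the argmax of the label-probability
vector, the density vector and the weight vector all agree (lowest-index
tie rule); otherwise it is *ambiguous*.  Target cells with no kept
cross-modality edge at all are ambiguous by definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityReport",
    "threshold_reconstructed_graph",
    "density_weight",
    "flag_predictions",
]


@dataclass
class ReliabilityReport:
    """Per-target-cell density/weight vectors and the confident|ambiguous flag."""

    density: np.ndarray  # (n_target, k)
    weight: np.ndarray  # (n_target, k)
    z_hat: np.ndarray  # (n_target, k) label probabilities
    flags: list[str]
    labels: list[str]
    tau: float

    def summary_by_prediction(self) -> pd.DataFrame:
        """Fraction ambiguous per predicted type.

        A predicted type dominated by ambiguous cells is the signature of a
        cell type missing from the reference.
        """
        pred = self.z_hat.argmax(axis=1)
        rows = []
        for j, lab in enumerate(self.labels):
            mask = pred == j
            if mask.sum() == 0:
                continue
            frac = float(np.mean([self.flags[i] == "ambiguous" for i in np.nonzero(mask)[0]]))
            rows.append({"predicted_label": lab, "n_cells": int(mask.sum()),
                         "fraction_ambiguous": frac})
        return pd.DataFrame(rows)

    def to_frame(self, cell_ids: list[str]) -> pd.DataFrame:
        pred = self.z_hat.argmax(axis=1)
        top3 = []
        for i in range(len(cell_ids)):
            order = np.argsort(-self.density[i], kind="stable")[:3]
            top3.append(";".join(
                f"{self.labels[j]}:d={self.density[i, j]:.3f},w={self.weight[i, j]:.3f}"
                for j in order
            ))
        return pd.DataFrame({
            "cell_id": cell_ids,
            "predicted_label": [self.labels[j] for j in pred],
            "flag": self.flags,
            "top3_density_weight": top3,
        })


def threshold_reconstructed_graph(
    G_hat: np.ndarray, n_rna: int, tau: float = 0.6
) -> tuple[np.ndarray, np.ndarray]:
    """Binarize the cross-modality block of the decoded graph at ``tau``.

    Returns ``(edges, weights)``: boolean and float (n_target, n_rna)
    matrices over ATAC rows x RNA columns.  An edge exists iff the decoded
    probability is >= tau (boundary inclusive); weights are retained only
    on kept edges.

    The default ``tau=0.6`` demands a margin over the inner-product
    decision boundary: at exactly 0.5, a target cell whose latent is near
    the origin (the signature of a cell with no matching reference type)
    picks up saturated pseudo-edges to entire reference groups from the
    sign noise of near-zero inner products, which defeats the density/
    weight scoring.  Any threshold comfortably above the boundary and
    below the saturated same-type probabilities (~0.55-0.7) behaves
    equivalently.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must be in (0, 1)")
    cross = np.asarray(G_hat)[n_rna:, :n_rna]
    edges = cross >= tau
    return edges, np.where(edges, cross, 0.0)


def density_weight(
    edges: np.ndarray,
    weights: np.ndarray,
    groups: dict[str, np.ndarray],
    labels: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Edge density and mean edge weight of each target cell per label group.

    ``groups`` maps each reference label to the RNA column indices of that
    group; the groups must partition the reference cells and be non-empty.
    """
    for lab in labels:
        members = groups.get(lab)
        if members is None or len(members) == 0:
            raise ValueError(f"reference group {lab!r} is empty")
    n_target = edges.shape[0]
    k = len(labels)
    density = np.zeros((n_target, k))
    weight = np.zeros((n_target, k))
    for j, lab in enumerate(labels):
        members = np.asarray(groups[lab], dtype=int)
        e = edges[:, members].sum(axis=1)
        density[:, j] = e / len(members)
        w_sum = weights[:, members].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            weight[:, j] = np.where(e > 0, w_sum / np.maximum(e, 1), 0.0)
    return density, weight


def flag_predictions(
    z_hat: np.ndarray,
    density: np.ndarray,
    weight: np.ndarray,
    labels: list[str],
    tau: float = 0.6,
) -> ReliabilityReport:
    """Apply the triple-argmax agreement rule per target cell."""
    if not (z_hat.shape == density.shape == weight.shape):
        raise ValueError("z_hat, density and weight must share a shape")
    flags = []
    zi = z_hat.argmax(axis=1)
    di = density.argmax(axis=1)
    wi = weight.argmax(axis=1)
    isolated = density.sum(axis=1) == 0
    for i in range(z_hat.shape[0]):
        if isolated[i]:
            flags.append("ambiguous")
        elif zi[i] == di[i] == wi[i]:
            flags.append("confident")
        else:
            flags.append("ambiguous")
    return ReliabilityReport(density, weight, z_hat, flags, list(labels), tau)
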