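"""Paired scRNA-seq + scATAC-seq simulator with shared cell-type structure.

The generator emulates the data regime the annotation method assumes:

* RNA counts are negative binomial with per-type marker genes (disjoint
  random gene subsets per type) whose log-means are shifted upward by an
  amount scaled by ``sigma_sep``.
* Each gene is linked to ``peaks_per_gene`` peaks placed inside its body /
  2 kb-upstream window; peaks linked to a type's marker genes form that
  type's *planted peak set* and are accessible at rate ``q1`` in cells of
  the type (background ``q0`` elsewhere), so gene activity correlates with
  expression structurally rather than by copying values.
* Peak counts are Bernoulli presence times ``1 + Poisson`` magnitude,
  thinned by a capture efficiency; background rates are chosen so a cell
  detects roughly 5-10% of peaks, matching the sparsity of real scATAC-seq.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from graphanno.io import FeatureMatrix, GeneTable, LabelTable, PeakTable

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_paired",
    "inject_label_noise",
    "drop_reference_type",
]

_GENE_BODY = 2000
_GENE_SPACING = 10_000
_PEAK_WIDTH = 400


@dataclass
class SimulationConfig:
    """Study conditions of the paired simulation.

    Defaults are the well-separated five-type condition used throughout:
    1500 cells per modality, 2000 genes, 10000 peaks, separation 4 (natural
    log-scale marker shift), with sparsity matching the ~5-10% per-cell
    peak detection rate of real data.
    """

    n_types: int = 5
    n_rna: int = 1500
    n_atac: int = 1500
    n_genes: int = 2000
    n_peaks: int = 10_000
    peaks_per_gene: int = 3
    sigma_sep: float = 4.0
    nb_dispersion: float = 2.0
    q0: float = 0.06  # background accessibility rate
    q1: float = 0.4  # planted (type-specific) accessibility rate
    capture: float = 0.8  # capture efficiency (1 - dropout)
    marker_frac: float = 0.1  # fraction of genes that are markers, per type

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.q1 < self.q0:
            raise ValueError("q1 must be >= q0")
        for name in ("n_rna", "n_atac", "n_genes", "n_peaks", "peaks_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes * self.peaks_per_gene > self.n_peaks:
            raise ValueError(
                "infeasible geometry: n_genes * peaks_per_gene exceeds n_peaks"
            )
        if self.n_types * max(1, int(self.marker_frac * self.n_genes)) > self.n_genes:
            raise ValueError("marker_frac too large for disjoint marker sets")


@dataclass
class SyntheticDataset:
    """A complete paired input bundle plus generator ground truth."""

    X_rna: FeatureMatrix
    X_atac: FeatureMatrix
    peaks: PeakTable
    genes: GeneTable
    peak_gene_links: sp.csr_matrix  # (n_peaks, n_genes) binary
    rna_labels: LabelTable
    atac_labels: LabelTable
    marker_genes: dict = field(default_factory=dict)  # type -> gene ids
    planted_peaks: dict = field(default_factory=dict)  # type -> peak ids
    config: SimulationConfig | None = None
    seed: int | None = None

    @property
    def type_names(self) -> list[str]:
        return list(self.rna_labels.vocabulary)


def _balanced_types(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    base = np.arange(n) % k
    return rng.permutation(base)


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """NB via gamma-Poisson mixture: var = mu + mu^2 / dispersion."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def simulate_paired(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Generate one paired dataset under the given study conditions."""
    rng = np.random.default_rng(seed)
    k = config.n_types
    g = config.n_genes
    p = config.n_peaks
    type_names = [f"type_{t}" for t in range(k)]
    gene_ids = [f"gene_{i}" for i in range(g)]
    peak_ids = [f"peak_{i}" for i in range(p)]

    # ---- genome layout: one chromosome, evenly spaced genes
    gene_start = 10_000 + np.arange(g) * _GENE_SPACING
    gene_end = gene_start + _GENE_BODY
    strand = ["+" if i % 2 == 0 else "-" for i in range(g)]
    genes = GeneTable(gene_ids, ["chr1"] * g, gene_start, gene_end, strand)

    # ---- linked peaks: peaks_per_gene per gene within body/upstream window
    peak_start = np.zeros(p, dtype=int)
    link_rows, link_cols = [], []
    idx = 0
    for i in range(g):
        for j in range(config.peaks_per_gene):
            if j == 0:  # one peak in the strand-aware upstream extension
                if strand[i] == "+":
                    s = gene_start[i] - 1000
                else:
                    s = gene_end[i] + 600
            else:
                s = gene_start[i] + (j - 1) * 600 + 100
            peak_start[idx] = s
            link_rows.append(idx)
            link_cols.append(i)
            idx += 1
    # intergenic background peaks beyond the gene array
    tail = 10_000 + g * _GENE_SPACING + 5000
    for j in range(p - idx):
        peak_start[idx + j] = tail + j * 1000
    peak_end = peak_start + _PEAK_WIDTH
    peaks = PeakTable(["chr1"] * p, peak_start, peak_end, peak_ids)
    links = sp.csr_matrix(
        (np.ones(len(link_rows)), (link_rows, link_cols)), shape=(p, g)
    )

    # ---- per-type marker genes (disjoint) and their planted peaks
    n_markers = max(1, int(config.marker_frac * g))
    gene_perm = rng.permutation(g)
    marker_genes: dict[str, list[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    planted_peaks: dict[str, list[str]] = {}
    for t, name in enumerate(type_names):
        sel = np.sort(gene_perm[t * n_markers : (t + 1) * n_markers])
        marker_idx[name] = sel
        marker_genes[name] = [gene_ids[i] for i in sel]
        peak_sel = np.sort(links[:, sel].tocoo().row)
        planted_peaks[name] = [peak_ids[i] for i in peak_sel]

    # ---- RNA counts
    base_log_mean = rng.normal(0.0, 0.5, size=g)
    type_log_mean = np.tile(base_log_mean, (k, 1))
    for t, name in enumerate(type_names):
        shift = config.sigma_sep * rng.uniform(0.5, 1.0, size=n_markers)
        type_log_mean[t, marker_idx[name]] += shift
    rna_types = _balanced_types(config.n_rna, k, rng)
    size_factor = rng.lognormal(0.0, 0.3, size=config.n_rna)
    rna_counts = np.zeros((config.n_rna, g), dtype=np.int64)
    for t in range(k):
        cells = np.nonzero(rna_types == t)[0]
        mean = np.exp(type_log_mean[t])[None, :] * size_factor[cells, None]
        rna_counts[cells] = _nb_counts(mean, config.nb_dispersion, rng)

    # ---- ATAC counts
    atac_types = _balanced_types(config.n_atac, k, rng)
    rate = np.full((k, p), config.q0)
    for t, name in enumerate(type_names):
        cols = [int(pid.split("_")[1]) for pid in planted_peaks[name]]
        rate[t, cols] = config.q1
    rows, cols, data = [], [], []
    for t in range(k):
        cells = np.nonzero(atac_types == t)[0]
        prob = rate[t] * config.capture
        present = rng.random((len(cells), p)) < prob[None, :]
        r, c = np.nonzero(present)
        rows.append(cells[r])
        cols.append(c)
        data.append(1 + rng.poisson(0.3, size=len(r)))
    atac = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(config.n_atac, p), dtype=np.int64,
    )

    rna_ids = [f"rna_{i:05d}" for i in range(config.n_rna)]
    atac_ids = [f"atac_{i:05d}" for i in range(config.n_atac)]
    return SyntheticDataset(
        X_rna=FeatureMatrix(sp.csr_matrix(rna_counts), rna_ids, gene_ids, "rna"),
        X_atac=FeatureMatrix(atac, atac_ids, peak_ids, "atac"),
        peaks=peaks,
        genes=genes,
        peak_gene_links=links,
        rna_labels=LabelTable(rna_ids, [type_names[t] for t in rna_types], type_names),
        atac_labels=LabelTable(atac_ids, [type_names[t] for t in atac_types], type_names),
        marker_genes=marker_genes,
        planted_peaks=planted_peaks,
        config=config,
        seed=seed,
    )


def inject_label_noise(labels: LabelTable, p: float, seed: int) -> LabelTable:
    """Reassign exactly ``round(p * n)`` cells to a uniformly random WRONG label."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("noise proportion must be in [0, 1]")
    vocab = list(labels.vocabulary)
    if len(vocab) < 2:
        raise ValueError("cannot inject noise with a single-label vocabulary")
    rng = np.random.default_rng(seed)
    n = len(labels)
    n_flip = int(round(p * n))
    flip = rng.choice(n, size=n_flip, replace=False)
    new_labels = list(labels.labels)
    for i in flip:
        wrong = [v for v in vocab if v != new_labels[i]]
        new_labels[i] = wrong[rng.integers(len(wrong))]
    return LabelTable(list(labels.cell_ids), new_labels, vocab)


def drop_reference_type(dataset: SyntheticDataset, type_name: str) -> SyntheticDataset:
    """Remove one cell type from the reference; the target stays untouched.

    The training vocabulary shrinks by one, emulating a biased reference
    that lacks a cell type present in the target.
    """
    if type_name not in dataset.rna_labels.vocabulary:
        raise ValueError(f"type {type_name!r} not in the reference vocabulary")
    remaining = [v for v in dataset.rna_labels.vocabulary if v != type_name]
    if len(remaining) < 2:
        raise ValueError("dropping this type would leave fewer than 2 types")
    keep = [i for i, lab in enumerate(dataset.rna_labels.labels) if lab != type_name]
    new_rna = dataset.X_rna.subset_cells(keep)
    new_labels = LabelTable(
        [dataset.rna_labels.cell_ids[i] for i in keep],
        [dataset.rna_labels.labels[i] for i in keep],
        remaining,
    )
    return replace(dataset, X_rna=new_rna, rna_labels=new_labels)
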