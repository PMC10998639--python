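"""End-to-end orchestration: preprocessing -> graphs -> training -> reliability.

`run_pipeline` is the single entry point the CLI and the test-suite share.
It takes raw count matrices plus reference labels and returns predictions,
the reliability report and (when target truth is supplied) the metric
report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from graphanno import evaluate as ev
from graphanno.graphs import (
    AnchorSet,
    CellGraph,
    build_hybrid_graph,
    build_merged_graph,
    cca_shared_space,
    detect_anchors,
    mutual_knn_graph,
)
from graphanno.io import FeatureMatrix, GeneTable, LabelTable, PeakTable
from graphanno.model import ModelConfig, TrainResult, predict_labels, train
from graphanno.preprocess import (
    gene_activity,
    log_normalize,
    lsi_embed,
    pca_embed,
    select_hvg,
    standardize,
    tfidf,
)
from graphanno.reliability import (
    ReliabilityReport,
    density_weight,
    flag_predictions,
    threshold_reconstructed_graph,
)

__all__ = [
    "PipelineConfig",
    "GraphBundle",
    "PipelineResult",
    "prepare_graphs",
    "annotate_from_bundle",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the annotation pipeline.

    ``n_dims`` applies to PCA, LSI and CCA (30, the robust setting);
    ``k1`` / ``k2`` are the intra- and cross-modality mutual-kNN sizes
    (midpoint 15 of the robust 5-25 range).  ``model`` carries the VGAE
    hyperparameters; ``tau`` is the edge-probability threshold for the
    reliability scoring.
    """

    n_hvg: int | None = 2000
    n_dims: int = 30
    k1: int = 15
    k2: int = 15
    upstream: int = 2000
    tau: float = 0.6
    model: ModelConfig = field(default_factory=ModelConfig)


@dataclass
class GraphBundle:
    """Everything the trainer needs, prepared from raw inputs."""

    hybrid: object
    G_atac: CellGraph
    atac_tfidf: FeatureMatrix
    merged: CellGraph
    Y: np.ndarray
    anchors: AnchorSet
    anchor_purity: float | None
    truth_idx: np.ndarray | None
    vocabulary: list[str]
    rna_cell_ids: list[str]
    atac_cell_ids: list[str]
    ref_label_idx: np.ndarray


@dataclass
class PipelineResult:
    predictions: pd.DataFrame
    reliability: ReliabilityReport
    metrics: ev.MetricReport | None
    anchors: AnchorSet
    anchor_purity: float | None
    train_result: TrainResult
    merged_graph: CellGraph
    vocabulary: list[str]
    rna_cell_ids: list[str]
    atac_cell_ids: list[str]
    target_embedding: np.ndarray


def prepare_graphs(
    X_rna: FeatureMatrix,
    rna_labels: LabelTable,
    X_atac: FeatureMatrix,
    peaks: PeakTable,
    genes: GeneTable,
    config: PipelineConfig | None = None,
    X_gam: FeatureMatrix | None = None,
    target_labels: LabelTable | None = None,
) -> GraphBundle:
    """Run preprocessing and graph construction up to the training inputs."""
    config = config or PipelineConfig()

    # ---- gene-level features
    n_hvg = min(config.n_hvg or X_rna.n_features, X_rna.n_features)
    hvg = select_hvg(X_rna, n_hvg)
    X_rna_std = standardize(log_normalize(hvg))

    # ---- peak-level features (all-zero cells dropped with a warning)
    atac_tfidf = tfidf(X_atac)
    kept_ids = set(atac_tfidf.cell_ids)
    X_atac_kept = (
        X_atac if len(kept_ids) == X_atac.n_cells
        else X_atac.subset_cells([i for i, c in enumerate(X_atac.cell_ids) if c in kept_ids])
    )

    if X_gam is None:
        X_gam = gene_activity(
            X_atac_kept, peaks, genes, upstream=config.upstream,
            gene_subset=list(hvg.feature_ids),
        )
    else:
        X_gam = X_gam.subset_features(list(hvg.feature_ids))
    X_gam_std = standardize(log_normalize(X_gam))

    # ---- graphs
    G_rna = mutual_knn_graph(pca_embed(X_rna_std, config.n_dims), config.k1, "rna")
    lsi = lsi_embed(atac_tfidf, config.n_dims, drop_first=True)
    G_atac = mutual_knn_graph(lsi, config.k1, "atac")
    U_rna, U_gam = cca_shared_space(X_rna_std, X_gam_std, config.n_dims)
    anchors = detect_anchors(U_rna, U_gam, config.k2)
    hybrid = build_hybrid_graph(G_rna, anchors, X_rna_std, X_gam_std)
    merged = build_merged_graph(hybrid, G_atac)

    anchor_purity = None
    truth_idx = None
    if target_labels is not None:
        ref_idx = rna_labels.to_indices(X_rna.cell_ids)
        vocab_map = {v: i for i, v in enumerate(target_labels.vocabulary)}
        tgt_lut = dict(zip(target_labels.cell_ids, target_labels.labels))
        truth_idx = np.array([vocab_map[tgt_lut[c]] for c in X_atac_kept.cell_ids])
        ref_names = [rna_labels.vocabulary[i] for i in ref_idx]
        pure = [
            ref_names[r] == tgt_lut[X_atac_kept.cell_ids[a]]
            for r, a in anchors.pairs
        ]
        anchor_purity = float(np.mean(pure))
        logger.info("anchor purity vs truth: %.3f", anchor_purity)

    return GraphBundle(
        hybrid=hybrid,
        G_atac=G_atac,
        atac_tfidf=atac_tfidf,
        merged=merged,
        Y=rna_labels.one_hot(X_rna.cell_ids),
        anchors=anchors,
        anchor_purity=anchor_purity,
        truth_idx=truth_idx,
        vocabulary=list(rna_labels.vocabulary),
        rna_cell_ids=list(X_rna.cell_ids),
        atac_cell_ids=list(X_atac_kept.cell_ids),
        ref_label_idx=rna_labels.to_indices(X_rna.cell_ids),
    )


def annotate_from_bundle(
    bundle: GraphBundle,
    config: PipelineConfig,
    target_labels: LabelTable | None = None,
) -> PipelineResult:
    """Train on a prepared bundle, predict, and score reliability."""
    result = train(
        bundle.hybrid, bundle.G_atac, bundle.atac_tfidf, bundle.merged,
        bundle.Y, config.model, target_truth=bundle.truth_idx,
    )

    n1 = len(bundle.rna_cell_ids)
    Z_hat = result.latent.Z_hat
    target_rows = np.arange(n1, n1 + bundle.G_atac.n_nodes)
    labels_idx, max_prob, _ = predict_labels(Z_hat, target_rows)
    vocab = bundle.vocabulary
    pred_names = [vocab[i] for i in labels_idx]

    # ---- reliability on the reconstructed graph (true reference groups)
    edges, weights = threshold_reconstructed_graph(result.G_hat, n1, config.tau)
    groups = {lab: np.nonzero(bundle.ref_label_idx == j)[0] for j, lab in enumerate(vocab)}
    density, weight = density_weight(edges, weights, groups, vocab)
    report = flag_predictions(Z_hat[target_rows], density, weight, vocab, config.tau)

    predictions = pd.DataFrame({
        "cell_id": bundle.atac_cell_ids,
        "predicted_label": pred_names,
        "max_probability": max_prob,
        "flag": report.flags,
    })

    metrics = None
    if target_labels is not None:
        tgt_lut = dict(zip(target_labels.cell_ids, target_labels.labels))
        truth_names = [tgt_lut[c] for c in bundle.atac_cell_ids]
        metrics = ev.metric_report(
            truth_names, pred_names, embedding=result.latent.Z_a
        )

    return PipelineResult(
        predictions=predictions,
        reliability=report,
        metrics=metrics,
        anchors=bundle.anchors,
        anchor_purity=bundle.anchor_purity,
        train_result=result,
        merged_graph=bundle.merged,
        vocabulary=vocab,
        rna_cell_ids=bundle.rna_cell_ids,
        atac_cell_ids=bundle.atac_cell_ids,
        target_embedding=result.latent.Z_a,
    )


def run_pipeline(
    X_rna: FeatureMatrix,
    rna_labels: LabelTable,
    X_atac: FeatureMatrix,
    peaks: PeakTable,
    genes: GeneTable,
    config: PipelineConfig | None = None,
    X_gam: FeatureMatrix | None = None,
    target_labels: LabelTable | None = None,
) -> PipelineResult:
    """Annotate the ATAC target from the labeled RNA reference.

    ``X_gam`` may supply a precomputed gene-activity matrix; otherwise it
    is computed from the peak matrix and the gene annotation.  When
    ``target_labels`` (ground truth) is given, anchor purity and the
    metric report are evaluated against it.
    """
    config = config or PipelineConfig()
    bundle = prepare_graphs(
        X_rna, rna_labels, X_atac, peaks, genes, config, X_gam, target_labels
    )
    return annotate_from_bundle(bundle, config, target_labels)
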