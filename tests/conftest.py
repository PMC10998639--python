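"""Shared fixtures.

Heavy fixtures are session-scoped: a standard well-separated five-type
paired dataset at the package's test scale (400+400 cells, 600 genes,
3000 peaks) and a fully trained pipeline run on it, reused by every test
that needs a realistic end-to-end result.
"""

from __future__ import annotations

import numpy as np
import pytest

from graphanno.model import ModelConfig
from graphanno.pipeline import PipelineConfig, prepare_graphs, annotate_from_bundle
from graphanno.simulate import SimulationConfig, simulate_paired

# the documented test-scale study conditions (reduced cell/feature counts,
# same separation and sparsity regime as the generator defaults)
TEST_SCALE = dict(n_types=5, n_rna=400, n_atac=400, n_genes=600, n_peaks=3000)
N_HVG = 300


def make_pipeline_config(seed: int, epochs: int = 500, **model_kwargs) -> PipelineConfig:
    return PipelineConfig(
        n_hvg=N_HVG, model=ModelConfig(epochs=epochs, seed=seed, **model_kwargs)
    )


@pytest.fixture(scope="session")
def std_dataset():
    """Well-separated five-type paired dataset, seed 1."""
    return simulate_paired(SimulationConfig(**TEST_SCALE), seed=1)


@pytest.fixture(scope="session")
def std_bundle(std_dataset):
    """Prepared graphs/features for the standard dataset."""
    return prepare_graphs(
        std_dataset.X_rna, std_dataset.rna_labels, std_dataset.X_atac,
        std_dataset.peaks, std_dataset.genes, make_pipeline_config(1),
        target_labels=std_dataset.atac_labels,
    )


@pytest.fixture(scope="session")
def std_result(std_dataset, std_bundle):
    """Full 500-epoch pipeline run on the standard dataset."""
    return annotate_from_bundle(
        std_bundle, make_pipeline_config(1), target_labels=std_dataset.atac_labels
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
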