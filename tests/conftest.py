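import numpy as np
import pandas as pd
import pytest

from becabench.core_io import ExpressionMatrix, SampleSheet
from becabench.scenarios import build_full_design
from becabench.simulate import BatchEffectModel, simulate_measurements, simulate_truth


@pytest.fixture(scope="session")
def full_design() -> SampleSheet:
    """15 batches × 4 donors × 3 replicates, D6 reference (180 libraries)."""
    return build_full_design()


@pytest.fixture(scope="session")
def small_design() -> SampleSheet:
    """3 batches × 4 donors × 3 replicates (fast unit-test design)."""
    return build_full_design(n_batches=3)


@pytest.fixture(scope="session")
def identity_log2(small_design):
    """Noiseless, offset-free log2 matrix: every sample equals its donor's truth."""
    truth = simulate_truth(n_features=60, seed=11)
    model = BatchEffectModel.identity(truth.feature_ids, small_design.batches)
    raw = simulate_measurements(truth, model, small_design, layer="proteomics")
    values = np.log2(raw.values)
    mat = ExpressionMatrix(values=values, scale="log2", layer="proteomics")
    return mat, truth


def toy_matrix(values, scale="log2", layer="transcriptomics", features=None, samples=None):
    arr = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=features, columns=samples)
    return ExpressionMatrix(values=df, scale=scale, layer=layer)


def toy_sheet(rows):
    """rows: list of (sample_id, donor, replicate, batch, batch_order, role)."""
    return SampleSheet(
        pd.DataFrame(
            rows, columns=["sample_id", "donor", "replicate", "batch", "batch_order", "role"]
        )
    )
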