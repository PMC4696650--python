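import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from consig import (
    PipelineConfig,
    SimulationConfig,
    signature_from_datasets,
    simulate_multistudy,
)
from consig.io import ExpressionDataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(
    values: dict[str, list[float]],
    classes: list[str],
    dataset_id: str = "DS",
    sample_prefix: str = "S",
) -> ExpressionDataset:
    """Small in-memory dataset: values maps probe -> per-sample expression."""
    samples = [f"{sample_prefix}{i + 1}" for i in range(len(classes))]
    frame = pd.DataFrame.from_dict(values, orient="index", columns=samples)
    return ExpressionDataset(
        dataset_id=dataset_id,
        platform_id="TEST",
        values=frame.astype(float),
        sample_class=pd.Series(classes, index=samples),
    )


@pytest.fixture(scope="session")
def sim_default():
    """The default five-study simulation, seed 42, with ground truth."""
    datasets, truth, annotation = simulate_multistudy(SimulationConfig(seed=42))
    return datasets, truth, annotation


@pytest.fixture(scope="session")
def pipeline_default(sim_default):
    """Signature pipeline run on the default simulation."""
    datasets, truth, annotation = sim_default
    result = signature_from_datasets(datasets, annotation, PipelineConfig(seed=42))
    return datasets, truth, annotation, result


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
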