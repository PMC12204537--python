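import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from omicsgsm import OmicsMatrix, PipelineConfig, SampleLabels, SyntheticSpec, generate_multiomics
from omicsgsm.synthetic import PlantedModule

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """30 samples/class, one planted discriminative module, light background."""
    spec = SyntheticSpec(
        n_samples_per_class=30,
        n_genes=40,
        n_mirnas=8,
        n_cpgs=8,
        planted_modules=[PlantedModule(n_genes=3, rho=0.9, delta=2.0)],
        seed=11,
    )
    return generate_multiomics(spec)


@pytest.fixture
def tiny_config():
    return PipelineConfig(n_outer_iterations=2, n_trees=50, master_seed=7)


@pytest.fixture
def two_class_labels():
    def make(n_a: int, n_b: int, names=("HR+", "HR-")) -> SampleLabels:
        ids = [f"s{i}" for i in range(n_a + n_b)]
        return SampleLabels(pd.Series([names[0]] * n_a + [names[1]] * n_b, index=ids))

    return make


@pytest.fixture
def matrix_factory():
    def make(kind: str, values, feature_ids=None, sample_ids=None) -> OmicsMatrix:
        values = np.asarray(values, dtype=float)
        feature_ids = feature_ids or [f"{kind}_f{i}" for i in range(values.shape[0])]
        sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
        return OmicsMatrix(kind, pd.DataFrame(values, index=feature_ids, columns=sample_ids))

    return make
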