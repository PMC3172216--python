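import numpy as np
import pandas as pd
import pytest

from persig import (
    CohortSimConfig,
    ExpressionDataset,
    ModeratedTTest,
    PerturbationSimConfig,
    preprocess,
    simulate_cohort,
    simulate_perturbation,
)


@pytest.fixture(scope="session")
def default_experiment():
    """One full perturbation run at generator defaults, shared across tests."""
    dataset, truth = simulate_perturbation(PerturbationSimConfig(seed=1))
    return dataset, truth


@pytest.fixture(scope="session")
def normalized_experiment(default_experiment):
    dataset, truth = default_experiment
    normalized, removed, vst_params = preprocess(dataset)
    return normalized, removed, vst_params, truth


@pytest.fixture(scope="session")
def late_results(normalized_experiment):
    normalized, _, _, _ = normalized_experiment
    return ModeratedTTest(normalized, time="48h").fit()


@pytest.fixture(scope="session")
def late_signature(late_results):
    return late_results.derive_signature(name="late")


@pytest.fixture(scope="session")
def default_cohort(late_signature):
    cohort, truth = simulate_cohort(late_signature, CohortSimConfig(seed=1))
    return cohort, truth


def make_dataset(values, scale="log2-vst", condition=None, time=None, subset=None):
    """Small-dataset helper: values is a dict {sample_id: list} or DataFrame."""
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(values)
        values.index = [f"G{i}" for i in range(len(values))]
    ann = None
    if condition is not None or subset is not None:
        ann = pd.DataFrame(index=values.columns)
        if condition is not None:
            ann["condition"] = condition
        if time is not None:
            ann["time"] = time
        if subset is not None:
            ann["subset"] = subset
    return ExpressionDataset(values.astype(float), scale, ann)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
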