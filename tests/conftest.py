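import logging

import numpy as np
import pandas as pd
import pytest

from m6ascore import (
    ExpressionMatrix,
    SimulationParams,
    filter_low_count,
    gene_zscore,
    normalize_log,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort small enough for per-module tests."""
    return simulate_cohort(SimulationParams(n_samples=120, seed=11))


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    return normalize_log(filter_low_count(small_cohort.counts))


@pytest.fixture(scope="session")
def small_zscores(small_normalized):
    return gene_zscore(small_normalized)


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(5)
    data = pd.DataFrame(
        rng.normal(size=(20, 8)),
        index=[f"G{i}" for i in range(20)],
        columns=[f"S{j}" for j in range(8)],
    )
    return ExpressionMatrix(data, "normalized")


@pytest.fixture(autouse=True)
def _capture_logs(caplog):
    caplog.set_level(logging.INFO, logger="m6ascore")
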