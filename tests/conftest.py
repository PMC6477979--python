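import numpy as np
import pytest

from dlnafilter import ParameterSet, generate_dataset


@pytest.fixture(scope="session")
def params_true() -> ParameterSet:
    """The reference simulation-truth parameter set."""
    return ParameterSet()


@pytest.fixture(scope="session")
def dataset10(params_true):
    """Ten replicate synthetic series at SNR 100 over five days."""
    return generate_dataset(params_true, n_rep=10, snr=100.0, seed=101,
                            horizon=120.0)


@pytest.fixture(scope="session")
def series_one(dataset10):
    """A single five-day replicate (with truth metadata)."""
    return dataset10[0]


def true_params_for(series, params_true: ParameterSet) -> ParameterSet:
    """Truth with the replicate's realized measurement scales."""
    return params_true.replace(
        kappa=series.meta["kappa"], sigma_eps=series.meta["sigma_eps"]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
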