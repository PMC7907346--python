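import numpy as np
import pytest

from tssnmix import ScenarioSpec, simulate_dataset, fit_tss


@pytest.fixture(scope="session")
def favorable_scenario():
    """The easiest design cell: large population, high detection, long study."""
    return ScenarioSpec(trend_coeff=0.1, initial_abundance=100, n_years=20,
                        n_surveys=5, detection_prob=0.7, n_reps=200,
                        base_seed=123)


@pytest.fixture(scope="session")
def favorable_fit(favorable_scenario):
    """One converged fit on a favorable-scenario dataset."""
    ds = simulate_dataset(favorable_scenario, 0)
    fit = fit_tss(ds.counts, K="adaptive")
    assert fit.converged
    return ds, fit


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
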