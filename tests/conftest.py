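import numpy as np
import pytest

from ndeepsurv import SimulationConfig, SurvivalDataset, simulate_cohort


@pytest.fixture
def toy_ds():
    """Tiny complete single-task dataset: 6 subjects, 3 features."""
    X = np.array([[1.0, 2.0, 0.5],
                  [0.0, 1.0, 1.5],
                  [2.0, 0.0, 1.0],
                  [1.5, 1.0, 0.0],
                  [0.5, 2.5, 2.0],
                  [2.5, 0.5, 0.5]])
    T = np.array([2.0, 5.0, 1.0, 7.0, 3.0, 4.0])
    E = np.array([[1], [0], [1], [0], [1], [1]])
    return SurvivalDataset(np.arange(6).astype(str), X, ["a", "b", "c"],
                           T, E, ["event"])


@pytest.fixture
def signal_cohort():
    """Moderate-signal PH cohort: 2 informative + 2 null features."""
    beta = np.array([[1.0], [-1.0], [0.0], [0.0]])
    cfg = SimulationConfig(n=1500, d=4, beta=beta, baseline_rate=0.03,
                           followup_years=10, seed=11)
    ds, truth = simulate_cohort(cfg)
    return ds, truth


def random_survival_instance(rng, n, with_ties=True):
    """Random (r, T, E) triple, optionally with risk and time ties."""
    if with_ties:
        r = rng.integers(0, 5, size=n).astype(float)
        T = rng.integers(0, 8, size=n).astype(float)
    else:
        r = rng.standard_normal(n)
        T = rng.random(n) * 10
    E = (rng.random(n) < 0.5).astype(int)
    return r, T, E
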