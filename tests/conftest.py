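import numpy as np
import pytest

import voxgc as v

# fixed base seed for every stochastic check in the suite
SUITE_SEED = 1


@pytest.fixture(scope="session")
def study_result():
    """One full 56-model simulation study (T=200, one iteration).

    Shared session-wide: the headline method comparison and the
    averaged-signal correlation checks both read from it.
    """
    return v.run_simulation_study(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def study_comparison(study_result):
    return v.compare_methods(study_result)


@pytest.fixture
def small_dataset():
    """Deterministic 3+4-voxel dataset from a known stable VAR(1)."""
    rng = np.random.default_rng(42)
    d = 7
    B = np.zeros((d, d))
    B[np.diag_indices(d)] = 0.4
    B[0, 3], B[4, 1], B[5, 6] = 0.3, -0.35, 0.25
    model = v.MvarModel(coeffs=[B], partition=(3, 4), innovation_sd=0.1)
    assert model.is_stable()
    return model, v.iterate_model(model, T=300, seed=int(rng.integers(1 << 30)))


def make_regression(n, p, seed, beta=None, noise_sd=0.1):
    """Demeaned synthetic regression problem for solver tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    if beta is None:
        beta = np.zeros(p)
    y = X @ beta + rng.normal(0, noise_sd, n)
    y -= y.mean()
    return v.RegressionProblem(
        design=X,
        response=y,
        predictor_index=[(j, 1) for j in range(p)],
        obs_trial=np.zeros(n, dtype=int),
        obs_time=np.arange(n),
    )
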