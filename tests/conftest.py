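import numpy as np
import pytest
from dataclasses import replace

from aapref import oracle as oc


@pytest.fixture(scope="session")
def default_params():
    return oc.default_params()


@pytest.fixture(scope="session")
def noiseless_params(default_params):
    return replace(default_params, noise_mult_sd=0.0, noise_add_sd=0.0)


@pytest.fixture(scope="session")
def r0_summaries(default_params):
    """Round-0 screening measurements (simulated once per session)."""
    from aapref.campaign import OracleTester, design_round0

    comps = design_round0()
    tester = OracleTester(params=default_params, replicates=4)
    return comps, tester.test(comps, seed=11)


class LinearModel:
    """Tiny deterministic stand-in surrogate: f(x) = intercept + w @ x."""

    def __init__(self, w, intercept=0.0):
        self.w = np.asarray(w, dtype=float)
        self.intercept = float(intercept)

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.w + self.intercept


@pytest.fixture
def linear_model_cls():
    return LinearModel
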