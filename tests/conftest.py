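import numpy as np
import pytest

import survecon as se
from survecon.scenarios import AnalysisInputs, fits_from_curves


class ExpSurv:
    """Closed-form exponential survival curve used as an analytic stand-in."""

    def __init__(self, rate: float):
        self.rate = rate

    def survival(self, t):
        return np.exp(-self.rate * np.asarray(t, dtype=float))

    def hazard(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.rate)

    def cumulative_hazard(self, t):
        return self.rate * np.asarray(t, dtype=float)


@pytest.fixture(scope="session")
def exp_curves():
    """A consistent bound curve set with known exponential dynamics."""
    return {
        "RFS": ExpSurv(0.02),
        "OS": ExpSurv(0.01),
        "DMFS": ExpSurv(0.015),
        "1LPFS": ExpSurv(0.05),
        "2LOS": ExpSurv(0.04),
    }


@pytest.fixture(scope="session")
def bundle():
    """Small simulated two-arm trial bundle shared across tests."""
    return se.simulate_trial(se.TrialSpec(n_per_arm=300, seed=11))


@pytest.fixture(scope="session")
def fitted_inputs(bundle):
    """AnalysisInputs with AIC-selected fits for the shared bundle."""
    fits = fits_from_curves(bundle.curves, bundle.at_risk)
    return AnalysisInputs(
        config=se.ModelConfig(),
        econ=bundle.economics,
        fits=fits,
        life_table=bundle.life_table,
        projection_hrs={"OS": 0.8975, "RFS": 0.9202, "DMFS": 0.8827},
    )


@pytest.fixture(scope="session")
def life_table():
    return se.synthetic_life_table()
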