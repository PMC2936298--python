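import numpy as np
import pandas as pd
import pytest

import birthmix as bm


@pytest.fixture(scope="session")
def scenario():
    """The four-component reference scenario (true mixture + risk)."""
    return bm.four_component_scenario()


@pytest.fixture(scope="session")
def small_sample(scenario):
    """A modest seeded draw from the reference scenario."""
    return bm.simulate_records(scenario.mixture, scenario.risk, 20_000, seed=11)


@pytest.fixture(scope="session")
def fitted_small(scenario, small_sample):
    """Mixture + PMLR fit on the small sample (shared across tests)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mix = bm.fit_mixture_em(small_sample, 4, seed=11)
        riskm = bm.fit_pmlr(small_sample, mix, seed=11)
    return mix, riskm


def constant_risk_model(mixture, rates):
    """RiskModel with constant per-component risks (handy test helper)."""
    from scipy.special import logit

    k = mixture.k
    coeffs = np.zeros((k, 5))
    coeffs[:, 0] = logit(np.asarray(rates, dtype=float))
    return bm.RiskModel(mixture=mixture, coeffs=coeffs, degree=4)
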