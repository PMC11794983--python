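import warnings

import numpy as np
import pandas as pd
import pytest

from dielact.occasions import aggregate_binomial, bin_detections
from dielact.sim import SimParams, simulate_detections


@pytest.fixture(scope="session")
def bimodal_params():
    """Default bimodal generator with no phase variability (tractable truth)."""
    return SimParams(sigma_gamma=0.0, sigma_tau=1.0)


@pytest.fixture(scope="session")
def bimodal_occasions(bimodal_params):
    """One mid-sized simulated dataset aggregated to binomial occasions."""
    det, eff, effects = simulate_detections(bimodal_params, n_sites=60,
                                            n_days=40, bin_hours=1.0, seed=101)
    occ = aggregate_binomial(bin_detections(det, eff, 1.0))
    return occ, effects


@pytest.fixture(scope="session")
def bimodal_fit(bimodal_occasions):
    from dielact.trig import TrigModelSpec, fit_trig
    occ, _ = bimodal_occasions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_trig(TrigModelSpec(), occ)


@pytest.fixture
def toy_occasions():
    """2 sites x 4 bins, hand-enterable counts."""
    return pd.DataFrame({
        "site": ["A"] * 4 + ["B"] * 4,
        "time": [0.0, 6.0, 12.0, 18.0] * 2,
        "success": [3, 1, 0, 5, 2, 2, 1, 7],
        "failure": [7, 9, 10, 5, 8, 8, 9, 3],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
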