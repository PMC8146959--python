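import numpy as np
import pytest

import ketoflux as kf


@pytest.fixture
def reference_preset():
    """Exchange-dominated fasted scenario used for the corruption and
    sensitivity demonstrations."""
    return kf.get_preset("fasted_14wk")


@pytest.fixture
def recovery_preset():
    """Moderate-exchange scenario where all six fluxes are well
    identified at the default noise level."""
    return kf.get_preset("obese_fasted")


@pytest.fixture
def protocol():
    return kf.TracerProtocol()


@pytest.fixture
def clean_experiment(reference_preset):
    noise = kf.NoiseConfig(mid_sigma=0.0, rinf_sigma_rel=0.0)
    return kf.generate_experiment(reference_preset, noise)


@pytest.fixture
def fast_fit_config():
    return kf.FitConfig(multistart=3, seed=1)


def random_flux_state(rng, rinf_acac=1.91, rinf_bhb=2.08):
    """Draw an admissible flux state: non-negative fluxes, balanced
    nodes, positive outflows, enrichments strictly inside (0, 1)."""
    while True:
        ra_a, ra_b = rng.uniform(2.0, 60.0, 2)
        ri_a, ri_b = rng.uniform(0.0, 80.0, 2)
        state = kf.FluxState.from_free(
            ra_a, ra_b, ri_a, ri_b, rinf_acac, rinf_bhb,
            pool_ratio_acac=rng.uniform(0.1, 0.9),
        )
        if state.rd_acac > 0.5 and state.rd_bhb > 0.5:
            return state
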