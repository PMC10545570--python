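import numpy as np
import pytest

from denseior.simulate import (DesignConfig, EffectParams, NoiseParams,
                               simulate_cohort)

# published grand-average hybrid-curve estimates (z-units, seconds, Hz, rad)
HYBRID_TABLE = dict(b0=-0.48, N0=0.82, tau=0.18, a=0.14, f=1.05, phi=0.72)
EXPONENTIAL_TABLE = dict(b0=-0.51, N0=1.10, tau=0.18)
RHYTHMIC_TABLE = dict(b0=-0.35, a=0.30, f=1.00, phi=0.74)

# published information criteria for the five candidate models
AICC_TABLE = {"intercept": 6.71, "linear": -6.21, "exponential": -34.91,
              "rhythmic": -15.23, "hybrid": -57.41}
BIC_TABLE = {"intercept": 8.60, "linear": -3.69, "exponential": -32.04,
             "rhythmic": -12.29, "hybrid": -55.47}


@pytest.fixture(scope="session")
def grid():
    """Default 25-point CTOA grid in seconds (42..1050 ms)."""
    return DesignConfig().ctoa_grid


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated cohort for pipeline-level tests."""
    cfg = DesignConfig(n_participants=8)
    return cfg, simulate_cohort(cfg, EffectParams(), NoiseParams(),
                                master_seed=11)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Deterministic cohort: no trial noise, no lapses, effect in raw units."""
    cfg = DesignConfig(n_participants=4)
    noise = NoiseParams(participant_intercept_sd=0.0, participant_scale_sd=0.0,
                        trial_sd=0.0, effect_scale=1.0, false_alarm_rate=0.0,
                        miss_rate=0.0, base_rt_mean=0.9)
    return cfg, noise, simulate_cohort(cfg, EffectParams(), noise,
                                       master_seed=3)
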