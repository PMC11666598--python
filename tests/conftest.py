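import pytest

import cycleamp as ca

# Study-scale cohort used by recovery tests: 200 participants, 3-5 cycles
# each, default noise and missingness.
DEFAULT_SEED = 1234


def noiseless_config(**overrides):
    """Deterministic generator settings: no noise, no missing days, no
    outliers, no covariate effects, uniform amplitude."""
    base = dict(
        n_participants=12,
        rng_seed=9,
        noise_sd_rhr=0.0,
        noise_sd_rmssd=0.0,
        p_missing_day=0.0,
        p_outlier_day=0.0,
        weekend_rhr_effect=0.0,
        weekend_rmssd_effect=0.0,
        kj_slope_rhr=0.0,
        kj_slope_rmssd=0.0,
        age_slope_rhr_amp=0.0,
        age_slope_rmssd_amp=0.0,
    )
    base.update(overrides)
    return ca.SimConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    return ca.simulate_cohort(ca.SimConfig(n_participants=200, rng_seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_run(default_cohort):
    return ca.run_pipeline(default_cohort.daily, default_cohort.participants)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return ca.simulate_cohort(noiseless_config())


@pytest.fixture(scope="session")
def noiseless_run(noiseless_cohort):
    # outlier removal off: with zero noise the Tukey fences collapse onto
    # the flat mid-cycle offsets and would excise the genuine extremes
    return ca.run_pipeline(
        noiseless_cohort.daily,
        noiseless_cohort.participants,
        fit_model=False,
        peak_day=26,
        nadir_day=5,
        mean_cycle_len=27.4,
        remove_outliers=False,
    )
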