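import numpy as np
import pytest

from fetalgrowth.synthetic_cohort import (
    STUDY_COUNTRIES,
    EffectProfile,
    SimConfig,
    simulate_cohort,
)

#: linear log-median curve (log grams vs centred GA weeks) used by the
#: calibration simulations so a degree-1 GA model is exactly specified
LINEAR_BASE = (6.5, 0.09, 0.0, 0.0)


def neutral_config(**overrides) -> SimConfig:
    """Cohort config with every country/covariate effect switched off."""
    defaults = dict(countries={c: 0.0 for c in STUDY_COUNTRIES},
                    covariate_effects={}, seed=0)
    defaults.update(overrides)
    return SimConfig(**defaults)


def calibration_config(seed, *, n_per_country=100,
                       countries=("Argentina", "Brazil", "Norway"),
                       **overrides) -> SimConfig:
    """Small, correctly-specified, independent-observation cohort for
    checking the asymptotic inference machinery."""
    defaults = dict(n_per_country=n_per_country,
                    countries={c: 0.0 for c in countries},
                    covariate_effects={}, base_median_coefs=LINEAR_BASE,
                    visit_weeks=(18, 28, 38), rank_tracking=False,
                    missed_visit_rate=0.0, withdrawal_rate=0.0,
                    loss_rate=0.0, seed=seed)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def bundle():
    from fetalgrowth.reference_charts import load_bundle

    return load_bundle()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest multi-country cohort with default effects (deterministic)."""
    cfg = SimConfig(n_per_country=30,
                    countries={"Argentina": -0.03, "Brazil": 0.0,
                               "Norway": 0.03},
                    seed=11)
    return cfg, *simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
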