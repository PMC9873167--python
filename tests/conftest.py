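import numpy as np
import pandas as pd
import pytest

from timeuse_coda import ActivityMap, GeneratorConfig, close
from timeuse_coda.synthetic import CovariateSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def compositions(rng):
    """50 random strictly positive compositions closed to 24 h."""
    return close(np.exp(rng.normal(scale=0.7, size=(50, 3))))


@pytest.fixture
def weights(rng):
    return rng.uniform(0.2, 3.0, size=50)


@pytest.fixture(scope="session")
def default_map():
    return ActivityMap.default()


def two_factor_config(
    n: int = 400,
    sex_effect_2015: np.ndarray | None = None,
    weight_sigma: float = 0.5,
    seed_sigma: float = 0.25,
) -> GeneratorConfig:
    """Small two-covariate, two-wave generator used across the suite.

    ``sex_effect_2015`` overrides the male-level effect in 2015 to plant a
    wave interaction; by default effects are wave-constant (no interaction).
    """
    sex_09 = np.array([[0.0, 0.0], [0.30, -0.15]])
    sex_15 = sex_09.copy()
    if sex_effect_2015 is not None:
        sex_15 = np.array([[0.0, 0.0], list(sex_effect_2015)])
    sex = CovariateSpec(
        "sex",
        ("female", "male"),
        {2009: np.array([0.5, 0.5]), 2015: np.array([0.5, 0.5])},
        {2009: sex_09, 2015: sex_15},
    )
    edu = CovariateSpec(
        "education",
        ("primary_or_below", "secondary_high_school", "college_university_higher"),
        {2009: np.array([0.5, 0.3, 0.2]), 2015: np.array([0.4, 0.35, 0.25])},
        {
            2009: np.array([[0.0, 0.0], [0.12, 0.05], [-0.08, 0.20]]),
            2015: np.array([[0.0, 0.0], [0.12, 0.05], [-0.08, 0.20]]),
        },
    )
    return GeneratorConfig(
        n_per_wave={2009: n, 2015: n},
        intercepts={2009: np.array([0.35, 0.05]), 2015: np.array([0.28, 0.10])},
        covariates=(sex, edu),
        sigma=np.array([[seed_sigma, -0.05], [-0.05, 0.18]]),
        weight_sigma=weight_sigma,
    )


@pytest.fixture
def small_survey():
    """A generated two-wave person-day table with ground truth."""
    from timeuse_coda import generate_person_days

    cfg = two_factor_config(n=600)
    df, gt = generate_person_days(cfg, seed=11)
    return df, gt, cfg
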