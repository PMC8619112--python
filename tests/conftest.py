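import numpy as np
import pytest

from abrelates import (
    CodingScheme,
    InteractionTerm,
    Theta,
    TrialData,
)

# --- fixture parameter sets built from printed trial coefficient tables ---
# (3-dp rounded coefficients; synthetic stand-ins for the raw trial data,
# which is not packaged)


@pytest.fixture
def sepsis_theta():
    """Sepsis trial, intercept-free, no absolute effect: weight & sex covariates."""
    return Theta(0.0, [0.0], [-6.755, 0.225], [0.240])


@pytest.fixture
def influenza_theta():
    """Influenza vaccination trial: round and HAI-titer covariates."""
    return Theta(0.0, [-1.596], [-0.280, -0.590], [-0.242])


@pytest.fixture
def covid_theta():
    """COVID-19 hydroxychloroquine trial (sum-to-zero coding, no intercept)."""
    return Theta(0.0, [-3.279], [-0.099, -0.947, 0.833, 0.463], [-0.513])


@pytest.fixture
def covid_coding():
    return CodingScheme("sum_zero")


@pytest.fixture
def covid_interactions():
    # column 3 = symptoms x treatment indicator, base covariate column 2
    return (InteractionTerm(column=3, treatment=1, base_column=2),)


def random_theta(rng, g=2, p=3, delta_scale=0.6):
    return Theta(
        mu=rng.normal(scale=0.5),
        tau=rng.normal(scale=0.5, size=g - 1),
        beta=rng.normal(scale=0.5, size=p),
        delta=rng.uniform(-delta_scale, delta_scale, size=g - 1),
    )


def random_data(rng, n=50, g=2, p=3, coding="baseline"):
    group = rng.integers(1, g + 1, size=n)
    # guarantee every arm occupied
    group[:g] = np.arange(1, g + 1)
    return TrialData(
        y=rng.integers(0, 2, size=n).astype(float),
        group=group,
        X=rng.standard_normal((n, p)),
        coding=CodingScheme(coding),
        g=g,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
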