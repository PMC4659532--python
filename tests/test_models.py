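"""Model functions and closed-form BMD inversions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bmdpotency.models import (
    BmrSpec,
    CANCER_BMR,
    CONTINUOUS_BMR,
    ExponentialParams,
    ParameterDomainError,
    QuantalParams,
    bmd_continuous,
    bmd_quantal,
    exponential_mean,
    loglogistic_risk,
    potency_from_bmd_continuous,
    potency_from_bmd_quantal,
)


@pytest.mark.parametrize(
    "dose, params, expected",
    [
        (0.0, ExponentialParams(1.5, 1, 3, 1), 1.5),  # background at dose 0
        (17.3, ExponentialParams(2, 1, 1, 1), 2.0),  # c=1 is a flat curve
        (1.0, ExponentialParams(1, 0.693147, 2, 1), 1.5),  # exp(-ln 2) = 1/2
    ],
)
def test_exponential_mean_values(dose, params, expected):
    assert exponential_mean(dose, params) == pytest.approx(expected, rel=1e-6)


@pytest.mark.parametrize(
    "dose, params, expected",
    [
        (5.0, QuantalParams(0.2, 5, 2), 0.6),  # midpoint: a + (1-a)/2
        (0.0, QuantalParams(0.1, 5, 2), 0.1),  # background at dose 0
        (3.0, QuantalParams(0.0, 1, 2), 0.9),  # 9/(1+9)
    ],
)
def test_loglogistic_risk_values(dose, params, expected):
    assert loglogistic_risk(dose, params) == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize(
    "params, expected",
    [
        (ExponentialParams(1, 1, 2, 1), 0.0512933),  # -ln 0.95
        (ExponentialParams(1, 1, 2, 2), 0.226480),  # sqrt of the d=1 case
    ],
)
def test_bmd_continuous_values(params, expected):
    assert bmd_continuous(params, CONTINUOUS_BMR) == pytest.approx(expected, rel=1e-5)


def test_bmd_continuous_infinite_when_plateau_below_bmr():
    # max fold-change 1.04 can never produce a 5% increase
    assert math.isinf(bmd_continuous(ExponentialParams(1, 1, 1.04, 1), CONTINUOUS_BMR))
    assert math.isinf(bmd_continuous(ExponentialParams(1, 0.0, 2, 1), CONTINUOUS_BMR))


@pytest.mark.parametrize(
    "params, bmr, expected",
    [
        (QuantalParams(0.1, 7, 3), BmrSpec("extra-risk", 0.5), 7.0),
        (QuantalParams(0.1, 10, 1), CANCER_BMR, 10.0 / 9.0),
        (QuantalParams(0.0, 2, 2), CANCER_BMR, 2.0 / 3.0),
    ],
)
def test_bmd_quantal_values(params, bmr, expected):
    assert bmd_quantal(params, bmr) == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(a=0, b=1, c=2, d=1),
        dict(a=1, b=-0.1, c=2, d=1),
        dict(a=1, b=1, c=0, d=1),
        dict(a=1, b=1, c=2, d=0),
    ],
)
def test_exponential_params_domain(kwargs):
    with pytest.raises(ParameterDomainError):
        ExponentialParams(**kwargs)


@pytest.mark.parametrize(
    "kwargs",
    [dict(a=1.0, b=1, c=1), dict(a=-0.1, b=1, c=1), dict(a=0.1, b=0, c=1), dict(a=0.1, b=1, c=0)],
)
def test_quantal_params_domain(kwargs):
    with pytest.raises(ParameterDomainError):
        QuantalParams(**kwargs)


def test_negative_dose_rejected():
    with pytest.raises(ValueError):
        exponential_mean(-1.0, ExponentialParams(1, 1, 2, 1))
    with pytest.raises(ValueError):
        loglogistic_risk(-1.0, QuantalParams(0.1, 1, 1))


def test_bmr_kind_mismatch_rejected():
    with pytest.raises(ValueError):
        bmd_continuous(ExponentialParams(1, 1, 2, 1), CANCER_BMR)
    with pytest.raises(ValueError):
        bmd_quantal(QuantalParams(0.1, 1, 1), CONTINUOUS_BMR)
    with pytest.raises(ValueError):
        BmrSpec("percent-change-in-mean", 1.5)


# -- properties --------------------------------------------------------------

pos = st.floats(min_value=1e-3, max_value=1e3)


@given(a=pos, b=st.floats(min_value=1e-4, max_value=10), c=st.floats(min_value=1 + 1e-6, max_value=50),
       d=st.floats(min_value=0.2, max_value=5))
def test_exponential_monotone_increasing_for_c_above_one(a, b, c, d):
    params = ExponentialParams(a, b, c, d)
    doses = np.geomspace(1e-3, 1e2, 40)
    y = exponential_mean(doses, params)
    assert np.all(np.diff(y) >= -1e-12 * np.abs(y[:-1]))
    assert exponential_mean(0.0, params) == pytest.approx(a)


@given(a=pos, b=st.floats(min_value=1e-4, max_value=10),
       c=st.floats(min_value=1.2, max_value=50), d=st.floats(min_value=0.2, max_value=5),
       q=st.floats(min_value=0.01, max_value=0.15))
def test_bmd_continuous_roundtrip(a, b, c, d, q):
    """The mean response at the closed-form BMD is exactly a*(1+BMR)."""
    bmr = BmrSpec("percent-change-in-mean", q)
    params = ExponentialParams(a, b, c, d)
    bmd = bmd_continuous(params, bmr)
    if math.isfinite(bmd):
        assert exponential_mean(bmd, params) == pytest.approx(a * (1 + q), rel=1e-9)
        # potency inversion is the inverse map
        assert potency_from_bmd_continuous(bmd, c, d, bmr) == pytest.approx(b, rel=1e-9)


@given(a=st.floats(min_value=0, max_value=0.5), b=st.floats(min_value=1e-2, max_value=1e3),
       c=st.floats(min_value=0.2, max_value=8), q=st.floats(min_value=0.01, max_value=0.5))
def test_bmd_quantal_roundtrip(a, b, c, q):
    """Extra risk at the closed-form BMD equals the BMR exactly."""
    bmr = BmrSpec("extra-risk", q)
    params = QuantalParams(a, b, c)
    bmd = bmd_quantal(params, bmr)
    risk = loglogistic_risk(bmd, params)
    assert (risk - a) / (1 - a) == pytest.approx(q, rel=1e-9)
    assert potency_from_bmd_quantal(bmd, c, bmr) == pytest.approx(b, rel=1e-9)


@given(b=st.floats(min_value=1e-3, max_value=10), c=st.floats(min_value=1.2, max_value=20),
       d=st.floats(min_value=0.25, max_value=4), k=st.floats(min_value=1e-2, max_value=1e2))
def test_dose_scale_equivariance(b, c, d, k):
    """Rescaling the dose axis by k rescales the BMD by k in both families."""
    base = bmd_continuous(ExponentialParams(1.0, b, c, d), CONTINUOUS_BMR)
    scaled = bmd_continuous(ExponentialParams(1.0, b * k**-d, c, d), CONTINUOUS_BMR)
    assert scaled == pytest.approx(k * base, rel=1e-9)
    qbase = bmd_quantal(QuantalParams(0.05, b, c), CANCER_BMR)
    qscaled = bmd_quantal(QuantalParams(0.05, b * k, c), CANCER_BMR)
    assert qscaled == pytest.approx(k * qbase, rel=1e-9)
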