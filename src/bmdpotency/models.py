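"""Dose-response model families and closed-form benchmark-dose inversions.

Two families are used for genotoxic-potency estimation:

* a 4-parameter exponential model for continuous endpoints
  (percent of cells carrying micronuclei),

      y(x) = a * [c - (c - 1) * exp(-b * x**d)]

  with background ``a`` (> 0), potency rate ``b`` (>= 0, units dose**-d),
  asymptotic fold-change ``c`` (> 0) and shape exponent ``d`` (> 0); and

* a log-logistic model for quantal endpoints (fraction of tumour-bearing
  animals),

      y(x) = a + (1 - a) / (1 + exp(-c * ln(x / b)))

  with background risk ``a`` in [0, 1), the dose ``b`` at 50% extra risk and
  log-dose slope ``c`` (> 0).

The benchmark dose (BMD) is the dose producing a predefined benchmark
response (BMR): a relative increase in the mean for continuous data, extra
risk for quantal data.  Both inversions are available in closed form, which
the profile-likelihood machinery exploits to reparameterise potency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParameterDomainError",
    "ExponentialParams",
    "QuantalParams",
    "BmrSpec",
    "CONTINUOUS_BMR",
    "CANCER_BMR",
    "exponential_mean",
    "loglogistic_risk",
    "bmd_continuous",
    "bmd_quantal",
    "potency_from_bmd_continuous",
    "potency_from_bmd_quantal",
]


class ParameterDomainError(ValueError):
    """A model parameter is outside its mathematical domain."""


@dataclass(frozen=True)
class ExponentialParams:
    """Parameters of the 4-parameter exponential continuous model.

    Attributes
    ----------
    a : float
        Background mean response at dose 0 (same units as the response,
        here % cells with MN); must be > 0.
    b : float
        Potency rate, units dose**-d; must be >= 0.  ``b = 0`` gives a flat
        curve.
    c : float
        Asymptotic fold-change relative to background (y -> a*c as the dose
        grows); must be > 0.  ``c = 1`` gives a flat curve, ``c > 1`` an
        increasing one.
    d : float
        Shape exponent; must be > 0.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ParameterDomainError(f"background a must be > 0, got {self.a}")
        if not (self.b >= 0):
            raise ParameterDomainError(f"potency b must be >= 0, got {self.b}")
        if not (self.c > 0):
            raise ParameterDomainError(f"fold-change c must be > 0, got {self.c}")
        if not (self.d > 0):
            raise ParameterDomainError(f"shape d must be > 0, got {self.d}")


@dataclass(frozen=True)
class QuantalParams:
    """Parameters of the log-logistic quantal model.

    ``a`` is the background risk in [0, 1); ``b`` (> 0) is the dose at which
    extra risk reaches 50%; ``c`` (> 0) is the slope against natural-log
    dose.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (0 <= self.a < 1):
            raise ParameterDomainError(f"background risk a must be in [0, 1), got {self.a}")
        if not (self.b > 0):
            raise ParameterDomainError(f"midpoint dose b must be > 0, got {self.b}")
        if not (self.c > 0):
            raise ParameterDomainError(f"slope c must be > 0, got {self.c}")


@dataclass(frozen=True)
class BmrSpec:
    """Benchmark-response definition.

    kind
        ``"percent-change-in-mean"`` (continuous endpoints) or
        ``"extra-risk"`` (quantal endpoints).
    value
        Dimensionless fraction in (0, 1), e.g. 0.05 for a 5% increase in
        the mean, 0.10 for 10% extra risk.
    direction
        Only ``"increase"`` is supported: micronucleus induction and tumour
        incidence are studied as increases over background.
    """

    kind: str
    value: float
    direction: str = field(default="increase")

    _KINDS = ("percent-change-in-mean", "extra-risk")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown BMR kind {self.kind!r}; expected one of {self._KINDS}")
        if not (0 < self.value < 1):
            raise ValueError(f"BMR value must be in (0, 1), got {self.value}")
        if self.direction != "increase":
            raise ValueError("only direction='increase' is supported")


#: 5% increase in mean response: the conventional BMR for continuous
#: micronucleus data.
CONTINUOUS_BMR = BmrSpec("percent-change-in-mean", 0.05)

#: 10% extra risk: the conventional BMR for quantal carcinogenicity data.
CANCER_BMR = BmrSpec("extra-risk", 0.10)


def exponential_mean(dose, params: ExponentialParams):
    """Mean response of the exponential model at ``dose`` (scalar or array).

    Returns ``a`` at dose 0 and tends to ``a*c`` as dose grows; monotone
    nondecreasing in dose when ``c > 1``.
    """
    x = np.asarray(dose, dtype=float)
    if np.any(x < 0):
        raise ValueError("dose must be nonnegative")
    with np.errstate(over="ignore"):
        y = params.a * (params.c - (params.c - 1.0) * np.exp(-params.b * x**params.d))
    return float(y) if np.isscalar(dose) else y


def loglogistic_risk(dose, params: QuantalParams):
    """Probability of response of the log-logistic model at ``dose``.

    Evaluates a + (1-a) / (1 + (x/b)**-c); the dose-0 value is the
    continuity limit ``a``.
    """
    x = np.asarray(dose, dtype=float)
    if np.any(x < 0):
        raise ValueError("dose must be nonnegative")
    y = np.full_like(x, params.a, dtype=float)
    pos = x > 0
    if np.any(pos):
        # (x/b)^c / (1 + (x/b)^c) computed via logistic of c*ln(x/b) for stability
        from scipy.special import expit

        t = params.c * (np.log(x[pos]) - math.log(params.b))
        y[pos] = params.a + (1.0 - params.a) * expit(t)
    return float(y) if np.isscalar(dose) else y


def bmd_continuous(params: ExponentialParams, bmr: BmrSpec = CONTINUOUS_BMR) -> float:
    """Closed-form BMD for a relative increase in the mean.

    Solves ``y(BMD) = a * (1 + BMR)``:

        BMD = [ -ln((c - 1 - BMR) / (c - 1)) / b ] ** (1/d)

    Returns ``math.inf`` when the asymptotic effect never reaches the BMR
    (``c <= 1 + BMR``) or the curve is flat (``b = 0``); the infinity is a
    deliberate sentinel that drives the unbounded-interval logic downstream.
    """
    if bmr.kind != "percent-change-in-mean":
        raise ValueError("continuous BMD requires a percent-change-in-mean BMR")
    q = bmr.value
    if params.c <= 1.0 + q or params.b == 0:
        return math.inf
    k = -math.log((params.c - 1.0 - q) / (params.c - 1.0))
    return (k / params.b) ** (1.0 / params.d)


def bmd_quantal(params: QuantalParams, bmr: BmrSpec = CANCER_BMR) -> float:
    """Closed-form BMD for extra risk: (y - a)/(1 - a) = BMR.

        BMD = b * (BMR / (1 - BMR)) ** (1/c)
    """
    if bmr.kind != "extra-risk":
        raise ValueError("quantal BMD requires an extra-risk BMR")
    q = bmr.value
    return params.b * (q / (1.0 - q)) ** (1.0 / params.c)


def potency_from_bmd_continuous(bmd: float, c: float, d: float, bmr: BmrSpec = CONTINUOUS_BMR) -> float:
    """Invert the continuous BMD formula for the potency rate ``b``.

    Used to reparameterise a compound's potency in terms of its BMD during
    profile-likelihood computation.  Requires ``c > 1 + BMR`` (otherwise no
    finite dose attains the BMR).
    """
    q = bmr.value
    if c <= 1.0 + q:
        raise ParameterDomainError(f"c must exceed 1 + BMR = {1 + q}, got {c}")
    if not (bmd > 0):
        raise ParameterDomainError(f"bmd must be > 0, got {bmd}")
    k = -math.log((c - 1.0 - q) / (c - 1.0))
    return k / bmd**d


def potency_from_bmd_quantal(bmd: float, c: float, bmr: BmrSpec = CANCER_BMR) -> float:
    """Invert the quantal BMD formula for the midpoint dose ``b``."""
    if not (bmd > 0):
        raise ParameterDomainError(f"bmd must be > 0, got {bmd}")
    q = bmr.value
    return bmd * ((1.0 - q) / q) ** (1.0 / c)
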