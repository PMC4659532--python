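"""Cross-system potency correlation and interval prediction.

Potency in two systems (e.g. in vitro micronucleus concentration vs in vivo
micronucleus dose, or vs carcinogenicity dose) is compared by plotting each
compound's BMD confidence interval as a rectangle on double-log10 axes and
bracketing the cloud with two parallel unity-slope lines.  A unity slope on
log-log axes corresponds to strict proportionality between the systems, so
the pair of lines is fully described by two log10 intercepts; their vertical
separation is the prediction uncertainty in orders of magnitude.

Given such a band, a BMD interval measured in the x system maps to a
predicted range in the y system by intersecting the interval's verticals
with the two lines: lower line at the interval's lower end, upper line at
its upper end.  The predicted lower bound feeds a Margin-of-Exposure (MOE)
screen against the conventional 10 000 threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .models import BmrSpec
from .profile import BMDResult

__all__ = [
    "PotencyInterval",
    "CorrelationBand",
    "UnitySlopeBand",
    "MoeResult",
    "pair_intervals",
    "fit_band",
    "predict_interval",
    "margin_of_exposure",
    "finite_bound_box",
]

MOE_THRESHOLD = 10_000.0


@dataclass(frozen=True)
class PotencyInterval:
    """A compound's BMD confidence interval in one test system."""

    compound: str
    system: str  # e.g. in-vitro-MN | in-vivo-MN | cancer
    bmdl: float
    bmdu: float  # may be math.inf
    units: str = ""
    bmr: BmrSpec | None = None

    def __post_init__(self) -> None:
        if not (self.bmdl > 0):
            raise ValueError(f"{self.compound}: bmdl must be > 0 (got {self.bmdl})")
        if not (self.bmdl <= self.bmdu):
            raise ValueError(f"{self.compound}: bmdl must not exceed bmdu")

    @property
    def finite(self) -> bool:
        return math.isfinite(self.bmdu)

    @classmethod
    def from_result(cls, result: BMDResult, system: str, units: str = "") -> "PotencyInterval":
        if result.status == "unbounded":
            raise ValueError(f"{result.compound}: unbounded interval carries no potency")
        return cls(result.compound, system, result.bmdl, result.bmdu, units, result.bmr)


@dataclass(frozen=True)
class CorrelationBand:
    """Two unity-slope lines on log10-log10 axes, described by their intercepts."""

    intercept_lo: float
    intercept_hi: float
    provenance: str = "manual"  # manual | fitted
    coverage: float | None = None  # achieved fraction of finite rectangles inside

    def __post_init__(self) -> None:
        if not (self.intercept_lo < self.intercept_hi):
            raise ValueError("intercept_lo must be below intercept_hi")

    slope: float = 1.0

    @property
    def width(self) -> float:
        """Vertical separation in log10 units."""
        return self.intercept_hi - self.intercept_lo


def pair_intervals(x_results: list[PotencyInterval], y_results: list[PotencyInterval]):
    """Inner-join two systems' intervals on compound id.

    Returns ``(pairs, unmatched)``: ``pairs`` is a list of
    ``(x_interval, y_interval)`` tuples; ``unmatched`` maps system label to
    the compounds present only there.  Duplicated compounds within one
    system are an error.
    """
    for results in (x_results, y_results):
        ids = [r.compound for r in results]
        dupes = {c for c in ids if ids.count(c) > 1}
        if dupes:
            raise ValueError(f"duplicate compounds within one system: {sorted(dupes)}")
    x_by = {r.compound: r for r in x_results}
    y_by = {r.compound: r for r in y_results}
    common = [c for c in x_by if c in y_by]
    pairs = [(x_by[c], y_by[c]) for c in common]
    unmatched = {
        "x_only": sorted(set(x_by) - set(y_by)),
        "y_only": sorted(set(y_by) - set(x_by)),
    }
    return pairs, unmatched


def _offset_range(pair) -> tuple[float, float]:
    """Feasible log10(y/x) offsets for one rectangle (may have +inf top)."""
    x, y = pair
    lo = math.log10(y.bmdl) - (math.log10(x.bmdu) if x.finite else math.inf)
    hi = (math.log10(y.bmdu) if y.finite else math.inf) - math.log10(x.bmdl)
    return lo, hi


def _rect_intersects(pair, lo: float, hi: float) -> bool:
    """Whether a CI rectangle touches the band [lo, hi] of log10 offsets."""
    r_lo, r_hi = _offset_range(pair)
    return r_lo <= hi and r_hi >= lo


class UnitySlopeBand(BaseEstimator):
    """Unity-slope correlation band, manual or fitted to interval pairs.

    Parameters
    ----------
    intercepts : tuple (lo, hi) or None
        Fixed log10 intercepts (manual mode, mirroring lines drawn by eye);
        when None the band is fitted to the pairs.
    coverage : float
        Target fraction of doubly-finite CI rectangles that must intersect
        the fitted band.
    min_width : float
        Minimum vertical separation in log10 units; a degenerate fit (all
        pairs exactly proportional) is widened symmetrically to this.

    Attributes
    ----------
    band_ : :class:`CorrelationBand`
    intercept_lo_, intercept_hi_ : float
    coverage_ : float, achieved coverage of finite rectangles
    n_pairs_, n_finite_ : int
    """

    def __init__(self, intercepts: tuple | None = None, coverage: float = 0.95,
                 min_width: float = 0.1):
        self.intercepts = intercepts
        self.coverage = coverage
        self.min_width = min_width

    def fit(self, pairs, y=None):
        """Fit (or adopt) the band; ``pairs`` as from :func:`pair_intervals`."""
        pairs = list(pairs)
        finite = [p for p in pairs if p[0].finite and p[1].finite]
        if self.intercepts is not None:
            lo, hi = map(float, self.intercepts)
            provenance = "manual"
        else:
            if not finite:
                raise ValueError("band fitting needs at least one doubly-finite pair")
            mids = np.array([np.mean(_offset_range(p)) for p in finite])
            if self.coverage >= 1.0:
                # envelope of the rectangles: every finite CI fully inside
                lo = float(min(_offset_range(p)[0] for p in finite))
                hi = float(max(_offset_range(p)[1] for p in finite))
            else:
                alpha = (1.0 - self.coverage) / 2.0
                lo = float(np.quantile(mids, alpha))
                hi = float(np.quantile(mids, 1.0 - alpha))
            # widen symmetrically until the target fraction of rectangles is hit
            target = math.ceil(self.coverage * len(finite) - 1e-9)
            while sum(_rect_intersects(p, lo, hi) for p in finite) < target:
                pad = 0.05 * max(hi - lo, self.min_width)
                lo, hi = lo - pad, hi + pad
            provenance = "fitted"
        if hi - lo < self.min_width:
            mid = 0.5 * (lo + hi)
            lo, hi = mid - self.min_width / 2.0, mid + self.min_width / 2.0
        covered = (
            sum(_rect_intersects(p, lo, hi) for p in finite) / len(finite) if finite else np.nan
        )
        self.intercept_lo_, self.intercept_hi_ = lo, hi
        self.coverage_ = covered
        self.n_pairs_ = len(pairs)
        self.n_finite_ = len(finite)
        self.band_ = CorrelationBand(lo, hi, provenance, covered)
        return self

    def predict(self, X):
        """Map x-system intervals to predicted y ranges.

        ``X`` is an iterable of ``(lower, upper)`` tuples (upper may be
        inf) or of :class:`PotencyInterval`; returns an array of
        ``(lower, upper)`` predictions.
        """
        out = []
        for item in X:
            if isinstance(item, PotencyInterval):
                lo_x, hi_x = item.bmdl, item.bmdu
            else:
                lo_x, hi_x = item
            out.append(predict_interval(self.band_, (lo_x, hi_x)))
        return np.array(out)

    def report(self, pairs) -> pd.DataFrame:
        """Per-pair offsets, in/out-of-band flags and predicted y ranges."""
        rows = []
        for x, y in pairs:
            r_lo, r_hi = _offset_range((x, y))
            pred_lo, pred_hi = predict_interval(self.band_, (x.bmdl, x.bmdu))
            rows.append(
                {
                    "compound": x.compound,
                    "x_bmdl": x.bmdl,
                    "x_bmdu": x.bmdu,
                    "y_bmdl": y.bmdl,
                    "y_bmdu": y.bmdu,
                    "offset_lo": r_lo,
                    "offset_hi": r_hi,
                    "doubly_finite": x.finite and y.finite,
                    "in_band": _rect_intersects((x, y), self.intercept_lo_, self.intercept_hi_),
                    "pred_y_lo": pred_lo,
                    "pred_y_hi": pred_hi,
                }
            )
        return pd.DataFrame(rows)


def fit_band(pairs, coverage: float = 0.95, min_width: float = 0.1) -> CorrelationBand:
    """Fit a unity-slope band covering >= ``coverage`` of finite rectangles."""
    return UnitySlopeBand(coverage=coverage, min_width=min_width).fit(pairs).band_


def predict_interval(band: CorrelationBand, x_interval) -> tuple[float, float]:
    """Predicted y-system range for an x-system BMD interval.

    Lower band line evaluated at the interval's lower end, upper line at its
    upper end: ``(10**intercept_lo * L, 10**intercept_hi * U)``.  An
    infinite x upper bound propagates to an infinite predicted upper bound.
    """
    lo_x, hi_x = x_interval
    if not (lo_x > 0):
        raise ValueError(f"x interval lower bound must be > 0, got {lo_x}")
    if hi_x < lo_x:
        raise ValueError("x interval upper bound below lower bound")
    lower = 10.0**band.intercept_lo * lo_x
    upper = math.inf if math.isinf(hi_x) else 10.0**band.intercept_hi * hi_x
    return lower, upper


@dataclass(frozen=True)
class MoeResult:
    """Margin-of-Exposure screen for a predicted potency range."""

    moe_lower: float
    moe_upper: float
    verdict: str  # no-concern | concern | inconclusive
    threshold: float = MOE_THRESHOLD


def margin_of_exposure(predicted_lower: float, predicted_upper: float, exposure: float,
                       threshold: float = MOE_THRESHOLD) -> MoeResult:
    """MOE = predicted BMD bound / estimated exposure, with a screening verdict.

    no-concern when even the *lower* bound of the predicted potency range
    sits more than ``threshold``-fold above the exposure; concern when even
    the *upper* bound sits less than ``threshold``-fold above it; otherwise
    inconclusive.
    """
    if not (predicted_lower > 0 and exposure > 0):
        raise ValueError("predicted bounds and exposure must be positive")
    if predicted_upper < predicted_lower:
        raise ValueError("predicted upper bound below lower bound")
    moe_lo = predicted_lower / exposure
    moe_hi = predicted_upper / exposure
    if moe_lo > threshold:
        verdict = "no-concern"
    elif moe_hi < threshold:
        verdict = "concern"
    else:
        verdict = "inconclusive"
    return MoeResult(moe_lo, moe_hi, verdict, threshold)


def finite_bound_box(intervals: list[PotencyInterval]) -> tuple[float, float]:
    """Dashed reference box limits: lowest BMDL and largest finite BMDU.

    Plot metadata making infinite bounds directly visible (a CI crossing
    outside the box has an infinite bound).
    """
    bmdls = [r.bmdl for r in intervals]
    finite_us = [r.bmdu for r in intervals if math.isfinite(r.bmdu)]
    if not finite_us:
        raise ValueError("no finite upper bounds among the intervals")
    return min(bmdls), max(finite_us)
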