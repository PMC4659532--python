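"""Profile-likelihood benchmark-dose confidence intervals.

The BMD for one compound in a fitted cluster is treated as the parameter of
interest by reparameterising that compound's potency through the closed-form
BMD inversion.  For a candidate BMD value every other parameter (all
backgrounds, the other potencies, the shared shape and — continuous case —
the residual SDs) is re-maximised; the profile confidence set at level
``level`` is where the log-likelihood drop from the global maximum stays
below half the chi-square(1 df) quantile (1.35277 for a two-sided 90%
interval).

Weak or absent dose-response shows up as an interval whose upper bound never
materialises: the profile stays above the threshold all the way to an
operational ceiling (default 1000 x the compound's maximum tested dose), and
the bound is reported as infinite rather than forced to a number.  When even
the lower bound escapes below the floor the interval is fully unbounded and
the compound carries no usable potency information; such compounds are
excluded from downstream correlation work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .models import BmrSpec

__all__ = ["BMDResult", "profile_ci", "classify_and_filter", "bmd_table"]

_REL_TOL = 0.01  # relative precision of the located bounds


@dataclass
class BMDResult:
    """BMD point estimate and profile-likelihood confidence interval."""

    compound: str
    bmd: float
    bmdl: float
    bmdu: float
    bmr: BmrSpec
    level: float
    status: str  # finite | upper-unbounded | unbounded
    ceiling: float
    floor: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("finite", "upper-unbounded", "unbounded"):
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def usable(self) -> bool:
        """Whether the interval carries potency information."""
        return self.status != "unbounded"


def _profile_fn(model, compound: str, bmr: BmrSpec, thr: float):
    """Memoised profile log-likelihood with warm-start threading.

    Each evaluation warm-starts from the previous point's optimum; points
    that land below the decision threshold are re-solved from the cold start
    as well, so a stalled warm start cannot fake a crossing.
    """
    cache: dict[float, float] = {}
    state = {"x0": None}

    def prof(t: float) -> float:
        if t in cache:
            return cache[t]
        ll, theta = model.profile_loglik(compound, t, bmr=bmr, x0=state["x0"])
        if ll < thr:
            # a value below the threshold decides a bound: make sure it is
            # not an optimiser artefact by re-solving from the cold start
            # with perturbed restarts
            ll2, theta2 = model.profile_loglik(compound, t, bmr=bmr, x0=None, n_starts=4)
            if ll2 > ll:
                ll, theta = ll2, theta2
        state["x0"] = theta
        cache[t] = ll
        return ll

    return prof


def _bisect_log(prof, t_in: float, t_out: float, thr: float) -> float:
    """Locate the threshold crossing between an inside and an outside point."""
    while abs(math.log(t_out / t_in)) > math.log1p(_REL_TOL):
        mid = math.sqrt(t_in * t_out)
        if prof(mid) >= thr:
            t_in = mid
        else:
            t_out = mid
    return math.sqrt(t_in * t_out)


def profile_ci(fit, compound: str, bmr: BmrSpec | None = None, level: float = 0.90,
               ceiling_multiplier: float = 1000.0, floor_divisor: float = 1e6,
               step: float = 2.0) -> BMDResult:
    """Profile-likelihood BMD confidence interval for one cluster member.

    Parameters
    ----------
    fit : ClusterFit or fitted estimator
        Result of :func:`~bmdpotency.cluster.fit_continuous_cluster` /
        ``fit_quantal_cluster``, or the fitted estimator itself.
    compound : str
        Cluster member to profile.
    bmr : BmrSpec, optional
        Benchmark response; defaults to the one the cluster was fitted with.
    level : float
        Two-sided confidence level (default 0.90: log-likelihood drop
        1.35277).
    ceiling_multiplier : float
        The upper bound is declared infinite when the profile stays above
        the threshold up to ``ceiling_multiplier`` x the member's maximum
        tested dose.
    floor_divisor : float
        The interval is declared fully unbounded when the lower bound
        escapes below max tested dose / ``floor_divisor``.
    step : float
        Multiplicative step of the outward bracketing scan.
    """
    model = getattr(fit, "model", fit)  # accept ClusterFit or estimator
    if not model.converged_:
        raise RuntimeError("cluster fit did not converge; refusing to profile")
    if compound not in model.members_:
        raise KeyError(f"{compound!r} not among fitted members")
    bmr = bmr or model._bmr
    if not (0.5 < level < 1.0):
        raise ValueError("level must be in (0.5, 1)")

    data = model._data
    gi = model.members_.index(compound)
    sel = data.gidx == gi
    max_dose = float(data.dose[sel].max())
    ceiling = ceiling_multiplier * max_dose
    floor = max_dose / floor_divisor

    max_ll = model.loglik_
    drop = 0.5 * chi2.ppf(level, df=1)
    thr = max_ll - drop
    prof = _profile_fn(model, compound, bmr, thr)

    # anchor: the MLE BMD when finite, else the profile's best point on a grid
    bmd_point = model.bmd(compound, bmr)
    diagnostics: dict = {"loglik_max": max_ll, "threshold": thr}
    if math.isfinite(bmd_point) and floor < bmd_point < ceiling:
        anchor = bmd_point
    else:
        grid = np.geomspace(floor, ceiling, 17)
        lls = [prof(t) for t in grid]
        anchor = float(grid[int(np.argmax(lls))])
        diagnostics["anchor_from_grid"] = True
    anchor_ll = prof(anchor)
    if anchor_ll < thr - 0.5:
        # profile never reaches the confidence region near the anchor:
        # scan the whole range before giving up
        grid = np.geomspace(floor, ceiling, 25)
        lls = [prof(t) for t in grid]
        best = int(np.argmax(lls))
        anchor, anchor_ll = float(grid[best]), lls[best]
        if anchor_ll < thr:
            raise RuntimeError(
                f"{compound}: profile log-likelihood never enters the confidence "
                f"region (best {anchor_ll:.3f} < threshold {thr:.3f}); "
                "flat-profile pathology"
            )

    # lower bound
    t_in, bmdl = anchor, None
    t = anchor
    while t > floor:
        t = max(t / step, floor)
        if prof(t) >= thr:
            t_in = t
        else:
            bmdl = _bisect_log(prof, t_in, t, thr)
            break
    lower_unbounded = bmdl is None

    # upper bound
    t_in, bmdu = anchor, None
    t = anchor
    while t < ceiling:
        t = min(t * step, ceiling)
        if prof(t) >= thr:
            t_in = t
        else:
            bmdu = _bisect_log(prof, t_in, t, thr)
            break
    upper_unbounded = bmdu is None

    if lower_unbounded and upper_unbounded:
        status = "unbounded"
        bmdl_out, bmdu_out = 0.0, math.inf
    elif upper_unbounded:
        status = "upper-unbounded"
        bmdl_out, bmdu_out = bmdl, math.inf
    elif lower_unbounded:
        # not observed in practice for increasing dose-responses; report
        # faithfully rather than masking
        status = "unbounded"
        bmdl_out, bmdu_out = 0.0, bmdu
        diagnostics["lower_unbounded_only"] = True
    else:
        status = "finite"
        bmdl_out, bmdu_out = bmdl, bmdu

    diagnostics["anchor"] = anchor
    return BMDResult(
        compound=compound,
        bmd=bmd_point,
        bmdl=bmdl_out,
        bmdu=bmdu_out,
        bmr=bmr,
        level=level,
        status=status,
        ceiling=ceiling,
        floor=floor,
        diagnostics=diagnostics,
    )


def classify_and_filter(results: list[BMDResult]):
    """Drop fully unbounded intervals; report counts by status.

    Returns ``(retained, excluded, counts)`` where ``counts`` maps status to
    the number of results with that status.
    """
    retained = [r for r in results if r.status != "unbounded"]
    excluded = [r for r in results if r.status == "unbounded"]
    counts: dict[str, int] = {}
    for r in results:
        counts[r.status] = counts.get(r.status, 0) + 1
    return retained, excluded, counts


def bmd_table(results: list[BMDResult]) -> pd.DataFrame:
    """Per-compound BMDL/BMDU table with the literal ``Inf`` for unbounded uppers."""
    rows = []
    for r in results:
        rows.append(
            {
                "compound": r.compound,
                "bmdl": r.bmdl,
                "bmdu": "Inf" if math.isinf(r.bmdu) else r.bmdu,
                "status": r.status,
                "level": r.level,
                "bmr_kind": r.bmr.kind,
                "bmr": r.bmr.value,
            }
        )
    return pd.DataFrame(rows)
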