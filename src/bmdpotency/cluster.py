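"""Covariate (shared-shape) maximum-likelihood fitting of dose-response clusters.

Many compounds are fitted jointly: each compound keeps its own background
(``a``), potency (``b``) and — for continuous data — residual spread on the
log scale (``s``), while the shape parameters (``c``, ``d`` for the
exponential family, ``c`` for the log-logistic family) are shared across the
cluster.  Joint fitting borrows strength across compounds and sharpens the
benchmark-dose confidence intervals relative to fitting each compound alone.

Likelihoods
-----------
continuous
    log-responses are normal around ``log(exponential_mean)`` with
    per-compound standard deviation ``s_i`` (i.e. responses are lognormal);
    ``s_i`` is concentrated out of the optimisation in closed form.
quantal
    binomial counts with success probability ``loglogistic_risk``.

Replicate studies of the same compound are pooled into one member, so each
compound contributes a single (a, b, s) triple and its benchmark dose
reflects the average of its replicate studies.

The public surface is a pair of sklearn-style estimators,
:class:`ExponentialClusterModel` and :class:`LogLogisticClusterModel`, plus
thin functional wrappers (:func:`fit_continuous_cluster`,
:func:`fit_quantal_cluster`, :func:`log_likelihood`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import ContinuousDataset, QuantalDataset
from .models import (
    BmrSpec,
    CANCER_BMR,
    CONTINUOUS_BMR,
    ExponentialParams,
    QuantalParams,
    bmd_continuous,
    bmd_quantal,
    potency_from_bmd_continuous,
    potency_from_bmd_quantal,
)

__all__ = [
    "ClusterFit",
    "ConvergenceWarning",
    "ExponentialClusterModel",
    "LogLogisticClusterModel",
    "fit_continuous_cluster",
    "fit_quantal_cluster",
    "log_likelihood",
]

_LOG_2PI = math.log(2.0 * math.pi)
# floor on the per-compound residual variance; keeps the concentrated
# likelihood finite when a compound's data are fitted exactly
_VAR_FLOOR = 1e-12


class ConvergenceWarning(UserWarning):
    """Optimisation did not converge within the configured multi-starts."""


@dataclass
class ClusterFit:
    """Result of a joint shared-shape fit.

    ``params`` maps member id to its fitted parameter set; ``sigma`` (continuous
    only) maps member id to the MLE of the log-scale residual SD.
    """

    family: str
    members: list
    params: dict
    shape: tuple
    loglik: float
    converged: bool
    n_iter: int
    n_starts: int
    sigma: dict | None = None
    flags: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-member parameter report (one row per compound/dataset)."""
        rows = []
        for m in self.members:
            p = self.params[m]
            row = {"member": m, "a": p.a, "b": p.b, "c": p.c}
            if self.family == "continuous":
                row["d"] = p.d
                row["sigma_log"] = self.sigma[m]
            row["flags"] = ";".join(self.flags.get(m, []))
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# continuous family
# ---------------------------------------------------------------------------


class _ContinuousData:
    """Pooled arrays for the continuous-cluster likelihood."""

    def __init__(self, datasets: Sequence[ContinuousDataset], zero_half_count: bool,
                 default_cells_scored: float):
        by_compound: dict[str, list[ContinuousDataset]] = {}
        for ds in datasets:
            by_compound.setdefault(ds.compound, []).append(ds)
        self.members = list(by_compound)
        self.m = len(self.members)
        dose_parts, resp_parts, gidx_parts = [], [], []
        n_adjusted = 0
        for gi, comp in enumerate(self.members):
            for ds in by_compound[comp]:
                resp = ds.response.astype(float).copy()
                zero = resp <= 0
                if np.any(zero):
                    if not zero_half_count:
                        raise ValueError(
                            f"{comp}: zero responses present; enable the half-count "
                            "adjustment or remove them"
                        )
                    cells = (
                        ds.cells_scored
                        if ds.cells_scored is not None
                        else np.full(len(resp), default_cells_scored)
                    )
                    resp[zero] = 100.0 * 0.5 / cells[zero]
                    n_adjusted += int(zero.sum())
                dose_parts.append(ds.dose)
                resp_parts.append(resp)
                gidx_parts.append(np.full(len(resp), gi, dtype=int))
        if n_adjusted:
            warnings.warn(
                f"replaced {n_adjusted} zero response(s) with half a count before "
                "the log transform",
                UserWarning,
                stacklevel=3,
            )
        self.dose = np.concatenate(dose_parts)
        self.z = np.log(np.concatenate(resp_parts))
        self.gidx = np.concatenate(gidx_parts)
        self.counts = np.bincount(self.gidx, minlength=self.m).astype(float)
        with np.errstate(divide="ignore"):
            self.logdose = np.where(self.dose > 0, np.log(self.dose), -np.inf)
        self.max_dose = float(self.dose.max())
        self.jacobian = -float(self.z.sum())  # d(log y)/dy term of the lognormal density


def _cont_group_ss(data: _ContinuousData, a, b, c, d):
    """Per-compound residual sums of squares of log-response around log-mean."""
    with np.errstate(over="ignore", under="ignore"):
        xd = np.exp(d * data.logdose)  # dose**d, exactly 0 at dose 0
        mu = a[data.gidx] * (c - (c - 1.0) * np.exp(-b[data.gidx] * xd))
        resid = data.z - np.log(mu)
    return np.bincount(data.gidx, weights=resid * resid, minlength=data.m)


def _cont_conc_nll(data: _ContinuousData, a, b, c, d) -> float:
    """Concentrated negative log-likelihood (s_i profiled out; Jacobian omitted)."""
    ss = _cont_group_ss(data, a, b, c, d)
    if not np.all(np.isfinite(ss)):
        return np.inf
    var = np.maximum(ss / data.counts, _VAR_FLOOR)
    return float(0.5 * np.sum(data.counts * (np.log(var) + _LOG_2PI + 1.0)))


def _make_cont_objective(data: _ContinuousData, bmr: BmrSpec, profile_member: int | None,
                         profile_bmd: float | None):
    """Build the packed objective.

    Free layout: [log a (m), log b (m), gamma, delta] with c = 1 + e^gamma.
    Profile layout (member i pinned at BMD = t): log b_i is dropped and
    c = 1 + q + e^gamma so that the potency reparameterisation
    b_i = -ln((c-1-q)/(c-1)) / t**d stays inside its domain.
    """
    m = data.m
    q = bmr.value

    if profile_member is None:

        def nll(theta):
            a = np.exp(theta[:m])
            b = np.exp(theta[m : 2 * m])
            c = 1.0 + math.exp(theta[2 * m])
            d = math.exp(theta[2 * m + 1])
            return _cont_conc_nll(data, a, b, c, d)

        return nll

    t = float(profile_bmd)
    keep = [j for j in range(m) if j != profile_member]

    def nll(theta):
        a = np.exp(theta[:m])
        b = np.empty(m)
        b[keep] = np.exp(theta[m : 2 * m - 1])
        c = 1.0 + q + math.exp(theta[2 * m - 1])
        d = math.exp(theta[2 * m])
        b[profile_member] = potency_from_bmd_continuous(t, c, d, bmr)
        return _cont_conc_nll(data, a, b, c, d)

    return nll


def _cont_start(data: _ContinuousData, bmr: BmrSpec) -> np.ndarray:
    """Heuristic start: control geometric means, top-dose fold-change."""
    m = data.m
    la = np.zeros(m)
    lb = np.zeros(m)
    ratios = []
    for gi in range(m):
        sel = data.gidx == gi
        zg, xg = data.z[sel], data.dose[sel]
        z0 = zg[xg == 0]
        la[gi] = z0.mean() if len(z0) else zg.min()
        top = xg.max()
        if top > 0:
            ratios.append(math.exp(zg[xg == xg.max()].mean() - la[gi]))
    c0 = max(1.0 + 2.0 * bmr.value, (max(ratios) if ratios else 2.0))
    c0 = min(c0, 50.0)
    d0 = 1.0
    for gi in range(m):
        sel = data.gidx == gi
        zg, xg = data.z[sel], data.dose[sel]
        top = xg.max()
        ytop = math.exp(zg[xg == top].mean() - la[gi]) if top > 0 else 1.0
        # solve exp(-b x^d) = (c - ytop)/(c - 1) at the top dose
        frac = min(max((c0 - ytop) / (c0 - 1.0), 1e-6), 1.0 - 1e-6)
        lb[gi] = math.log(-math.log(frac) / max(top, 1e-12) ** d0) if top > 0 else -10.0
    return np.concatenate([la, lb, [math.log(c0 - 1.0)], [math.log(d0)]])


# ---------------------------------------------------------------------------
# quantal family
# ---------------------------------------------------------------------------


class _QuantalData:
    def __init__(self, datasets: Sequence[QuantalDataset]):
        self.members = [ds.dataset_id for ds in datasets]
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate quantal dataset ids")
        self.m = len(self.members)
        self.dose = np.concatenate([ds.dose for ds in datasets])
        self.n = np.concatenate([ds.n_tested for ds in datasets]).astype(float)
        self.k = np.concatenate([ds.n_affected for ds in datasets]).astype(float)
        self.gidx = np.concatenate(
            [np.full(len(ds.dose), gi, dtype=int) for gi, ds in enumerate(datasets)]
        )
        with np.errstate(divide="ignore"):
            self.logdose = np.where(self.dose > 0, np.log(self.dose), -np.inf)
        self.max_dose = float(self.dose.max())
        # binomial coefficients: constant part of the full log-likelihood
        self.logcoef = float(
            np.sum(gammaln(self.n + 1) - gammaln(self.k + 1) - gammaln(self.n - self.k + 1))
        )


def _quantal_nll(data: _QuantalData, a, b, c) -> float:
    """Binomial negative log-likelihood (without the coefficient constant)."""
    av = a[data.gidx]
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        t = c * (data.logdose - np.log(b[data.gidx]))
        frac = expit(t)
        p = av + (1.0 - av) * frac
    p = np.where(data.dose > 0, p, av)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = data.k * np.log(p) + (data.n - data.k) * np.log1p(-p)
    return float(-ll.sum())


def _make_quantal_objective(data: _QuantalData, bmr: BmrSpec, profile_member: int | None,
                            profile_bmd: float | None):
    """Free layout: [logit a (m), log b (m), log c]; profile drops log b_i."""
    m = data.m
    if profile_member is None:

        def nll(theta):
            a = expit(theta[:m])
            b = np.exp(theta[m : 2 * m])
            c = math.exp(theta[2 * m])
            return _quantal_nll(data, a, b, c)

        return nll

    t = float(profile_bmd)
    keep = [j for j in range(m) if j != profile_member]

    def nll(theta):
        a = expit(theta[:m])
        b = np.empty(m)
        b[keep] = np.exp(theta[m : 2 * m - 1])
        c = math.exp(theta[2 * m - 1])
        b[profile_member] = potency_from_bmd_quantal(t, c, bmr)
        return _quantal_nll(data, a, b, c)

    return nll


def _quantal_start(data: _QuantalData) -> np.ndarray:
    m = data.m
    alpha = np.zeros(m)
    lb = np.zeros(m)
    for gi in range(m):
        sel = data.gidx == gi
        xg, ng, kg = data.dose[sel], data.n[sel], data.k[sel]
        p0 = (kg[xg == 0].sum() + 0.5) / (ng[xg == 0].sum() + 1.0)
        alpha[gi] = math.log(p0 / (1.0 - p0))
        # crude midpoint guess: dose where observed extra risk crosses 0.5
        extra = np.where(xg > 0, (kg / ng - p0) / max(1.0 - p0, 1e-6), 0.0)
        above = xg[(xg > 0) & (extra >= 0.5)]
        lb[gi] = math.log(above.min()) if len(above) else math.log(max(xg.max(), 1e-6))
    return np.concatenate([alpha, lb, [0.0]])


# ---------------------------------------------------------------------------
# shared optimisation driver
# ---------------------------------------------------------------------------


def _multistart_minimize(nll, x0: np.ndarray, bounds, n_starts: int, rng: np.random.Generator,
                         max_iter: int, tol: float, extra_starts: Sequence[np.ndarray] = ()):
    """Best-of-N local optimisation with perturbed restarts."""
    starts = [x0] + [np.asarray(s, dtype=float) for s in extra_starts]
    while len(starts) < n_starts:
        starts.append(x0 + rng.normal(scale=0.7, size=x0.shape))
    best = None
    for s in starts:
        s = np.clip(s, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        try:
            res = minimize(
                nll,
                s,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": max_iter, "ftol": tol, "maxfun": 20 * max_iter},
            )
        except (FloatingPointError, OverflowError):  # pragma: no cover - defensive
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    if not best.success:
        # L-BFGS-B occasionally stops short (line-search aborts on the noisy
        # finite-difference gradient, or the iteration cap); polish from the
        # best point and count it converged when the polish cannot improve
        # the log-likelihood beyond the relative tolerance.
        if len(best.x) <= 12:
            polish = minimize(
                nll,
                best.x,
                method="Nelder-Mead",
                options={"maxiter": 200 * len(best.x), "fatol": 10 * tol, "xatol": 1e-7},
            )
        else:
            polish = minimize(
                nll,
                best.x,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 4 * max_iter, "ftol": tol, "maxfun": 80 * max_iter},
            )
        if np.isfinite(polish.fun) and polish.fun <= best.fun:
            stalled = best.fun - polish.fun < 1e-6 * max(1.0, abs(best.fun))
            polish.x = np.clip(polish.x, [lo for lo, _ in bounds], [hi for _, hi in bounds])
            if polish.success or stalled:
                polish.success = True
            best = polish
    return best


def _cont_bounds(m: int, profile: bool, d_bounds: tuple[float, float]):
    la = [(-20.0, 10.0)] * m
    lb = [(-40.0, 40.0)] * (m - 1 if profile else m)
    gamma = [(-18.0, 8.0)]
    delta = [(math.log(d_bounds[0]), math.log(d_bounds[1]))]
    return la + lb + gamma + delta


def _quantal_bounds(m: int, profile: bool):
    alpha = [(-16.0, 5.0)] * m
    lb = [(-40.0, 40.0)] * (m - 1 if profile else m)
    lc = [(-4.0, 5.0)]
    return alpha + lb + lc


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _as_continuous_datasets(X, y=None) -> list[ContinuousDataset]:
    if isinstance(X, ContinuousDataset):
        return [X]
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], ContinuousDataset):
        return list(X)
    df = pd.DataFrame(X).copy()
    if y is not None:
        df["response"] = np.asarray(y, dtype=float)
    if "replicate" not in df.columns:
        df["replicate"] = "r1"
    return [
        ContinuousDataset.from_frame(sub) for _, sub in df.groupby("compound", sort=False)
    ]


def _as_quantal_datasets(X, y=None) -> list[QuantalDataset]:
    if isinstance(X, QuantalDataset):
        return [X]
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], QuantalDataset):
        return list(X)
    df = pd.DataFrame(X).copy()
    if y is not None:
        df["n_affected"] = np.asarray(y, dtype=int)
    return [QuantalDataset.from_frame(sub) for _, sub in df.groupby("dataset", sort=False)]


class ExponentialClusterModel(BaseEstimator, RegressorMixin):
    """Shared-shape exponential dose-response model for continuous endpoints.

    Fits ``y = a_i [c - (c-1) exp(-b_i x^d)]`` jointly over compounds ``i``
    with lognormal errors: compound-specific background ``a_i``, potency
    ``b_i`` and log-scale SD ``s_i``; shape ``(c, d)`` shared.

    Parameters
    ----------
    bmr : float
        Benchmark response as a fractional increase in the mean (default
        0.05, i.e. a 5% increase over the fitted background).
    n_starts : int
        Number of multi-start local optimisations.
    max_iter : int
        Iteration cap per local optimisation.
    tol : float
        Relative convergence tolerance on the log-likelihood.
    random_state : int
        Seed for the restart perturbations.
    zero_half_count : bool
        Replace 0% responses by half a count (0.5 / cells scored) before the
        log transform.
    default_cells_scored : float
        Cells per culture assumed when the data carry no count column.
    d_bounds : tuple
        Allowed range of the shape exponent ``d``.

    Attributes
    ----------
    params_ : dict mapping compound -> :class:`ExponentialParams`
    sigma_ : dict mapping compound -> fitted log-scale residual SD
    shape_ : tuple (c, d) shared across compounds
    loglik_ : float, maximised full log-likelihood (lognormal density)
    converged_ : bool
    result_ : :class:`ClusterFit`
    """

    def __init__(self, bmr: float = 0.05, n_starts: int = 10, max_iter: int = 2000,
                 tol: float = 1e-8, random_state: int = 0, zero_half_count: bool = True,
                 default_cells_scored: float = 1000.0, d_bounds: tuple = (0.1, 10.0)):
        self.bmr = bmr
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.zero_half_count = zero_half_count
        self.default_cells_scored = default_cells_scored
        self.d_bounds = d_bounds

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the cluster.

        ``X`` may be a tidy frame (columns compound, dose, response,
        optionally replicate and cells_scored), a frame of (compound, dose)
        with ``y`` holding responses, or a list of
        :class:`ContinuousDataset`.
        """
        datasets = _as_continuous_datasets(X, y)
        for ds in datasets:
            if ds.n_dose_levels < 2:
                raise ValueError(f"{ds.compound}: needs >= 2 distinct dose levels")
        data = _ContinuousData(datasets, self.zero_half_count, self.default_cells_scored)
        bmr = BmrSpec("percent-change-in-mean", self.bmr)
        nll = _make_cont_objective(data, bmr, None, None)
        rng = np.random.default_rng(self.random_state)
        x0 = _cont_start(data, bmr)
        bounds = _cont_bounds(data.m, False, self.d_bounds)
        res = _multistart_minimize(nll, x0, bounds, self.n_starts, rng, self.max_iter, self.tol)
        self._finalize(data, datasets, bmr, res)
        return self

    def _finalize(self, data, datasets, bmr, res):
        m = data.m
        theta = res.x
        a = np.exp(theta[:m])
        b = np.exp(theta[m : 2 * m])
        c = 1.0 + math.exp(theta[2 * m])
        d = math.exp(theta[2 * m + 1])
        ss = _cont_group_ss(data, a, b, c, d)
        sigma = np.sqrt(np.maximum(ss / data.counts, _VAR_FLOOR))
        self.datasets_ = datasets
        self._data = data
        self._bmr = bmr
        self.members_ = list(data.members)
        self.params_ = {
            comp: ExponentialParams(a=float(a[i]), b=float(b[i]), c=float(c), d=float(d))
            for i, comp in enumerate(data.members)
        }
        self.sigma_ = {comp: float(sigma[i]) for i, comp in enumerate(data.members)}
        self.shape_ = (float(c), float(d))
        self.loglik_ = -float(res.fun) + data.jacobian
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        flags = {}
        for comp, p in self.params_.items():
            if not math.isfinite(bmd_continuous(p, bmr)):
                flags.setdefault(comp, []).append("no-finite-bmd-at-mle")
        if not self.converged_:
            warnings.warn(
                f"continuous cluster fit did not converge after {self.n_starts} starts: "
                f"{res.message}",
                ConvergenceWarning,
                stacklevel=3,
            )
        self.result_ = ClusterFit(
            family="continuous",
            members=self.members_,
            params=dict(self.params_),
            shape=self.shape_,
            loglik=self.loglik_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            n_starts=self.n_starts,
            sigma=dict(self.sigma_),
            flags=flags,
        )

    def predict(self, X):
        """Expected mean response for rows of (compound, dose)."""
        df = pd.DataFrame(X)
        from .models import exponential_mean

        return np.array(
            [
                exponential_mean(row.dose, self.params_[row.compound])
                for row in df.itertuples()
            ]
        )

    # -- domain API --------------------------------------------------------

    def bmd(self, compound: str | None = None, bmr: BmrSpec | None = None):
        """Closed-form BMD at the MLE (per compound or for one compound)."""
        bmr = bmr or self._bmr
        if compound is not None:
            return bmd_continuous(self.params_[compound], bmr)
        return {comp: bmd_continuous(p, bmr) for comp, p in self.params_.items()}

    def profile_loglik(self, compound: str, bmd_value: float, bmr: BmrSpec | None = None,
                       x0=None, n_starts: int = 1):
        """Profile log-likelihood at a pinned BMD for one compound.

        All other parameters (including the shared shape) are re-maximised.
        Returns ``(loglik, theta)`` where ``theta`` is the profile-layout
        optimum, reusable as a warm start for neighbouring BMD values.
        """
        bmr = bmr or self._bmr
        data = self._data
        gi = data.members.index(compound)
        nll = _make_cont_objective(data, bmr, gi, bmd_value)
        bounds = _cont_bounds(data.m, True, self.d_bounds)
        cold = self._profile_start(gi, bmr)
        x0 = cold if x0 is None else np.asarray(x0, float)
        extra = []
        if n_starts > 1:
            # the profile surface can switch between shape regimes; seed the
            # restarts with systematically different (c, d) values
            for delta in (0.0, math.log(2.0), math.log(0.4)):
                for gamma in (math.log(0.5), math.log(2.0), math.log(8.0)):
                    s = cold.copy()
                    s[-2], s[-1] = gamma, delta
                    extra.append(s)
        rng = np.random.default_rng(self.random_state + 1)
        res = _multistart_minimize(nll, x0, bounds, n_starts, rng,
                                   self.max_iter, self.tol,
                                   extra_starts=extra[: max(0, n_starts - 1)])
        return -float(res.fun) + data.jacobian, res.x

    def _profile_start(self, gi: int, bmr: BmrSpec) -> np.ndarray:
        m = self._data.m
        la = np.log([self.params_[c].a for c in self.members_])
        lb = np.log(np.maximum([self.params_[c].b for c in self.members_], 1e-17))
        lb = np.delete(lb, gi)
        c, d = self.shape_
        gamma = math.log(max(c - 1.0 - bmr.value, 1e-8))
        return np.concatenate([la, lb, [gamma], [math.log(d)]])


class LogLogisticClusterModel(BaseEstimator):
    """Shared-slope log-logistic model for quantal (tumour incidence) data.

    Fits ``p = a_i + (1 - a_i) / (1 + exp(-c ln(x / b_i)))`` jointly over
    datasets ``i`` with binomial errors; the log-dose slope ``c`` is shared.

    ``X`` may be a tidy frame (columns dataset, dose, n_tested, n_affected),
    a frame without n_affected plus ``y`` holding affected counts, or a list
    of :class:`QuantalDataset`.
    """

    def __init__(self, bmr: float = 0.10, n_starts: int = 10, max_iter: int = 2000,
                 tol: float = 1e-8, random_state: int = 0):
        self.bmr = bmr
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        datasets = _as_quantal_datasets(X, y)
        data = _QuantalData(datasets)
        bmr = BmrSpec("extra-risk", self.bmr)
        nll = _make_quantal_objective(data, bmr, None, None)
        rng = np.random.default_rng(self.random_state)
        x0 = _quantal_start(data)
        bounds = _quantal_bounds(data.m, False)
        res = _multistart_minimize(nll, x0, bounds, self.n_starts, rng, self.max_iter, self.tol)
        m = data.m
        theta = res.x
        a = expit(theta[:m])
        b = np.exp(theta[m : 2 * m])
        c = math.exp(theta[2 * m])
        self.datasets_ = datasets
        self._data = data
        self._bmr = bmr
        self.members_ = list(data.members)
        self.params_ = {
            mid: QuantalParams(a=float(a[i]), b=float(b[i]), c=float(c))
            for i, mid in enumerate(data.members)
        }
        self.shape_ = (float(c),)
        self.loglik_ = -float(res.fun) + data.logcoef
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        flags = {}
        from .models import loglogistic_risk

        for i, mid in enumerate(data.members):
            sel = data.gidx == i
            top = data.dose[sel].max()
            p = self.params_[mid]
            extra_top = (loglogistic_risk(top, p) - p.a) / max(1.0 - p.a, 1e-12)
            if extra_top < 1e-4:
                flags.setdefault(mid, []).append("no-dose-effect")
        if not self.converged_:
            warnings.warn(
                f"quantal cluster fit did not converge after {self.n_starts} starts: "
                f"{res.message}",
                ConvergenceWarning,
                stacklevel=2,
            )
        self.flags_ = flags
        self.result_ = ClusterFit(
            family="quantal",
            members=self.members_,
            params=dict(self.params_),
            shape=self.shape_,
            loglik=self.loglik_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            n_starts=self.n_starts,
            flags=flags,
        )
        return self

    def predict_proba(self, X):
        """Fitted risk for rows of (dataset, dose)."""
        from .models import loglogistic_risk

        df = pd.DataFrame(X)
        return np.array(
            [loglogistic_risk(row.dose, self.params_[row.dataset]) for row in df.itertuples()]
        )

    def bmd(self, member: str | None = None, bmr: BmrSpec | None = None):
        bmr = bmr or self._bmr
        if member is not None:
            return bmd_quantal(self.params_[member], bmr)
        return {mid: bmd_quantal(p, bmr) for mid, p in self.params_.items()}

    def profile_loglik(self, member: str, bmd_value: float, bmr: BmrSpec | None = None,
                       x0=None, n_starts: int = 1):
        bmr = bmr or self._bmr
        data = self._data
        gi = data.members.index(member)
        nll = _make_quantal_objective(data, bmr, gi, bmd_value)
        bounds = _quantal_bounds(data.m, True)
        alpha = [math.log(self.params_[mid].a / (1 - self.params_[mid].a))
                 if self.params_[mid].a > 1e-7 else -16.0 for mid in self.members_]
        lb = np.log([self.params_[mid].b for mid in self.members_])
        lb = np.delete(lb, gi)
        cold = np.concatenate([alpha, lb, [math.log(self.shape_[0])]])
        x0 = cold if x0 is None else np.asarray(x0, float)
        extra = []
        if n_starts > 1:
            for lc in (0.0, math.log(0.5), math.log(3.0)):
                s = cold.copy()
                s[-1] = lc
                extra.append(s)
        rng = np.random.default_rng(self.random_state + 1)
        res = _multistart_minimize(nll, x0, bounds, n_starts, rng,
                                   self.max_iter, self.tol,
                                   extra_starts=extra[: max(0, n_starts - 1)])
        return -float(res.fun) + data.logcoef, res.x


# ---------------------------------------------------------------------------
# functional wrappers (module-level operations)
# ---------------------------------------------------------------------------


def fit_continuous_cluster(datasets: Sequence[ContinuousDataset], **config) -> ClusterFit:
    """Joint shared-shape fit of continuous MN datasets; returns a ClusterFit."""
    model = ExponentialClusterModel(**config).fit(list(datasets))
    fit = model.result_
    fit.model = model  # keep the estimator reachable for profiling
    return fit


def fit_quantal_cluster(datasets: Sequence[QuantalDataset], **config) -> ClusterFit:
    """Joint shared-slope fit of quantal datasets; returns a ClusterFit."""
    model = LogLogisticClusterModel(**config).fit(list(datasets))
    fit = model.result_
    fit.model = model
    return fit


def log_likelihood(fit: ClusterFit, datasets) -> float:
    """Recompute the full log-likelihood of ``datasets`` at the fitted parameters.

    For continuous fits this is the sum of lognormal log-densities of the
    responses (using the stored per-compound sigma); for quantal fits the sum
    of binomial log-pmfs.  Equals ``fit.loglik`` at the stored MLE.
    """
    if fit.family == "continuous":
        data = _ContinuousData(list(datasets), True, 1000.0)
        if data.members != fit.members and set(data.members) != set(fit.members):
            raise ValueError("datasets do not match the fitted compounds")
        total = data.jacobian
        for gi, comp in enumerate(data.members):
            p = fit.params[comp]
            s = fit.sigma[comp]
            sel = data.gidx == gi
            with np.errstate(divide="ignore"):
                xd = np.exp(p.d * data.logdose[sel])
            mu = p.a * (p.c - (p.c - 1.0) * np.exp(-p.b * xd))
            resid = data.z[sel] - np.log(mu)
            total += float(
                np.sum(-0.5 * _LOG_2PI - math.log(s) - resid**2 / (2.0 * s * s))
            )
        return total
    if fit.family == "quantal":
        data = _QuantalData(list(datasets))
        if set(data.members) != set(fit.members):
            raise ValueError("datasets do not match the fitted datasets")
        a = np.array([fit.params[mid].a for mid in data.members])
        b = np.array([fit.params[mid].b for mid in data.members])
        c = fit.params[data.members[0]].c
        return -_quantal_nll(data, a, b, c) + data.logcoef
    raise ValueError(f"unknown family {fit.family!r}")
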