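"""Shared-shape cluster fitting: recovery, nesting, likelihood consistency."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

import bmdpotency as bp
from bmdpotency.cluster import (
    ClusterFit,
    fit_continuous_cluster,
    fit_quantal_cluster,
    log_likelihood,
)


def _fit_free_shape(datasets, **kw):
    """Each compound fitted alone (its own shape); sum of log-likelihoods."""
    total = 0.0
    for ds in datasets:
        total += bp.ExponentialClusterModel(**kw).fit([ds]).loglik_
    return total


def test_no_trend_data_gives_flat_curve():
    """Identical response pattern at every dose: the fit collapses to the
    constant model (flat curve, background at the common level, likelihood
    matching the constant-model MLE)."""
    ds = bp.ContinuousDataset(
        compound="flat",
        dose=np.array([0, 0, 0, 0, 1, 1, 5, 5, 25, 25], dtype=float),
        response=np.array([1.9, 2.1, 1.9, 2.1, 1.9, 2.1, 1.9, 2.1, 1.9, 2.1]),
        replicate=np.array(["r1"] * 10),
    )
    m = bp.ExponentialClusterModel(random_state=0).fit([ds])
    gmean = math.sqrt(1.9 * 2.1)
    assert m.params_["flat"].a == pytest.approx(gmean, rel=5e-3)
    preds = m.predict([{"compound": "flat", "dose": d} for d in (0.0, 1.0, 25.0)])
    assert np.ptp(preds) < 1e-2  # flat within a fraction of the noise
    # no dose effect: the BMD sits far beyond any tested dose (or is infinite)
    assert m.bmd("flat") > 1000 * 25.0
    # likelihood of the constant lognormal model, sigma at its MLE
    z = np.log(ds.response)
    sigma = float(np.std(z))
    const = ClusterFit(
        family="continuous",
        members=["flat"],
        params={"flat": bp.ExponentialParams(float(np.exp(z.mean())), 0.0, 2.0, 1.0)},
        shape=(2.0, 1.0),
        loglik=float("nan"),
        converged=True,
        n_iter=0,
        n_starts=0,
        sigma={"flat": sigma},
    )
    assert m.loglik_ == pytest.approx(log_likelihood(const, [ds]), abs=1e-3)


def test_parameter_recovery_large_n():
    """With many replicate studies and small noise, (a, b, c, d) come back
    within 10% of truth."""
    design = bp.StudyDesign(doses=(0, 0.5, 1, 2, 4, 8), treated_replicates=4,
                            control_replicates=4, cells_scored=10**6)
    truth = {"A": bp.ExponentialParams(a=1.0, b=0.1, c=3.0, d=1.0)}
    datasets = []
    for s in range(10):
        datasets += bp.simulate_continuous_mn(design, truth, noise_gsd=math.exp(0.05),
                                              seed=100 + s)
    m = bp.ExponentialClusterModel(n_starts=5, random_state=0).fit(datasets)
    p = m.params_["A"]
    assert p.a == pytest.approx(1.0, rel=0.10)
    assert p.b == pytest.approx(0.1, rel=0.10)
    assert p.c == pytest.approx(3.0, rel=0.10)
    assert p.d == pytest.approx(1.0, rel=0.10)


def test_shared_shape_nested_in_free_shape():
    """When the truth really has a common shape, constraining it costs
    almost nothing; the likelihood-ratio statistic stays small and
    nonnegative."""
    design = bp.StudyDesign(doses=(0, 1, 2, 4, 8, 16), treated_replicates=4,
                            control_replicates=4)
    truth = {
        "p": bp.ExponentialParams(a=1.0, b=0.2, c=3.0, d=1.0),
        "q": bp.ExponentialParams(a=2.0, b=0.05, c=3.0, d=1.0),
    }
    datasets = bp.simulate_continuous_mn(design, truth, noise_gsd=1.15, seed=21)
    shared = bp.ExponentialClusterModel(random_state=0).fit(datasets).loglik_
    free = _fit_free_shape(datasets, random_state=0)
    lrt = 2.0 * (free - shared)
    assert lrt >= -1e-4  # nesting: shared can never beat free
    assert free - shared < 2.0


def test_replicate_studies_pooled_into_one_member():
    design = bp.StudyDesign(doses=(0, 1, 4, 16))
    truth = {"A": bp.ExponentialParams(a=1.0, b=0.1, c=3.0, d=1.0)}
    rep1 = bp.simulate_continuous_mn(design, truth, seed=1)
    rep2 = bp.simulate_continuous_mn(design, truth, seed=2)
    fit = fit_continuous_cluster(rep1 + rep2, random_state=0)
    assert fit.members == ["A"]
    assert set(fit.params) == {"A"}
    assert set(fit.sigma) == {"A"}


def test_log_likelihood_self_consistency_and_maximality(two_compound_cluster):
    model, datasets, _ = two_compound_cluster
    fit = model.result_
    assert log_likelihood(fit, datasets) == pytest.approx(model.loglik_, abs=1e-6)

    def perturbed(**changes):
        params = {}
        for comp, p in fit.params.items():
            kw = dict(a=p.a, b=p.b, c=p.c, d=p.d)
            for key, factor in changes.items():
                if key in kw:
                    kw[key] *= factor
            params[comp] = bp.ExponentialParams(**kw)
        sigma = {
            comp: s * changes.get("sigma", 1.0) for comp, s in fit.sigma.items()
        }
        return ClusterFit(
            family="continuous", members=fit.members, params=params, shape=fit.shape,
            loglik=float("nan"), converged=True, n_iter=0, n_starts=0, sigma=sigma,
        )

    for key in ("a", "b", "c", "d", "sigma"):
        ll = log_likelihood(perturbed(**{key: 1.1}), datasets)
        assert ll <= model.loglik_ + 1e-6, f"perturbing {key} increased the likelihood"


def test_log_likelihood_matches_scipy_lognormal():
    """Hand-checkable case: the stored likelihood is the sum of lognormal
    log-densities (scipy.stats.lognorm as the independent oracle)."""
    ds = bp.ContinuousDataset(
        compound="tiny",
        dose=np.array([0.0, 0.0, 2.0, 2.0]),
        response=np.array([1.1, 0.9, 1.8, 2.3]),
        replicate=np.array(["r1", "r2", "r1", "r2"]),
    )
    p = bp.ExponentialParams(a=1.0, b=0.2, c=3.0, d=1.0)
    sigma = 0.17
    fit = ClusterFit(
        family="continuous", members=["tiny"], params={"tiny": p}, shape=(3.0, 1.0),
        loglik=float("nan"), converged=True, n_iter=0, n_starts=0,
        sigma={"tiny": sigma},
    )
    mu = bp.exponential_mean(ds.dose, p)
    expected = stats.lognorm(s=sigma, scale=mu).logpdf(ds.response).sum()
    assert log_likelihood(fit, [ds]) == pytest.approx(expected, abs=1e-9)


def test_dose_rescaling_leaves_max_loglik_unchanged(two_compound_cluster):
    model, datasets, _ = two_compound_cluster
    scaled = [
        bp.ContinuousDataset(
            compound=ds.compound, dose=ds.dose * 7.0, response=ds.response,
            replicate=ds.replicate, cells_scored=ds.cells_scored,
        )
        for ds in datasets
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m2 = bp.ExponentialClusterModel(random_state=0).fit(scaled)
    assert m2.loglik_ == pytest.approx(model.loglik_, abs=0.05)


def test_requires_two_dose_levels():
    ds = bp.ContinuousDataset(
        compound="one", dose=np.zeros(3), response=np.ones(3),
        replicate=np.array(["a", "b", "c"]),
    )
    with pytest.raises(ValueError, match="dose levels"):
        bp.ExponentialClusterModel().fit([ds])


# -- quantal -----------------------------------------------------------------


def test_quantal_two_point_toy_matches_saturated_fit():
    """Doses {0, 10}, affected {5, 25}/50: the 3-parameter curve can match
    the observed proportions exactly, so the MLE does."""
    ds = bp.QuantalDataset("toy", [0, 10], [50, 50], [5, 25])
    m = bp.LogLogisticClusterModel(random_state=0).fit([ds])
    p = m.params_["toy"]
    assert p.a == pytest.approx(0.1, abs=1e-3)
    assert bp.loglogistic_risk(10.0, p) == pytest.approx(0.5, abs=1e-3)
    # saturated binomial likelihood as the ceiling
    saturated = (
        stats.binom(50, 0.1).logpmf(5) + stats.binom(50, 0.5).logpmf(25)
    )
    assert m.loglik_ == pytest.approx(saturated, abs=1e-4)


def test_quantal_zero_affected_flagged_flat():
    ds = bp.QuantalDataset("null", [0, 10, 100], [50, 50, 50], [0, 0, 0])
    m = bp.LogLogisticClusterModel(random_state=0).fit([ds])
    assert m.params_["null"].a < 1e-4
    assert "no-dose-effect" in m.flags_["null"]


def test_quantal_cluster_recovery():
    """Many replicated bioassays: the average fitted midpoint dose comes
    back near the true b = 50."""
    truth = {f"d{i:02d}": bp.QuantalParams(a=0.05, b=50.0, c=2.0) for i in range(60)}
    design = bp.StudyDesign(doses=(0, 12.5, 50, 200), animals_per_group=50)
    datasets = bp.simulate_quantal_cancer(design, truth, seed=9)
    m = bp.LogLogisticClusterModel(n_starts=3, random_state=0).fit(datasets)
    bs = np.array([p.b for p in m.params_.values()])
    assert np.mean(bs) == pytest.approx(50.0, rel=0.10)
    assert m.shape_[0] == pytest.approx(2.0, rel=0.2)


def test_quantal_log_likelihood_matches_scipy_binom(quantal_cluster):
    model, datasets, _ = quantal_cluster
    fit = model.result_
    assert log_likelihood(fit, datasets) == pytest.approx(model.loglik_, abs=1e-6)
    expected = 0.0
    for ds in datasets:
        p = model.params_[ds.dataset_id]
        risks = np.array([bp.loglogistic_risk(float(d), p) for d in ds.dose])
        expected += stats.binom(ds.n_tested, risks).logpmf(ds.n_affected).sum()
    assert model.loglik_ == pytest.approx(expected, abs=1e-6)
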