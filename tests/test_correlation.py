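"""Cross-system interval pairing, unity-slope bands, prediction and MOE."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bmdpotency.correlation import (
    CorrelationBand,
    PotencyInterval,
    UnitySlopeBand,
    _rect_intersects,
    finite_bound_box,
    fit_band,
    margin_of_exposure,
    pair_intervals,
    predict_interval,
)


def _iv(compound, lo, hi, system="x"):
    return PotencyInterval(compound, system, lo, hi)


# -- pairing -----------------------------------------------------------------


def test_pairing_matches_all_when_ids_align():
    x = [_iv(f"c{i}", 1, 2) for i in range(19)]
    y = [_iv(f"c{i}", 10, 20, "y") for i in range(19)]
    pairs, unmatched = pair_intervals(x, y)
    assert len(pairs) == 19
    assert unmatched == {"x_only": [], "y_only": []}


def test_pairing_reports_unmatched():
    x = [_iv(f"c{i}", 1, 2) for i in range(19)]
    y = [_iv(f"c{i}", 10, 20, "y") for i in range(17)]
    pairs, unmatched = pair_intervals(x, y)
    assert len(pairs) == 17
    assert unmatched["x_only"] == ["c17", "c18"]


def test_pairing_disjoint_sets():
    pairs, unmatched = pair_intervals([_iv("a", 1, 2)], [_iv("b", 1, 2, "y")])
    assert pairs == []
    assert unmatched == {"x_only": ["a"], "y_only": ["b"]}


def test_pairing_rejects_duplicates():
    with pytest.raises(ValueError, match="duplicate"):
        pair_intervals([_iv("a", 1, 2), _iv("a", 3, 4)], [_iv("a", 1, 2, "y")])


def test_interval_validation():
    with pytest.raises(ValueError):
        PotencyInterval("a", "x", 0.0, 1.0)
    with pytest.raises(ValueError):
        PotencyInterval("a", "x", 2.0, 1.0)


# -- band fitting ------------------------------------------------------------


def test_band_degenerate_proportional_pairs_widened():
    """Point intervals exactly on y = 100 x collapse to offset 2 and get the
    minimum width."""
    pairs = [(_iv(f"c{i}", v, v), _iv(f"c{i}", 100 * v, 100 * v, "y"))
             for i, v in enumerate([0.1, 1.0, 10.0])]
    band = fit_band(pairs, coverage=1.0, min_width=0.1)
    assert band.intercept_lo == pytest.approx(1.95)
    assert band.intercept_hi == pytest.approx(2.05)
    assert band.coverage == 1.0


def test_band_single_pair_envelope():
    pairs = [(_iv("a", 1.0, 10.0), _iv("a", 5.0, 50.0, "y"))]
    band = fit_band(pairs, coverage=1.0)
    # envelope: lo = log10(5/10), hi = log10(50/1)
    assert band.intercept_lo == pytest.approx(math.log10(0.5))
    assert band.intercept_hi == pytest.approx(math.log10(50.0))


def test_band_quantile_fit_records_coverage():
    rng = np.random.default_rng(5)
    pairs = []
    for i in range(40):
        x = 10.0 ** rng.uniform(-2, 2)
        y = 10.0 * x * 10.0 ** rng.normal(0, 0.5)
        pairs.append((_iv(f"c{i}", x / 1.3, x * 1.3), _iv(f"c{i}", y / 1.3, y * 1.3, "y")))
    bander = UnitySlopeBand(coverage=0.95).fit(pairs)
    assert bander.band_.provenance == "fitted"
    assert bander.coverage_ >= 0.95
    assert 1.0 < bander.band_.width < 3.0


def test_band_requires_a_finite_pair():
    pairs = [(_iv("a", 1.0, math.inf), _iv("a", 1.0, 2.0, "y"))]
    with pytest.raises(ValueError):
        fit_band(pairs)


# -- prediction --------------------------------------------------------------


def test_predict_interval_worked_example():
    band = CorrelationBand(-0.5, 2.0)
    lo, hi = predict_interval(band, (1.0, 2.512))
    assert lo == pytest.approx(10**-0.5)
    assert hi == pytest.approx(251.2)


def test_predict_interval_identity_band():
    band = CorrelationBand(-0.005, 0.005)
    lo, hi = predict_interval(band, (3.0, 7.0))
    assert lo == pytest.approx(3.0, rel=0.02)
    assert hi == pytest.approx(7.0, rel=0.02)


def test_predict_interval_point_input():
    assert predict_interval(CorrelationBand(-1, 1), (10, 10)) == pytest.approx((1.0, 100.0))


def test_predict_interval_infinite_upper_propagates():
    lo, hi = predict_interval(CorrelationBand(-1, 1), (10, math.inf))
    assert lo == pytest.approx(1.0)
    assert math.isinf(hi)


def test_predict_interval_rejects_bad_input():
    with pytest.raises(ValueError):
        predict_interval(CorrelationBand(-1, 1), (0.0, 1.0))
    with pytest.raises(ValueError):
        predict_interval(CorrelationBand(-1, 1), (2.0, 1.0))


@given(lo=st.floats(min_value=1e-3, max_value=10), width=st.floats(min_value=0, max_value=100),
       grow=st.floats(min_value=1, max_value=10))
def test_predict_interval_monotone(lo, width, grow):
    """Enlarging the x interval never shrinks the predicted range."""
    band = CorrelationBand(-0.5, 2.0)
    base = predict_interval(band, (lo, lo + width))
    bigger = predict_interval(band, (lo / grow, (lo + width) * grow))
    assert bigger[0] <= base[0] + 1e-12
    assert bigger[1] >= base[1] - 1e-12


def test_band_unit_coherence():
    """Scaling x by k shifts both intercepts by -log10 k; predictions are
    unchanged in the y units."""
    rng = np.random.default_rng(11)
    pairs, scaled = [], []
    k = 37.0
    for i in range(20):
        x = 10.0 ** rng.uniform(-1, 1)
        y = 5.0 * x * 10.0 ** rng.normal(0, 0.3)
        pairs.append((_iv(f"c{i}", x / 1.2, x * 1.2), _iv(f"c{i}", y / 1.2, y * 1.2, "y")))
        scaled.append((_iv(f"c{i}", k * x / 1.2, k * x * 1.2), pairs[-1][1]))
    b1 = fit_band(pairs, coverage=0.9)
    b2 = fit_band(scaled, coverage=0.9)
    assert b2.intercept_lo == pytest.approx(b1.intercept_lo - math.log10(k), abs=1e-9)
    assert b2.intercept_hi == pytest.approx(b1.intercept_hi - math.log10(k), abs=1e-9)
    p1 = predict_interval(b1, (0.5, 2.0))
    p2 = predict_interval(b2, (0.5 * k, 2.0 * k))
    assert p2 == pytest.approx(p1, rel=1e-9)


def test_in_band_flag_matches_brute_force():
    """A rectangle is flagged inside iff some point of it lies between the
    lines (exhaustive grid check)."""
    rng = np.random.default_rng(23)
    for _ in range(200):
        lo, hi = sorted(rng.uniform(-2, 2, 2))
        if hi - lo < 1e-3:
            continue
        xl = 10.0 ** rng.uniform(-2, 2)
        xu = xl * 10.0 ** rng.uniform(0, 1.5)
        yl = 10.0 ** rng.uniform(-3, 3)
        yu = yl * 10.0 ** rng.uniform(0, 1.5)
        pair = (_iv("a", xl, xu), _iv("a", yl, yu, "y"))
        gx = np.linspace(math.log10(xl), math.log10(xu), 60)
        gy = np.linspace(math.log10(yl), math.log10(yu), 60)
        offs = gy[None, :] - gx[:, None]
        brute = bool(np.any((offs >= lo - 1e-9) & (offs <= hi + 1e-9)))
        assert _rect_intersects(pair, lo, hi) == brute


# -- margin of exposure ------------------------------------------------------


def test_moe_no_concern_when_lower_bound_far_above_exposure():
    res = margin_of_exposure(0.32, math.inf, 1e-5)
    assert res.moe_lower == pytest.approx(32_000)
    assert res.verdict == "no-concern"


def test_moe_concern_when_upper_bound_close():
    res = margin_of_exposure(0.32, 250.0, 1.0)
    assert res.moe_upper == pytest.approx(250.0)
    assert res.verdict == "concern"


def test_moe_point_equal_to_exposure_is_concern():
    res = margin_of_exposure(1.0, 1.0, 1.0)
    assert res.moe_lower == pytest.approx(1.0)
    assert res.verdict == "concern"


def test_moe_intermediate_is_inconclusive():
    # lower MOE 320 below the threshold, upper MOE 2.5e7 above it
    assert margin_of_exposure(0.32, 250.0, 1e-3).verdict == "inconclusive"


def test_moe_rejects_nonpositive():
    with pytest.raises(ValueError):
        margin_of_exposure(0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        margin_of_exposure(1.0, 2.0, 0.0)


def test_finite_bound_box():
    ivs = [_iv("a", 0.5, 3.0), _iv("b", 1.0, math.inf), _iv("c", 2.0, 9.0)]
    assert finite_bound_box(ivs) == (0.5, 9.0)
    with pytest.raises(ValueError):
        finite_bound_box([_iv("a", 1.0, math.inf)])
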