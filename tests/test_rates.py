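"""Slope-based rate estimators against closed-form oracles."""

import numpy as np
import pytest

import asmbatch as ab
from asmbatch.rates import (
    MeasurementSeries,
    RateWarning,
    fit_rate,
    max_window_rate,
    nur_window,
    p_per_n_ratio,
    release_per_cod_ratio,
    removal_efficiency,
)


def _series(t, v, vss=3.0, phase="anaerobic", variable="PO4"):
    return MeasurementSeries(np.asarray(t, float), np.asarray(v, float),
                             vss, phase, variable)


def test_linear_release_matches_two_point_slope_oracle():
    """PO4 rising 6 mg/L/h with X = 3 gVSS/L gives exactly 2 mgP/gVSS/h."""
    s = _series([0, 0.5, 1.0, 1.5], [10, 13, 16, 19])
    res = fit_rate(s)
    oracle = (19 - 10) / (1.5 - 0.0) / 3.0
    assert res.rate == pytest.approx(oracle)      # = 2.0
    assert res.direction == "release"
    assert res.r2 == pytest.approx(1.0)


def test_constant_series_has_zero_rate():
    res = fit_rate(_series([0, 1, 2, 3], [5, 5, 5, 5]))
    assert res.rate == 0.0


def test_time_origin_shift_invariance():
    t = np.array([0, 0.25, 0.5, 0.75, 1.0])
    v = np.array([1.0, 2.2, 2.9, 4.1, 5.0])
    r0 = fit_rate(_series(t, v)).rate
    r1 = fit_rate(_series(t + 7.3, v)).rate
    assert r1 == pytest.approx(r0)


def test_vss_rescaling_equivariance():
    t, v = [0, 0.5, 1.0, 1.5], [10, 13, 16, 19]
    assert fit_rate(_series(t, v, vss=6.0)).rate == pytest.approx(
        fit_rate(_series(t, v, vss=3.0)).rate / 2.0
    )


def test_inconsistent_sign_is_flagged_but_returned():
    s = _series([0, 1, 2, 3], [10, 8, 6, 4], phase="anaerobic")  # P falling
    with pytest.warns(RateWarning):
        res = fit_rate(s)
    assert not res.sign_consistent
    assert res.rate == pytest.approx(2.0 / 3.0)


def test_needs_three_points():
    with pytest.raises(ValueError, match=">= 3 points"):
        fit_rate(_series([0, 1, 2, 3], [1, 2, 3, 4]), window=(0, 1))


def test_max_window_on_linear_series_equals_global_fit():
    s = _series(np.linspace(0, 2.5, 11), np.linspace(5, 30, 11))
    assert max_window_rate(s, 0.75).rate == pytest.approx(fit_rate(s).rate)


def test_max_window_finds_the_fast_early_segment():
    """Piecewise fast-then-slow release: slopes 8 then 1 mg/L/h."""
    t = np.arange(0, 2.51, 0.25)
    v = np.where(t <= 1.0, 10 + 8 * t, 18 + 1 * (t - 1.0))
    res = max_window_rate(_series(t, v), 0.75)
    assert res.window[0] == pytest.approx(0.0, abs=0.26)
    assert res.rate == pytest.approx(8.0 / 3.0, rel=0.01)
    assert max_window_rate(_series(t, v), 0.75).rate >= fit_rate(_series(t, v)).rate


def test_removal_efficiency_bounds():
    assert removal_efficiency(_series([0, 1, 2], [40, 30, 40], variable="COD",
                                      phase="anoxic")) == 0.0
    assert removal_efficiency(_series([0, 1, 2], [40, 20, 0], variable="COD",
                                      phase="anoxic")) == 100.0
    with pytest.raises(ZeroDivisionError):
        removal_efficiency(_series([0, 1, 2], [0, 0, 0], variable="COD",
                                   phase="anoxic"))


def test_release_per_cod_ratio_arithmetic():
    p = _series([0, 1, 2], [5, 15, 25])                       # dP = 20
    cod = _series([0, 1, 2], [100, 75, 50], variable="COD")   # dCOD = 50
    assert release_per_cod_ratio(p, cod) == pytest.approx(0.4)
    flat = _series([0, 1, 2], [5, 5, 5])
    assert release_per_cod_ratio(flat, cod) == 0.0


def test_p_per_n_ratio_and_degenerate_inputs():
    p = _series([2.5, 5, 7.5], [30, 20, 10], phase="anoxic")
    n = _series([2.5, 5, 7.5], [19, 10, 3], phase="anoxic", variable="NO3")
    assert p_per_n_ratio(p, n) == pytest.approx(20 / 16)
    with pytest.raises(ZeroDivisionError):
        p_per_n_ratio(p, _series([2.5, 5, 7.5], [3, 3, 3], phase="anoxic",
                                 variable="NO3"))
    flat_p = _series([2.5, 5, 7.5], [10, 10, 10], phase="anoxic")
    assert p_per_n_ratio(flat_p, n) == 0.0


def test_nur_window_truncates_at_depletion():
    t = np.arange(2.5, 7.51, 0.25)
    v = np.maximum(19 - 6 * (t - 2.5), 0.2)
    s = _series(t, v, phase="anoxic", variable="NO3")
    lo, hi = nur_window(s)
    assert lo == pytest.approx(2.5)
    assert hi < 6.0   # nitrate < 1 mgN/L well before the phase end


def test_trajectory_rates_windows_cover_the_phases(all_trajectories):
    rates = ab.trajectory_rates(all_trajectories[6])
    lo, hi = rates["PRR_window"]
    assert 0.0 <= lo and hi <= 2.5
    lo, hi = rates["NUR_window"]
    assert 2.5 <= lo < hi <= 7.5
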