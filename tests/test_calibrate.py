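"""Calibration objective, fitting, and goodness-of-fit statistics."""

import warnings

import numpy as np
import pandas as pd
import pytest

import asmbatch as ab
from asmbatch.calibrate import ObservedRates, objective, r_squared, regression_r2
from asmbatch.scenarios import preset_scenario


@pytest.fixture(scope="module")
def test6_setup():
    sc = preset_scenario(6)
    kin, sto = ab.load_profile(sc.profile)
    return [(sc, kin, sto)]


@pytest.fixture(scope="module")
def self_consistent_observed(test6_setup, request):
    """Observed table generated by the model itself (exact predictions)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        predicted = ab.predict_rates(test6_setup)
    rows = [
        {"test": 6, "parameter": k, "value": float(predicted[k].iloc[0]),
         "sd": max(0.05 * float(predicted[k].iloc[0]), 1e-3)}
        for k in ("PRR", "PUR", "NUR")
    ]
    return ObservedRates(pd.DataFrame(rows))


def test_objective_zero_iff_predictions_match(test6_setup, self_consistent_observed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = objective({}, self_consistent_observed, test6_setup)
    assert val == pytest.approx(0.0, abs=1e-12)


def test_one_sd_residual_contributes_one(test6_setup, self_consistent_observed):
    frame = self_consistent_observed.frame.copy()
    keep = frame["parameter"] == "NUR"
    frame.loc[keep, "value"] += frame.loc[keep, "sd"]
    shifted = ObservedRates(frame[keep])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = objective({}, shifted, test6_setup)
    assert val == pytest.approx(1.0, rel=1e-6)


def test_degenerate_bounds_force_the_parameter(test6_setup, self_consistent_observed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ab.fit_params(["q_PHA"], {"q_PHA": (2.0, 2.0)},
                            self_consistent_observed, test6_setup,
                            seed=0, n_starts=1)
    assert fit.params["q_PHA"] == pytest.approx(2.0)
    assert fit.bounds_hit["q_PHA"]


def test_observed_table_validation():
    with pytest.raises(ValueError):
        ObservedRates(pd.DataFrame({"test": [1], "parameter": ["NUR"],
                                    "value": [-1.0], "sd": [0.1]}))
    with pytest.raises(ValueError):
        ObservedRates(pd.DataFrame({"test": [1], "value": [1.0]}))


def test_r_squared_closed_forms():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    assert r_squared(obs, obs) == pytest.approx(1.0)
    assert r_squared(np.full(4, obs.mean()), obs) == pytest.approx(0.0)
    with pytest.raises(ZeroDivisionError):
        r_squared(obs, np.full(4, 2.0))
    with pytest.raises(ValueError):
        r_squared(obs[:2], obs[:2])


def test_regression_r2_is_scale_invariant():
    obs = np.array([0.5, 2.6, 0.6, 2.1])
    assert regression_r2(1.3 * obs, obs) == pytest.approx(1.0)
    assert regression_r2(obs + 0.4, obs) == pytest.approx(1.0)


def test_profile_mismatch_shows_in_release_residuals(observed_table):
    """Evaluating the non-acclimated profile on the acclimated tests is
    dominated by the huge release-rate misfit (q_PHA 2.7 vs 7)."""
    sc6 = preset_scenario(6)
    kin_na, sto_na = ab.load_profile("non_acclimated")
    observed = ObservedRates(observed_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wrong = objective({}, observed, [(sc6, kin_na, sto_na)],
                          rate_types=("PRR",))
        right = objective({}, observed,
                          [(sc6, *ab.load_profile("acclimated"))],
                          rate_types=("PRR",))
    assert wrong > 10 * right
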