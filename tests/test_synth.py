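"""Preset scenarios, synthetic measurement noise, and recovery."""

import warnings

import numpy as np
import pytest

import asmbatch as ab
from asmbatch.batch import DoseEvent, PrecipEvent, SpikeEvent
from asmbatch.scenarios import Scenario, preset_scenario
from asmbatch.synth import (
    NoiseModel,
    recovery_experiment,
    sample_measurements,
)


def _events_of(scenario, kind):
    return [e for e in scenario.protocol.events if isinstance(e, kind)]


def test_preset_test2_matches_the_dosing_table():
    sc = preset_scenario(2)
    doses = _events_of(sc, DoseEvent)
    assert len(doses) == 2
    ana, anox = sorted(doses, key=lambda e: e.time_h)
    assert (ana.source, ana.volume_mL, ana.time_h) == ("acetate", 0.46, 0.0)
    assert (anox.source, anox.volume_mL, anox.time_h) == ("fusel", 0.25, 2.5)
    assert not _events_of(sc, PrecipEvent)
    assert _events_of(sc, SpikeEvent)[0].delta_NO3 == 19.0
    assert sc.profile == "non_acclimated"


def test_preset_test7_has_precipitation_and_the_large_spike():
    sc = preset_scenario(7)
    assert [e.source for e in _events_of(sc, DoseEvent)] == ["fusel", "fusel"]
    precip = _events_of(sc, PrecipEvent)
    assert len(precip) == 1 and precip[0].time_h == 2.5
    assert _events_of(sc, SpikeEvent)[0].delta_NO3 == 48.0
    assert sc.profile == "acclimated"
    # precipitation is applied to the anaerobic supernatant, before the
    # fresh dose and the nitrate spike
    ordered = sc.protocol.sorted_events()
    at_25 = [type(e).__name__ for e in ordered if e.time_h == 2.5]
    assert at_25[0] == "PrecipEvent"


def test_unknown_test_id_rejected():
    with pytest.raises(KeyError):
        preset_scenario(0)


def test_scenario_round_trip(tmp_path):
    from asmbatch.scenarios import load_scenario, save_scenario

    sc = preset_scenario(4)
    assert Scenario.from_flat_dict(sc.to_flat_dict()) == sc
    save_scenario(sc, tmp_path / "t4.yaml")
    assert load_scenario(tmp_path / "t4.yaml") == sc


def test_sampling_is_deterministic_and_truncated(all_trajectories):
    noise = NoiseModel(seed=42)
    a = sample_measurements(all_trajectories[3], noise)
    b = sample_measurements(all_trajectories[3], noise)
    assert a.equals(b)
    assert (a["value"] >= 0).all()
    c = sample_measurements(all_trajectories[3], NoiseModel(seed=43))
    assert not a.equals(c)


def test_zero_noise_reproduces_the_trajectory(all_trajectories):
    traj = all_trajectories[1]
    table = sample_measurements(traj, NoiseModel(sd={"NO3": 0.0}))
    sampled = table[np.isclose(table["time_h"], 5.0)]["value"].iloc[0]
    from asmbatch.components import IDX
    i = np.where(np.isclose(traj.times, 5.0))[0][-1]
    assert sampled == pytest.approx(traj.states[i, IDX["S_NO3"]])


def test_empirical_noise_sd_matches_nominal(all_trajectories):
    """1000 seeded draws of one sample point scatter with the nominal SD."""
    traj = all_trajectories[1]
    draws = []
    for seed in range(1000):
        t = sample_measurements(traj, NoiseModel(sd={"PO4": 0.3}, seed=seed))
        draws.append(t[np.isclose(t["time_h"], 1.0)]["value"].iloc[0])
    assert np.std(draws) == pytest.approx(0.3, rel=0.05)


def test_recovery_rejects_zero_reps():
    with pytest.raises(ValueError):
        recovery_experiment({"q_PHA": 7.0}, n_reps=0)


def test_noise_model_validation():
    with pytest.raises(ValueError):
        NoiseModel(sd={"PO4": -0.1})
    with pytest.raises(ValueError):
        NoiseModel(interval_min=0.0)


def test_noiseless_recovery_is_nearly_exact():
    """With no measurement noise the storage-rate constant is recovered
    to well within 2%."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df = recovery_experiment(
            {"q_PHA": 7.0},
            NoiseModel(sd={"PO4": 0.0, "NO3": 0.0, "COD": 0.0},
                       interval_min=5.0),
            n_reps=1, seed=0,
        )
    assert abs(df["rel_error"].iloc[0]) < 0.02
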