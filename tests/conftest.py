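import warnings

import numpy as np
import pytest

import asmbatch as ab


@pytest.fixture(scope="session")
def stoich():
    return ab.StoichParams()


@pytest.fixture(scope="session")
def matrix(stoich):
    return ab.build_matrix(stoich)


@pytest.fixture(scope="session")
def na_params():
    return ab.load_profile("non_acclimated")


@pytest.fixture(scope="session")
def a_params():
    return ab.load_profile("acclimated")


def _simulate(test_id, **kwargs):
    sc = ab.preset_scenario(test_id)
    kin, sto = ab.load_profile(sc.profile)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ab.simulate_protocol(sc.ic, sc.protocol, kin, sto, **kwargs)


@pytest.fixture(scope="session")
def all_trajectories():
    """One simulation per preset test, shared across the suite."""
    return {tid: _simulate(tid) for tid in range(1, 8)}


@pytest.fixture(scope="session")
def all_rates(all_trajectories):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            tid: ab.trajectory_rates(traj)
            for tid, traj in all_trajectories.items()
        }


@pytest.fixture(scope="session")
def flux_breakdowns(all_trajectories):
    return {
        tid: ab.flux_attribution(traj)
        for tid, traj in all_trajectories.items()
    }


@pytest.fixture(scope="session")
def diff_breakdowns():
    out = {}
    for tid in range(1, 8):
        sc = ab.preset_scenario(tid)
        kin, sto = ab.load_profile(sc.profile)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[tid] = ab.difference_attribution(sc.protocol, sc.ic, kin, sto)
    return out


@pytest.fixture(scope="session")
def observed_table():
    return ab.observed_rates()
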