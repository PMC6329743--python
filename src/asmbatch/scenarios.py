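"""Preset scenarios of the seven anaerobic/anoxic batch tests.

Each scenario bundles the dosing protocol and the measured mixed-liquor
initial conditions of one test:

==== ========== ============= ==================== =====================
test biomass    anaerobic     anoxic dose          phosphate
     profile    dose                               precipitation
==== ========== ============= ==================== =====================
1    na         none          none                 no
2    na         acetate 0.46  fusel 0.25           no
3    na         fusel 0.17    fusel 0.19           no
4    na         acetate 0.46  fusel 0.25           yes (2.5 mL PIX)
5    na         fusel 0.17    fusel 0.17           yes
6    a          fusel 0.25    fusel 0.25           no
7    a          fusel 0.25    fusel 0.25           yes
==== ========== ============= ==================== =====================

Volumes in mL; tests 1-5 use non-acclimated (na) biomass and a nitrate
spike of +19 mgN/L at the start of the anoxic phase, tests 6-7 use
fusel-acclimated (a) biomass and +48 mgN/L.  Fusel doses printed as a
range use the midpoint.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import pandas as pd

from .batch import DoseEvent, InitialConditions, PrecipEvent, Protocol, SpikeEvent

#: stock-solution COD strengths, mgO2/L
FUSEL_COD = 1_690_000.0
ACETATE_COD = 913_000.0

#: default precipitation efficiency of the ferric-chloride treatment
PIX_EFFICIENCY = 0.90

ANAEROBIC_END_H = 2.5
TEST_IDS = (1, 2, 3, 4, 5, 6, 7)

_LABELS = {
    1: "RT (na)", 2: "A-FO (na)", 3: "FO-FO (na)", 4: "A-FO/PIX (na)",
    5: "FO-FO/PIX (na)", 6: "FO-FO (a)", 7: "FO-FO/PIX (a)",
}

# measured initial conditions: COD, TP, NO3-N, NO2-N, MLSS, pH
_INITIALS = {
    1: (47.0, 9.1, 0.3, 0.08, 2829.0, 7.0),
    2: (35.0, 7.5, 0.2, 0.02, 3117.0, 7.1),
    3: (35.0, 6.9, 0.4, 0.03, 3010.0, 7.3),
    4: (37.0, 9.4, 0.3, 0.02, 3335.0, 7.2),
    5: (38.0, 8.3, 0.3, 0.03, 2929.0, 6.9),
    6: (40.0, 4.2, 0.5, 0.01, 3128.0, 7.3),
    7: (41.0, 2.5, 0.4, 0.03, 3208.0, 7.2),
}

# (anaerobic dose, anoxic dose, PIX) with dose = (source, mL) or None
_DOSES = {
    1: (None, None, False),
    2: (("acetate", 0.46), ("fusel", 0.25), False),
    3: (("fusel", 0.17), ("fusel", 0.19), False),
    4: (("acetate", 0.46), ("fusel", 0.25), True),
    5: (("fusel", 0.17), ("fusel", 0.17), True),
    6: (("fusel", 0.25), ("fusel", 0.25), False),
    7: (("fusel", 0.25), ("fusel", 0.25), True),
}

_SPIKES = {1: 19.0, 2: 19.0, 3: 19.0, 4: 19.0, 5: 19.0, 6: 48.0, 7: 48.0}

_STOCKS = {"acetate": ACETATE_COD, "fusel": FUSEL_COD}


@dataclass(frozen=True)
class Scenario:
    """One batch test: id, acclimation profile, protocol and initials."""

    test_id: int
    label: str
    profile: str                  # non_acclimated / acclimated
    protocol: Protocol
    ic: InitialConditions

    def to_flat_dict(self) -> dict:
        """Serializable representation (round-trips via from_flat_dict)."""
        events = []
        for ev in self.protocol.events:
            d = asdict(ev)
            d["kind"] = type(ev).__name__
            events.append(d)
        return {
            "test_id": self.test_id,
            "label": self.label,
            "profile": self.profile,
            "phases": [list(p) for p in self.protocol.phases],
            "volume_L": self.protocol.volume_L,
            "fusel_rb_fraction": self.protocol.fusel_rb_fraction,
            "events": events,
            "initial_conditions": asdict(self.ic),
        }

    @classmethod
    def from_flat_dict(cls, d: dict) -> "Scenario":
        kinds = {"DoseEvent": DoseEvent, "SpikeEvent": SpikeEvent,
                 "PrecipEvent": PrecipEvent}
        events = []
        for ev in d["events"]:
            ev = dict(ev)
            events.append(kinds[ev.pop("kind")](**ev))
        protocol = Protocol(
            phases=tuple((n, float(t)) for n, t in d["phases"]),
            events=tuple(events),
            volume_L=d["volume_L"],
            fusel_rb_fraction=d["fusel_rb_fraction"],
        )
        return cls(
            test_id=d["test_id"],
            label=d["label"],
            profile=d["profile"],
            protocol=protocol,
            ic=InitialConditions(**d["initial_conditions"]),
        )


def preset_scenario(
    test_id: int,
    pix_efficiency: float = PIX_EFFICIENCY,
    x_pp0_frac: float = 0.10,
) -> Scenario:
    """Build the full scenario of one of the seven tests.

    ``x_pp0_frac`` sets the initial polyphosphate reserve as a fraction
    of the PAO biomass (sludge from an operating EBPR plant holds a
    polyphosphate pool that fuels the anaerobic release).
    """
    if test_id not in TEST_IDS:
        raise KeyError(f"unknown test id {test_id!r}; expected 1-7")
    cod0, tp0, no3_0, no2_0, mlss, ph = _INITIALS[test_id]
    profile = "acclimated" if test_id >= 6 else "non_acclimated"

    ana, anox, pix = _DOSES[test_id]
    events: list = []
    if ana is not None:
        source, vol = ana
        events.append(DoseEvent(0.0, source, vol, _STOCKS[source]))
    if pix:
        events.append(PrecipEvent(ANAEROBIC_END_H, pix_efficiency))
    if anox is not None:
        source, vol = anox
        events.append(DoseEvent(ANAEROBIC_END_H, source, vol, _STOCKS[source]))
    events.append(SpikeEvent(ANAEROBIC_END_H, _SPIKES[test_id]))

    ic = InitialConditions(
        cod0=cod0, tp0=tp0, no3_0=no3_0, no2_0=no2_0, mlss=mlss, ph=ph,
        x_pp0_frac=x_pp0_frac,
    )
    return Scenario(
        test_id=test_id,
        label=_LABELS[test_id],
        profile=profile,
        protocol=Protocol(events=tuple(events)),
        ic=ic,
    )


def save_scenario(scenario: Scenario, path) -> None:
    """Write a scenario (protocol + initial conditions) as YAML."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_flat_dict(), fh, sort_keys=True)


def load_scenario(path) -> Scenario:
    """Read a scenario written by :func:`save_scenario`."""
    import yaml

    with open(path) as fh:
        return Scenario.from_flat_dict(yaml.safe_load(fh))


def total_dosed_cod(scenario: Scenario) -> float:
    """COD added by all dose events, mgCOD per litre of reactor volume."""
    return sum(
        ev.added_cod / scenario.protocol.volume_L
        for ev in scenario.protocol.events
        if isinstance(ev, DoseEvent)
    )


def observed_rates() -> pd.DataFrame:
    """Measured batch-test summary rates (long form: test, parameter,
    value, sd), the calibration/validation surface."""
    from importlib import resources

    ref = resources.files("asmbatch.data").joinpath("observed_rates.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)
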