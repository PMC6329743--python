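"""Kinetic and stoichiometric parameter sets.

Defaults follow the published ASM2d parameter set at 20 degC (Henze et
al., Activated Sludge Models ASM1, ASM2, ASM2d and ASM3, IWA 2000),
extended with constants for the external readily biodegradable substrate
``S_A1`` (fusel-oil COD): a fermentation rate ``q_fe_A1`` turning S_A1
into acetate under anaerobic conditions, a heterotrophic growth rate
``mu_H_A1`` on S_A1, a PAO storage rate ``q_PHA_A1`` for S_A1 gated on
electron-acceptor presence, and a half-saturation constant ``K_A1``.

Two bundled acclimation profiles override selected constants:

* ``non_acclimated`` -- storage rate constants q_PHA = 2.7 1/d and
  q_PP = 2.0 1/d, slow fusel turnover (biomass never exposed to fusel).
* ``acclimated`` -- q_PHA = 7 1/d and fast fusel fermentation/uptake,
  representing sludge conditioned to fusel oil for ~50 days.

All rates are per day internally; the batch interface works in hours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import yaml

PROFILES = ("non_acclimated", "acclimated")

_PROFILE_ALIASES = {
    "na": "non_acclimated",
    "non_acclimated": "non_acclimated",
    "a": "acclimated",
    "acclimated": "acclimated",
}


@dataclass
class StoichParams:
    """Yields, inert fractions and elemental composition factors."""

    # yields (gCOD/gCOD unless noted)
    Y_H: float = 0.625          # heterotrophic yield
    Y_PAO: float = 0.625        # PAO yield on PHA
    Y_A: float = 0.24           # autotrophic yield, gCOD/gN
    Y_PO4: float = 0.40         # gP released per gCOD PHA stored
    Y_PHA: float = 0.20         # gCOD PHA required per gP polyphosphate stored
    # inert fractions
    f_SI: float = 0.0           # soluble inert from hydrolysis
    f_XI: float = 0.10          # particulate inert from biomass lysis
    # nitrogen content, gN/gCOD
    i_N_SF: float = 0.03
    i_N_SI: float = 0.01
    i_N_XS: float = 0.04
    i_N_XI: float = 0.02
    i_N_BM: float = 0.07
    # phosphorus content, gP/gCOD
    i_P_SF: float = 0.01
    i_P_SI: float = 0.0
    i_P_XS: float = 0.01
    i_P_XI: float = 0.01
    i_P_BM: float = 0.02
    # TSS conversion, gTSS/g component
    i_TSS_XI: float = 0.75
    i_TSS_XS: float = 0.75
    i_TSS_BM: float = 0.90
    i_TSS_PP: float = 3.23
    i_TSS_PHA: float = 0.60

    def validate(self) -> None:
        for name in ("Y_H", "Y_PAO", "Y_A", "Y_PO4", "Y_PHA"):
            y = getattr(self, name)
            if not 0.0 < y < 1.6:
                raise ValueError(f"yield {name}={y} outside (0, 1.6)")
        for f in dataclasses.fields(self):
            if f.name.startswith("i_") and getattr(self, f.name) < 0:
                raise ValueError(f"composition factor {f.name} negative")
        if not 0.0 <= self.f_SI < 1.0 or not 0.0 <= self.f_XI < 1.0:
            raise ValueError("inert fractions must lie in [0, 1)")


@dataclass
class KineticParams:
    """Maximum rates (1/d) and half-saturation constants (mg/L)."""

    # hydrolysis
    K_h: float = 3.0
    eta_NO3_hyd: float = 0.6
    eta_fe_hyd: float = 0.40
    K_O2: float = 0.2
    K_NO3: float = 0.5
    K_X: float = 0.1            # gCOD_XS/gCOD_XH
    # ordinary heterotrophs
    mu_H: float = 6.0
    q_fe: float = 3.0
    b_H: float = 0.4
    eta_NO3_H: float = 0.8
    K_F: float = 4.0
    K_fe: float = 4.0
    K_A: float = 4.0
    K_NH4: float = 0.05
    K_P: float = 0.01
    # phosphorus accumulating organisms
    q_PHA: float = 3.0
    q_PP: float = 1.5
    mu_PAO: float = 1.0
    eta_NO3_PAO: float = 0.6
    b_PAO: float = 0.2
    b_PP: float = 0.2
    b_PHA: float = 0.2
    K_PS: float = 0.2           # phosphate half-saturation for PP storage
    K_PP: float = 0.01          # gPP/gPAO, for PHA storage
    K_MAX: float = 0.34         # maximum PP/PAO ratio
    K_IPP: float = 0.02         # inhibition range of the PP ceiling
    K_PHA: float = 0.01         # gPHA/gPAO
    # autotrophs
    mu_AUT: float = 1.0
    b_AUT: float = 0.15
    K_O2_AUT: float = 0.5
    K_NH4_AUT: float = 1.0
    # extension: external readily biodegradable substrate S_A1
    K_A1: float = 4.0
    q_fe_A1: float = 3.0        # anaerobic fermentation of S_A1 to S_A
    mu_H_A1: float = 1.0        # heterotrophic growth on S_A1
    q_PHA_A1: float = 0.0       # PAO storage from S_A1 (needs O2 or NO3)
    acclimation_profile: str = "default"

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "acclimation_profile":
                continue
            v = getattr(self, f.name)
            # extension/reduction factors may be zero (pathway absent or
            # deliberately disabled in a counterfactual run); proper rate
            # and half-saturation constants must be strictly positive
            if f.name == "q_PHA_A1" or f.name.startswith("eta_"):
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0")
                continue
            if v <= 0:
                raise ValueError(f"kinetic constant {f.name}={v} must be > 0")


def _flat_dict(kin: KineticParams, stoich: StoichParams) -> dict[str, float | str]:
    out: dict[str, float | str] = {}
    for obj in (kin, stoich):
        for f in dataclasses.fields(obj):
            out[f.name] = getattr(obj, f.name)
    return out


def save_profile(path, kin: KineticParams, stoich: StoichParams) -> None:
    """Serialize a parameter profile as a flat key-value YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(_flat_dict(kin, stoich), fh, sort_keys=True)


def _split_flat(flat: dict) -> tuple[KineticParams, StoichParams]:
    kin_names = {f.name for f in dataclasses.fields(KineticParams)}
    sto_names = {f.name for f in dataclasses.fields(StoichParams)}
    kin_kwargs, sto_kwargs = {}, {}
    for key, value in flat.items():
        if key in kin_names:
            kin_kwargs[key] = value
        elif key in sto_names:
            sto_kwargs[key] = value
        else:
            raise KeyError(f"unknown parameter {key!r} in profile")
    kin = KineticParams(**kin_kwargs)
    sto = StoichParams(**sto_kwargs)
    kin.validate()
    sto.validate()
    return kin, sto


def read_profile(path) -> tuple[KineticParams, StoichParams]:
    """Read a flat key-value YAML parameter profile."""
    with open(path) as fh:
        flat = yaml.safe_load(fh) or {}
    return _split_flat(flat)


def load_profile(name: str) -> tuple[KineticParams, StoichParams]:
    """Load a bundled acclimation profile (``non_acclimated``/``acclimated``).

    Short aliases ``na`` and ``a`` are accepted.
    """
    canonical = _PROFILE_ALIASES.get(name)
    if canonical is None:
        raise KeyError(f"unknown profile {name!r}; expected one of {PROFILES}")
    ref = resources.files("asmbatch.profiles").joinpath(f"{canonical}.yaml")
    flat = yaml.safe_load(ref.read_text())
    kin, sto = _split_flat(flat)
    kin.acclimation_profile = canonical
    return kin, sto


def iter_fields(obj) -> Iterator[str]:
    for f in dataclasses.fields(obj):
        yield f.name


def with_updates(params, **updates):
    """Return a copy of a parameter dataclass with fields replaced."""
    return dataclasses.replace(params, **updates)
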