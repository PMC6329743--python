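"""Model state vector: the 17 soluble and particulate components.

Concentrations are mg/L throughout (COD for organics, N for nitrogen
species, P for phosphorus species, TSS as dry solids).  ``S_A1`` is the
external readily biodegradable substrate introduced for fusel oil: COD
that ordinary heterotrophs can ferment or oxidise but that phosphorus
accumulating organisms (PAOs) cannot store anaerobically.
"""

from __future__ import annotations

import numpy as np

#: canonical component ordering (columns of the Gujer matrix)
COMPONENTS: tuple[str, ...] = (
    "S_O2",   # dissolved oxygen, mgO2/L (negative COD)
    "S_F",    # fermentable readily biodegradable substrate, mgCOD/L
    "S_A",    # fermentation products / acetate, mgCOD/L
    "S_A1",   # external readily biodegradable substrate (fusel-derived), mgCOD/L
    "S_I",    # inert soluble organics, mgCOD/L
    "S_NH4",  # ammonium, mgN/L
    "S_NO3",  # nitrate + nitrite (lumped), mgN/L
    "S_N2",   # dinitrogen produced by denitrification, mgN/L
    "S_PO4",  # orthophosphate, mgP/L
    "X_I",    # inert particulate organics, mgCOD/L
    "X_S",    # slowly biodegradable substrate, mgCOD/L
    "X_H",    # ordinary heterotrophic organisms (OHO), mgCOD/L
    "X_PAO",  # phosphorus accumulating organisms, mgCOD/L
    "X_PP",   # stored polyphosphate, mgP/L
    "X_PHA",  # stored poly-hydroxy-alkanoates, mgCOD/L
    "X_AUT",  # autotrophic nitrifiers, mgCOD/L
    "X_TSS",  # total suspended solids, mg/L (bookkeeping only)
)

IDX: dict[str, int] = {name: i for i, name in enumerate(COMPONENTS)}
N_COMPONENTS = len(COMPONENTS)

#: components that carry COD with weight 1 in the conservation check
ORGANIC_COMPONENTS = (
    "S_F", "S_A", "S_A1", "S_I", "X_I", "X_S", "X_H", "X_PAO", "X_PHA", "X_AUT",
)

# Electron-acceptor oxygen equivalents (g COD per g N).  Reduction of
# nitrate to dinitrogen accepts 64/14 - 24/14 = 40/14 = 2.857 gCOD/gN.
COD_PER_NO3N = 64.0 / 14.0
COD_PER_N2N = 24.0 / 14.0
DENIT_COD_PER_N = COD_PER_NO3N - COD_PER_N2N  # 2.857...


def make_state(**values: float) -> np.ndarray:
    """Build a state vector from keyword component concentrations.

    Unspecified components default to zero.
    """
    state = np.zeros(N_COMPONENTS)
    for name, value in values.items():
        if name not in IDX:
            raise KeyError(f"unknown component {name!r}")
        state[IDX[name]] = float(value)
    return state


def as_dict(state: np.ndarray) -> dict[str, float]:
    """Return a component-name -> concentration mapping."""
    return {name: float(state[i]) for i, name in enumerate(COMPONENTS)}
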