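"""Gujer matrix of the extended activated-sludge model.

Each biological process is one row of stoichiometric coefficients over
the 17 components.  Rows are built from the mechanistic coefficients
(substrate, product, biomass, storage polymers) and then *closed* on the
three conservation laws:

* COD -- the electron balance.  Organic components carry weight +1,
  dissolved oxygen -1, nitrate-N -64/14 and dinitrogen-N -24/14, so that
  denitrification of 1 gN accepts 40/14 = 2.86 gCOD.  The electron
  acceptor coefficient (S_O2 under aerobic regimes, the S_NO3/S_N2 pair
  under anoxic regimes) is computed from the closure.
* Nitrogen -- closed through S_NH4 using the i_N composition factors.
* Phosphorus -- closed through S_PO4 using the i_P factors; polyphosphate
  carries weight 1, which makes the P release/uptake coupled to storage
  fall out of the closure (e.g. PHA storage releases Y_PO4 gP per gCOD).

X_TSS is bookkeeping (weighted sum of particulates), not conserved.

Beyond standard ASM2d, the matrix carries four extension processes for
the fusel-oil substrate S_A1: aerobic and anoxic heterotrophic growth,
anaerobic fermentation of S_A1 to acetate, and PAO storage of S_A1 as
PHA, which is only active in the presence of an electron acceptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .components import (
    COD_PER_N2N,
    COD_PER_NO3N,
    DENIT_COD_PER_N,
    COMPONENTS,
    IDX,
    N_COMPONENTS,
    ORGANIC_COMPONENTS,
)
from .parameters import StoichParams

CONTINUITY_TOL = 1e-8

#: process category tags (used by the attribution module)
CATEGORIES = (
    "hydrolysis", "fermentation", "OHO_aerobic", "OHO_anoxic",
    "PAO_storage_anaerobic", "PAO_storage_exogenous", "PAO_PP_storage",
    "PAO_growth", "lysis", "autotroph",
)


def conservation_weights(stoich: StoichParams) -> dict[str, np.ndarray]:
    """Per-component weights of the COD, N and P conservation laws."""
    cod = np.zeros(N_COMPONENTS)
    for name in ORGANIC_COMPONENTS:
        cod[IDX[name]] = 1.0
    cod[IDX["S_O2"]] = -1.0
    cod[IDX["S_NO3"]] = -COD_PER_NO3N
    cod[IDX["S_N2"]] = -COD_PER_N2N

    nw = np.zeros(N_COMPONENTS)
    nw[IDX["S_NH4"]] = 1.0
    nw[IDX["S_NO3"]] = 1.0
    nw[IDX["S_N2"]] = 1.0
    nw[IDX["S_F"]] = stoich.i_N_SF
    nw[IDX["S_I"]] = stoich.i_N_SI
    nw[IDX["X_S"]] = stoich.i_N_XS
    nw[IDX["X_I"]] = stoich.i_N_XI
    for name in ("X_H", "X_PAO", "X_AUT"):
        nw[IDX[name]] = stoich.i_N_BM

    pw = np.zeros(N_COMPONENTS)
    pw[IDX["S_PO4"]] = 1.0
    pw[IDX["X_PP"]] = 1.0
    pw[IDX["S_F"]] = stoich.i_P_SF
    pw[IDX["S_I"]] = stoich.i_P_SI
    pw[IDX["X_S"]] = stoich.i_P_XS
    pw[IDX["X_I"]] = stoich.i_P_XI
    for name in ("X_H", "X_PAO", "X_AUT"):
        pw[IDX[name]] = stoich.i_P_BM
    return {"COD": cod, "N": nw, "P": pw}


@dataclass
class GujerMatrix:
    """Stoichiometric matrix with per-process tags."""

    process_names: list[str]
    categories: list[str]
    substrates: list[str]            # S_F / S_A / S_A1 / X_S / PHA / none
    coefficients: np.ndarray         # (n_processes, 17)
    stoich: StoichParams
    weights: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_processes(self) -> int:
        return len(self.process_names)

    def index(self, name: str) -> int:
        return self.process_names.index(name)

    def row(self, name: str) -> np.ndarray:
        return self.coefficients[self.index(name)]

    def coefficient(self, process: str, component: str) -> float:
        return float(self.coefficients[self.index(process), IDX[component]])

    @property
    def nitrate_sink_processes(self) -> list[str]:
        """Processes that consume nitrate (negative S_NO3 coefficient)."""
        j = IDX["S_NO3"]
        return [
            name
            for name, row in zip(self.process_names, self.coefficients)
            if row[j] < -CONTINUITY_TOL
        ]


def _close_row(
    nu: np.ndarray,
    regime: str,
    weights: dict[str, np.ndarray],
    stoich: StoichParams,
) -> None:
    """Fill electron acceptor, S_NH4, S_PO4 and X_TSS coefficients in place."""
    cod = weights["COD"]
    if regime == "aerobic":
        nu[IDX["S_O2"]] = 0.0
        nu[IDX["S_O2"]] = float(nu @ cod)  # weight of S_O2 is -1
    elif regime == "anoxic":
        deficit = float(nu @ cod)
        nu[IDX["S_NO3"]] += deficit / DENIT_COD_PER_N
        nu[IDX["S_N2"]] -= deficit / DENIT_COD_PER_N
    elif regime != "none":
        raise ValueError(f"unknown regime {regime!r}")
    # nitrogen closure through ammonium
    nw = weights["N"]
    nu[IDX["S_NH4"]] = 0.0
    nu[IDX["S_NH4"]] = -float(nu @ nw)
    # phosphorus closure through orthophosphate
    pw = weights["P"]
    nu[IDX["S_PO4"]] = 0.0
    nu[IDX["S_PO4"]] = -float(nu @ pw)
    # TSS bookkeeping
    tss = (
        stoich.i_TSS_XI * nu[IDX["X_I"]]
        + stoich.i_TSS_XS * nu[IDX["X_S"]]
        + stoich.i_TSS_BM * (nu[IDX["X_H"]] + nu[IDX["X_PAO"]] + nu[IDX["X_AUT"]])
        + stoich.i_TSS_PP * nu[IDX["X_PP"]]
        + stoich.i_TSS_PHA * nu[IDX["X_PHA"]]
    )
    nu[IDX["X_TSS"]] = tss


def build_matrix(stoich: StoichParams) -> GujerMatrix:
    """Assemble the full extended-ASM2d Gujer matrix.

    Raises ``ValueError`` naming the offending process if any row fails
    the COD/N/P continuity check (cannot happen for valid parameters;
    the check guards against future edits).
    """
    stoich.validate()
    weights = conservation_weights(stoich)
    Y_H, Y_PAO, Y_A = stoich.Y_H, stoich.Y_PAO, stoich.Y_A
    f_SI, f_XI = stoich.f_SI, stoich.f_XI

    hydrolysis = {"X_S": -1.0, "S_F": 1.0 - f_SI, "S_I": f_SI}
    lysis_bm = {"X_I": f_XI, "X_S": 1.0 - f_XI}

    # (name, category, substrate, regime, mechanistic coefficients)
    process_defs: list[tuple[str, str, str, str, dict[str, float]]] = [
        ("hydrolysis_aerobic", "hydrolysis", "X_S", "none", hydrolysis),
        ("hydrolysis_anoxic", "hydrolysis", "X_S", "none", hydrolysis),
        ("hydrolysis_anaerobic", "hydrolysis", "X_S", "none", hydrolysis),
        ("fermentation_SF", "fermentation", "S_F", "none",
         {"S_F": -1.0, "S_A": 1.0}),
        ("oho_growth_SF_aerobic", "OHO_aerobic", "S_F", "aerobic",
         {"S_F": -1.0 / Y_H, "X_H": 1.0}),
        ("oho_growth_SA_aerobic", "OHO_aerobic", "S_A", "aerobic",
         {"S_A": -1.0 / Y_H, "X_H": 1.0}),
        ("oho_growth_SA1_aerobic", "OHO_aerobic", "S_A1", "aerobic",
         {"S_A1": -1.0 / Y_H, "X_H": 1.0}),
        ("oho_growth_SF_anoxic", "OHO_anoxic", "S_F", "anoxic",
         {"S_F": -1.0 / Y_H, "X_H": 1.0}),
        ("oho_growth_SA_anoxic", "OHO_anoxic", "S_A", "anoxic",
         {"S_A": -1.0 / Y_H, "X_H": 1.0}),
        ("oho_growth_SA1_anoxic", "OHO_anoxic", "S_A1", "anoxic",
         {"S_A1": -1.0 / Y_H, "X_H": 1.0}),
        ("fermentation_SA1", "fermentation", "S_A1", "none",
         {"S_A1": -1.0, "S_A": 1.0}),
        ("oho_lysis", "lysis", "none", "none", {"X_H": -1.0, **lysis_bm}),
        ("pao_storage_PHA_SA", "PAO_storage_anaerobic", "S_A", "none",
         {"S_A": -1.0, "X_PHA": 1.0, "X_PP": -stoich.Y_PO4}),
        ("pao_storage_PHA_SA1", "PAO_storage_exogenous", "S_A1", "none",
         {"S_A1": -1.0, "X_PHA": 1.0, "X_PP": -stoich.Y_PO4}),
        ("pao_storage_PP_aerobic", "PAO_PP_storage", "PHA", "aerobic",
         {"X_PP": 1.0, "X_PHA": -stoich.Y_PHA}),
        ("pao_storage_PP_anoxic", "PAO_PP_storage", "PHA", "anoxic",
         {"X_PP": 1.0, "X_PHA": -stoich.Y_PHA}),
        ("pao_growth_aerobic", "PAO_growth", "PHA", "aerobic",
         {"X_PHA": -1.0 / Y_PAO, "X_PAO": 1.0}),
        ("pao_growth_anoxic", "PAO_growth", "PHA", "anoxic",
         {"X_PHA": -1.0 / Y_PAO, "X_PAO": 1.0}),
        ("pao_lysis", "lysis", "none", "none", {"X_PAO": -1.0, **lysis_bm}),
        ("pp_lysis", "lysis", "none", "none", {"X_PP": -1.0}),
        ("pha_lysis", "lysis", "none", "none", {"X_PHA": -1.0, "S_A": 1.0}),
        ("aut_growth", "autotroph", "none", "aerobic",
         {"X_AUT": 1.0, "S_NO3": 1.0 / Y_A}),
        ("aut_lysis", "lysis", "none", "none", {"X_AUT": -1.0, **lysis_bm}),
    ]

    names, categories, substrates = [], [], []
    rows = np.zeros((len(process_defs), N_COMPONENTS))
    for i, (name, category, substrate, regime, mech) in enumerate(process_defs):
        nu = rows[i]
        for comp, value in mech.items():
            nu[IDX[comp]] = value
        _close_row(nu, regime, weights, stoich)
        names.append(name)
        categories.append(category)
        substrates.append(substrate)

    gm = GujerMatrix(names, categories, substrates, rows, stoich, weights)
    residuals = check_continuity(gm, per_process=True)
    for law, res in residuals.items():
        worst = int(np.argmax(res))
        if res[worst] > CONTINUITY_TOL:
            raise ValueError(
                f"continuity violated for {law} in process "
                f"{names[worst]!r}: residual {res[worst]:.3e}"
            )
    return gm


def check_continuity(matrix: GujerMatrix, per_process: bool = False):
    """Absolute conservation residuals of every row for COD, N and P.

    Returns a mapping law -> max residual (or per-process residual
    arrays when ``per_process`` is set).
    """
    weights = matrix.weights or conservation_weights(matrix.stoich)
    out = {}
    for law, w in weights.items():
        res = np.abs(matrix.coefficients @ w)
        out[law] = res if per_process else float(res.max(initial=0.0))
    return out
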