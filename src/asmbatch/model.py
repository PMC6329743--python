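"""Process rates and the ODE right-hand side of the extended model.

Every rate is a product of a maximum rate constant (1/d), Monod
saturation and inhibition switches, and the relevant biomass
concentration, so rates are non-negative whenever the state is.  The
fusel-oil substrate S_A1 follows the definition of an "external readily
biodegradable substrate": heterotrophs ferment it to acetate under
anaerobic conditions and grow on it under anoxic/aerobic conditions,
while PAOs can only store it as PHA when an electron acceptor (oxygen
or nitrate) is present.
"""

from __future__ import annotations

import numpy as np

from .components import IDX, N_COMPONENTS
from .matrix import GujerMatrix
from .parameters import KineticParams

_EPS = 1e-12


def _monod(s: float, k: float) -> float:
    return s / (k + s)


def _inhib(s: float, k: float) -> float:
    return k / (k + s)


def rate_vector(state: np.ndarray, kin: KineticParams) -> np.ndarray:
    """Per-process rates, mg/(L d), ordered as the Gujer-matrix rows.

    Raises ``ValueError`` for negative state components (beyond a small
    round-off allowance handled by the integrator wrapper).
    """
    if np.any(state[:N_COMPONENTS] < -1e-6):
        worst = int(np.argmin(state[:N_COMPONENTS]))
        raise ValueError(
            f"negative concentration in component index {worst}: "
            f"{state[worst]:.3e}"
        )
    s = np.maximum(state, 0.0)
    S_O2, S_F, S_A, S_A1 = s[0], s[1], s[2], s[3]
    S_NH4, S_NO3, S_PO4 = s[5], s[6], s[8]
    X_S, X_H, X_PAO, X_PP, X_PHA, X_AUT = s[10], s[11], s[12], s[13], s[14], s[15]

    k = kin
    aer = _monod(S_O2, k.K_O2)
    anox = _inhib(S_O2, k.K_O2) * _monod(S_NO3, k.K_NO3)
    anaer = _inhib(S_O2, k.K_O2) * _inhib(S_NO3, k.K_NO3)
    nut = _monod(S_NH4, k.K_NH4) * _monod(S_PO4, k.K_P)

    # hydrolysis saturation on the X_S/X_H ratio
    r_xs = X_S / (X_H + _EPS)
    hyd = k.K_h * r_xs / (k.K_X + r_xs) * X_H

    # substrate preference among the three soluble carbon pools
    s_tot = S_F + S_A + S_A1 + _EPS
    pref_F, pref_A, pref_A1 = S_F / s_tot, S_A / s_tot, S_A1 / s_tot
    grow_F = k.mu_H * _monod(S_F, k.K_F) * pref_F * nut * X_H
    grow_A = k.mu_H * _monod(S_A, k.K_A) * pref_A * nut * X_H
    grow_A1 = k.mu_H_A1 * _monod(S_A1, k.K_A1) * pref_A1 * nut * X_H

    # PAO storage pools (ratios per unit PAO biomass)
    r_pp = X_PP / (X_PAO + _EPS)
    r_pha = X_PHA / (X_PAO + _EPS)
    pp_room = max(k.K_MAX - r_pp, 0.0)
    store_pha_sat = _monod(r_pp, k.K_PP) * X_PAO
    store_pp = (
        k.q_PP
        * _monod(S_PO4, k.K_PS)
        * _monod(r_pha, k.K_PHA)
        * pp_room / (k.K_IPP + pp_room)
        * X_PAO
    )
    grow_pao = k.mu_PAO * _monod(r_pha, k.K_PHA) * nut * X_PAO
    # electron-acceptor presence switch for storage of S_A1 by PAOs
    acceptor = aer + anox

    rho = np.array([
        hyd * aer,                                        # hydrolysis_aerobic
        hyd * k.eta_NO3_hyd * anox,                       # hydrolysis_anoxic
        hyd * k.eta_fe_hyd * anaer,                       # hydrolysis_anaerobic
        k.q_fe * anaer * _monod(S_F, k.K_fe) * X_H,       # fermentation_SF
        grow_F * aer,                                     # oho_growth_SF_aerobic
        grow_A * aer,                                     # oho_growth_SA_aerobic
        grow_A1 * aer,                                    # oho_growth_SA1_aerobic
        grow_F * k.eta_NO3_H * anox,                      # oho_growth_SF_anoxic
        grow_A * k.eta_NO3_H * anox,                      # oho_growth_SA_anoxic
        grow_A1 * k.eta_NO3_H * anox,                     # oho_growth_SA1_anoxic
        k.q_fe_A1 * anaer * _monod(S_A1, k.K_A1) * X_H,   # fermentation_SA1
        k.b_H * X_H,                                      # oho_lysis
        k.q_PHA * _monod(S_A, k.K_A) * store_pha_sat,     # pao_storage_PHA_SA
        k.q_PHA_A1 * acceptor * _monod(S_A1, k.K_A1) * store_pha_sat,
                                                          # pao_storage_PHA_SA1
        store_pp * aer,                                   # pao_storage_PP_aerobic
        store_pp * k.eta_NO3_PAO * anox,                  # pao_storage_PP_anoxic
        grow_pao * aer,                                   # pao_growth_aerobic
        grow_pao * k.eta_NO3_PAO * anox,                  # pao_growth_anoxic
        k.b_PAO * X_PAO,                                  # pao_lysis
        k.b_PP * X_PP,                                    # pp_lysis
        k.b_PHA * X_PHA,                                  # pha_lysis
        k.mu_AUT * _monod(S_O2, k.K_O2_AUT)               # aut_growth
        * _monod(S_NH4, k.K_NH4_AUT) * _monod(S_PO4, k.K_P) * X_AUT,
        k.b_AUT * X_AUT,                                  # aut_lysis
    ])
    return rho


def rhs(state: np.ndarray, kin: KineticParams, matrix: GujerMatrix) -> np.ndarray:
    """Time derivative of the component vector, mg/(L d)."""
    rho = rate_vector(state, kin)
    return matrix.coefficients.T @ rho
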