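"""Two-phase anaerobic/anoxic batch-test simulation.

A :class:`Protocol` is an ordered list of phases (anaerobic then anoxic
in the experiments emulated here) plus timed events: substrate doses,
nitrate spikes (KNO3 addition) and chemical phosphate precipitation
(ferric chloride treatment of the decanted supernatant).  Events are
instantaneous state jumps; the ODE system is integrated piecewise
between event times with a stiff-capable adaptive solver.

Alongside the 17 model components, the integrator accumulates the
nitrate consumed by every denitrifying process (the per-process nitrate
sinks used by the attribution module) and a provenance split of the
acetate pool: S_A formed from fusel-derived S_A1 or dosed directly is
booked as external carbon, S_A from fermentation of wastewater S_F,
PHA lysis or the initial mixed liquor as endogenous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .components import COMPONENTS, IDX, N_COMPONENTS, make_state
from .matrix import GujerMatrix, build_matrix
from .model import rate_vector
from .parameters import KineticParams, StoichParams

ANAEROBIC = "anaerobic"
ANOXIC = "anoxic"

#: VSS -> COD conversion for activated-sludge biomass, gCOD/gVSS
I_CV_DEFAULT = 1.42


# ---------------------------------------------------------------------------
# events and protocol

@dataclass(frozen=True)
class DoseEvent:
    """Instantaneous addition of a carbon-source stock solution."""

    time_h: float
    source: str                  # "acetate" or "fusel"
    volume_mL: float
    stock_COD: float             # mgO2/L of the stock

    def __post_init__(self):
        if self.source not in ("acetate", "fusel"):
            raise ValueError(f"unknown dose source {self.source!r}")
        if self.volume_mL <= 0 or self.stock_COD <= 0:
            raise ValueError("dose volume and stock COD must be positive")

    @property
    def added_cod(self) -> float:
        """Total dosed COD mass, mg."""
        return self.volume_mL / 1000.0 * self.stock_COD


@dataclass(frozen=True)
class SpikeEvent:
    """Instantaneous nitrate addition (KNO3), expressed as mgN/L."""

    time_h: float
    delta_NO3: float


@dataclass(frozen=True)
class PrecipEvent:
    """Chemical stripping of orthophosphate from the supernatant."""

    time_h: float
    efficiency: float

    def __post_init__(self):
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("precipitation efficiency must lie in [0, 1]")


Event = Union[DoseEvent, SpikeEvent, PrecipEvent]

# physical sequence when several events share a timestamp: the
# supernatant is precipitated before the new dose and nitrate spike
_EVENT_ORDER = {PrecipEvent: 0, DoseEvent: 1, SpikeEvent: 2}


@dataclass(frozen=True)
class Protocol:
    """Phases and events of one batch test."""

    phases: tuple[tuple[str, float], ...] = ((ANAEROBIC, 2.5), (ANOXIC, 5.0))
    events: tuple[Event, ...] = ()
    volume_L: float = 4.0
    fusel_rb_fraction: float = 0.85   # readily biodegradable share of fusel COD

    def __post_init__(self):
        for name, dur in self.phases:
            if dur <= 0:
                raise ValueError(f"phase {name!r} has non-positive duration")
        span = self.total_duration
        for ev in self.events:
            if not 0.0 <= ev.time_h <= span:
                raise ValueError(
                    f"event at t={ev.time_h} h outside protocol span {span} h"
                )

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.phases)

    @property
    def phase_bounds(self) -> list[tuple[str, float, float]]:
        bounds, t = [], 0.0
        for name, dur in self.phases:
            bounds.append((name, t, t + dur))
            t += dur
        return bounds

    def phase_of(self, t: float) -> str:
        for name, t0, t1 in self.phase_bounds:
            if t < t1 or t1 == self.total_duration:
                return name
        return self.phases[-1][0]

    def sorted_events(self) -> list[Event]:
        return sorted(self.events, key=lambda e: (e.time_h, _EVENT_ORDER[type(e)]))


# ---------------------------------------------------------------------------
# initial conditions

@dataclass
class InitialConditions:
    """Measured mixed-liquor characteristics plus fractionation choices.

    The measurements (COD, TP, NO3-N, NO2-N, MLSS, pH) come straight
    from the batch-test records; the fractionation parameters translate
    them into the 17-component state.  ``frac_PAO`` and ``frac_OHO`` are
    the PAO/OHO shares of the volatile solids (0.17 and 0.32 from
    full-scale simulation results); polyphosphate and PHA reserves are
    expressed as fractions of the PAO biomass.
    """

    cod0: float                  # initial soluble COD, mgO2/L
    tp0: float                   # initial phosphate, mgP/L
    no3_0: float                 # mgN/L
    no2_0: float                 # mgN/L (lumped into nitrate)
    mlss: float                  # mg/L
    ph: float = 7.0              # recorded only
    nh4_0: float = 10.0          # assumed mixed-liquor ammonium, mgN/L
    f_VSS: float = 0.75          # VSS/MLSS
    i_CV: float = I_CV_DEFAULT   # gCOD/gVSS
    frac_PAO: float = 0.17
    frac_OHO: float = 0.32
    frac_AUT: float = 0.03
    x_pp0_frac: float = 0.10     # X_PP as fraction of X_PAO (gP/gCOD)
    x_pha0_frac: float = 0.01    # X_PHA as fraction of X_PAO
    # calibrated fractionation of the measured mixed liquor: the initial
    # soluble COD is almost entirely inert (the reference test shows
    # nearly flat anaerobic P and COD profiles), and very little of the
    # particulate COD is slowly biodegradable at time zero
    x_s_frac: float = 0.004      # X_S share of non-biomass particulate COD
    sf_frac: float = 0.010       # soluble COD split
    sa_frac: float = 0.016
    si_frac: float = 0.974

    def __post_init__(self):
        if self.mlss < 0:
            raise ValueError("MLSS must be non-negative")
        for name in ("frac_PAO", "frac_OHO", "frac_AUT", "x_pp0_frac",
                     "x_pha0_frac", "x_s_frac", "f_VSS"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_PAO + self.frac_OHO + self.frac_AUT > 1.0:
            raise ValueError("biomass fractions exceed the volatile solids")
        if abs(self.sf_frac + self.sa_frac + self.si_frac - 1.0) > 1e-9:
            raise ValueError("soluble COD split must sum to 1")

    @property
    def vss(self) -> float:
        """Volatile suspended solids, mg/L."""
        return self.f_VSS * self.mlss

    @property
    def vss_g(self) -> float:
        """VSS in g/L (normalisation basis of the rate estimators)."""
        return self.vss / 1000.0


def build_initial_state(ic: InitialConditions) -> np.ndarray:
    """Translate measured initial conditions into the component vector."""
    if ic.mlss < 0:
        raise ValueError("MLSS must be non-negative")
    cod_x = ic.vss * ic.i_CV
    x_pao = ic.frac_PAO * cod_x
    x_h = ic.frac_OHO * cod_x
    x_aut = ic.frac_AUT * cod_x
    rest = max(cod_x - x_pao - x_h - x_aut, 0.0)
    x_s = ic.x_s_frac * rest
    x_i = rest - x_s
    return make_state(
        S_F=ic.sf_frac * ic.cod0,
        S_A=ic.sa_frac * ic.cod0,
        S_I=ic.si_frac * ic.cod0,
        S_NH4=ic.nh4_0,
        S_NO3=ic.no3_0 + ic.no2_0,
        S_PO4=ic.tp0,
        X_I=x_i,
        X_S=x_s,
        X_H=x_h,
        X_PAO=x_pao,
        X_PP=ic.x_pp0_frac * x_pao,
        X_PHA=ic.x_pha0_frac * x_pao,
        X_AUT=x_aut,
        X_TSS=ic.mlss,
    )


def apply_event(
    state: np.ndarray,
    event: Event,
    volume_L: float,
    fusel_rb_fraction: float = 0.85,
) -> np.ndarray:
    """Return the state immediately after an instantaneous event."""
    out = state.copy()
    if isinstance(event, DoseEvent):
        conc = event.added_cod / volume_L      # mgCOD/L added
        if event.source == "acetate":
            out[IDX["S_A"]] += conc
        else:
            out[IDX["S_A1"]] += fusel_rb_fraction * conc
            out[IDX["X_S"]] += (1.0 - fusel_rb_fraction) * conc
    elif isinstance(event, SpikeEvent):
        out[IDX["S_NO3"]] += event.delta_NO3
    elif isinstance(event, PrecipEvent):
        out[IDX["S_PO4"]] *= 1.0 - event.efficiency
    else:
        raise TypeError(f"unknown event type {type(event)!r}")
    return out


# ---------------------------------------------------------------------------
# trajectory container

@dataclass
class Trajectory:
    """Simulated series of all components plus nitrate-sink integrals."""

    times: np.ndarray                       # h
    states: np.ndarray                      # (nt, 17)
    sink_names: list[str]                   # denitrifying processes
    sinks: np.ndarray                       # (nt, n_sinks), cumulative mgN/L
    sa_sink_eocs: np.ndarray                # EOCS-credited share of the S_A sink
    sa_in_endo: np.ndarray                  # cumulative S_A inputs, mgCOD/L
    sa_in_eocs: np.ndarray
    protocol: Protocol
    ic: InitialConditions
    matrix: GujerMatrix

    def component(self, name: str) -> np.ndarray:
        return self.states[:, IDX[name]]

    def phase_mask(self, phase: str) -> np.ndarray:
        for name, t0, t1 in self.protocol.phase_bounds:
            if name == phase:
                return (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)
        raise KeyError(f"no phase {phase!r} in protocol")

    def sink_delta(self, phase: str) -> dict[str, float]:
        """Nitrate consumed per denitrifying process over one phase, mgN/L."""
        mask = self.phase_mask(phase)
        idx = np.where(mask)[0]
        first, last = idx[0], idx[-1]
        return {
            name: float(self.sinks[last, j] - self.sinks[first, j])
            for j, name in enumerate(self.sink_names)
        }

    def sa_sink_eocs_delta(self, phase: str) -> float:
        mask = np.where(self.phase_mask(phase))[0]
        return float(self.sa_sink_eocs[mask[-1]] - self.sa_sink_eocs[mask[0]])

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(COMPONENTS):
            rows.append(pd.DataFrame({
                "time_h": self.times,
                "variable": name,
                "value": self.states[:, j],
            }))
        return pd.concat(rows, ignore_index=True)

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(COMPONENTS))
        df.insert(0, "time_h", self.times)
        return df


# ---------------------------------------------------------------------------
# the simulator

class SimulationError(RuntimeError):
    pass


def simulate_protocol(
    ic: InitialConditions,
    protocol: Protocol,
    kin: KineticParams,
    stoich: StoichParams | None = None,
    *,
    matrix: GujerMatrix | None = None,
    grid_minutes: float = 5.0,
    rtol: float = 1e-7,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate one batch test and return the sampled trajectory.

    Event times are hard integration breakpoints with instantaneous
    state jumps.  Output is sampled on a regular grid (default 5 min)
    with the breakpoints themselves always included, duplicating each
    event time with the pre- and post-event states.
    """
    if matrix is None:
        matrix = build_matrix(stoich if stoich is not None else StoichParams())
    kin.validate()

    nu_no3 = matrix.coefficients[:, IDX["S_NO3"]]
    sink_names = matrix.nitrate_sink_processes
    sink_idx = np.array([matrix.index(n) for n in sink_names])
    i_sa_anox = sink_names.index("oho_growth_SA_anoxic")
    i_ferm_sf = matrix.index("fermentation_SF")
    i_ferm_sa1 = matrix.index("fermentation_SA1")
    i_pha_lys = matrix.index("pha_lysis")

    n_sinks = len(sink_names)
    n_aug = N_COMPONENTS + n_sinks + 3   # sinks + eocs-weighted sink + 2 buckets

    def rhs_aug(t, y):
        rho = rate_vector(y[:N_COMPONENTS], kin)
        dy = np.empty(n_aug)
        dy[:N_COMPONENTS] = matrix.coefficients.T @ rho
        sink_rates = -nu_no3[sink_idx] * rho[sink_idx]
        dy[N_COMPONENTS:N_COMPONENTS + n_sinks] = sink_rates
        endo = y[N_COMPONENTS + n_sinks + 1]
        eocs = y[N_COMPONENTS + n_sinks + 2]
        f_eocs = eocs / (endo + eocs + 1e-12)
        dy[N_COMPONENTS + n_sinks] = sink_rates[i_sa_anox] * f_eocs
        dy[N_COMPONENTS + n_sinks + 1] = rho[i_ferm_sf] + rho[i_pha_lys]
        dy[N_COMPONENTS + n_sinks + 2] = rho[i_ferm_sa1]
        return dy / 24.0   # rates are per day, time axis in hours

    state0 = build_initial_state(ic)
    y = np.zeros(n_aug)
    y[:N_COMPONENTS] = state0
    y[N_COMPONENTS + n_sinks + 1] = state0[IDX["S_A"]]

    span = protocol.total_duration
    events = protocol.sorted_events()
    breakpoints = sorted(
        {0.0, span}
        | {t1 for _, _, t1 in protocol.phase_bounds}
        | {ev.time_h for ev in events}
    )

    times_out: list[np.ndarray] = []
    ys_out: list[np.ndarray] = []
    t_prev = 0.0

    def record(ts, ys):
        times_out.append(np.asarray(ts))
        ys_out.append(np.asarray(ys))

    record([0.0], [y.copy()])
    dt_grid = grid_minutes / 60.0
    for t_next in breakpoints:
        if t_next > t_prev + 1e-12:
            n_pts = max(int(round((t_next - t_prev) / dt_grid)), 1)
            t_eval = np.linspace(t_prev, t_next, n_pts + 1)[1:]
            sol = solve_ivp(
                rhs_aug, (t_prev, t_next), y, method="LSODA",
                t_eval=t_eval, rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise SimulationError(
                    f"integrator failed at t={sol.t[-1] if sol.t.size else t_prev:.3f} h: "
                    f"{sol.message}; state={y[:N_COMPONENTS]}"
                )
            record(sol.t, sol.y.T)
            y = sol.y[:, -1].copy()
            low = y[:N_COMPONENTS].min()
            if low < -1e-6:
                j = int(np.argmin(y[:N_COMPONENTS]))
                raise SimulationError(
                    f"negative concentration {COMPONENTS[j]}={low:.3e} at t={t_next:.3f} h"
                )
            y[:N_COMPONENTS] = np.maximum(y[:N_COMPONENTS], 0.0)
            t_prev = t_next
        for ev in events:
            if abs(ev.time_h - t_next) < 1e-12:
                state = apply_event(
                    y[:N_COMPONENTS], ev, protocol.volume_L,
                    protocol.fusel_rb_fraction,
                )
                if isinstance(ev, DoseEvent):
                    added = ev.added_cod / protocol.volume_L
                    if ev.source == "acetate":
                        y[N_COMPONENTS + n_sinks + 2] += added
                elif isinstance(ev, PrecipEvent):
                    # P leaves the system: bucket states unaffected
                    pass
                y[:N_COMPONENTS] = state
                record([t_next], [y.copy()])

    times = np.concatenate(times_out)
    ys = np.vstack(ys_out)
    return Trajectory(
        times=times,
        states=ys[:, :N_COMPONENTS],
        sink_names=sink_names,
        sinks=ys[:, N_COMPONENTS:N_COMPONENTS + n_sinks],
        sa_sink_eocs=ys[:, N_COMPONENTS + n_sinks],
        sa_in_endo=ys[:, N_COMPONENTS + n_sinks + 1],
        sa_in_eocs=ys[:, N_COMPONENTS + n_sinks + 2],
        protocol=protocol,
        ic=ic,
        matrix=matrix,
    )
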