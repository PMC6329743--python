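"""Slope-based rate estimators and derived efficiencies.

The phosphate release rate (PRR), phosphate uptake rate (PUR) and
nitrate utilization rate (NUR) are ordinary least-squares slopes of the
concentration series over a fit window, normalised by the volatile
suspended solids:

    rate = |slope(C_i vs t_i)| / X        [mg / gVSS / h]

with direction inferred from the slope sign and the phase (phosphate
rising under anaerobic conditions is release, falling under anoxic
conditions is uptake; nitrate falling is utilization).  PRR and PUR in
batch tests are conventionally reported as the *maximum* windowed rate
(the release/uptake is fastest right after dosing), which
:func:`max_window_rate` provides; the NUR is taken over the whole
anoxic phase, truncated where nitrate approaches depletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .batch import ANAEROBIC, ANOXIC, Trajectory
from .components import IDX

#: default sliding-window length for PRR/PUR, hours (the maximum release
#: was observed within the first 45 min of the anaerobic phase)
MAX_WINDOW_H = 0.75
#: NUR windows end once nitrate falls below this level, mgN/L
NO3_DEPLETION = 1.0

_EXPECTED_SIGN = {
    (ANAEROBIC, "PO4"): +1,   # release
    (ANOXIC, "PO4"): -1,      # uptake
    (ANOXIC, "NO3"): -1,      # utilization
    (ANAEROBIC, "COD"): -1,
    (ANOXIC, "COD"): -1,
}

_DIRECTION = {
    (ANAEROBIC, "PO4"): "release",
    (ANOXIC, "PO4"): "uptake",
    (ANOXIC, "NO3"): "utilization",
}


class RateWarning(UserWarning):
    pass


@dataclass
class MeasurementSeries:
    """One measured (or simulated) concentration series for rate fitting."""

    times: np.ndarray            # h, strictly increasing
    values: np.ndarray           # mg/L
    vss_g: float                 # gVSS/L normalisation basis
    phase: str                   # "anaerobic" or "anoxic"
    variable: str = "PO4"        # PO4 / NO3 / COD

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.vss_g <= 0:
            raise ValueError("VSS must be positive")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class RateResult:
    """VSS-normalised rate magnitude with direction and fit quality."""

    rate: float                  # mg / gVSS / h, >= 0
    direction: str               # release / uptake / utilization / decline
    window: tuple[float, float]  # h
    r2: float
    slope: float                 # signed, mg/L/h
    sign_consistent: bool = True


def _ols_slope(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Slope and R^2 of an ordinary least-squares line fit."""
    t0 = t - t.mean()
    denom = float(t0 @ t0)
    slope = float(t0 @ (c - c.mean())) / denom
    resid = c - c.mean() - slope * t0
    ss_tot = float(((c - c.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return slope, r2


def fit_rate(
    series: MeasurementSeries,
    window: tuple[float, float] | None = None,
) -> RateResult:
    """OLS rate over a window, VSS-normalised, with direction checking.

    A slope whose sign contradicts the phase expectation (e.g. phosphate
    rising during the anoxic phase) is flagged via ``sign_consistent``
    and a :class:`RateWarning`; the magnitude is still returned.
    """
    lo, hi = window if window is not None else series.span
    mask = (series.times >= lo - 1e-9) & (series.times <= hi + 1e-9)
    t, c = series.times[mask], series.values[mask]
    if t.size < 3:
        raise ValueError(f"need >= 3 points in window [{lo}, {hi}], got {t.size}")
    slope, r2 = _ols_slope(t, c)
    key = (series.phase, series.variable)
    expected = _EXPECTED_SIGN.get(key)
    consistent = True
    if expected is not None and slope != 0.0 and np.sign(slope) != expected:
        consistent = False
        warnings.warn(
            f"{series.variable} slope {slope:.3g} mg/L/h contradicts the "
            f"{series.phase}-phase expectation",
            RateWarning,
            stacklevel=2,
        )
    direction = _DIRECTION.get(key, "decline" if slope <= 0 else "rise")
    return RateResult(
        rate=abs(slope) / series.vss_g,
        direction=direction,
        window=(float(t[0]), float(t[-1])),
        r2=r2,
        slope=slope,
        sign_consistent=consistent,
    )


def max_window_rate(
    series: MeasurementSeries,
    window_len: float = MAX_WINDOW_H,
) -> RateResult:
    """Maximum-magnitude phase-consistent rate over a sliding window."""
    t0, t1 = series.span
    if window_len > t1 - t0 + 1e-9:
        raise ValueError("window longer than the series span")
    best: RateResult | None = None
    starts = series.times[series.times <= t1 - window_len + 1e-9]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RateWarning)
        for s in starts:
            try:
                res = fit_rate(series, (s, s + window_len))
            except ValueError:
                continue
            if not res.sign_consistent:
                continue
            if best is None or res.rate > best.rate:
                best = res
    if best is None:
        # no phase-consistent window: fall back to the global fit
        return fit_rate(series, None)
    return best


def removal_efficiency(series: MeasurementSeries) -> float:
    """Percent removal between the first and last point of the series."""
    c_start, c_end = float(series.values[0]), float(series.values[-1])
    if c_start == 0.0:
        raise ZeroDivisionError("removal efficiency undefined for C_start = 0")
    return 100.0 * (c_start - c_end) / c_start


def release_per_cod_ratio(
    p_series: MeasurementSeries, cod_series: MeasurementSeries
) -> float:
    """Anaerobic P released per COD taken up, both up to the P maximum."""
    i_max = int(np.argmax(p_series.values))
    dp = float(p_series.values[i_max] - p_series.values[0])
    if dp <= 0.0:
        return 0.0
    t_pmax = p_series.times[i_max]
    j = int(np.searchsorted(cod_series.times, t_pmax, side="right")) - 1
    dcod = float(cod_series.values[0] - cod_series.values[j])
    if dcod <= 0:
        raise ZeroDivisionError("no COD uptake; release ratio undefined")
    return max(dp, 0.0) / dcod


def p_per_n_ratio(
    p_series: MeasurementSeries, n_series: MeasurementSeries
) -> float:
    """Anoxic phosphate taken up per nitrate reduced, mgP/mgN."""
    dp = float(p_series.values[0] - p_series.values[-1])
    dn = float(n_series.values[0] - n_series.values[-1])
    if dn <= 0:
        raise ZeroDivisionError("no nitrate removal; P/N ratio undefined")
    return max(dp, 0.0) / dn


# ---------------------------------------------------------------------------
# extraction from simulated trajectories

_VARIABLE_MAP = {
    "PO4": ("S_PO4",),
    "NO3": ("S_NO3",),
    # measured COD in the filtered samples: soluble biodegradable + inert
    "COD": ("S_F", "S_A", "S_A1", "S_I"),
}


def series_from_trajectory(
    traj: Trajectory, variable: str, phase: str
) -> MeasurementSeries:
    """Extract a phase-restricted series for one measured variable.

    For phases entered via an instantaneous event (nitrate spike, dose)
    the post-event sample at the boundary time is used as the first
    point, matching how a grab sample just after addition would read.
    """
    mask = traj.phase_mask(phase)
    idx = np.where(mask)[0]
    # duplicate timestamps at event boundaries: keep the *last* (post-event)
    # sample at the phase start and the *first* (pre-event) elsewhere
    t = traj.times[idx]
    t_start = t[0]
    keep = np.ones(idx.size, dtype=bool)
    for i in range(idx.size - 1):
        if t[i + 1] - t[i] < 1e-12:
            if abs(t[i] - t_start) < 1e-12:
                keep[i] = False      # phase start: drop pre-event samples
            else:
                keep[i + 1] = False  # phase end: drop post-event samples
    idx = idx[keep]
    cols = _VARIABLE_MAP[variable]
    values = sum(traj.states[idx, IDX[c]] for c in cols)
    return MeasurementSeries(
        times=traj.times[idx],
        values=np.asarray(values),
        vss_g=traj.ic.vss_g,
        phase=phase,
        variable=variable,
    )


def nur_window(series: MeasurementSeries) -> tuple[float, float]:
    """Anoxic NUR window: full phase, truncated at nitrate depletion."""
    t0, t1 = series.span
    below = np.where(series.values < NO3_DEPLETION)[0]
    if below.size and below[0] >= 3:
        t1 = float(series.times[below[0]])
    return t0, t1


def trajectory_rates(traj: Trajectory) -> dict[str, float]:
    """The standard summary rates of one simulated batch test.

    PRR/PUR use the maximum sliding-window estimator; NUR the full
    (depletion-truncated) anoxic window.  Efficiencies and stoichiometric
    ratios mirror the usual batch-test summary table.
    """
    p_ana = series_from_trajectory(traj, "PO4", ANAEROBIC)
    cod_ana = series_from_trajectory(traj, "COD", ANAEROBIC)
    p_anox = series_from_trajectory(traj, "PO4", ANOXIC)
    n_anox = series_from_trajectory(traj, "NO3", ANOXIC)
    cod_anox = series_from_trajectory(traj, "COD", ANOXIC)

    prr = max_window_rate(p_ana)
    pur = max_window_rate(p_anox)
    nur = fit_rate(n_anox, nur_window(n_anox))

    out = {
        "PRR": prr.rate,
        "PUR": pur.rate,
        "NUR": nur.rate,
        "PRR_window": prr.window,
        "PUR_window": pur.window,
        "NUR_window": nur.window,
        "peak_anaerobic_PO4": float(p_ana.values.max()),
        "cod_eff_anaerobic": removal_efficiency(cod_ana),
        "cod_eff_anoxic": removal_efficiency(cod_anox),
        "po4_eff_anoxic": removal_efficiency(p_anox),
        "no3_eff_anoxic": removal_efficiency(n_anox),
        "p_per_n": p_per_n_ratio(p_anox, n_anox),
    }
    try:
        out["release_per_cod"] = release_per_cod_ratio(p_ana, cod_ana)
    except ZeroDivisionError:
        out["release_per_cod"] = float("nan")
    return out
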