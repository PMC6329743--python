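"""Calibration of the free kinetic constants against observed rates.

The objective is standard-deviation-normalised least squares over the
batch-test summary rates (PRR, PUR, NUR by default): each simulated
scenario is run, the slope estimators are applied to the simulated
series, and the residuals against the observed table are accumulated as
``((predicted - observed)/sd)^2``.  Missing standard deviations default
to 10% of the observed value (the observed rates span nearly two orders
of magnitude, so unweighted least squares would be dominated by the
largest release rates).

Minimisation is derivative-free (Nelder-Mead simplex) with seeded
multistarts, since every objective evaluation involves ODE solves and
the Monod switches make the response surface non-smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .batch import simulate_protocol
from .parameters import KineticParams, StoichParams, with_updates
from .rates import trajectory_rates
from .scenarios import Scenario

DEFAULT_RATE_TYPES = ("PRR", "PUR", "NUR")
_MISSING_SD_FRACTION = 0.10


class CalibrationError(RuntimeError):
    pass


@dataclass
class ObservedRates:
    """Long-form observed summary table: test, parameter, value, sd."""

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"test", "parameter", "value", "sd"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"observed table needs columns {sorted(required)}")
        if (self.frame["value"].dropna() < 0).any():
            raise ValueError("observed rates must be non-negative")
        if (self.frame["sd"].dropna() <= 0).any():
            raise ValueError("standard deviations must be positive")

    def lookup(self, test: int, parameter: str) -> tuple[float, float] | None:
        rows = self.frame[
            (self.frame["test"] == test) & (self.frame["parameter"] == parameter)
        ]
        if rows.empty or np.isnan(rows["value"].iloc[0]):
            return None
        value = float(rows["value"].iloc[0])
        sd = rows["sd"].iloc[0]
        if pd.isna(sd) or sd <= 0:
            sd = max(_MISSING_SD_FRACTION * value, 1e-6)
        return value, float(sd)


@dataclass
class FitResult:
    """Estimated parameters with diagnostics."""

    params: dict[str, float]
    objective: float
    bounds_hit: dict[str, bool]
    residuals: pd.DataFrame
    starts: list[dict] = field(default_factory=list)
    r2: dict[str, float] = field(default_factory=dict)


def predict_rates(
    scenarios: list[tuple[Scenario, KineticParams, StoichParams]],
    **sim_kwargs,
) -> pd.DataFrame:
    """Simulate each scenario and estimate its summary rates."""
    rows = []
    for scenario, kin, stoich in scenarios:
        traj = simulate_protocol(scenario.ic, scenario.protocol, kin, stoich,
                                 **sim_kwargs)
        rates = trajectory_rates(traj)
        rows.append({"test": scenario.test_id, **{
            k: v for k, v in rates.items() if not k.endswith("_window")
        }})
    return pd.DataFrame(rows)


def objective(
    params: dict[str, float],
    observed: ObservedRates,
    scenarios: list[tuple[Scenario, KineticParams, StoichParams]],
    rate_types: tuple[str, ...] = DEFAULT_RATE_TYPES,
    **sim_kwargs,
) -> float:
    """Chi-square-style misfit of a candidate parameter set.

    Simulation failures propagate as :class:`CalibrationError` rather
    than being masked by a large penalty value.
    """
    updated = [
        (sc, with_updates(kin, **params), stoich)
        for sc, kin, stoich in scenarios
    ]
    try:
        predicted = predict_rates(updated, **sim_kwargs)
    except Exception as exc:   # integrator failures carry context
        raise CalibrationError(f"simulation failed for {params}: {exc}") from exc
    total = 0.0
    for _, row in predicted.iterrows():
        for rate in rate_types:
            obs = observed.lookup(int(row["test"]), rate)
            if obs is None:
                continue
            value, sd = obs
            total += ((row[rate] - value) / sd) ** 2
    return total


def fit_params(
    free_names: list[str],
    bounds: dict[str, tuple[float, float]],
    observed: ObservedRates,
    scenarios: list[tuple[Scenario, KineticParams, StoichParams]],
    seed: int = 0,
    n_starts: int = 5,
    rate_types: tuple[str, ...] = DEFAULT_RATE_TYPES,
    xatol: float = 0.02,
    fatol: float = 0.05,
    **sim_kwargs,
) -> FitResult:
    """Bounded derivative-free fit of 1-4 free kinetic constants."""
    if not 1 <= len(free_names) <= 4:
        raise ValueError("between 1 and 4 free parameters supported")
    lo = np.array([bounds[n][0] for n in free_names])
    hi = np.array([bounds[n][1] for n in free_names])
    if np.any(lo > hi):
        raise ValueError("lower bound exceeds upper bound")

    def wrapped(x: np.ndarray) -> float:
        params = dict(zip(free_names, np.clip(x, lo, hi)))
        return objective(params, observed, scenarios, rate_types, **sim_kwargs)

    rng = np.random.default_rng(seed)
    starts, best = [], None
    x0s = [0.5 * (lo + hi)]
    if np.any(hi > lo):
        x0s += [lo + rng.random(len(free_names)) * (hi - lo)
                for _ in range(n_starts - 1)]
    else:
        x0s = [lo]
    failures = 0
    for x0 in x0s:
        try:
            res = optimize.minimize(
                wrapped, x0, method="Nelder-Mead",
                options={"xatol": xatol, "fatol": fatol, "maxfev": 200},
            )
        except CalibrationError:
            failures += 1
            continue
        record = {
            "x0": dict(zip(free_names, x0)),
            "x": dict(zip(free_names, np.clip(res.x, lo, hi))),
            "objective": float(res.fun),
        }
        starts.append(record)
        if best is None or res.fun < best["objective"]:
            best = record
    if best is None:
        raise CalibrationError(f"all {failures} starts failed")

    params = best["x"]
    hit = {
        n: bool(
            abs(params[n] - bounds[n][0]) < 1e-9
            or abs(params[n] - bounds[n][1]) < 1e-9
        )
        for n in free_names
    }
    updated = [(sc, with_updates(kin, **params), st)
               for sc, kin, st in scenarios]
    predicted = predict_rates(updated, **sim_kwargs)
    rows = []
    for _, row in predicted.iterrows():
        for rate in rate_types:
            obs = observed.lookup(int(row["test"]), rate)
            if obs is None:
                continue
            value, sd = obs
            rows.append({
                "test": int(row["test"]), "parameter": rate,
                "observed": value, "predicted": float(row[rate]),
                "sd": sd, "z": (float(row[rate]) - value) / sd,
            })
    residuals = pd.DataFrame(rows)
    r2 = {}
    for rate in rate_types:
        sub = residuals[residuals["parameter"] == rate]
        if len(sub) >= 3:
            try:
                r2[rate] = r_squared(sub["predicted"].values,
                                     sub["observed"].values)
            except ZeroDivisionError:
                pass
    return FitResult(
        params=params,
        objective=best["objective"],
        bounds_hit=hit,
        residuals=residuals,
        starts=starts,
        r2=r2,
    )


def r_squared(predicted, observed) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot of predictions."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("need >= 3 matching prediction/observation pairs")
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ZeroDivisionError("zero variance in observations")
    ss_res = float(((observed - predicted) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def regression_r2(predicted, observed) -> float:
    """R^2 of the least-squares regression of observed on predicted.

    This is the statistic annotated on predicted-versus-observed scatter
    plots: the squared Pearson correlation of the two rate sets.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.std(predicted) == 0.0 or np.std(observed) == 0.0:
        raise ZeroDivisionError("zero variance")
    return float(np.corrcoef(predicted, observed)[0, 1] ** 2)
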