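"""CSV interchange and run configuration.

The canonical interchange format is a long (tidy) table with columns
``time_h, variable, value``; a wide table (one column per variable) is
accepted on input and offered as a convenience export.  All outputs use
UTF-8, a header row and a decimal point, with deterministic column
order so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger("asmbatch")

TIDY_COLUMNS = ("time_h", "variable", "value")

#: variables understood by the rate estimators
KNOWN_VARIABLES = {"PO4", "NO3", "COD"}


class SchemaError(ValueError):
    pass


@dataclass
class RunConfig:
    """Options shared by the pipeline commands."""

    tests: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    profile_path: str | None = None
    rtol: float = 1e-7
    atol: float = 1e-8
    grid_minutes: float = 5.0
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("integrator tolerances must be positive")


def read_timeseries_csv(path) -> pd.DataFrame:
    """Read a long or wide concentration table into tidy form.

    Rows are sorted by time within each variable.  Unknown variable
    names and non-monotone duplicate handling raise :class:`SchemaError`
    with the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path} is empty", UserWarning, stacklevel=2)
        return pd.DataFrame(columns=list(TIDY_COLUMNS))
    if set(TIDY_COLUMNS).issubset(df.columns):
        tidy = df[list(TIDY_COLUMNS)].copy()
    elif "time_h" in df.columns:
        tidy = df.melt(id_vars="time_h", var_name="variable", value_name="value")
    else:
        raise SchemaError(
            f"{path}: expected tidy columns {TIDY_COLUMNS} or a wide table "
            "with a time_h column"
        )
    unknown = set(tidy["variable"].unique()) - KNOWN_VARIABLES
    if unknown:
        rows = tidy.index[tidy["variable"].isin(unknown)]
        raise SchemaError(
            f"{path}: unknown variable(s) {sorted(unknown)} "
            f"(first at row {int(rows[0]) + 2})"
        )
    tidy = tidy.sort_values(["variable", "time_h"], kind="stable")
    for variable, sub in tidy.groupby("variable"):
        t = sub["time_h"].to_numpy()
        dup = (t[1:] - t[:-1]) <= 0 if t.size > 1 else []
        if any(dup):
            row = int(sub.index[1:][dup][0]) + 2
            raise SchemaError(
                f"{path}: non-increasing times for {variable} at row {row}"
            )
    return tidy.reset_index(drop=True)


def write_timeseries_csv(tidy: pd.DataFrame, path) -> None:
    tidy = tidy[list(TIDY_COLUMNS)]
    tidy.to_csv(path, index=False, float_format="%.6g")


#: row order of the summary table, mirroring the batch-test report
SUMMARY_ROWS = (
    "PRR", "cod_eff_anaerobic", "release_per_cod", "PUR", "NUR",
    "po4_eff_anoxic", "no3_eff_anoxic", "cod_eff_anoxic",
    "peak_anaerobic_PO4", "p_per_n",
)


def write_results(
    rates_by_test: dict[int, dict[str, float]],
    breakdowns_by_test: dict[int, list] | None,
    out_dir,
) -> list[Path]:
    """Write the per-test summary and attribution tables.

    ``summary.csv`` mirrors the conventional batch-test layout: one
    column per test, one row per rate/efficiency.  ``attribution.csv``
    holds the NUR shares per test and method.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    tests = sorted(rates_by_test)
    summary = pd.DataFrame(
        {
            f"test_{t}": [rates_by_test[t].get(row, float("nan"))
                          for row in SUMMARY_ROWS]
            for t in tests
        },
        index=list(SUMMARY_ROWS),
    )
    summary.index.name = "parameter"
    path = out_dir / "summary.csv"
    summary.to_csv(path, float_format="%.4g")
    written.append(path)

    if breakdowns_by_test is not None:
        rows = []
        for t in sorted(breakdowns_by_test):
            for bd in breakdowns_by_test[t]:
                rows.append({
                    "test": t,
                    "method": bd.method,
                    "total_NUR": bd.total_nur,
                    "DPAO": bd.group_shares["DPAO"],
                    "DOHO": bd.group_shares["DOHO"],
                    "EOCS": bd.source_shares["EOCS"],
                    "PHA": bd.source_shares["PHA"],
                    "endogenous": bd.source_shares["endogenous"],
                })
        path = out_dir / "attribution.csv"
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4g")
        written.append(path)
    return written


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
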