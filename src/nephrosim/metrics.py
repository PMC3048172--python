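"""Derived quantities: volume, volume reduction, growth-rate fits, composition.

All reported tumor characteristics — growth-rate constant k and doubling
time Td = ln2/k, growth fraction and subpopulation percentages, and the
percentage volume reduction after therapy — are computed here from the
hourly time series recorded by the simulation engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .cytokinetics import CompositionSummary

__all__ = [
    "SimulationResult",
    "GrowthFit",
    "volume_reduction",
    "fit_growth_rate",
    "composition_at",
]

#: Count columns recorded every hour.
COUNT_COLUMNS = (
    "total",
    "proliferating",
    "dormant",
    "stem",
    "limp",
    "differentiated",
    "apoptotic",
    "necrotic",
    "dead",
    "hit",
)


@dataclass
class SimulationResult:
    """Hourly time series of a simulation plus run metadata.

    ``data`` has one row per hour of the horizon (inclusive of hour 0 and
    the final hour) with the subpopulation tallies of
    :meth:`nephrosim.cytokinetics.CellStateVector.counts`, the tumor volume
    in cm^3 and, in lattice mode, the geometrical-cell count.
    """

    data: pd.DataFrame
    params: Any = None
    schedule: Any = None
    mode: str = "wellmixed"
    cell_density: float = 1e9
    gc_volume: float = 1e-3
    dose_log: list = field(default_factory=list)
    scenario: str | None = None

    def __post_init__(self):
        hours = self.data["hour"].to_numpy()
        if len(hours) == 0 or (np.diff(hours) != 1).any():
            raise ValueError("result must contain a record at every hour")

    @property
    def horizon_h(self) -> int:
        return int(self.data["hour"].iloc[-1])

    def row_at(self, hour: int) -> pd.Series:
        sel = self.data[self.data["hour"] == hour]
        if sel.empty:
            raise ValueError(f"hour {hour} outside the recorded horizon")
        return sel.iloc[0]

    def volume_at(self, hour: int) -> float:
        return float(self.row_at(hour)["volume_cm3"])

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def volume_reduction(v_baseline: float, v_final: float) -> float:
    """Percentage tumor volume reduction, 100 * (1 - v_final / v_baseline).

    A growing tumor yields a negative reduction.
    """
    if v_baseline <= 0:
        raise ValueError("baseline volume must be > 0")
    return 100.0 * (1.0 - v_final / v_baseline)


@dataclass
class GrowthFit:
    """Least-squares exponential growth fit over a treatment-free window."""

    k_per_hour: float
    doubling_time_days: float
    rvalue: float
    window: tuple[float, float]

    @classmethod
    def from_slope(cls, k: float, rvalue: float, window) -> "GrowthFit":
        td = math.log(2) / k / 24.0 if k > 0 else math.inf
        return cls(k_per_hour=k, doubling_time_days=td, rvalue=rvalue, window=tuple(window))


def fit_growth_rate(
    result: SimulationResult, window: tuple[float, float] = (48.0, None)
) -> GrowthFit:
    """Fit k (per hour) as the slope of ln(total cells) vs time.

    The window start defaults to 48 h to skip any residual initialization
    transient; the end defaults to the horizon.  The window must lie in a
    treatment-free interval for the fit to measure free growth.
    """
    lo, hi = window
    hi = result.horizon_h if hi is None else hi
    d = result.data[(result.data["hour"] >= lo) & (result.data["hour"] <= hi)]
    if len(d) < 3:
        raise ValueError("fit window contains fewer than 3 records")
    totals = d["total"].to_numpy()
    if (totals <= 0).any():
        raise ValueError("non-positive population in fit window")
    fit = stats.linregress(d["hour"].to_numpy(), np.log(totals))
    return GrowthFit.from_slope(float(fit.slope), float(fit.rvalue), (lo, hi))


def composition_at(result: SimulationResult, hour: int) -> CompositionSummary:
    """Subpopulation percentages of the total population at a given hour."""
    row = result.row_at(hour)
    t = float(row["total"])
    if t <= 0:
        raise ValueError(f"empty tumor at hour {hour}")
    return CompositionSummary(
        proliferating=100 * row["proliferating"] / t,
        dormant=100 * row["dormant"] / t,
        stem=100 * row["stem"] / t,
        limp=100 * row["limp"] / t,
        differentiated=100 * row["differentiated"] / t,
        dead=100 * row["dead"] / t,
    )
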