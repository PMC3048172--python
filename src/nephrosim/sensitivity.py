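"""Parameter sensitivity analyses: one-at-a-time ranking and dyad grids.

Two outputs are studied: the free-growth rate constant k (per hour) and
the percentage volume reduction after the standard chemotherapy course.
The one-at-a-time sweep varies a single parameter over a plausible range
with all others at their base values and summarizes the response curve
with a scale-free sorting criterion; ranking the twelve tumor-dynamics
parameters by this criterion orders the underlying biological mechanisms
by their impact on therapy outcome.  Two-parameter ("dyad") grids map the
joint response surface, masking parameter combinations that are not
biologically admissible (non-growing tumors for the free-growth output,
non-responding tumors for the reduction output).

``CKR_total`` is a dependent parameter; it is swept by scaling both
individual cell kill ratios proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lattice import run_simulation
from .cytokinetics import intrinsic_growth_rate
from .metrics import fit_growth_rate, volume_reduction
from .parameters import REFERENCE_VALUES, TumorParameters
from .pharmacodynamics import default_siop_schedule

__all__ = [
    "SweepSpec",
    "RankingResult",
    "DEFAULT_RANGES",
    "oat_sweep",
    "sorting_criterion",
    "rank_parameters",
    "dyad_grid",
    "DyadGrid",
]

SWEEPABLE = tuple(REFERENCE_VALUES) + ("CKR_total",)

#: Default plausible sweep ranges.  Parameters that differ between the
#: published virtual-tumor scenarios take the span of those values widened
#: by 20% (multiplicatively for scale parameters, additively for bounded
#: fractions, clipped to validity); parameters the scenarios never vary
#: are perturbed +/-50% around the reference value.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "Tc": (23 / 1.2, 55 * 1.2),
    "T_G0": (40 / 1.2, 96 * 1.2),
    "T_N": (20 / 1.2, 120 * 1.2),
    "T_A": (3.0, 9.0),
    "R_A": (0.0008 / 1.2, 0.001 * 1.2),
    "R_ADiff": (0.003 / 1.2, 0.05 * 1.2),
    "R_NDiff": (0.001 / 1.2, 0.05 * 1.2),
    "P_G0toG1": (0.005, 0.015),
    "N_LIMP": (2, 5),
    "P_sym": (0.45 - 0.2 * 0.31, 0.76 + 0.2 * 0.31),
    "P_sleep": (0.28 - 0.2 * 0.12, 0.40 + 0.2 * 0.12),
    "CKR_total": (0.5 - 0.2 * 0.2, 0.7 + 0.2 * 0.2),
}


@dataclass
class SweepSpec:
    """Specification of a sensitivity study.

    ``selector`` chooses the output: ``"volume_reduction"`` (percent, after
    the standard course, evaluated ``eval_hour`` hours into the run) or
    ``"growth_rate"`` (k per hour from a treatment-free run).
    """

    base: TumorParameters = field(default_factory=TumorParameters)
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    n_points: int = 5
    selector: str = "volume_reduction"
    eval_hour: int = 648
    free_growth_hours: int = 500

    def __post_init__(self):
        if self.selector not in ("volume_reduction", "growth_rate"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        for name, (lo, hi) in self.ranges.items():
            if name not in SWEEPABLE:
                raise ValueError(f"unknown parameter {name!r}")
            if lo > hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def params_with(base: TumorParameters, name: str, value: float) -> TumorParameters:
    """Base parameters with one (possibly dependent) parameter replaced."""
    if name == "CKR_total":
        scale = value / base.CKR_total
        return base.replace(
            CKR_VCR=min(1.0, base.CKR_VCR * scale), CKR_ACT=min(1.0, base.CKR_ACT * scale)
        )
    if name == "N_LIMP":
        return base.replace(N_LIMP=max(0, int(round(value))))
    return base.replace(**{name: float(value)})


def _evaluate(spec: SweepSpec, params: TumorParameters) -> float:
    if spec.selector == "growth_rate":
        result = run_simulation(params, horizon_h=spec.free_growth_hours, mode="wellmixed")
        return fit_growth_rate(result).k_per_hour
    schedule = default_siop_schedule(params=params)
    result = run_simulation(
        params, schedule=schedule, horizon_h=spec.eval_hour, mode="wellmixed"
    )
    return volume_reduction(result.volume_at(0), result.volume_at(spec.eval_hour))


def oat_sweep(spec: SweepSpec, parameter: str) -> pd.DataFrame:
    """One-at-a-time sweep of one parameter; all others stay at base values.

    Returns a data frame with columns ``value``, ``output`` and ``ok``;
    a failed simulation at a grid point is recorded as missing, not fatal.
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown parameter {parameter!r}")
    lo, hi = spec.ranges.get(parameter, DEFAULT_RANGES[parameter])
    rows = []
    for value in np.linspace(lo, hi, spec.n_points):
        try:
            out = _evaluate(spec, params_with(spec.base, parameter, value))
            rows.append({"value": float(value), "output": out, "ok": True})
        except Exception:
            rows.append({"value": float(value), "output": np.nan, "ok": False})
    return pd.DataFrame(rows)


def sorting_criterion(curve: pd.DataFrame) -> float:
    """Scale-free sensitivity score of a sweep curve.

    SC = (max - min of the output over the sweep) / mean(|output|); zero
    if and only if the output is constant over the range (and defined as
    zero for an identically-zero curve).  Invariant to reversing the sweep
    direction and to rescaling the output.
    """
    valid = curve[curve["ok"]] if "ok" in curve else curve
    out = valid["output"].to_numpy(dtype=float)
    out = out[np.isfinite(out)]
    if len(out) < 3:
        raise ValueError("sorting criterion needs at least 3 valid points")
    spread = float(out.max() - out.min())
    denom = float(np.mean(np.abs(out)))
    if denom == 0.0:
        return 0.0
    return spread / denom


@dataclass
class RankingResult:
    """Parameters ordered by nonincreasing sorting criterion."""

    ranking: list[tuple[str, float]]
    curves: dict[str, pd.DataFrame]

    @property
    def ordered_parameters(self) -> list[str]:
        return [name for name, _ in self.ranking]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["parameter", "SC"])


def rank_parameters(spec: SweepSpec, parameters=None) -> RankingResult:
    """Rank parameters by the sorting criterion of their one-at-a-time sweep.

    Ties (e.g. several insensitive parameters at SC = 0) keep the input
    order, which is stable and deterministic.
    """
    names = list(parameters) if parameters is not None else list(spec.ranges)
    scores = []
    curves = {}
    for name in names:
        curve = oat_sweep(spec, name)
        curves[name] = curve
        scores.append((name, sorting_criterion(curve)))
    order = sorted(range(len(scores)), key=lambda i: -scores[i][1])
    return RankingResult(ranking=[scores[i] for i in order], curves=curves)


@dataclass
class DyadGrid:
    """Joint response of two parameters on a rectangular grid."""

    param_x: str
    param_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    growth_rate: np.ndarray  # k per hour, shape (n_y, n_x)
    reduction: np.ndarray  # percent, shape (n_y, n_x)
    valid: np.ndarray  # admissible region mask

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for iy, y in enumerate(self.y_values):
            for ix, x in enumerate(self.x_values):
                rows.append(
                    {
                        self.param_x: x,
                        self.param_y: y,
                        "growth_rate": self.growth_rate[iy, ix],
                        "reduction": self.reduction[iy, ix],
                        "valid": bool(self.valid[iy, ix]),
                    }
                )
        return pd.DataFrame(rows)


def dyad_grid(
    base: TumorParameters,
    param_x: str,
    range_x: tuple[float, float],
    param_y: str,
    range_y: tuple[float, float],
    n_x: int = 5,
    n_y: int = 5,
    eval_hour: int = 648,
) -> DyadGrid:
    """Grids of free-growth k and post-therapy reduction over two parameters.

    Grid points whose tumor does not grow monotonically in the free-growth
    regime (k <= 0) or does not shrink under therapy (reduction <= 0) are
    masked as inadmissible; failures are absorbed into the mask.
    """
    if n_x < 5 or n_y < 5:
        raise ValueError("dyad grids need at least 5 points per axis")
    xs = np.linspace(*range_x, n_x)
    ys = np.linspace(*range_y, n_y)
    k = np.full((n_y, n_x), np.nan)
    red = np.full((n_y, n_x), np.nan)
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            try:
                p = params_with(params_with(base, param_x, x), param_y, y)
                k[iy, ix] = intrinsic_growth_rate(p).k_per_hour
                schedule = default_siop_schedule(params=p)
                result = run_simulation(p, schedule=schedule, horizon_h=eval_hour)
                red[iy, ix] = volume_reduction(result.volume_at(0), result.volume_at(eval_hour))
            except Exception:
                pass
    valid = np.isfinite(k) & np.isfinite(red) & (k > 0) & (red > 0)
    return DyadGrid(param_x, param_y, xs, ys, k, red, valid)
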