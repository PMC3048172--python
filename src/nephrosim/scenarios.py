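"""Packaged virtual-tumor scenarios and table reproduction.

Five scenarios are shipped: the "typical" tumor (all parameters at their
reference values) and four clinically adapted virtual tumors T1-T4 that
fit the imaging-measured volume reduction of a real nephroblastoma case.
T1 perturbs the stem-division symmetry and dormancy entry (P_sym,
P_sleep), T2 the cell-cycle duration and spontaneous apoptosis (Tc, R_A),
T3 only the cell kill ratios, and T4 combines all perturbations needed to
also match the post-surgery histology (blastemal type: negligible
differentiated component, large necrotic component).

:func:`reproduce_tables` runs all scenarios end to end and writes the
initial- and final-characteristics tables together with a per-cell
comparison against the packaged published reference values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cytokinetics import equilibrium_composition, intrinsic_growth_rate
from .lattice import run_simulation
from .metrics import SimulationResult, composition_at, volume_reduction
from .parameters import TumorParameters, build_parameters
from .pharmacodynamics import TreatmentSchedule, DrugAdministration, default_siop_schedule

__all__ = [
    "Scenario",
    "SCENARIO_PARAMETERS",
    "load_scenario",
    "scenario_names",
    "run_scenario",
    "reproduce_tables",
]

#: Parameter values of the packaged scenarios (only deviations from the
#: reference column are listed; the "typical" tumor deviates in nothing).
SCENARIO_PARAMETERS: dict[str, dict[str, float]] = {
    "typical": {},
    "T1": {"P_sym": 0.71, "P_sleep": 0.40},
    "T2": {"Tc": 40.0, "R_A": 0.0008},
    "T3": {"CKR_VCR": 0.36, "CKR_ACT": 0.34},
    "T4": {
        "Tc": 55.0,
        "T_G0": 40.0,
        "T_N": 120.0,
        "R_ADiff": 0.05,
        "R_NDiff": 0.05,
        "P_sym": 0.76,
        "P_sleep": 0.36,
        "CKR_VCR": 0.33,
        "CKR_ACT": 0.22,
    },
}

#: Final characteristics are read 1 day after completion of therapy for the
#: typical tumor and 3 days after completion for T1-T4 (last administration
#: at day 24; hours from simulation start).
FINAL_EVAL_HOUR = {"typical": 600, "T1": 648, "T2": 648, "T3": 648, "T4": 648}

#: Published reference characteristics of the five virtual tumors
#: (initial state; percentages of the total population, k per hour,
#: doubling time in days).  Used only for reporting deviations.
PUBLISHED_INITIAL = pd.DataFrame(
    {
        "typical": [0.001, 29, 14, 18, 12, 20, 62, 6],
        "T1": [0.0004, 72, 15, 36, 32, 19, 40, 9],
        "T2": [0.0004, 72, 19, 16, 14, 21, 59, 6],
        "T3": [0.001, 29, 14, 18, 12, 20, 62, 6],
        "T4": [0.0014, 21, 37, 14, 35, 16, 2, 47],
    },
    index=[
        "growth_rate_k_per_h",
        "doubling_time_days",
        "proliferating_pct",
        "dormant_pct",
        "stem_pct",
        "limp_pct",
        "differentiated_pct",
        "dead_pct",
    ],
)

#: Published reference characteristics after therapy (volume reduction in
#: percent and final composition percentages).
PUBLISHED_FINAL = pd.DataFrame(
    {
        "typical": [56, 7, 13, 7, 13, 74, 6],
        "T1": [72, 10, 27, 23, 14, 55, 8],
        "T2": [72, 11, 11, 8, 14, 73, 5],
        "T3": [72, 6, 11, 7, 10, 78, 5],
        "T4": [73, 30, 12, 29, 13, 1, 57],
    },
    index=[
        "volume_reduction_pct",
        "proliferating_pct",
        "dormant_pct",
        "stem_pct",
        "limp_pct",
        "differentiated_pct",
        "dead_pct",
    ],
)


@dataclass(frozen=True)
class Scenario:
    """A fully resolved simulation scenario."""

    name: str
    params: TumorParameters
    schedule: TreatmentSchedule
    initial_volume_cm3: float = 100.0
    baseline_hour: int = 0
    eval_hour: int = 648

    def horizon_h(self) -> int:
        return max(int(self.schedule.horizon_h), self.eval_hour)


def scenario_names() -> list[str]:
    return list(SCENARIO_PARAMETERS)


def _packaged_scenario(name: str, overrides: dict | None = None) -> Scenario:
    values = dict(SCENARIO_PARAMETERS[name])
    values.update(overrides or {})
    params = build_parameters(values)
    return Scenario(
        name=name,
        params=params,
        schedule=default_siop_schedule(params=params),
        eval_hour=FINAL_EVAL_HOUR[name],
    )


def load_scenario(name_or_path: str, overrides: dict | None = None) -> Scenario:
    """Resolve a packaged scenario name or a YAML configuration file.

    A configuration file is a flat document of parameter names (as in
    :data:`nephrosim.parameters.REFERENCE_VALUES`) plus the optional keys
    ``name``, ``base_scenario``, ``initial_volume_cm3``, ``eval_hour`` and
    ``schedule`` (a list of ``{day, ckr_vcr, ckr_act}`` entries with an
    optional ``horizon_days``).  Unspecified parameters take the values of
    the base scenario (default: the reference column).
    """
    if name_or_path in SCENARIO_PARAMETERS:
        return _packaged_scenario(name_or_path, overrides)
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(
            f"unknown scenario {name_or_path!r}: not one of {scenario_names()} "
            "and not an existing config file"
        )
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"malformed scenario config {path}")
    cfg.update(overrides or {})
    base = cfg.pop("base_scenario", "typical")
    if base not in SCENARIO_PARAMETERS:
        raise ValueError(f"unknown base_scenario {base!r}")
    name = cfg.pop("name", path.stem)
    volume = float(cfg.pop("initial_volume_cm3", 100.0))
    eval_hour = int(cfg.pop("eval_hour", FINAL_EVAL_HOUR[base]))
    schedule_cfg = cfg.pop("schedule", None)
    values = dict(SCENARIO_PARAMETERS[base])
    values.update(cfg)
    params = build_parameters(values)
    if schedule_cfg is None:
        schedule = default_siop_schedule(params=params)
    else:
        horizon_h = 24.0 * float(schedule_cfg.get("horizon_days", 28))
        admins = tuple(
            DrugAdministration(
                time_h=24.0 * float(e["day"]),
                ckr_vcr=float(e.get("ckr_vcr", 0.0)),
                ckr_act=float(e.get("ckr_act", 0.0)),
            )
            for e in schedule_cfg.get("administrations", [])
        )
        schedule = TreatmentSchedule(administrations=admins, horizon_h=horizon_h)
    return Scenario(
        name=name,
        params=params,
        schedule=schedule,
        initial_volume_cm3=volume,
        eval_hour=eval_hour,
    )


def run_scenario(scenario: Scenario, mode: str = "wellmixed") -> SimulationResult:
    """Run one scenario over its full horizon."""
    return run_simulation(
        scenario.params,
        schedule=scenario.schedule,
        initial_volume_cm3=scenario.initial_volume_cm3,
        mode=mode,
        horizon_h=scenario.horizon_h(),
        scenario=scenario.name,
    )


def reproduce_tables(out_dir=None, scenarios=None) -> dict[str, pd.DataFrame]:
    """Run all packaged scenarios and tabulate their characteristics.

    Returns (and optionally writes as CSV) an initial-characteristics
    table, a final-characteristics table and a comparison against the
    packaged published reference values with per-cell deviations.
    """
    names = scenarios or scenario_names()
    initial = {}
    final = {}
    for name in names:
        sc = load_scenario(name)
        growth = intrinsic_growth_rate(sc.params)
        comp0, _ = equilibrium_composition(sc.params)
        result = run_scenario(sc)
        comp_f = composition_at(result, sc.eval_hour)
        red = volume_reduction(
            result.volume_at(sc.baseline_hour), result.volume_at(sc.eval_hour)
        )
        initial[name] = [
            growth.k_per_hour,
            growth.doubling_time_days,
            comp0.proliferating,
            comp0.dormant,
            comp0.stem,
            comp0.limp,
            comp0.differentiated,
            comp0.dead,
        ]
        final[name] = [
            red,
            comp_f.proliferating,
            comp_f.dormant,
            comp_f.stem,
            comp_f.limp,
            comp_f.differentiated,
            comp_f.dead,
        ]
    initial_df = pd.DataFrame(initial, index=PUBLISHED_INITIAL.index)
    final_df = pd.DataFrame(final, index=PUBLISHED_FINAL.index)
    deviation_initial = initial_df - PUBLISHED_INITIAL[initial_df.columns]
    deviation_final = final_df - PUBLISHED_FINAL[final_df.columns]
    tables = {
        "initial": initial_df,
        "final": final_df,
        "deviation_initial": deviation_initial,
        "deviation_final": deviation_final,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        initial_df.to_csv(out / "initial_characteristics.csv")
        final_df.to_csv(out / "final_characteristics.csv")
        deviation_initial.to_csv(out / "deviation_initial.csv")
        deviation_final.to_csv(out / "deviation_final.csv")
    return tables
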