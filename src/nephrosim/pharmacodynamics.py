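"""Chemotherapy pharmacodynamics: treatment schedules and cell-kill rules.

A drug administration instantaneously "marks" a fraction of eligible cells
as lethally hit; the cell kill ratio (CKR = 1 - survival fraction) gives
that fraction per administration.  Vincristine binds cells in all cycling
phases and kills at the end of M; actinomycin-D binds cells in all phases
including G0 and kills at the end of S.  When both drugs are given at the
same instant their effect is additive: a fraction
``min(1, CKR_VCR + CKR_ACT)`` of every cycling compartment is marked,
attributed to each drug in proportion to its individual CKR.  Dormant (G0)
cells are only affected by actinomycin-D.  Marking conserves the total
cell count; hit cells stop dividing and traverse a rudimentary cycle to
apoptotic death (advanced each step by :func:`step_hit_cells`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cytokinetics import CellStateVector, _age_hit_cells
from .parameters import PHASES, TumorParameters

__all__ = [
    "DrugAdministration",
    "TreatmentSchedule",
    "default_siop_schedule",
    "apply_administration",
    "step_hit_cells",
    "DEFAULT_ADMINISTRATION_DAYS",
    "DEFAULT_ACT_DAYS",
]

#: Weekly vincristine administrations of the simulated preoperative regimen
#: (days from simulation start; day 0 is the first imaging instant).
DEFAULT_ADMINISTRATION_DAYS = (3, 10, 17, 24)
#: Administration days that also include actinomycin-D.  The preoperative
#: AV regimen gives vincristine weekly for four weeks but actinomycin-D
#: only in weeks 1 and 3.
DEFAULT_ACT_DAYS = (3, 17)
#: Simulation horizon: 28 days (the second imaging instant).
DEFAULT_HORIZON_H = 28 * 24


@dataclass(frozen=True)
class DrugAdministration:
    """One combined bolus administration at a given hour."""

    time_h: float
    ckr_vcr: float = 0.0
    ckr_act: float = 0.0

    def __post_init__(self):
        if self.time_h < 0:
            raise ValueError("administration time must be >= 0")
        for name in ("ckr_vcr", "ckr_act"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def ckr_total(self) -> float:
        return min(1.0, self.ckr_vcr + self.ckr_act)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered drug administrations within a simulation horizon."""

    administrations: tuple[DrugAdministration, ...]
    horizon_h: float = DEFAULT_HORIZON_H

    def __post_init__(self):
        times = [a.time_h for a in self.administrations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("administration times must be strictly increasing")
        if times and times[-1] > self.horizon_h:
            raise ValueError("all administrations must lie within the horizon")

    def doses_at(self, hour: float) -> list[DrugAdministration]:
        return [a for a in self.administrations if a.time_h == hour]

    @property
    def last_administration_h(self) -> float:
        return self.administrations[-1].time_h if self.administrations else 0.0


def default_siop_schedule(
    ckr_vcr: float | None = None,
    ckr_act: float | None = None,
    params: TumorParameters | None = None,
    administration_days=DEFAULT_ADMINISTRATION_DAYS,
    act_days=DEFAULT_ACT_DAYS,
    horizon_h: float = DEFAULT_HORIZON_H,
) -> TreatmentSchedule:
    """The simulated preoperative vincristine + actinomycin-D schedule.

    Four administrations at days 3, 10, 17 and 24 with vincristine at
    every instant and actinomycin-D at the week-1 and week-3 instants;
    horizon day 28.  CKRs default to the given parameter set's (or the
    reference) values.
    """
    if params is None:
        params = TumorParameters()
    cv = params.CKR_VCR if ckr_vcr is None else ckr_vcr
    ca = params.CKR_ACT if ckr_act is None else ckr_act
    admins = tuple(
        DrugAdministration(
            time_h=day * 24.0,
            ckr_vcr=cv,
            ckr_act=ca if day in act_days else 0.0,
        )
        for day in administration_days
    )
    return TreatmentSchedule(administrations=admins, horizon_h=horizon_h)


def apply_administration(
    state: CellStateVector, dose: DrugAdministration
) -> tuple[CellStateVector, dict[str, float]]:
    """Mark lethally hit cells at the instant of a drug administration.

    From every cycling (G1/S/G2/M) stem and LIMP compartment a fraction
    ``min(1, ckr_vcr + ckr_act)`` is moved to the hit compartments,
    preserving lineage, phase and age; the vincristine share is
    ``ckr_vcr / (ckr_vcr + ckr_act)``.  From every dormant compartment a
    fraction ``ckr_act`` is moved to the actinomycin-hit pool (it exits G0
    on the next step and traverses the rudimentary G1 + S).  Differentiated
    and dead cells are unaffected.  Returns the new state and a ledger of
    marked mass per drug; the total cell count is conserved exactly.
    """
    total_ckr = dose.ckr_total
    new = state.copy()
    marked = {"vcr": 0.0, "act": 0.0, "act_g0": 0.0}
    if total_ckr == 0.0:
        return new, marked
    denom = dose.ckr_vcr + dose.ckr_act
    f_vcr = dose.ckr_vcr / denom
    L = state.layout
    for key, lin, ph in L.cycling_keys():
        sl = L.slices[key]
        m = new.core[sl] * total_ckr
        new.core[sl] -= m
        width = sl.stop - sl.start
        new.hit[(lin, "vcr")][ph][:width] += m * f_vcr
        new.hit[(lin, "act")][ph][:width] += m * (1.0 - f_vcr)
        marked["vcr"] += float(m.sum() * f_vcr)
        marked["act"] += float(m.sum() * (1.0 - f_vcr))
    if dose.ckr_act > 0.0:
        for key, lin in L.g0_keys():
            sl = L.slices[key]
            m = new.core[sl] * dose.ckr_act
            new.core[sl] -= m
            new.hit_g0[lin] += float(m.sum())
            marked["act_g0"] += float(m.sum())
    return new, marked


def step_hit_cells(state: CellStateVector) -> tuple[CellStateVector, float]:
    """Advance hit compartments one hour; deaths enter the apoptotic pool.

    Provided for stand-alone use; during a simulation the engine step
    (:func:`nephrosim.cytokinetics.step_state`) performs the same update as
    part of its fixed intra-step order.
    """
    new = state.copy()
    died = _age_hit_cells(new)
    new.core[state.layout.apo.start] += died
    return new, died
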