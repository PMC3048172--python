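"""Tumor-dynamics parameters of the cytokinetic model.

The model describes a tumor cell population structured into stem cells
(unlimited mitotic potential), LIMP cells (LImited Mitotic Potential,
i.e. committed progenitors), terminally differentiated cells, and
apoptotic / necrotic cell remnants awaiting clearance.  Twelve parameters
govern the dynamics; the combined cell kill ratio ``CKR_total`` is a
dependent quantity (additive drug effect, capped at 1).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass

__all__ = [
    "PHASES",
    "DEFAULT_PHASE_SPLIT",
    "REFERENCE_VALUES",
    "TumorParameters",
    "build_parameters",
    "reference_parameters",
]

#: Cycling phases in traversal order.
PHASES = ("G1", "S", "G2", "M")

#: Default fractions of the cell-cycle time Tc spent in G1/S/G2/M.  The split
#: is not identifiable from population-level growth data (only the total Tc
#: matters for the growth rate); these are typical human cell-cycle
#: proportions and are configurable per parameter set.
DEFAULT_PHASE_SPLIT = (0.40, 0.39, 0.13, 0.08)

#: Reference values of the twelve tumor-dynamics parameters (typical
#: nephroblastoma; durations in hours, rates per hour, fractions in [0, 1]).
REFERENCE_VALUES: dict[str, float] = {
    "Tc": 23.0,
    "T_G0": 96.0,
    "T_N": 20.0,
    "T_A": 6.0,
    "R_A": 0.001,
    "R_ADiff": 0.003,
    "R_NDiff": 0.001,
    "P_G0toG1": 0.01,
    "N_LIMP": 3,
    "P_sym": 0.45,
    "P_sleep": 0.28,
    "CKR_VCR": 0.3,
    "CKR_ACT": 0.2,
}

_DURATIONS = ("Tc", "T_G0", "T_N", "T_A")
_RATES = ("R_A", "R_ADiff", "R_NDiff")
_FRACTIONS = ("P_G0toG1", "P_sym", "P_sleep", "CKR_VCR", "CKR_ACT")


@dataclass(frozen=True)
class TumorParameters:
    """Validated tumor-dynamics parameter set.

    Attributes
    ----------
    Tc : float
        Cell-cycle duration in hours.
    T_G0 : float
        Dormant (G0) phase duration in hours: the time a cell may remain
        dormant before dying through necrosis.
    T_N : float
        Time for necrosis products to be cleared from the tumor, hours.
    T_A : float
        Time for apoptosis products to be cleared from the tumor, hours.
    R_A : float
        Spontaneous apoptosis rate of living stem and LIMP cells, per hour.
    R_ADiff : float
        Apoptosis rate of terminally differentiated cells, per hour.
    R_NDiff : float
        Necrosis rate of terminally differentiated cells, per hour.
    P_G0toG1 : float
        Fraction of cells leaving the G0 compartment that re-enter the
        cycle at G1 (the remainder die through necrosis).
    N_LIMP : int
        Maximum number of mitoses a LIMP cell can perform before its
        offspring become terminally differentiated.
    P_sym : float
        Fraction of stem-cell mitoses that are symmetric (two stem
        daughters); the remainder yield one stem and one LIMP daughter.
    P_sleep : float
        Fraction of post-mitotic (stem or LIMP) daughters that enter G0.
    CKR_VCR, CKR_ACT : float
        Cell kill ratios (1 - survival fraction) per administration of
        vincristine and actinomycin-D respectively.
    phase_split : tuple of float
        Fractions of Tc assigned to G1, S, G2, M; must sum to 1.
    """

    Tc: float = REFERENCE_VALUES["Tc"]
    T_G0: float = REFERENCE_VALUES["T_G0"]
    T_N: float = REFERENCE_VALUES["T_N"]
    T_A: float = REFERENCE_VALUES["T_A"]
    R_A: float = REFERENCE_VALUES["R_A"]
    R_ADiff: float = REFERENCE_VALUES["R_ADiff"]
    R_NDiff: float = REFERENCE_VALUES["R_NDiff"]
    P_G0toG1: float = REFERENCE_VALUES["P_G0toG1"]
    N_LIMP: int = int(REFERENCE_VALUES["N_LIMP"])
    P_sym: float = REFERENCE_VALUES["P_sym"]
    P_sleep: float = REFERENCE_VALUES["P_sleep"]
    CKR_VCR: float = REFERENCE_VALUES["CKR_VCR"]
    CKR_ACT: float = REFERENCE_VALUES["CKR_ACT"]
    phase_split: tuple[float, float, float, float] = DEFAULT_PHASE_SPLIT

    def __post_init__(self) -> None:
        for name in _DURATIONS:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in _RATES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in _FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (isinstance(self.N_LIMP, int) and self.N_LIMP >= 0):
            raise ValueError(f"N_LIMP must be a nonnegative integer, got {self.N_LIMP}")
        if len(self.phase_split) != 4 or any(f <= 0 for f in self.phase_split):
            raise ValueError("phase_split must be four positive fractions")
        if abs(sum(self.phase_split) - 1.0) > 1e-12:
            raise ValueError(f"phase_split must sum to 1, got {sum(self.phase_split)!r}")
        # hourly per-cell loss rates must not exceed 1 (one-hour time step)
        if self.R_A > 1:
            raise ValueError("R_A must be <= 1 per hour")
        if self.R_ADiff + self.R_NDiff > 1:
            raise ValueError("R_ADiff + R_NDiff must be <= 1 per hour")

    @property
    def CKR_total(self) -> float:
        """Combined cell kill ratio (additive drug effect, capped at 1)."""
        return min(1.0, self.CKR_VCR + self.CKR_ACT)

    def phase_durations(self) -> dict[str, int]:
        """Integer phase durations (hours) from Tc and the phase split.

        Each phase gets ``round(fraction * Tc)`` hours with a floor of one
        hour; any rounding residue is absorbed by G1 so the total equals
        ``round(Tc)``.
        """
        d = [max(1, round(f * self.Tc)) for f in self.phase_split]
        d[0] += round(self.Tc) - sum(d)
        if d[0] < 1:
            raise ValueError(f"Tc={self.Tc} too short for phase split {self.phase_split}")
        return dict(zip(PHASES, d))

    def replace(self, **changes) -> "TumorParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        """The twelve independent parameters as a flat mapping."""
        d = {k: getattr(self, k) for k in REFERENCE_VALUES}
        return d


def build_parameters(raw_values: Mapping[str, float] | None = None, **kwargs) -> TumorParameters:
    """Build a validated :class:`TumorParameters` from a flat mapping.

    Missing parameters default to the reference values.  ``CKR_total`` is a
    dependent quantity and is rejected as an input; set ``CKR_VCR`` and
    ``CKR_ACT`` instead.

    Raises
    ------
    ValueError
        On unknown keys or out-of-range values (naming the parameter).
    """
    values = dict(raw_values or {})
    values.update(kwargs)
    allowed = set(REFERENCE_VALUES) | {"phase_split"}
    unknown = set(values) - allowed
    if unknown:
        raise ValueError(
            f"unknown parameter(s): {sorted(unknown)}; expected a subset of {sorted(allowed)}"
        )
    if "N_LIMP" in values:
        n = values["N_LIMP"]
        if float(n) != int(n):
            raise ValueError(f"N_LIMP must be an integer, got {n}")
        values["N_LIMP"] = int(n)
    if "phase_split" in values:
        values["phase_split"] = tuple(values["phase_split"])
    return TumorParameters(**values)


def reference_parameters() -> TumorParameters:
    """The reference ('typical tumor') parameter set."""
    return TumorParameters()
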