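"""Spatial discretization: geometrical-cell mesh and the simulation engine.

The tumor is discretized into a 3D cubic mesh of geometrical cells (GCs),
each initially holding ``nbc = cell_density * gc_volume`` biological cells
(1e6 cells for the default 1 mm^3 GC at 1e9 cells/cm^3) distributed at the
equilibrium composition, which avoids artificial initialization transients.
Every hour the mesh undergoes two scans: the first updates the state of
each GC with the cytokinetic rules, the second rebalances the mesh —
over-full GCs shed half their content outward (tumor expansion) and
under-populated GCs dissolve into a neighbor (tumor shrinkage) — so each
GC's population stays between configurable bounds around ``nbc``.

Because the cytokinetic dynamics are density-independent, a homogeneous
tumor is equivalently simulated in a fast well-mixed (0-D) mode that
aggregates the whole tumor into a single state vector; the lattice mode
exists for geometry-dependent studies and is validated against the
well-mixed aggregate.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytokinetics import (
    CellStateVector,
    StateLayout,
    StepLedger,
    equilibrium_composition,
    step_state,
)
from .metrics import SimulationResult
from .parameters import TumorParameters
from .pharmacodynamics import TreatmentSchedule, apply_administration

__all__ = ["TumorMesh", "initialize_mesh", "scan_update", "rebalance", "run_simulation"]

#: 6-connectivity neighbor offsets in the fixed tie-break order.
NEIGHBOR_OFFSETS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


@dataclass
class TumorMesh:
    """3D mesh of geometrical cells, each holding a population state."""

    cells: dict[tuple[int, int, int], CellStateVector]
    params: TumorParameters
    layout: StateLayout
    cell_density: float = 1e9
    gc_volume: float = 1e-3
    max_factor: float = 1.5
    min_factor: float = 0.5
    overrides: dict[tuple[int, int, int], TumorParameters] = field(default_factory=dict)

    @property
    def nbc(self) -> float:
        """Typical initial biological-cell content of one GC."""
        return self.cell_density * self.gc_volume

    @property
    def gc_count(self) -> int:
        return len(self.cells)

    def total(self) -> float:
        return sum(gc.total() for gc in self.cells.values())

    def aggregate_counts(self) -> dict[str, float]:
        keys = None
        agg: dict[str, float] = {}
        for gc in self.cells.values():
            c = gc.counts()
            if keys is None:
                keys = c.keys()
                agg = dict.fromkeys(keys, 0.0)
            for k in keys:
                agg[k] += c[k]
        return agg

    def aggregate_state(self) -> CellStateVector:
        out = CellStateVector.zeros(self.layout)
        for gc in self.cells.values():
            out.add_(gc)
        return out

    def params_at(self, coord) -> TumorParameters:
        return self.overrides.get(coord, self.params)

    def set_override(self, coord, params: TumorParameters) -> None:
        """Attach per-region parameter values to one GC.

        Overrides must keep the compartment layout (phase and residence
        durations) of the base parameter set; rates and fractions may vary.
        """
        if not StateLayout(params).compatible_with(self.layout):
            raise ValueError(
                "override changes compartment durations; only rates/fractions may differ per region"
            )
        self.overrides[coord] = params


def _connected(coords: set[tuple[int, int, int]]) -> bool:
    if not coords:
        return True
    seen = {next(iter(coords))}
    queue = deque(seen)
    while queue:
        c = queue.popleft()
        for d in NEIGHBOR_OFFSETS:
            nb = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
            if nb in coords and nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return len(seen) == len(coords)


def _quasi_sphere(n: int) -> list[tuple[int, int, int]]:
    """The n lattice sites nearest the origin (deterministic tie-break)."""
    r = int(math.ceil((3 * n / (4 * math.pi)) ** (1 / 3))) + 2
    sites = [
        (x, y, z)
        for x in range(-r, r + 1)
        for y in range(-r, r + 1)
        for z in range(-r, r + 1)
    ]
    sites.sort(key=lambda c: (c[0] ** 2 + c[1] ** 2 + c[2] ** 2, c))
    return sites[:n]


def initialize_mesh(
    params: TumorParameters,
    initial_volume_cm3: float | None = None,
    mask: np.ndarray | None = None,
    cell_density: float = 1e9,
    gc_volume: float = 1e-3,
    max_factor: float = 1.5,
    min_factor: float = 0.5,
) -> TumorMesh:
    """Build a mesh from a scalar volume (quasi-spherical) or a 3D mask.

    Every GC is populated with ``nbc`` cells at the equilibrium
    composition of the parameter set, so free growth starts without any
    composition transient.
    """
    if (initial_volume_cm3 is None) == (mask is None):
        raise ValueError("provide exactly one of initial_volume_cm3 or mask")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 3 or not mask.any():
            raise ValueError("mask must be a nonempty 3D boolean array")
        coords = [tuple(int(i) for i in c) for c in np.argwhere(mask)]
        if not _connected(set(coords)):
            raise ValueError("mask must form one connected component")
    else:
        if initial_volume_cm3 <= 0:
            raise ValueError("initial volume must be > 0")
        coords = _quasi_sphere(int(math.ceil(initial_volume_cm3 / gc_volume)))

    _, eq_state = equilibrium_composition(params)
    nbc = cell_density * gc_volume
    layout = eq_state.layout
    cells = {c: eq_state * nbc for c in coords}
    return TumorMesh(
        cells=cells,
        params=params,
        layout=layout,
        cell_density=cell_density,
        gc_volume=gc_volume,
        max_factor=max_factor,
        min_factor=min_factor,
    )


def scan_update(mesh: TumorMesh, rng: np.random.Generator | None = None) -> StepLedger:
    """First mesh scan: advance every GC one hour with the cytokinetic rules.

    Per-region parameter overrides are honored.  Returns the mesh-wide
    aggregated step ledger.
    """
    agg = StepLedger()
    for coord in sorted(mesh.cells):
        new, led = step_state(mesh.cells[coord], mesh.params_at(coord), rng=rng)
        mesh.cells[coord] = new
        for f in (
            "births",
            "spontaneous_apoptosis",
            "diff_apoptosis",
            "diff_necrosis",
            "g0_necrosis",
            "chemo_deaths",
            "cleared_apoptotic",
            "cleared_necrotic",
        ):
            setattr(agg, f, getattr(agg, f) + getattr(led, f))
    return agg


def _nearest_empty_step(mesh: TumorMesh, start) -> tuple[int, int, int]:
    """First step of the shortest path from an occupied GC to an empty site.

    Breadth-first search over the lattice with the fixed neighbor order;
    ties are therefore broken deterministically (+x, -x, +y, -y, +z, -z).
    """
    first_step = {}
    queue = deque()
    for d in NEIGHBOR_OFFSETS:
        nb = (start[0] + d[0], start[1] + d[1], start[2] + d[2])
        if nb not in mesh.cells:
            return nb
        first_step[nb] = nb
        queue.append(nb)
    seen = set(first_step) | {start}
    while queue:
        c = queue.popleft()
        for d in NEIGHBOR_OFFSETS:
            nb = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
            if nb in seen:
                continue
            if nb not in mesh.cells:
                return first_step[c]
            seen.add(nb)
            first_step[nb] = first_step[c]
            queue.append(nb)
    raise RuntimeError("mesh has no boundary")  # pragma: no cover


def rebalance(mesh: TumorMesh, max_passes: int = 200) -> list[tuple]:
    """Second mesh scan: expansion / shrinkage by cell-content shifting.

    A GC whose total exceeds ``max_factor * nbc`` sheds half its content
    one step along the shortest path to the mesh boundary, creating a new
    boundary GC when that step lands on an empty site; shed content
    cascades outward over subsequent passes.  A GC below
    ``min_factor * nbc`` empties into its most-populated occupied neighbor
    and is deleted.  Total cell content is conserved exactly; the mesh is
    left unchanged when all GCs are within thresholds.
    """
    events: list[tuple] = []
    hi = mesh.max_factor * mesh.nbc
    lo = mesh.min_factor * mesh.nbc
    for _ in range(max_passes):
        acted = False
        for coord in sorted(mesh.cells):
            gc = mesh.cells.get(coord)
            if gc is None or gc.total() <= hi:
                continue
            target = _nearest_empty_step(mesh, coord)
            half = gc * 0.5
            mesh.cells[coord] = half
            if target in mesh.cells:
                mesh.cells[target] = mesh.cells[target] + half
            else:
                mesh.cells[target] = half
                events.append(("create", target))
            acted = True
            events.append(("shed", coord, target))
        for coord in sorted(mesh.cells):
            gc = mesh.cells.get(coord)
            if gc is None or gc.total() >= lo or len(mesh.cells) <= 1:
                continue
            neighbors = [
                (coord[0] + d[0], coord[1] + d[1], coord[2] + d[2]) for d in NEIGHBOR_OFFSETS
            ]
            occupied = [nb for nb in neighbors if nb in mesh.cells]
            if not occupied:
                continue
            target = max(occupied, key=lambda nb: (mesh.cells[nb].total(), nb))
            mesh.cells[target] = mesh.cells[target] + gc
            del mesh.cells[coord]
            mesh.overrides.pop(coord, None)
            acted = True
            events.append(("delete", coord, target))
        if not acted:
            break
    return events


def _record(rows, hour, counts, gc_count, cell_density, gc_volume):
    row = {"hour": hour}
    row.update(
        {
            k: counts.get(k, 0.0)
            for k in (
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
        }
    )
    row["volume_cm3"] = counts["total"] / cell_density
    row["gc_count"] = gc_count
    rows.append(row)


def run_simulation(
    params: TumorParameters,
    schedule: TreatmentSchedule | None = None,
    initial_volume_cm3: float = 100.0,
    mask: np.ndarray | None = None,
    mode: str = "wellmixed",
    horizon_h: int | None = None,
    cell_density: float = 1e9,
    gc_volume: float = 1e-3,
    rng: np.random.Generator | None = None,
    scenario: str | None = None,
) -> SimulationResult:
    """Run the hourly simulation loop and record the full time series.

    Each hour: any administration due at that instant is applied, the state
    is recorded, then the cytokinetic update (and, in lattice mode, the
    rebalancing scan) advances the tumor by one hour.  ``mode`` is
    ``"wellmixed"`` (a single aggregated state; exact for homogeneous
    tumors since the dynamics are density-independent) or ``"lattice"``.
    """
    if mode not in ("wellmixed", "lattice"):
        raise ValueError(f"unknown mode {mode!r}")
    if schedule is None:
        schedule = TreatmentSchedule(administrations=(), horizon_h=horizon_h or 500)
    if horizon_h is None:
        horizon_h = int(schedule.horizon_h)
    if schedule.administrations and horizon_h < schedule.last_administration_h:
        raise ValueError("horizon ends before the last scheduled administration")

    rows: list[dict] = []
    dose_log: list[tuple] = []

    if mode == "wellmixed":
        _, eq_state = equilibrium_composition(params)
        state = eq_state * (initial_volume_cm3 * cell_density)
        for t in range(horizon_h + 1):
            for dose in schedule.doses_at(t):
                state, marked = apply_administration(state, dose)
                dose_log.append((t, dose, marked))
            _record(rows, t, state.counts(), 0, cell_density, gc_volume)
            if t < horizon_h:
                state, _ = step_state(state, params, rng=rng)
    else:
        mesh = initialize_mesh(
            params,
            initial_volume_cm3=initial_volume_cm3 if mask is None else None,
            mask=mask,
            cell_density=cell_density,
            gc_volume=gc_volume,
        )
        for t in range(horizon_h + 1):
            for dose in schedule.doses_at(t):
                marked_total = 0.0
                for coord in sorted(mesh.cells):
                    mesh.cells[coord], marked = apply_administration(mesh.cells[coord], dose)
                    marked_total += sum(marked.values())
                dose_log.append((t, dose, {"marked": marked_total}))
            _record(rows, t, mesh.aggregate_counts(), mesh.gc_count, cell_density, gc_volume)
            if t < horizon_h:
                scan_update(mesh, rng=rng)
                rebalance(mesh)

    data = pd.DataFrame(rows)
    return SimulationResult(
        data=data,
        params=params,
        schedule=schedule,
        mode=mode,
        cell_density=cell_density,
        gc_volume=gc_volume,
        dose_log=dose_log,
        scenario=scenario,
    )
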