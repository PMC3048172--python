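"""Age-structured cytokinetic model of tumor growth.

The tumor population is tracked in hourly age bins within every compartment:
cycling stem cells (G1/S/G2/M), cycling LIMP cells per remaining mitotic
potential, dormant (G0) cells, terminally differentiated cells, and
apoptotic / necrotic remnants awaiting clearance.  Lethally hit cells
(chemotherapy) live in separate compartments and traverse a rudimentary
cycle to their mechanism-specific death point; they are advanced here but
created by :mod:`nephrosim.pharmacodynamics`.

Without drugs the dynamics are linear, so a single one-hour update is
equivalently expressed as a nonnegative transition matrix.  The matrix is
built independently of the imperative stepper (:func:`transition_matrix` vs
:func:`step_state`) and the two formulations are cross-checked in the test
suite.  The dominant eigenpair of the matrix gives the exponential growth
rate and the stationary (artifact-free) population composition used to
initialize simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import PHASES, TumorParameters

__all__ = [
    "StateLayout",
    "CellStateVector",
    "CompositionSummary",
    "StepLedger",
    "GrowthRate",
    "step_state",
    "transition_matrix",
    "equilibrium_composition",
    "intrinsic_growth_rate",
]

LINEAGES = ("stem", "limp")
#: Death mechanisms of lethally hit cells: vincristine-hit cells die at the
#: end of M; actinomycin-D-hit cells die at the end of S (cells marked while
#: already past S, i.e. in G2 or M, die at the end of M without dividing).
HIT_MECHANISMS = ("vcr", "act")


class StateLayout:
    """Index layout of the age-resolved population vector for a parameter set.

    The "core" vector concatenates, in a fixed order: stem G1/S/G2/M age
    bins, stem G0 age bins, the same for each LIMP mitotic-potential level
    m = 1..N_LIMP, one differentiated-cell bin, apoptotic age bins and
    necrotic age bins.  Durations are rounded to whole hours (1 h step).
    """

    def __init__(self, params: TumorParameters):
        self.params = params
        self.dur = params.phase_durations()
        self.t_g0 = max(1, round(params.T_G0))
        self.t_a = max(1, round(params.T_A))
        self.t_n = max(1, round(params.T_N))
        self.n_limp = params.N_LIMP

        self.slices: dict[object, slice] = {}
        pos = 0

        def add(key, length):
            nonlocal pos
            self.slices[key] = slice(pos, pos + length)
            pos += length

        for ph in PHASES:
            add(("stem", ph), self.dur[ph])
        add(("stem", "G0"), self.t_g0)
        for m in range(1, self.n_limp + 1):
            for ph in PHASES:
                add(("limp", m, ph), self.dur[ph])
            add(("limp", m, "G0"), self.t_g0)
        add("diff", 1)
        add("apo", self.t_a)
        add("nec", self.t_n)
        self.n = pos

        self.diff_index = self.slices["diff"].start
        self.apo = self.slices["apo"]
        self.nec = self.slices["nec"]

        def mask(pred):
            m = np.zeros(self.n, dtype=bool)
            for key, sl in self.slices.items():
                if isinstance(key, tuple) and pred(key):
                    m[sl] = True
            return m

        self.stem_cycling = mask(lambda k: k[0] == "stem" and k[-1] in PHASES)
        self.limp_cycling = mask(lambda k: k[0] == "limp" and k[-1] in PHASES)
        self.stem_g0 = mask(lambda k: k[0] == "stem" and k[-1] == "G0")
        self.limp_g0 = mask(lambda k: k[0] == "limp" and k[-1] == "G0")

    def cycling_keys(self):
        """Keys of all cycling-phase slices, with (lineage, phase)."""
        for key in self.slices:
            if isinstance(key, tuple) and key[-1] in PHASES:
                yield key, key[0], key[-1]

    def g0_keys(self):
        for key in self.slices:
            if isinstance(key, tuple) and key[-1] == "G0":
                yield key, key[0]

    def compatible_with(self, other: "StateLayout") -> bool:
        return self.n == other.n and list(self.slices) == list(other.slices)


@dataclass
class CompositionSummary:
    """Population composition in percent of the total.

    Two exhaustive decompositions hold: ``proliferating + dormant +
    differentiated + dead = 100`` and ``stem + limp + differentiated +
    dead = 100``.  Lethally hit cells still traversing the rudimentary
    cycle are tallied in their current phase class (they occupy tumor
    volume until cleared).
    """

    proliferating: float
    dormant: float
    stem: float
    limp: float
    differentiated: float
    dead: float

    def __post_init__(self):
        s1 = self.proliferating + self.dormant + self.differentiated + self.dead
        s2 = self.stem + self.limp + self.differentiated + self.dead
        if abs(s1 - 100.0) > 0.1 or abs(s2 - 100.0) > 0.1:
            raise ValueError(f"composition does not sum to 100%: {s1:.3f} / {s2:.3f}")

    def as_dict(self) -> dict[str, float]:
        return {
            "proliferating": self.proliferating,
            "dormant": self.dormant,
            "stem": self.stem,
            "limp": self.limp,
            "differentiated": self.differentiated,
            "dead": self.dead,
        }


def _empty_hit(layout: StateLayout):
    return {
        (lin, mech): {ph: np.zeros(layout.dur[ph]) for ph in PHASES}
        for lin in LINEAGES
        for mech in HIT_MECHANISMS
    }


class CellStateVector:
    """Age-structured population state: core vector plus hit compartments.

    Populations are real-valued (deterministic expectation bookkeeping over
    ~1e6-1e9 cells per geometrical cell).
    """

    def __init__(self, layout: StateLayout, core=None, hit=None, hit_g0=None):
        self.layout = layout
        self.core = np.zeros(layout.n) if core is None else np.asarray(core, dtype=float)
        if self.core.shape != (layout.n,):
            raise ValueError(f"core must have shape ({layout.n},)")
        self.hit = hit if hit is not None else _empty_hit(layout)
        self.hit_g0 = dict(hit_g0) if hit_g0 is not None else {lin: 0.0 for lin in LINEAGES}

    # -- construction ------------------------------------------------------
    @classmethod
    def zeros(cls, layout: StateLayout) -> "CellStateVector":
        return cls(layout)

    def copy(self) -> "CellStateVector":
        return CellStateVector(
            self.layout,
            self.core.copy(),
            {k: {ph: a.copy() for ph, a in d.items()} for k, d in self.hit.items()},
            dict(self.hit_g0),
        )

    # -- arithmetic (used by lattice rebalancing) --------------------------
    def __mul__(self, a: float) -> "CellStateVector":
        out = self.copy()
        out.core *= a
        for d in out.hit.values():
            for arr in d.values():
                arr *= a
        for lin in out.hit_g0:
            out.hit_g0[lin] *= a
        return out

    __rmul__ = __mul__

    def add_(self, other: "CellStateVector") -> "CellStateVector":
        """In-place elementwise addition."""
        self.core += other.core
        for k, d in self.hit.items():
            for ph in d:
                d[ph] += other.hit[k][ph]
        for lin in self.hit_g0:
            self.hit_g0[lin] += other.hit_g0[lin]
        return self

    def __add__(self, other: "CellStateVector") -> "CellStateVector":
        return self.copy().add_(other)

    # -- tallies -----------------------------------------------------------
    def hit_total(self) -> float:
        return sum(a.sum() for d in self.hit.values() for a in d.values()) + sum(
            self.hit_g0.values()
        )

    def total(self) -> float:
        return float(self.core.sum() + self.hit_total())

    def counts(self) -> dict[str, float]:
        """Absolute subpopulation tallies (hit cells in their current class)."""
        L = self.layout
        hit_cyc = {
            lin: sum(self.hit[(lin, mech)][ph].sum() for mech in HIT_MECHANISMS for ph in PHASES)
            for lin in LINEAGES
        }
        cyc_stem = float(self.core[L.stem_cycling].sum() + hit_cyc["stem"])
        cyc_limp = float(self.core[L.limp_cycling].sum() + hit_cyc["limp"])
        g0_stem = float(self.core[L.stem_g0].sum() + self.hit_g0["stem"])
        g0_limp = float(self.core[L.limp_g0].sum() + self.hit_g0["limp"])
        diff = float(self.core[L.diff_index])
        apo = float(self.core[L.apo].sum())
        nec = float(self.core[L.nec].sum())
        return {
            "proliferating": cyc_stem + cyc_limp,
            "dormant": g0_stem + g0_limp,
            "stem": cyc_stem + g0_stem,
            "limp": cyc_limp + g0_limp,
            "differentiated": diff,
            "apoptotic": apo,
            "necrotic": nec,
            "dead": apo + nec,
            "hit": self.hit_total(),
            "total": cyc_stem + cyc_limp + g0_stem + g0_limp + diff + apo + nec,
        }

    def composition(self) -> CompositionSummary:
        c = self.counts()
        t = c["total"]
        if t <= 0:
            raise ValueError("cannot compute composition of an empty tumor")
        return CompositionSummary(
            proliferating=100 * c["proliferating"] / t,
            dormant=100 * c["dormant"] / t,
            stem=100 * c["stem"] / t,
            limp=100 * c["limp"] / t,
            differentiated=100 * c["differentiated"] / t,
            dead=100 * c["dead"] / t,
        )

    def validate(self) -> None:
        if (self.core < -1e-9 * max(1.0, self.core.max(initial=0.0))).any():
            raise ValueError("negative compartment content")
        for d in self.hit.values():
            for a in d.values():
                if (a < -1e-9).any():
                    raise ValueError("negative hit-compartment content")


@dataclass
class StepLedger:
    """Cell bookkeeping of one engine step.

    ``births`` is the net mass created by mitosis (each mitosis turns one
    mother into two daughters).  Death events move cells between
    compartments; only clearance of apoptotic / necrotic remnants removes
    cells from the tumor, so
    ``total(t+1) = total(t) + births - cleared_apoptotic - cleared_necrotic``.
    """

    births: float = 0.0
    spontaneous_apoptosis: float = 0.0
    diff_apoptosis: float = 0.0
    diff_necrosis: float = 0.0
    g0_necrosis: float = 0.0
    chemo_deaths: float = 0.0
    cleared_apoptotic: float = 0.0
    cleared_necrotic: float = 0.0

    @property
    def clearances(self) -> float:
        return self.cleared_apoptotic + self.cleared_necrotic


def _age_hit_cells(state: CellStateVector) -> float:
    """Advance hit compartments one hour in place; return mass dying now.

    Vincristine-hit cells traverse the remaining cycle and die at the end
    of M.  Actinomycin-D-hit cells die at the end of S; those marked in
    G2/M (past the S checkpoint) die at the end of M without dividing.
    Actinomycin-D-hit dormant cells leave G0 at the next step and traverse
    the rudimentary G1 + S.
    """
    died = 0.0
    for (lin, mech), d in state.hit.items():
        carry: dict[str, float] = {}
        for i, ph in enumerate(PHASES):
            a = d[ph]
            out = float(a[-1])
            a[1:] = a[:-1]
            a[0] = 0.0
            if ph == "M" or (ph == "S" and mech == "act"):
                died += out
            elif ph != "M":
                carry[PHASES[i + 1]] = out
        for ph, mass in carry.items():
            d[ph][0] += mass
        if mech == "act":
            d["G1"][0] += state.hit_g0[lin]
    for lin in state.hit_g0:
        state.hit_g0[lin] = 0.0
    return died


def step_state(
    state: CellStateVector,
    params: TumorParameters | None = None,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[CellStateVector, StepLedger]:
    """Advance the population one hour; return the new state and a ledger.

    Intra-step order (fixed for reproducibility): spontaneous death at the
    hourly rates; aging of every age bin; phase exits (end of M triggers
    mitosis, end of G0 triggers re-entry or necrosis); clearance of
    apoptotic / necrotic bins past their residence time; aging and death
    of lethally hit cells.  Mitosis branching: a stem mother yields two
    stem daughters with probability mass ``P_sym`` and one stem plus one
    LIMP (full potential ``N_LIMP``) otherwise; a LIMP mother at remaining
    potential m yields two LIMP daughters at m - 1, or two terminally
    differentiated cells when m - 1 = 0.  Each stem/LIMP daughter enters
    G0 with mass ``P_sleep`` and G1 otherwise.

    With ``rng`` given, compartment contents of the new state are
    stochastically rounded to integers (floor plus Bernoulli on the
    fractional part); conservation then holds only in expectation.
    """
    L = state.layout
    p = params if params is not None else L.params
    if dt != 1.0:
        raise ValueError("the engine uses a fixed 1 h time step")
    led = StepLedger()
    core = state.core
    new = CellStateVector.zeros(L)
    new.hit = {k: {ph: a.copy() for ph, a in d.items()} for k, d in state.hit.items()}
    new.hit_g0 = dict(state.hit_g0)
    nc = new.core
    sl = L.slices
    surv = 1.0 - p.R_A
    apo_in = 0.0
    nec_in = 0.0

    def enter(lineage_key_g1, lineage_key_g0, mass):
        nc[sl[lineage_key_g0].start] += mass * p.P_sleep
        nc[sl[lineage_key_g1].start] += mass * (1.0 - p.P_sleep)

    # living cycling compartments: spontaneous apoptosis, then aging
    for key, lin, ph in L.cycling_keys():
        a = core[sl[key]]
        led.spontaneous_apoptosis += a.sum() * p.R_A
        s = a * surv
        nc[sl[key]][1:] += s[:-1]
        out = s[-1]
        if out == 0.0:
            continue
        if ph != "M":
            nxt = key[:-1] + (PHASES[PHASES.index(ph) + 1],)
            nc[sl[nxt].start] += out
        else:
            led.births += out
            if lin == "stem":
                enter(("stem", "G1"), ("stem", "G0"), (1.0 + p.P_sym) * out)
                if L.n_limp >= 1:
                    enter(("limp", L.n_limp, "G1"), ("limp", L.n_limp, "G0"),
                          (1.0 - p.P_sym) * out)
                else:
                    nc[L.diff_index] += (1.0 - p.P_sym) * out
            else:
                m = key[1]
                if m > 1:
                    enter(("limp", m - 1, "G1"), ("limp", m - 1, "G0"), 2.0 * out)
                else:
                    nc[L.diff_index] += 2.0 * out

    # dormant compartments: apoptosis hazard plus the T_G0 deadline
    for key, lin in L.g0_keys():
        a = core[sl[key]]
        led.spontaneous_apoptosis += a.sum() * p.R_A
        s = a * surv
        nc[sl[key]][1:] += s[:-1]
        out = s[-1]
        g1_key = key[:-1] + ("G1",)
        nc[sl[g1_key].start] += out * p.P_G0toG1
        led.g0_necrosis += out * (1.0 - p.P_G0toG1)
        nec_in += out * (1.0 - p.P_G0toG1)
    apo_in += led.spontaneous_apoptosis

    # differentiated cells: spontaneous apoptosis and necrosis
    dmass = core[L.diff_index]
    nc[L.diff_index] += dmass * (1.0 - p.R_ADiff - p.R_NDiff)
    led.diff_apoptosis = dmass * p.R_ADiff
    led.diff_necrosis = dmass * p.R_NDiff
    apo_in += led.diff_apoptosis
    nec_in += led.diff_necrosis

    # dead-cell remnants: age; the oldest bin is cleared from the tumor
    nc[L.apo][1:] += core[L.apo][:-1]
    led.cleared_apoptotic = float(core[L.apo][-1])
    nc[L.nec][1:] += core[L.nec][:-1]
    led.cleared_necrotic = float(core[L.nec][-1])

    # lethally hit cells traverse the rudimentary cycle
    led.chemo_deaths = _age_hit_cells(new)
    apo_in += led.chemo_deaths

    nc[L.apo.start] += apo_in
    nc[L.nec.start] += nec_in

    if rng is not None:
        frac, flo = np.modf(nc)
        nc[:] = flo + (rng.random(nc.shape) < frac)
    return new, led


def transition_matrix(params: TumorParameters) -> np.ndarray:
    """One-hour transition matrix over the core (drug-free) compartments.

    Built directly from the compartment rules, independently of
    :func:`step_state`; one matrix-vector product equals one drug-free step
    exactly (the drug-free dynamics are linear).
    """
    L = StateLayout(params)
    p = params
    n = L.n
    M = np.zeros((n, n))
    sl = L.slices
    apo0 = L.apo.start
    nec0 = L.nec.start
    surv = 1.0 - p.R_A

    def age_chain(key, survival, death_row=None, death_rate=0.0):
        s = sl[key]
        for a in range(s.start, s.stop - 1):
            M[a + 1, a] += survival
        if death_row is not None and death_rate:
            for a in range(s.start, s.stop):
                M[death_row, a] += death_rate
        return s.stop - 1  # index of the oldest bin

    def offspring(col, key_g1, key_g0, mass):
        M[sl[key_g0].start, col] += mass * p.P_sleep
        M[sl[key_g1].start, col] += mass * (1.0 - p.P_sleep)

    lineages = [("stem",)] + [("limp", m) for m in range(1, L.n_limp + 1)]
    for lin in lineages:
        for i, ph in enumerate(PHASES):
            last = age_chain(lin + (ph,), surv, apo0, p.R_A)
            if ph != "M":
                M[sl[lin + (PHASES[i + 1],)].start, last] += surv
            elif lin[0] == "stem":
                offspring(last, ("stem", "G1"), ("stem", "G0"), (1.0 + p.P_sym) * surv)
                if L.n_limp >= 1:
                    offspring(last, ("limp", L.n_limp, "G1"), ("limp", L.n_limp, "G0"),
                              (1.0 - p.P_sym) * surv)
                else:
                    M[L.diff_index, last] += (1.0 - p.P_sym) * surv
            else:
                m = lin[1]
                if m > 1:
                    offspring(last, ("limp", m - 1, "G1"), ("limp", m - 1, "G0"), 2.0 * surv)
                else:
                    M[L.diff_index, last] += 2.0 * surv
        last = age_chain(lin + ("G0",), surv, apo0, p.R_A)
        M[sl[lin + ("G1",)].start, last] += surv * p.P_G0toG1
        M[nec0, last] += surv * (1.0 - p.P_G0toG1)

    M[L.diff_index, L.diff_index] = 1.0 - p.R_ADiff - p.R_NDiff
    M[apo0, L.diff_index] += p.R_ADiff
    M[nec0, L.diff_index] += p.R_NDiff
    for s in (L.apo, L.nec):
        for a in range(s.start, s.stop - 1):
            M[a + 1, a] += 1.0
    return M


def _dominant_eigenpair(M: np.ndarray) -> tuple[float, np.ndarray]:
    w, V = np.linalg.eig(M)
    i = int(np.argmax(w.real))
    lam = float(w[i].real)
    v = np.abs(V[:, i].real)
    v = v / v.sum()
    resid = float(np.linalg.norm(M @ v - lam * v, ord=1))
    if resid > 1e-8 * max(1.0, abs(lam)):
        raise RuntimeError(f"eigenpair did not converge (residual {resid:.2e})")
    return lam, v


def equilibrium_composition(
    params: TumorParameters,
) -> tuple[CompositionSummary, CellStateVector]:
    """Stationary composition of free exponential growth.

    Returns the dominant eigenvector of the one-hour transition structure,
    normalized to a total of 1, as both a percentage summary and a full
    state vector.  Advancing this state one drug-free step multiplies every
    compartment by the same factor exp(k), which is the initialization that
    avoids artificial transient growth behavior.
    """
    M = transition_matrix(params)
    _, v = _dominant_eigenpair(M)
    L = StateLayout(params)
    state = CellStateVector(L, core=v)
    return state.composition(), state


@dataclass
class GrowthRate:
    """Exponential growth characteristics of the free-growth regime."""

    k_per_hour: float
    doubling_time_days: float = field(default=math.nan)
    shrinking: bool = False

    def __post_init__(self):
        if math.isnan(self.doubling_time_days):
            self.doubling_time_days = (
                math.log(2) / self.k_per_hour / 24.0 if self.k_per_hour > 0 else math.inf
            )


def intrinsic_growth_rate(params: TumorParameters) -> GrowthRate:
    """Per-hour growth-rate constant k from the dominant eigenvalue.

    k = ln(dominant per-hour multiplication factor); the volume doubling
    time is ln2 / k converted to days.  A non-growing tumor (factor <= 1)
    yields k <= 0 with ``shrinking=True`` rather than an error.
    """
    lam, _ = _dominant_eigenpair(transition_matrix(params))
    k = math.log(lam)
    return GrowthRate(k_per_hour=k, shrinking=lam <= 1.0)
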