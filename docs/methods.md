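# Methods

## Model overview

`nephrosim` simulates the response of a solid tumor — the motivating
system is blastemal-type nephroblastoma (Wilms' tumor) under preoperative
vincristine + actinomycin-D chemotherapy — with a predominantly discrete,
cytokinetic compartment model.  Five cell classes are tracked: stem cells
(unlimited mitotic potential), LIMP cells (LImited Mitotic Potential,
committed progenitors), terminally differentiated cells, and apoptotic and
necrotic remnants awaiting clearance.  Cycling stem and LIMP cells move
through G1 → S → G2 → M in hourly age bins; after mitosis each daughter
enters the dormant G0 compartment with probability mass `P_sleep`
(representing inadequate oxygen/nutrient supply) or re-enters G1.  A stem
mitosis is symmetric (two stem daughters) with mass `P_sym`, otherwise
asymmetric (one stem + one LIMP daughter with full potential `N_LIMP`); a
LIMP mitosis decrements the remaining potential, producing two terminally
differentiated cells at the last division.  Dormant cells that reach the
G0 residence limit `T_G0` re-enter G1 with fraction `P_G0toG1` and die
through necrosis otherwise.  Living stem/LIMP cells die spontaneously at
rate `R_A` per hour; differentiated cells at `R_ADiff` (apoptosis) and
`R_NDiff` (necrosis).  Apoptotic and necrotic material leaves the tumor
after `T_A` and `T_N` hours respectively.

Populations are real-valued expectation bookkeeping: a geometrical cell
holds ~1e6 biological cells, so mean-field dynamics are appropriate and
make every reported quantity deterministic.  An optional stochastic
rounding of compartment contents (seeded `numpy` generator passed to the
engine step) exists for small-population experiments; it is off by
default, and conservation then holds only in expectation.

## Time discretization and linear structure

The engine uses a fixed 1 h step; all rates are per hour and all durations
are rounded to whole hours.  The split of the cell-cycle duration `Tc`
over G1/S/G2/M is not identifiable from population growth (only the total
matters for the growth rate); the default 40:39:13:8 split follows typical
human cell-cycle proportions and only shifts drug-death timing by hours.
The intra-step order is fixed: (1) spontaneous death hazards, (2) aging of
every age bin with phase exits and mitosis, (3) G0-deadline branching,
(4) clearance of apoptotic/necrotic bins past their residence time,
(5) aging/death of chemotherapy-hit cells.

Without drugs the dynamics are linear, so one step is equivalently a
nonnegative transition matrix over the ~500 age-resolved compartments.
The matrix is constructed directly from the rules, independently of the
imperative stepper, and the two are cross-checked to 1e-10 in the tests.
Its dominant eigenpair (dense `numpy.linalg.eig`; the Perron root of the
living block) yields

* the intrinsic growth-rate constant `k = ln(dominant factor)` per hour
  and the volume doubling time `Td = ln 2 / k` (days), and
* the stationary composition of exponential growth, used to initialize
  every simulation.  Initializing on the eigenvector is what removes
  latent artificial transients: composition drift over the first 48 h of
  free growth is below one percentage point (tested).

A non-growing parameter set yields `k <= 0` with a `shrinking` flag, not
an exception.  In that regime the dominant eigenvalue saturates at the
differentiated-cell decay `1 - R_ADiff - R_NDiff`, so monotonicity of `k`
in parameters is strict only where the tumor actually grows; the dyad-grid
analyses mask the non-growing (and non-responding) regions.

## Pharmacodynamics

A drug administration instantaneously marks a fraction of eligible cells
as lethally hit (cell kill ratio, CKR = 1 - survival fraction, per
administration).  Vincristine binds cells in all cycling phases and kills
at the end of M; actinomycin-D binds cells in all phases including G0 and
kills at the end of S.  Combined administrations act additively: a
fraction `min(1, CKR_VCR + CKR_ACT)` of every cycling compartment is
marked, attributed per drug proportionally to the individual CKRs.  Only
actinomycin-D affects dormant cells.  Marked cells stop dividing and
traverse a rudimentary cycle at normal speed to their death point;
design choices where the mechanism is underdetermined:

* actinomycin-hit cells already in G2/M (past the S checkpoint) die at
  the end of M without dividing;
* actinomycin-hit dormant cells leave G0 at the next step and traverse a
  rudimentary G1 + S rather than waiting out `T_G0`;
* hit cells are exempt from the spontaneous-death hazards (they are
  already committed to death; the double-counting would be ~`R_A` per
  remaining hour, i.e. a per-mille effect).

Marking conserves the total cell count exactly; cells leave the tumor
only through apoptotic/necrotic clearance, and a per-step ledger verifies
`total(t+1) = total(t) + births - clearances` to 1e-9 relative.

### Default schedule

The packaged preoperative regimen administers vincristine at days 3, 10,
17 and 24 and actinomycin-D at the week-1 and week-3 instants (days 3 and
17), over a 28-day horizon — the drug pattern of the SIOP/GPOH
preoperative AV protocol for stage I–III unilateral tumors.  Under this
pattern the packaged scenarios reproduce the published volume reductions
and final compositions within the stated tolerances; giving actinomycin-D
at all four instants over-kills every scenario by 6–15 percentage points.
Per-administration CKRs are fully configurable, so other patterns can be
expressed.

## Tally conventions

The growth fraction ("proliferating") counts all cycling living stem+LIMP
cells; "dormant" is G0; "dead" is apoptotic + necrotic not yet cleared.
Hit cells still traversing the rudimentary cycle are counted in their
current phase class and lineage (they occupy volume until clearance), so
both decompositions — proliferating + dormant + differentiated + dead and
stem + LIMP + differentiated + dead — are exhaustive and sum to 100%.

## Spatial lattice

The tumor occupies a 3D cubic mesh of geometrical cells (GCs), 1 mm^3
each by default, initially holding `nbc = cell_density × gc_volume` cells
(1e6 at the typical 1e9 cells/cm^3) at the equilibrium composition.  A
scalar initial volume produces a quasi-spherical region (lattice sites
sorted by distance from the center, deterministic tie-break); a 3D
boolean mask is accepted for arbitrary connected geometries, and
per-region parameter overrides (rates and fractions; durations are fixed
by the shared compartment layout) support macroscopically distinct
metabolic regions.

Each hour two scans run: the first advances every GC with the cytokinetic
rules; the second rebalances.  A GC above `1.5 × nbc` sheds half its
content one step along the shortest path (breadth-first, 6-connectivity,
ties broken in the fixed order +x, −x, +y, −y, +z, −z) toward the mesh
boundary, creating a new boundary GC when the step lands outside the
tumor; shed content cascades outward over subsequent passes.  A GC below
`0.5 × nbc` empties into its most-populated neighbor and is deleted.  The
thresholds were chosen so that a homogeneous tumor's GC count tracks its
total population within one rebalancing quantum; shifting conserves every
compartment exactly (0.5-scaling and addition are exact in binary
floating point).  Because the GC content may sit anywhere inside the
0.5–1.5 band, the mesh-derived volume (GC count × GC volume) is
guaranteed to agree with the population-derived volume only within that
band; over windows without rebalancing events they agree within one GC
volume (tested).

Since the dynamics at this model stage are density-independent and
shifting only moves cells, a homogeneous tumor's aggregate trajectory in
lattice mode equals the well-mixed (0-D) trajectory; the test suite
verifies agreement within 1% (observed: machine precision).  The
clinical-case scenarios are therefore run in the equivalent-homogeneous,
well-mixed mode, with lattice mode reserved for geometry-dependent
studies.

## Scenarios and evaluation instants

Five parameter sets are packaged: the reference ("typical") tumor and
four virtual tumors T1–T4 adapted to a real clinical case (T1 perturbs
P_sym/P_sleep; T2 Tc/R_A; T3 only the CKRs; T4 everything needed to also
match the blastemal histology).  Day 0 is the first imaging instant, the
last administration is at day 24 and the horizon is day 28.  Final
characteristics are read 1 day after completion of therapy (day 25) for
the typical tumor and 3 days after (day 27) for T1–T4.  The default
initial volume is 100 cm^3; the dynamics are linear, so reductions and
compositions are invariant to the absolute volume (tested).

Known limitation: T3, whose fit relies solely on raising the CKRs to
0.36/0.34, comes out at ~79% volume reduction against the published 72%.
The kill of this implementation is more super-linear in `CKR_total` than
the original's, whose PK/PD-derived per-drug details are not fully
specified; the other four scenarios (and all composition and growth-rate
figures, including T3's, which equal the typical tumor's) reproduce
within ±4 percentage points / ±15% relative.

## Sensitivity analysis

One-at-a-time sweeps rerun the full simulation at each of `n >= 3` grid
points of one parameter (the dependent `CKR_total` is swept by scaling
both drug CKRs proportionally).  The response curve is summarized by the
sorting criterion

    SC = (max - min of the output over the sweep) / mean(|output|),

a scale-free score that is zero iff the output is constant and invariant
to sweep direction; the criterion is pluggable.  Default sweep ranges use
the spans of the packaged scenario columns widened by 20% where the
scenarios vary a parameter, and ±50% around the reference value where
they do not (T_A, P_G0toG1, N_LIMP); all ranges are configurable.
Non-responding tumors (negative reductions) remain in OAT curves — they
are informative for ranking — whereas the two-parameter (dyad) grids mask
grid points whose free growth is non-monotonic (`k <= 0`) or which show
no volume reduction, reproducing the restricted admissible regions of the
joint analyses.  With the defaults, the ranking places P_sym and P_sleep
clearly on top, with Tc and CKR_total leading the next tier — exact SC
values depend on the (configurable) ranges and are not comparable across
range choices.

## Problem sizes and determinism

Default analyses are well-mixed: a 28-day treated run costs ~650 matrix
steps over ~500 compartments (≈0.3 s); the full five-scenario table
reproduction a few seconds; the twelve-parameter ranking ~60 runs
(≈10 s); lattice validation uses a 27-GC tumor.  All default-mode results
are bit-reproducible: no randomness enters unless a generator is passed
explicitly, and all tie-breaks are fixed.

## What the virtual tumors do and do not capture

The scenarios emulate macroscopic volume response and coarse histological
composition of a homogeneous tumor under constant per-administration cell
kill.  They do not model explicit pharmacokinetics (dose–CKR mapping),
the density-dependent "inoculum" effect of vincristine, nutrient/oxygen
diffusion (dormancy is parameter-driven), Gompertzian saturation on long
horizons, cell-cycle checkpoints, or molecular heterogeneity.  Passing
tests therefore demonstrate internal consistency and agreement with the
published virtual-tumor characteristics, not predictive validity for an
individual patient.
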