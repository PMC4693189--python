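# Methods

## Model

diuFBA treats one diurnal cycle as two quasi-steady-state intervals — a
light phase of duration Δt_light and a dark phase of duration Δt_dark —
of the same metabolic network (s species, r reactions, stoichiometric
matrix S). Within each phase, environmental conditions are assumed
constant and internal metabolites balanced; only the declared carry-over
species may accumulate in one phase and be consumed in the other. This
assumption fits monitored cultivation and early blooms without nutrient
limitation; it does not capture sub-phase dynamics (dawn/dusk ramps,
within-phase depletion).

The extended problem has 2r + p + q variables, all time-integrated
concentration changes (mmol/gDCW per phase; M for the example model):

* 2r reaction variables, bounds = per-phase flux bounds (after per-phase
  overrides) × the phase duration. Equality-constrained fluxes (lb = ub,
  e.g. maintenance demands) remain equalities after scaling.
* p transfer variables, one per carry-over species, with coefficient −1
  in the species' light-phase row and +1 in its dark-phase row.
  Unbounded and reversible by default (night→day transfer is a negative
  value); per-species caps can be set in the configuration, which is also
  how transfer amounts are frozen for phase-plane scans.
* q export variables (q ≤ p), one per exportable species, −1 in the
  species' dark-phase row, bounds [0, ∞): accumulation beyond the cycle
  leaves the system and cannot enter it.

Because each phase block must balance and transfers are the only
inter-phase coupling, cyclic closure is implicit: any carried amount not
exported must be consumed in the dark phase. No explicit periodicity
constraint is added.

Export is attached to the dark (final) phase only. "Accumulation beyond
the diurnal cycle" is an end-of-cycle removal; effective light-phase
export can be expressed by declaring the species exportable and bounding
its transfer column.

Species that must merely *persist* overnight (functional biomass) are
declared carry-over exactly like storage metabolites: the
functional/storage distinction is a reporting label, not a matrix-level
one — the transfer mechanics are identical.

## Solving

The LP `max w·ṽ s.t. S̃ṽ = 0, bounds` is solved with HiGHS through
`scipy.optimize.linprog`. Optimal solutions are checked against a
relative mass-balance residual of 1e-9 (a violation raises a solver
failure); infeasible and unbounded outcomes are reported as statuses,
never exceptions. The solver is deterministic for a fixed problem, so
identical inputs give byte-identical reports (modulo timestamps).

If the configuration supplies no objective, weight 1 is placed on every
export column (maximize total long-term accumulation). An optional
secondary stage (`secondary="min_total_flux"`) minimizes Σ|ṽ| at the
fixed optimal objective value via a split-variable LP, selecting a
parsimonious representative among alternate optima. The default is
single-stage for speed; the bundled example is constructed (no futile
sinks, a single export) so its optimal vertex is unique without it.

The transition composition reports, at the light→dark boundary, the net
light-phase production of each functional-labeled species and the
transfer amount of each storage-labeled species, with fractions over
their sum. Percentages are rounded to one decimal only at the reporting
layer; raw values stay unrounded in all JSON output.

## Phase-plane scans

A scan pins one or two extended variables by equality (lb = ub = grid
value) and re-solves the LP per cell, column-major. Pins outside a
variable's own bounds, and infeasible cells generally, are recorded as
masked NaNs so the grid shape is stable for plotting. Because the LP
value is concave in a bound parameter, each scanned line must lie on or
below the chord of its neighbours; the tests assert this at 1e-8.

Mode classification computes per-cell forward-difference gradients
(backward at the trailing edge, so a kink of a piecewise-linear surface
lands on its own cell), groups gradients agreeing within 1e-6, and
numbers 4-connected components of each group as modes. This gradient
clustering is one reasonable algorithmic reading of region drawing done
by inspection in the PhPP literature; grids smaller than 3 points in
every scanned direction return a single region with a warning.

## The example model and its calibration

Species {SUB, STO, BIO, MNT}; reactions: substrate supply EX_sub
(ub = supply/Δt_light in light, 0 in dark), 1:1 conversions SUB→BIO,
SUB→STO, SUB→MNT, lossy conversions STO→e_sto·MNT, STO→e_sto·BIO,
BIO→e_bio·MNT (starvation), and the maintenance demand DM_mnt with
lb = ub = 0.1 M/h in both phases. Carry-over {STO, BIO}, exportable
{BIO}, objective = BIO export. Defaults: 1 h light with 1 M total
substrate; dark phase 1 h (scenario 1) or 2 h (scenario 2).

The efficiencies are not free dials; they are recovered from scenario 1
alone. The greedy sequential run loses 0.2 M biomass covering 0.1 M of
night maintenance, fixing e_bio = 0.5; the diurnal optimum covers the
same demand with 0.125 M storage, fixing e_sto = 0.8; and
0.1 + 0.775 + 0.125 = 1.0 forces the substrate conversions to be 1:1.
Scenario 2's endpoints (0.5 M final under the sequential run; 72.2% /
27.8% composition) then serve as independent validation, not inputs.
Storage feeds growth at the same efficiency as maintenance — the single
stated efficiency ordering gives no basis for two values. Biomass is
expressed in molar precursor units throughout; no molar-mass weighting.

The closed-form oracle is direct resource accounting: night maintenance
is cheapest from storage (e_sto > e_bio), so
storage* = maintenance·Δt_dark / e_sto and
biomass* = supply − maintenance·Δt_light − storage*; a negative residual
flags an unsustainable scenario. The test suite checks the LP against
this closed form over a 56-point sweep (supply 0.5–2 M, nights 0.5–4 h,
e_sto 0.6–0.95) at 1e-9.

The sequential comparator uses two steps, one per phase — sufficient
because within-phase conditions are constant. Phase 1 maximizes biomass
accumulation with no lookahead (pool species get sink columns); the
end-of-phase pools become bounded source columns for phase 2, which
maximizes what remains of the biomass pool. An unsatisfiable night is
reported as starvation collapse.

## What the example does and does not show

The example exercises every structural element of the method — transfer,
export, Δt scaling, equality maintenance, the optimality trade-off — at
a size where the optimum is known in closed form, so agreement is exact
rather than statistical. It does not emulate genome-scale features:
compartments, cofactor coupling, alternate optimal flux patterns, or
futile cycles that absorb forced overproduction. Passing tests therefore
validate the machinery, not any genome-scale prediction; runs on a real
reconstruction additionally depend on that model's curation, objective
weights, and maintenance values, which the user must supply.

## Numerical choices

* Feasibility tolerance: 1e-9 relative on ‖S̃ṽ‖∞.
* Fraction sums are exact to 1e-12 by construction (division by the sum).
* File serialization keeps ≥12 significant digits (`repr` of floats), so
  coefficients like 0.8 survive TSV/JSON/SBML round-trips bit-exactly;
  infinite bounds serialize as `inf`.
* The TSV dialect stores species row order in an optional
  `# species: ...` comment so ordering round-trips; without it, order is
  first appearance in the equations.
* Scan grids and the test sweep are desk-scale (≤ a few hundred LPs of
  ~20 columns); the full suite runs in seconds.

## Known limitations

* Exactly two phases in the validated path; N-phase chains and sub-phase
  discretization are out of scope.
* No flux variability analysis, elementary modes, MILP or thermodynamic
  extensions.
* Mode classification on degenerate (flat) surfaces merges regions that
  inspection of flux patterns might separate; gradients, not shadow
  prices, define the regions.
* The sequential comparator assumes a single objective (exportable)
  species and pool-style starvation reactions; it is a toy-faithful
  baseline, not a general dynamic-FBA implementation.
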