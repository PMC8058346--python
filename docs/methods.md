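# Methods

## Scope and model of the computation

The package identifies lumped reactions — nonnegative linear combinations
of thermodynamically undetermined reactions in which every metabolite of
unknown standard Gibbs free energy of formation (Δ_f G⁰) cancels — and
uses them as additional constraints in thermodynamic metabolic flux
analysis (TMFA).  The steady-state assumption, mass balance S·v = 0 and
flux bounds are taken as given; lumped reactions never carry flux
variables, so the flux polytope is provably unchanged (this is asserted by
tests that compare FBA optima with and without lumps under permissive
concentration bounds).

## Network preparation

All reversible reactions (lb < 0 < ub) are split into irreversible
forward/reverse halves before lumping, because the combination
coefficients α are constrained nonnegative and direction must therefore be
explicit.  Purely backward reactions (ub ≤ 0) are flipped in place.
Infinite bounds are capped at 1000 flux units.

Reaction roles: the objective reaction (and both split halves of it) is
*biomass*; a reaction with exactly one nonzero stoichiometric entry is an
*exchange*; a reaction in which the same chemical species appears in two
or more compartments is a *transport* reaction; everything else is
*internal*.  Compartments are read from the model and fall back to the
trailing `_<compartment>` id suffix (BiGG convention).  Biomass and
exchange reactions are always excluded from the reduced matrix R: the
biomass reaction is synthetic, and blocking it through an infeasible lump
would be catastrophic; exchanges are poorly evidenced.  Lumping of
internal transport reactions can be switched off (`include_transport`).

A reaction is *undetermined* when it has no reaction-level ΔG⁰ override
and touches at least one metabolite without Δ_f G⁰.  An override marks a
reaction determined even if participants are unannotated; for the reverse
half of a split reaction the override changes sign.

Unknown metabolites are partitioned into groups as the connected
components of the bipartite graph on unknown metabolites and the columns
of R, after removing all annotated metabolites from the graph.  Groups are
separable by construction: no column of R touches unknown metabolites of
two groups, so each group can be lumped independently.  Group order and
within-group member order follow the model's metabolite order, making all
procedure traces and LP counts deterministic.

## The lumping program

For a target set U (rows of R) the program is

    min Σ(y⁺ + y⁻)  s.t.  Rα = y⁺ − y⁻,  y_u = 0 ∀u∈U,
                          α_min ≤ α ≤ α_max,  y⁺, y⁻ ≥ 0,

minimizing the total absolute net stoichiometry of the candidate lump via
the standard variable split.  α_min_j = 1 exactly for columns in which a
*seed* metabolite appears, 0 otherwise.  The seed set equals U in group
mode; in sequential mode it stays the single starting metabolite even as U
grows.  This seed-only scope is deliberate: extending the unit lower bound
to metabolites added during the iteration would contradict the accepted
lump of the packaged walkthrough (r4 + r5 + r6 has α₃ = 0 although the
iteration's target set contains a metabolite occurring in r3).

Numerical choices:

* α is continuous and the program an LP (solved with HiGHS through
  scipy); an integer-α MILP mode exists and is exercised in tests, where
  both modes are also checked against an exhaustive integer grid search on
  small systems.
* α_max defaults to 1000 (boundedness; configurable).
* Net coefficients below 1e-9 in absolute value count as zero, both for
  detecting involved unknown metabolites and for reporting lump
  stoichiometries.  The desk-scale problems are small-integer, so HiGHS
  vertex solutions are exact to well below this tolerance.
* Alternative optima are not enumerated — the first solver optimum is
  taken, trading completeness of the lump *composition* for the absence of
  backtracking.  The set of eliminable metabolites is not affected, but
  compositions and per-seed LP counts could in principle differ between
  solvers; the packaged toy is engineered so that all its optima are
  unique vertices.
* If both split directions of one reversible reaction end up in a
  solution's support, the smaller weight is subtracted from both — the
  pair is a null combination invisible to the objective.

## Procedures

**Group implementation.** One LP with U = seeds = the whole group.  A
solution is accepted only if it involves no unknown metabolite outside the
group (possible in principle through zero-cost side columns, therefore
checked).

**Sequential implementation.** Per seed u: solve with U′ = {u}; on
infeasibility abandon the seed; if the solution involves other unknown
metabolites, add the one with the smallest model index to U′, append the
interim solution y as a new column of the working matrix (α_min = 0 for
that column, its primitive composition retained for later expansion), and
re-solve.  Accepted lumps are recorded in primitive reactions by
recursively substituting augmentation columns.  Augmentations are
discarded between seeds; seeds already eliminated by earlier seeds are
*not* skipped (each metabolite is checked exhaustively); accepted lumps
are not added to R for later seeds, as a lump free of unknown metabolites
cannot help eliminate one.  A per-seed iteration cap of 50 guards against
pathological loops.

**Combined procedure.** Group LP first; on failure, sequential over the
group's members.  It eliminates exactly the same metabolites as running
the sequential implementation alone (asserted on random models) while
solving at most one extra LP per group.

**Naive iterative baseline.** The sequential iteration applied to every
unknown metabolite regardless of grouping; used for LP-count comparisons.

LP counts include infeasible solves — this makes the packaged
walkthrough's totals (8 LPs for the three-metabolite group, 4 for the
two-metabolite group, 10 for the combined run) exact.

## TMFA encoding

Variables: fluxes v (model reactions only), log-concentrations ln x, Gibbs
energy variables ΔG for determined internal/transport reactions and for
lumps, binary indicators z_j (internal/transport model reactions) and y_k
(lumps).  Constraints:

* S·v = 0, flux bounds;
* v_j ≤ z_j·v_j^max for every internal/transport reaction;
* ΔG_j = ΔG⁰_j + RT Σ_i s_ij ln x_i and ΔG_j ≤ (1 − z_j)·M − ε for the
  determined ones;
* per lump k: ΔG_k = ΔG⁰_k + RT Σ_i s_ik ln x_i, ΔG_k ≤ (1 − y_k)·M, and
  Σ_j α_kj z_j ≤ Σ_j α_kj − (1 − y_k), so an infeasible lump forces at
  least one member inactive.

Exchange and biomass pseudo-reactions carry no thermodynamic constraints —
their ΔG⁰ has no physical meaning.  Undetermined model reactions keep flux
variables and the v–z coupling (their z appears in lump constraints) but
no ΔG constraint.

Parameters (defaults): T = 298.15 K, R = 8.314×10⁻³ kJ/(mol·K),
concentrations 1 µM – 20 mM with per-metabolite overrides (never applied
silently; a documented example is relaxing water and abundant cofactors),
big-M = 1000 kJ/mol (must dominate |ΔG⁰| plus the RT·ln span; configurable),
ε = 1e-6 kJ/mol implementing strict negativity, 120 s time limit per MILP
solve.  The ΔG⁰ of a lump is the net-stoichiometry-weighted sum of
formation energies; by linearity this equals the α-weighted sum of member
reaction ΔG⁰ (asserted to 1e-8 relative error on fully annotated models).
Lumps whose net stoichiometry spans compartments would need a membrane
transport correction to ΔG⁰; the correction is a pluggable hook
(`transport_adjustment`) that by default applies nothing and warns.

Variability analysis minimizes and maximizes each ΔG variable subject to
the full MILP plus a biomass floor at a fraction (default 0.9) of the
plain FBA optimum.  A reaction is irreversible iff its maximum ΔG is
strictly negative; a maximum of exactly 0 is reversible.  Because the
with-lump MILP is the no-lump MILP plus constraints, every with-lump range
nests within its no-lump counterpart and the TMFA optimum never exceeds
the FBA optimum — both asserted in tests.

## Fixtures and what the tests show

The toy network freezes the canonical two-group example.  Only the
unknown-metabolite submatrix of the second group is canonical

        r3  r4  r5  r6
    E [ -1   1  -1   0 ]
    G [  0  -1   0   1 ]
    H [ -1   0   1  -1 ]

— the known-metabolite coefficients are this package's reconstruction,
found by a bounded integer search over small coefficient grids such that
the LP optima follow the reference walkthrough exactly (seed E: 3 LPs
involving G then H; seed G: 2 LPs accepting r4 + r5 + r6; seed H: 3 LPs;
2 LPs per seed on the A–B group) with *unique* optimal vertices, so the
counts are solver-independent.  `verify_toy` re-derives all of these
properties against the live LP solver (continuous and integer mode) at
test time.  The toy also carries three determined internal reactions and
boundary exchanges so that FBA and TMFA are nontrivial on it.

The synthetic generator emulates genome-scale models only in the features
the procedures consume: a sparse stoichiometric matrix with a guaranteed
flux-carrying backbone, a controllable reversible fraction, a controllable
fraction of metabolites without Δ_f G⁰, and formation energies drawn from
N(−300, 200²) kJ/mol — magnitudes typical of small metabolites.  It does
not emulate realistic pathway topology, compartmentalization, cofactor
coupling, or correlated annotation gaps (in real models missingness
clusters in lipid/polymer chemistry).  Passing tests therefore demonstrate
algorithmic correctness and the procedure-level invariants, not biological
performance on curated genome-scale reconstructions; those require the
user's own model and annotation files through the SBML/TSV interfaces.

Problem sizes used in the packaged checks — the 10-metabolite,
17-reaction (after splitting) toy and synthetic models of 12–30
metabolites with 10–25 noise reactions — were chosen as the smallest
instances that exercise every code path, including multi-group
partitions, reversible splits and infeasible group LPs.

## Known limitations

* No enumeration of alternative optima: lump compositions are one optimal
  choice among possibly many, and minimal lump cardinality is not
  guaranteed.
* The membrane-transport ΔG⁰ correction for cross-compartment lumps is a
  hook, not an implementation.
* pH/ionic-strength transforms of formation energies and group
  contribution estimation are out of scope; annotations are taken as
  given, in kJ/mol.
* Reversibility classification depends on the concentration bounds and on
  ε; counts on real models additionally depend on the modeller's
  relaxations of individual metabolite bounds.
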