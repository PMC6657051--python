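# Methods

## Model representation

A metabolic model is an ordered list of metabolites and reactions; the
stoichiometric matrix `S` (metabolites × reactions), bound vectors `a`, `b`
and objective vector `c` are derived views that index strictly off that
order. Ordering is preserved from the source file and never sorted, so
solver behaviour under degeneracy is reproducible across reads of the same
file. Fluxes are mmol/gDCW/h; the biomass flux is the specific growth rate
(1/h).

Exchange and demand pseudo-reactions touch exactly one metabolite. Two
orientations occur in practice: the COBRA community convention
`met → ∅` (uptake = negative flux, capacity = negative lower bound) and the
source convention `∅ → met` (uptake = positive flux). Rather than assuming
one, every operation that needs "the uptake direction" derives it from the
stoichiometric sign (`Reaction.import_sign`). Blocking a nutrient uptake
zeroes the import direction only, leaving secretion of the same species
possible — necessary because phosphate-limited cells secrete
nitrogen-containing compounds. A `block_both` mode fixes the flux to zero
for sensitivity checks.

SBML L3+FBC I/O is delegated to cobrapy/libSBML; COBRA-dialect JSON is
read and written directly and stays interoperable with
`cobra.io.load_json_model`. Files missing bounds get the community default
magnitude 1000 (±1000 reversible, [0, 1000] irreversible), logged. A file
without an objective is an explicit error, never a silent zero. Published
models that need curation are handled through `ModelPatch`, an ordered JSON
list of edits (set_bounds / remove_reaction / add_reaction / set_objective)
applied atomically and purely; a failing edit names its index and id.

## The three-stage procedure

1. **FBA.** `max c·v` s.t. `S v = 0`, `a ≤ v ≤ b`. Only the optimum value
   `f_opt` is contractual; the returned vertex is informational, since the
   optimal face is generally degenerate.
2. **pFBA.** `min Σ|v_i|` s.t. the same cone plus `c·v = f_opt`.
   Implemented by splitting `v = p − q` with `p, q ≥ 0` and bounds chosen
   so `p − q` spans exactly `[a, b]`; the LP minimises `Σ(p+q)`. The growth
   constraint is an exact equality, not a `≥ (1−ε) f_opt` relaxation;
   callers of fragile models can rescale `f_opt` themselves. The L1-minimal
   vector can itself be non-unique; the implementation pins deterministic
   solver settings and reports `l1_norm` so alternative optima are
   detectable, with no further lexicographic tie-breaking.
3. **MOMA step.** `min ‖v − v_ref‖²` over the cone of the *perturbed*
   model. The distance runs over all reactions, exchanges included (the
   perturbed exchange profile is itself the prediction of interest, and
   excluding exchanges would decouple uptake from the adjustment). The
   squared norm is minimised; the argmin equals that of the norm. Strict
   convexity gives a unique minimiser, which is what makes the limited
   state well-defined where FBA is not.

Maintenance energy needs no special code: growth-associated maintenance
rides in the biomass equation and vanishes when growth is zero, while the
non-growth ATP-hydrolysis reaction keeps its fixed lower bound in both
states. TAG accumulation is always read from the TAG demand reaction
(config key, default `DM_tag`), never from the biomass equation, which is
treated as storage-fat-free.

## Numerical choices

LPs run on HiGHS through `scipy.optimize.linprog` with feasibility/
optimality tolerances of 1e-9. The QP runs on OSQP (`eps 1e-10`, polishing
on, 2·10⁵ iteration cap, deterministic single-threaded). Every vector any
kernel returns passes an independent post-solve check — `‖S v‖∞ ≤ 1e-6`
and bounds within 1e-6 — that does not trust the solver's status report;
violations downgrade the status to `numeric_failure`. The looser
validation tolerance reflects genome-scale stoichiometries whose
coefficients span several orders of magnitude. Knockouts are imposed as
bounds `(0, 0)`; an equality-row formulation is also exposed and tested to
give the same minimiser. Infeasibility and unboundedness are reported as
statuses (pipeline stages raise a `StageError` naming the stage; the
design scan records per-mutant statuses instead of raising).

## Strain-design scan

Candidate pool: internal reactions with a gene rule. Exchanges, demands,
the biomass pseudo-reaction and orphans (no gene association) cannot be
genetically engineered and never enter. Knockout candidates must keep FBA
growth ≥ 0.9·μ_wt with the flux fixed to zero; overexpression candidates
additionally need nonzero reference flux (doubling a zero flux is a vacuous
constraint, which is also why pFBA-zeroed degradation pathways never rank).
The overexpression fold starts at 2 and is relaxed down a descending
0.1-step grid to 1.1; the first feasible, growth-admissible fold wins.
Grid, direction and the FBA-stage screen (cheapest check consistent with
the replete-phase growth criterion) are package decisions; interval
endpoints and the 90 % floor are the method's stated conditions.

Per mutant, the overexpression equality binds the FBA and pFBA stages only;
the mutant's own pFBA solution becomes the MOMA anchor and the limited
state may re-adjust the target within its original bounds. Knockouts stay
fixed in all three stages. Scoring: `yield` (TAG demand flux / substrate
uptake, both in the limited state; the default, since substrate uptake
differs between mutants) or `rate` (raw TAG flux), improvement relative to
a wild-type run with identical settings. Candidates are scored by pure
per-candidate computation, so execution order cannot change results.

## What the toy networks emulate — and what they do not

The fixtures are built so that every pipeline stage has an independent
oracle at desk scale:

* **TOY-A/TOY-B** are solvable by single-variable calculus: with ammonium
  blocked, growth is forced to zero and the QP splits the carbon deviation
  across the available sinks — (5, 5) with one sink, (20/3, 10/3, 10/3)
  with two. They pin the QP arithmetic exactly.
* **TOY-C** has an uptake ceiling that caps a twofold overexpression at
  1.2-fold, pinning the fold-adjustment logic.
* **TOY-Y** (27 reactions, 18 metabolites, integer stoichiometry,
  carbon-balanced outside the biomass sink) caricatures oleaginous
  metabolism: glycolysis, a TCA-like loop, a citrate node with an export
  route and an ATP-citrate-lyase route into TAG synthesis, respiration, an
  NGAM drain (lower bound 1), a glutamate synthesis/degradation pair whose
  synthesis leg feeds biomass (so it carries reference flux) and whose
  closed cycle burns ATP + NADH, a glycogen storage cycle with zero
  reference flux, an amino-acid secretion channel that only engages under
  phosphate limitation, and a structurally blocked sterol-degradation
  reaction whose knockout is a strict no-op. Under nitrogen blockage it
  reproduces the qualitative physiology: growth stops, glucose uptake
  drops (to 59 % of reference), TAG and citrate become the carbon sinks,
  the futile cycle spins, and knocking the cycle's degradation leg out
  redirects the saved energy into lipid — the top-ranked knockout.

What passing these tests does **not** show: real GEMs have thousands of
reactions, compartments, realistic biomass compositions and thermodynamic
loops; the toys probe the optimisation machinery and the scan logic, not
model quality. Reproducing published genome-scale target lists additionally
requires the published *Y. lipolytica* model plus its curation patch and
medium definition, supplied by the user through the SBML/JSON loader,
`ModelPatch` and the CLI.

## Problem sizes and defaults

All shipped computations are desk-scale: the largest fixture has 27
reactions, the full TOY-Y scan solves ~3 optimisations for each of its 14
candidates, and the whole test suite plus the acceptance script run in
seconds. Defaults — uptake capacity 10 on the toy carbon sources, NGAM 1,
growth threshold 0.9, fold grid 2.0→1.1 step 0.1, reporting cutoff 10 % —
are fixed in the generators and `ScanConfig`; the sampling-based optimality
checks use 100 growth-pinned vertices (pFBA) and 40 vertices × 60 convex
combinations (QP), seeded for reproducibility.

## Known limitations

* No loopless-FBA or flux-variability machinery; thermodynamically
  infeasible cycles in a user's GEM must be removed by a patch, as was done
  for the published *Y. lipolytica* reconstruction.
* pFBA degeneracy is detected (via `l1_norm`) but not resolved further;
  on degenerate GEMs the reference state, and hence downstream
  predictions, can depend on solver internals.
* Single interventions only: no double mutants, no heterologous pathway
  addition, no gene-level (GPR-resolved) deletion mapping — the scan
  operates on reactions, storing gene rules for reporting.
* Two quasi-steady states are modelled; there is no batch time course or
  chemostat growth-coupling scenario.
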