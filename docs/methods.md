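# Methods

## The model

`fluxcast` predicts the central-carbon fluxome of a heterotrophic bacterium
from a description of its culture condition, in two stages.

**Stage 1 — per-flux regression.** The central metabolism is lumped into 29
fluxes `v1..v29` covering glycolysis (EMP), the pentose-phosphate (PP)
pathway, the Entner–Doudoroff (ED) pathway, the TCA cycle, the glyoxylate
shunt, and two lumped anaplerotic routes (PEP + CO₂ → OAA, flux `v28`, and
MAL → PYR + CO₂, flux `v29`). All fluxes are normalized so that the total
carbon uptake is 100. Each flux gets its own single-output regressor
(RBF- or linear-kernel support-vector regression, k-nearest neighbours, or a
decision tree) trained on an encoded condition vector: six one-hot
categorical descriptors (species, nutrient type, oxygen condition,
engineering method, genetic background, cultivation method) followed by 16
standardized continuous descriptors (growth rate in 1/h, substrate uptake
rate, and the uptake ratios of 14 substrates). Targets are min–max scaled
to [0, 1] per flux so that cross-validated mean-squared errors are
comparable between fluxes with very different dynamic ranges.

**Stage 2 — stoichiometric reconciliation.** Because the 29 regressors are
independent, their joint output v̂ generally violates mass balance. Each of
the 21 balanced metabolite pools yields a steady-state constraint; pools
that feed biomass synthesis or excretion carry an implicit non-negative
drain and therefore relax to inequalities, while the remaining pools give
strict equalities. Together with the substrate-entry identity
`v1 = 100·(ratio_glucose + ratio_galactose)` this gives, for a substrate
mix with ratios r,

    S v  = b_eq(r)    (9 rows)
    A v ≥ b_in(r)     (12 rows; 13 with the optional SUC row)

with the `100·ratio` entry constants moved to the right-hand side. In the
spirit of minimization of metabolic adjustment (MOMA), the reported fluxome
is the feasible vector closest to v̂ in range-scaled coordinates:

    minimize  Σᵢ [(vᵢ − v̂ᵢ)/(Maxᵢ − Minᵢ)]²   s.t.  S v = b_eq, A v ≥ b_in

where Minᵢ/Maxᵢ default to the extremes of flux i in the training table.
Expanding the square gives a strictly convex QP with diagonal Hessian
1/(Maxᵢ − Minᵢ)²; the constant term and a factor of two are dropped. The
same Min/Max pairs may additionally act as hard box constraints
(`use_boxes`, on by default and switchable off); a knockout pins one flux's
box to [0, 0] and survives `--no-box` (e.g. a *zwf* knockout zeroes `v10`,
the oxidative-PP entry). In *zwf*-knockout mode the direction of the OAA
inequality can be reversed, the one case in which its sign is known to flip.

## Numerical choices

* **QP solver.** The projection is solved by an in-house primal active-set
  scheme: each iterate solves the KKT system of the equalities plus the
  current working set exactly (dense symmetric solve), then drops the
  working-set row with the most negative multiplier (lowest index first) or
  adds the most violated inequality. For these small dense systems
  (29 variables, ≤ 80 rows) every iterate is exact to linear-solve
  precision, so the returned point satisfies the KKT conditions to ~1e-10.
  A `scipy.optimize` trust-constr run guards the (never observed) cycling
  case. Infeasibility is certified by a phase-1 LP; an elastic relaxation
  then names the unsatisfiable rows in the error.
* **Feasibility tolerance** is 1e-6 on the normalized-flux scale;
  `check_feasibility` reports every violated row beyond it.
* **Degenerate ranges.** A flux constant in the training data (Max = Min)
  is excluded from regression, predicted at its constant, and its QP weight
  uses a floored range of 1e-6 × the largest observed range so the Hessian
  stays positive-definite.
* **Infeasible user bounds** raise an error naming the violated rows;
  optionally (`auto_relax_boxes`) the boxes — never the stoichiometry — are
  widened by a geometrically growing, recorded margin.
* **Standardization** uses population (÷N) variance; vocabularies keep
  first-appearance order, so the encoded column order is a pure function of
  the training table and serializes with the scaler state.
* **Tie-breaking** in grid search takes the first grid point (declared
  iteration order) among minimizers; folds come from a seeded uniform
  shuffle split into k near-equal parts.
* **Unseen categorical levels** at prediction time encode as an all-zero
  block with a warning (the service must accept novel species); a strict
  mode raises instead.

## Design choices where the design was open

* The canonical equations leave lactate, acetate and NaHCO₃ without a
  balance term. Lactate enters at the PYR pool, acetate at the AceCoA pool
  (their biochemical entry points); NaHCO₃ contributes no carbon-balance
  constant because CO₂ pools are not balanced in this carbon-only network.
  Both mappings are flagged options, on by default.
* The SUC pool is drained but has no corresponding inequality in the
  canonical row list; the package reproduces that omission by default and
  offers the extra row behind `suc_inequality=True`.
* Six categorical features are implemented (the descriptor list is more
  specific than any summary count of it).
* Min/Max serve both as objective weights and, independently, as optional
  box constraints; with boxes disabled the dataset ranges still define the
  weights.
* Min–max target scaling is the default; z-score scaling is available
  behind a flag (`scale_targets(..., method="zscore")`). The two behave
  very similarly, and min–max additionally supplies the QP range weights,
  so the bundled pipeline keeps it.
* Hyperparameters are tuned per flux; a shared-per-algorithm mode can be
  emulated by passing a single-point grid.
* Flux labels for `v9`, `v26`, `v27` (AcCoA/PYR-consuming excretion routes)
  and parts of the non-oxidative PP wiring are marked "inferred" in the
  annotation table: their endpoints follow mechanically from the balance
  equations, but the exact enzyme identities are not pinned down.
* The input-validation rule inventory (growth rate in [0, 2.5] 1/h, positive
  uptake, oxygen level in its set, ratio simplex, an anaerobic-growth
  warning ceiling of 1.0 1/h) is an artifact default, fully overridable from
  a YAML rules file. The error/warning severity split is likewise an
  artifact choice: warnings inform, errors gate the pipeline.

## The synthetic-data generator

Real training tables for this pipeline come from curated isotope-tracing
(¹³C-MFA) literature; the generator emulates that table's shape so the whole
pipeline is testable offline.

* **Conditions** draw categorical levels from configurable vocabularies,
  substrate mixes from a Dirichlet over a random subset of 1–3 substrates,
  and growth/uptake rates log-uniformly within oxygen-dependent ranges; all
  draws pass the default validation rules.
* **True fluxes** come from a deterministic response kernel — substrate
  entries fix the boundary constants, oxygen throttles TCA fluxes, species
  offsets shift the PP/ED split, growth rate modulates biomass drains with a
  saturating (tanh) response — projected onto the constraint polytope of
  the sample's own mix (unit weights) and stepped a random fraction
  (5–25 %) toward the polytope's Chebyshev center so the result is strictly
  feasible at 1e-8. The center LP is bounded by a generous sampler box
  (−25 to 250 normalized units). A hit-and-run sampler
  (`sample_feasible_flux(..., method="hit_and_run")`) is available for
  distributional studies of the feasible set; the projection scheme stays
  the default because it reuses the tested QP machinery and tracks the
  kernel target.
* **Observed fluxes** add iid Gaussian noise per flux, default sd 2
  normalized-flux units, mirroring roughly symmetric isotope-tracing
  confidence intervals.
* Default dataset sizes of 450 (and a 150-sample subset for data-size
  comparisons) mirror the whole-phenotype vs wild-type-only split sizes of
  the curated literature corpus.

What the kernel does **not** emulate: real species composition and its
literature bias, regulatory flux re-organization in engineered strains,
anaerobic overflow metabolism, or correlated measurement errors. Passing
tests therefore demonstrate that the pipeline recovers a smooth,
stoichiometrically consistent condition→flux map under iid noise — not that
it reproduces any organism's measured fluxome.

## Problem sizes used by the test suite

The suite runs the full pipeline at 450 training + 100 held-out samples for
the recovery experiment (with a 3-point SVR grid under 10-fold CV), 200
draws for the correction-improves-RMSE check, 100 corrections across 20
random mixes for the feasibility sweep, and 300 fuzzed conditions for the
validation→encoding→correction flow. These sizes are the package's own
defaults for a fast, deterministic suite; all of them are arguments, not
constants.

## Known limitations

* The network balances carbon pools only — no cofactor (ATP/NAD(P)H)
  balancing, no thermodynamic constraints, no genome-scale models.
* Normalization to 100 units of uptake means absolute rates are out of
  scope; the uptake-rate feature only informs the regression.
* The QP can only repair predictions toward the polytope; systematic biases
  in the regressors (e.g. for fluxes absent from the training distribution)
  are not corrected, and a pointwise error reduction is not guaranteed —
  only the ensemble-mean improvement is (and is what the tests assert).
* Predictions for substrates outside the 14-substrate vocabulary require
  mapping them to existing entry points by hand.
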