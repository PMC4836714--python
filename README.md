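# fluxcast

Rapid prediction of bacterial central-carbon fluxomes from culture
conditions, for systems biologists and metabolic engineers who want a
first-pass flux map without running an isotope-tracing (¹³C-MFA)
experiment.

## What it computes

The central metabolism of heterotrophic bacteria — glycolysis, the pentose
phosphate and Entner–Doudoroff pathways, the TCA cycle, the glyoxylate
shunt, and two lumped anaplerotic routes — is represented by 29 fluxes
`v1..v29`, normalized to a total carbon uptake of 100. Given a culture
condition (species, oxygen regime, cultivation method, genetic background,
growth rate, uptake rate, and the ratios of up to 14 substrates), the
package:

1. **predicts** each flux with its own tuned regressor (RBF-kernel SVR by
   default; k-NN and decision trees are also available), trained with
   per-flux grid search under seeded 10-fold cross-validation scored by MSE
   on min–max-scaled targets, and then
2. **reconciles** the 29 independent predictions v̂ with the steady-state
   mass balances of the network by a MOMA-style quadratic program,

       min Σᵢ [(vᵢ − v̂ᵢ)/(Maxᵢ − Minᵢ)]²   s.t.  S v = b_eq,  A v ≥ b_in,

   where the nine equalities come from metabolite pools without a biomass
   drain (plus the substrate-entry identity `v1 = 100·(r_glc + r_gal)`),
   the twelve inequalities from pools whose non-negative biomass/excretion
   drain relaxes the balance, and Minᵢ/Maxᵢ are the per-flux extremes of
   the training data. Knockouts pin a flux's bounds to zero (e.g. *zwf* →
   `v10 = 0`).

Inputs are domain-checked first (ratio simplex, realistic growth rates,
known oxygen levels, …) so nonsense requests fail with a readable report
instead of a numeric answer.

A synthetic-data module generates training tables with the exact shape the
pipeline consumes — conditions paired with stoichiometrically feasible
"true" fluxomes plus Gaussian observation noise — so everything here runs
and is tested without any external dataset.

## Worked example

Simulate a 450-sample training table, tune and fit the SVR ensemble, then
predict an aerobic glucose-fed *E. coli* culture:

```sh
fluxcast simulate --n 450 --seed 7 --noise 2.0 --out train.tsv

cat > grid.yaml <<'YAML'
C: [1.0, 10.0, 100.0]
epsilon: [0.01]
gamma_scale_multiplier: [1.0]
YAML
fluxcast train --data train.tsv --algorithm svr-rbf --grid grid.yaml \
    --folds 10 --seed 7 --out model.zip --cv-report cv.tsv

cat > condition.yaml <<'YAML'
species: "E. coli"
nutrient_type: minimal
oxygen: aerobic
cultivation_method: shake_flask
genetic_background: wild_type
engineering_method: none
growth_rate: 0.6       # 1/h
uptake_rate: 8.0       # mmol/gDW/h
substrate_ratios:
  glucose: 1.0
YAML
fluxcast predict --model model.zip --condition condition.yaml \
    --out fluxes.tsv --no-box
```

The run logs each stage and writes a diffable TSV:

```
[fluxcast] stage=validate passed=True issues=0 hash=b11c07156dd9
[fluxcast] stage=predict model=central-carbon-29flux-v1 seed=0
[fluxcast] stage=correct feasible=True objective=0.004672 tolerance=1e-06
[fluxcast] stage=write out=fluxes.tsv
```

```
# fluxcast 0.1.0 config_hash=b11c07156dd9
flux_id	label	ml_value	corrected_value
v1	glucose/galactose uptake to G6P	105.079328	100.000000
v2	phosphoglucose isomerase (G6P->F6P)	83.414380	83.414380
v3	FBP aldolase (FBP->DHAP+GAP)	83.212986	84.119013
v4	triose phosphate isomerase (DHAP->GAP)	85.041561	84.119013
...
```

Reading it: `ml_value` is the raw ensemble output, which needs no
stoichiometric consistency — here it puts 105.1 units into glycolysis
although a pure-glucose feed fixes the entry flux at exactly 100.
`corrected_value` is the quadratic-programming reconciliation: `v1` snaps
to 100.000000, `v3` and `v4` are pulled onto the DHAP balance
(`v3 + 100·r_glycerol = v4`, here simply `v3 = v4`), and every balance
holds to the 1e-6 feasibility tolerance. Fluxes already consistent with
the constraints (e.g. `v2`) pass through unchanged.

Knockouts and constraint variants:

```sh
fluxcast predict ... --knockout v10 --zwf-mode   # zwf deletion: v10 = 0,
                                                 # OAA inequality reversed
fluxcast validate --condition condition.yaml     # domain check only
fluxcast summarize --data train.tsv              # per-flux mean/range/95%
```

The same functionality is available as a library (`fluxcast.stoichiometry`,
`.encoding`, `.regressors`, `.qp_correction`, `.input_validation`,
`.synthetic_data`, `.io_cli`); see `docs/methods.md` for the model,
numerical choices and limitations.

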