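# dooit

Dual-objective ν-SVR modeling of drug solubility in binary solvent
mixtures, with iterative feature pruning and stability-based champion
selection.

## The problem

Solubility of a solid solute (e.g. a phenolic or benzoic acid) in a binary
aqueous–organic mixture is strongly non-additive: maxima at intermediate
composition, synergy in some systems and none in others.  Physics-based
predictions (COSMO-RS) capture the right scale but carry systematic errors,
while the experimental record is fragmented across papers that disagree in
temperatures and compositions.  This package provides the full modeling
chain used to turn that raw material into a compact, reproducible QSPR
model of `log x₁` (decadic log of mole-fraction solubility):

* **Descriptors** — per-mixture feature vectors from per-molecule COSMO-RS
  quantities (`E_int`, `E_misfit`, `E_HB`, `E_vdW`, `μ`, σ-potential):
  set 1 = 16 features (COSMO-RS-predicted solubility + solute terms +
  mole-fraction-weighted solvent terms + differences), set 2 = 28 (plus 12
  condensed σ-potential bins over the HBD/HH/HBA regions).
* **Curation** — the Buchowski–Ksiązczak λh equation, the three-parameter
  van't Hoff model `ln x = a + b/T + c ln T`, and the Jouyban–Acree
  cosolvency model
  `ln x_m = w₁ln x₁ + w₂ln x₂ + (w₁w₂/T)ΣᵢJᵢ(w₁−w₂)ⁱ`, plus the
  consistency taxonomy (categories 1–4) that decides which standardization
  a literature dataset needs.
* **Model search** — per run: an 80/20 split, then per feature count a
  seeded dual-objective search over ν-SVR hyperparameters (ν, C, and a
  log-scale factor on a median-distance gamma anchor) minimizing both
  5-fold CV MAE and the support-vector ratio; Pareto-front extraction; the
  one-standard-error rule; out-of-fold permutation importance (10
  repeats); elimination of the least important feature.
* **Stability selection** — across many independent runs: per-run
  parsimony votes, a ≥30 % frequency rule with a one-SE accuracy band to
  fix the architecture (feature count), and a composite 50/30/20 score
  (accuracy / R² / train-test gap) to crown the champion model.
* **Synthetic data** — seeded generators for planted-feature QSPR tables,
  σ-potential curves and model-generated solubility curves, so the entire
  pipeline is testable without any external data.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Generate a planted table (8 features, 3 informative), run the
search-and-prune pipeline under three independent splits, and aggregate:

```
$ dooit synth-qspr --n 200 --informative 3 --noise 5 --solutes 6 --seed 7 \
        --out synth.csv --truth truth.json
wrote 200 rows, informative: x04,x05,x07

$ for s in 1 2 3; do
    dooit dooit-run --table synth.csv --target log_x \
          --pool x00,x01,x02,x03,x04,x05,x06,x07 \
          --trials 40 --min-features 3 --seed $s --out runs/run$s.json
  done
run run-seed1: 6 levels, final mae_test=0.1184
run run-seed2: 6 levels, final mae_test=0.0953
run run-seed3: 6 levels, final mae_test=0.1457

$ dooit dooit-select --runs runs --out champion.json --report report.csv
architecture: 3 features; champion mae_test=0.0953 score=1.000
```

Each run prunes from 8 features down to 3 (6 levels), reporting the
held-out MAE of the 1-SE-selected candidate at the floor.  The aggregator
finds that all runs vote for a 3-feature architecture and crowns the
best-scoring candidate — whose features `x04, x05, x07` are exactly the
planted informative set, and whose test MAE (0.095 log units) approaches
the generator's noise floor.  `champion.json` carries the full model
record (hyperparameters, importances, metrics); `report.csv` the
per-feature-count stability table.

The curation models are exposed the same way, e.g.

```
$ dooit curate-fit --model lh --data curve.csv --tm 500 --out fit.json
fitted lh: rmse_lnx=4.5e-16
```

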