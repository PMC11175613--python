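# brainage-eval

Evaluation of Brain Age as a biomarker of cognitive decline, on
synthetic cohorts with known ground truth.

Brain Age — the age a regression model predicts for a person from
their brain imaging features — is widely used as an aging biomarker:
if your brain "looks older" than you are, the gap is read as a warning
sign. This package asks the question that matters for that use: **once
chronological age is already known, how much extra variance in fluid
cognition do Brain Age indices actually capture?** It implements the
full evaluation pipeline:

1. **Synthetic cohort generator** — a linear-Gaussian simulator of an
   aging-cohort study (default: 504 participants aged 36–100, 18
   brain-feature sets spanning task contrasts, task/rest functional
   connectivity and structural MRI), with closed-form ground-truth R²
   for every feature set so recovery can be tested exactly.
2. **Prediction engine** — nested 5×5 cross-validated Elastic Net per
   feature set, plus stacked second-level models over the per-set
   predictions; 18 sets + 8 stacks = 26 models per target. Predicting
   age gives *Brain Age*; predicting fluid cognition from the same
   features gives *Brain Cognition*.
3. **Brain Age indices** — Brain Age Gap (predicted − chronological
   age), and the slope/intercept-corrected variants that remove the
   regression-to-the-mean age dependence, fitted on training folds and
   applied out of fold.
4. **Commonality analysis** — decomposes the R² of fluid cognition
   regressed on {age, index} (and {age, index, Brain Cognition}) into
   unique and common effects, with hierarchical F-change tests.

The headline result this pipeline is built to expose: even a Brain Age
model with excellent age accuracy can carry almost **no unique
cognition signal beyond age itself**, while Brain Cognition — trained
on the same features — carries an order of magnitude more. Accuracy at
predicting age and usefulness as a cognition biomarker are different
things, and can even trade off: the better a feature set tracks age,
the more of its cognition variance is *shared* with age rather than
unique.

## Worked example

A full study-scale run (504 participants, 18 feature sets at
desk-scale dimensions, reduced 7×5 hyperparameter grid) takes about
half a minute on one CPU. Write a config file:

```yaml
# study.yaml
seed: 1
cohort: {preset: study, n_participants: 504, contrast_dim: 40, connectivity_dim: 300}
grid: reduced
n_components: 20
importance: true
out_dir: run
```

then `brainage-eval all --config study.yaml`, or equivalently in
Python:

```python
from brainage_eval import RunConfig, run_all, report

cfg = RunConfig(
    seed=1,
    cohort={"preset": "study", "n_participants": 504,
            "contrast_dim": 40, "connectivity_dim": 300},
    grid="reduced", n_components=20, out_dir="run",
)
run_all(cfg)
summary = report("run")
```

With seed 1 this produces (from `performance_summary.csv`):

```
== age ==
model                           pearson_r      r2    mae
stacked_all                        0.8918  0.7899  6.598
stacked_all_excl_task_contrast     0.8848  0.7801  6.723
cortical_thickness (best single)   0.8510  0.7158  7.732

== cognition ==
stacked_all                        0.6455  0.4075  9.312
```

Stacking all feature sets predicts age well (R² = 0.79, MAE 6.6
years). The observed age–cognition R² in the cohort is 0.340 (design
value 0.32). But the commonality decomposition of fluid cognition on
{age, index} (`commonality2.csv`) shows where that leaves the indices:

```
max unique effect of any Brain Age index  : ΔR² = 0.0115
max unique effect of Brain Cognition      : ΔR² = 0.1616
```

Every Brain Age index — gap, corrected or not, from any of the 26
models — adds at most ~1% unique variance once age is in the model;
most of what the indices explain is *common* with chronological age
(common effect up to 0.316). Brain Cognition, trained on the same
brain features, uniquely adds 16%. The raw gap's negative correlation
with age (−0.55 for `stacked_all`) shrinks to −0.20 out of fold after
slope/intercept correction.

## Reproduction

The numbered scripts under `analysis/` reproduce the full study into
`results/run/` (each stage is a pure function of the seed, so later
scripts re-derive earlier stages bit-identically):

```bash
cd analysis
python 01_simulate.py            # cohort + ground truth
python 02_fit_predictions.py     # 26 models x 2 targets, nested CV
python 03_brain_age_indices.py   # gap / corrected indices per model
python 04_commonality.py         # variance decompositions
python 05_report.py              # summary tables
```

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
runs the pipeline end to end and writes the principal quantities
(model counts, best-model R²/MAE, maximum unique effects, conservation
residuals) as JSON. Re-running any entry point with the same seed
reproduces every CSV byte-for-byte.

To analyse your own data instead of a synthetic cohort, write a
`manifest.json` + CSV layout matching `brainage_eval.cohort.write_cohort`
(see `docs/methods.md`) and point the config at it:
`cohort: {manifest: path/to/manifest.json}`.

## Testing

```bash
python -m pytest -q tests/
```

The suite covers closed-form oracles for the Elastic Net and PCA,
brute-force inclusion–exclusion oracles for the commonality
components, leakage (bit-identity under outer-test perturbation),
ground-truth recovery, and end-to-end reproducibility; the acceptance
contracts live in `tests/test_acceptance.py`.

## Layout

- `src/brainage_eval/` — the library (cohort, prep, folds, enet,
  engine, indices, commonality, pipeline, cli)
- `analysis/` — numbered thin driver scripts writing under `results/`
- `scripts/acceptance.py` — end-to-end run + JSON summary
- `docs/methods.md` — model, assumptions and numerical choices
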