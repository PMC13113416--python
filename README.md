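# emgdose

Data-driven dosing of shoulder-rehabilitation exercise from surface
electromyography (sEMG). The package is aimed at researchers in
rehabilitation biomechanics and biomedical signal processing who want a
tested, reproducible reference pipeline for turning multi-muscle sEMG
recordings into (a) cross-subject predictions of muscle activation and
(b) an optimized division of a fixed-length therapy session across
exercises.

Because real multi-subject shoulder sEMG corpora are rarely shareable,
the package ships a first-class synthetic cohort generator with planted,
controllable structure, so every downstream stage is testable without
any data download.

## The pipeline

1. **Synthetic cohort** (`emgdose.cohort`) — 8 subjects × 2 sessions × 4
   movements (scaption, internal rotation at side, external rotation at
   side, external rotation at 90° abduction), six muscles at 2000 Hz:
   three superficial (medial deltoid, posterior deltoid, trapezius) and
   three deep (supraspinatus, infraspinatus, teres minor). Channel model:

   `x_m(t) = g[m,v] · c_subj · env(t) · (ρ·z(t) + √(1−ρ²)·n_m(t)) + σ₀·w_m(t)`

   with 20–450 Hz band-limited noise terms, a shared latent drive `z`
   whose weight ρ plants learnable inter-muscle correlation, and a
   movement-dependent gain table `g` encoding which muscles each
   exercise primarily activates.
2. **Features** (`emgdose.features`) — sliding-window RMS (250 samples,
   non-overlapping by default), peak normalization per subject × muscle
   across both sessions and all movements (each value in [0, 1], every
   subject attains 1.0 per muscle), integer label encoding of the
   movement. Windows never straddle a session boundary.
3. **Cross-subject validation** (`emgdose.crossval`) — leave-one-subject-
   out: for each target muscle a regressor (SVR, k-NN, AdaBoost or
   XGBoost) predicts its normalized RMS from the other five muscles plus
   the movement code; scored with MSE = (1/n)Σ(yᵢ−ŷᵢ)² and
   R² = 1 − SSres/SStot, ranked by R² first.
4. **Dose optimization** (`emgdose.dosage`) — per-exercise superficial and
   deep activation means (sᵢ, dᵢ) from the pooled out-of-fold
   predictions, then minutes xᵢ minimizing

   `f(x) = −ws·Σ xᵢsᵢ − wd·Σ xᵢdᵢ + 0.1·Var(x)`,  `Σxᵢ = 60`, `5 ≤ xᵢ ≤ 30`

   via SciPy's trust-region constrained solver from the equal split, for
   weighting cases 70/30, 50/50 and 30/70 (superficial/deep). An
   exhaustive 0.5-minute grid oracle independently verifies the solver.

## Worked example

```python
import emgdose as e

config = e.CohortConfig(n_subjects=4, n_sessions=2, duration_per_trial=5.0,
                        shared_drive_correlation=0.9, seed=7)
table = e.build_feature_table(e.generate_cohort(config))
report = e.run_comparison(table, [e.ModelSpec("knn"), e.ModelSpec("xgboost", seed=7)])
print(report.per_model_summary().round(4))

preds = report.predictions["xgboost"].copy()
preds["movement_code"] = table["movement_code"]
profile = e.activation_profile(preds)
for plan in e.run_cases(profile):
    print(plan.weights.case_label, plan.minutes_rounded, round(plan.objective_value, 2))
```

prints

```
            mse      r2  mse_sd   r2_sd  train_time
model
knn      0.0011  0.9867  0.0009  0.0107      0.0344
xgboost  0.0015  0.9819  0.0016  0.0193      1.5433
70/30 [18 13 15 15] -18.84
50/50 [18 12 15 15] -19.72
30/70 [18 11 15 15] -20.65
```

Reading this: both models generalize across held-out subjects (grand R²
≈ 0.98 on this strongly structured synthetic cohort; `mse` is on the
dimensionless normalized-RMS scale). The three session plans allocate
the most time to scaption — the movement whose planted gains activate
the most muscles — and shift a minute from internal rotation toward the
deep-weighted cases, while always summing to 60 minutes within bounds.

The same stages are available from a shell:

```bash
emgdose simulate --subjects 8 --sessions 2 --seed 17 --out cohort/
emgdose extract --window 250 --in cohort/ --out features.csv
emgdose validate --features features.csv --models svr,knn,adaboost,xgboost --seed 7 --report cv.json
emgdose run-all --seed 7 --out run/   # full pipeline + report
```

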