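# Methods

## Problem setting

Surface EMG measures superficial shoulder muscles reliably but deep
rotator-cuff muscles only indirectly. The pipeline asks two questions:
(1) how well can one muscle's activation be predicted from the other
five across *people*, and (2) given predicted per-exercise activation,
how should a fixed 60-minute therapy session be divided among four
standard shoulder exercises so that superficial activation is promoted,
deep-muscle strain weighted as the clinician chooses, and the schedule
stays practical?

## Synthetic cohort model

Each trial (one subject, session, movement) produces six channels

x_m(t) = g[m,v] · c_subj · env(t) · (ρ·z(t) + √(1−ρ²)·n_m(t)) + σ₀·w_m(t)

- **Gain table g (μV).** Movement-dependent amplitude: muscles primarily
  activated by a movement get 1.0, others 0.2. The high/low contrast
  makes the activation pattern recoverable yet overlapping; both values
  are configurable.
- **Shared drive z, weight ρ ∈ [0,1].** A latent band-limited signal
  common to all channels of a trial. ρ controls the planted inter-muscle
  correlation and hence how learnable cross-muscle prediction is.
  Default 0.6 (moderate physiological synergy); benchmark runs that
  exercise planted-structure recovery use ρ = 0.9.
- **Envelope env(t).** Repeated raised-cosine bursts (period 3 s, one
  burst per repetition) over a small tonic baseline (0.1) standing for
  stabilizing co-contraction. The envelope is shared across channels —
  all muscles follow the movement cycle — which itself couples windowed
  RMS across channels; a *null* cohort with no cross-channel linkage
  therefore needs `envelope_tonic=1.0` (flat envelope) in addition to
  ρ = 0.
- **Subject scale c_subj.** One log-normal multiplier per subject
  (σ = 0.2), shared across sessions and movements — a stand-in for
  electrode placement and anthropometric variability. It cancels under
  peak normalization by design.
- **Noise floor σ₀ = 0.05 μV.** Additive band-limited instrument noise.
- **Band limitation.** Every stochastic term is 4th-order Butterworth
  band-passed to 20–450 Hz (zero-phase) and normalized to unit RMS, so
  channel RMS scales exactly linearly with gain and out-of-band power is
  a few percent at most. No 50/60 Hz component is generated, so the
  notch filter of a real acquisition chain is implicit.
- **Determinism.** All random streams derive from
  `SeedSequence([seed, tag, subject, session, movement])`; the same
  configuration reproduces the identical cohort bit for bit.
- **Trial length.** Default 30 s per movement per session. Recording
  length is a free design parameter here; benchmark scripts and heavier
  tests use 5–10 s trials, which already give hundreds of windows per
  subject.

What the generator does *not* emulate: motor-unit physiology, crosstalk
between deep and superficial channels, movement artifacts, electrode
drift, inter-session electrode-repositioning effects, or fatigue. A
passing benchmark on this cohort demonstrates that the pipeline's
mechanics (windowing, normalization, subject-wise validation,
optimization) are correct and that planted structure is recovered — not
that comparable accuracy would be reached on clinical recordings, where
cross-subject R² is far lower.

## Feature extraction

- **Windowed RMS**: 250-sample windows (125 ms at 2000 Hz),
  non-overlapping by default. Overlap is configurable via `stride`;
  non-overlap keeps windows statistically independent. Windows are
  computed per recording segment, so merged two-session blocks never
  yield a window spanning the session joint (which would create an
  artificial discontinuity window).
- **Peak normalization**: each value divided by its subject × muscle
  maximum across both sessions and all four movements (the broadest
  scope, so activations are comparable across movements); a per-session
  scope is available. The group maximum maps to exactly 1.0 and peaks
  are retained for inverting the transform. An all-zero channel raises
  rather than dividing by zero. Consequence: MSE and R² downstream are
  dimensionless (normalized-RMS scale), even though raw channels are in
  μV.
- **Movement encoding**: fixed integer codes in the canonical order
  (scaption 0, internal rotation at side 1, external rotation at side
  2, external rotation at 90° abduction 3). Label encoding follows the
  convention of treating the movement as contextual task information; a
  one-hot option exists (`one_hot_movement=True`) since plain integer
  codes impose an artificial ordering on tree-agnostic learners like SVR.

## Cross-subject validation

- **Protocol**: one fold per subject; all of that subject's windows are
  the test set, the remaining subjects train. One model per (target
  muscle, fold): 6 × n_subjects fits per model kind. The target muscle
  is structurally excluded from the feature list (asserted at fit time).
- **Metrics**: MSE and R² per fold × muscle cell. Grand means are the
  unweighted mean over cells (the window-count-weighted alternative is
  available via `aggregate="windows"`); with equal windows per subject
  the two coincide. Ranking is by grand R² descending, then MSE.
- **Models**: SVR, k-NN, AdaBoost, XGBoost with their library defaults
  (recorded verbatim in every report, since results are irreproducible
  otherwise), `random_state` seeded for the stochastic learners, and
  XGBoost pinned to one thread for determinism.
- **Training time** is measured around the `fit` call only and reported
  for completeness; it is hardware-dependent and excluded from any
  correctness claim.
- **Null behaviour**: on a cohort with equal gains, no shared drive and a
  flat envelope, an interpolating tree learner lands at *negative*
  out-of-subject R² (noise memorization roughly doubles the error
  variance, R² ≈ −1). The meaningful property is the absence of positive
  skill, which the test suite asserts; R² exactly near 0 would require a
  mean-predicting learner.

## Session-dose optimization

- **Profile**: sᵢ (dᵢ) is the mean predicted normalized RMS over the
  three superficial (deep) muscles over all pooled out-of-fold windows
  of exercise i. Pooling LOSO test predictions keeps the profile an
  honest cross-subject estimate; no final refit on all data is done.
- **Objective** (minimized): f(x) = −ws·Σxᵢsᵢ − wd·Σxᵢdᵢ + λᵥ·Var(x),
  λᵥ = 0.1, Var the population variance (divide by n = 4) of the minutes
  vector. The variance term penalizes concentrating the session in one
  exercise. The sign of the variance term is the substantive choice
  here: a *negated* variance term under minimization would reward
  extreme schedules, contradicting the stated goal of balanced,
  practical plans, so the penalized ("goal-consistent") form is the
  default and the alternative is available as `sign_mode="literal"` for
  comparison, never chosen silently.
- **Constraints**: Σxᵢ = 60 min (equality), 5 ≤ xᵢ ≤ 30 min (bounds);
  infeasible combinations are rejected before solving.
- **Solver**: `scipy.optimize.minimize(method="trust-constr")` with the
  analytic gradient and the constant exact Hessian, started from the
  equal split (15, 15, 15, 15); gtol 1e-10, xtol 1e-12. The
  goal-consistent objective is convex (linear + convex quadratic), so
  the solution is global and start-independent; tiny solver drift is
  re-projected onto the equality constraint (interior coordinates only)
  before the plan is returned. Interior solutions obey
  xᵢ = 15 + (n/2λᵥ)·(cᵢ − c̄) with cᵢ = ws·sᵢ + wd·dᵢ, which is the
  closed form used in the analytic test case.
- **Grid oracle**: exhaustive evaluation on the 0.5-minute feasible
  lattice, vectorized; used in tests as an independent optimality check.
  Because the continuous optimum is generically off-lattice, the
  comparison is one-sided (solver never worse than the lattice best)
  plus a resolution-limited gap bound derived from the variance-term
  Hessian (0.05·(I − ¼·11ᵀ)).
- **Rounding**: plans are displayed in whole minutes; all invariants are
  checked on the raw solution.
- **Weighting cases**: 70/30, 50/50, 30/70 superficial/deep. When s = d
  the combined coefficient equals s for every case (ws + wd = 1), so all
  three cases provably coincide — a useful invariance test. For d ∝ s
  with a ratio ≠ 1 the cases genuinely differ because the variance
  penalty does not rescale with the weights.

## Pipeline and reproducibility

One `RunConfig` (YAML-serializable) drives simulate → extract → validate
→ profile → optimize; every intermediate is persisted (cohort CSVs,
features.csv, cv_report.json, profile.json, per-case plan JSONs,
run.log with library versions, seeds, the full hyperparameter record and
per-stage wall time). A failing stage aborts with its name while keeping
completed outputs. All randomness flows from the root seed; repeated
runs are byte-identical for the deterministic stages.

## Problem sizes

The default cohort (8 × 2 × 4 trials of 30 s) yields 15 360 windows.
The bundled benchmark script runs the same design at 10 s per trial
(5 120 windows) and the heavier tests at 2–6 s, sizes at which the
planted structure is already comfortably recovered while the four-model
LOSO benchmark completes in well under a minute of model fitting.

## Known limitations

- Synthetic-cohort realism as listed above; absolute R²/MSE values on
  this cohort are optimistic relative to clinical sEMG.
- Deep-muscle "activation" inherits surface-EMG's indirectness; the
  optimizer treats dᵢ as given, making no crosstalk correction.
- Single-session planning only: no longitudinal adaptation, and dosage
  dimensions other than time (sets, reps, load) are out of scope.
- Hyperparameters are library defaults by design; no tuning, no model
  explanation (e.g. SHAP) is provided.
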