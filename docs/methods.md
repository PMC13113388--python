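# Methods

This note records the models, the defaults and the judgement calls behind
specfuse, in enough detail to reproduce or criticise them.

## The regression problem

The target is the lecithin/sphingomyelin ratio `r = L/S` of a two-lipid
vesicle, observed through two vibrational spectra per sample. At constant
total lipid the component fractions are `f_L = r/(1+r)` and
`f_S = 1/(1+r)`; the analyte signal is modelled as linear in `(f_L, f_S)`
while the regression target is `r`, which is a smooth *nonlinear*
function of `f_L`. A linear model on the raw spectra therefore has an
irreducible error floor; in practice per-spectrum SNV normalisation bends
the data manifold (the normalisation scale itself depends on
composition), which gives PLS components beyond the first genuine
predictive content. This is why cross-validation selects 2+ latent
variables on data whose clean signal is, channel-wise, one-dimensional.

## Synthetic data generator

`synthesis.generate_spectrum` draws

```
intensity = gain · (f_L·L(ν) + f_S·S(ν) + artifacts(ν) + baseline(ν)) + offset + noise
```

with `gain ~ 1 + N(0, scatter_sd)`, `offset ~ N(0, scatter_sd)` and
i.i.d. channel noise `N(0, noise_sd)`. Axes: FTIR 700–4000 cm⁻¹ at
4 cm⁻¹ (826 channels), Raman 400–3200 cm⁻¹ at 2 cm⁻¹ (1401 channels).
The per-lipid band templates place 7–9 Gaussian bands at
literature-typical positions (CH stretches near 2850/2880/2918 cm⁻¹,
ester C=O at 1738 cm⁻¹, amide I/II for sphingomyelin, phosphate bands at
1085/1228 cm⁻¹ in FTIR only, skeletal C–C and choline bands in Raman).
Artifacts: negative water bands at ~3400, ~1645 and ~800 cm⁻¹ in FTIR
(imperfect aqueous background subtraction); a strong Si 2TO substrate
band at ~950 cm⁻¹ and a broad polynomial fluorescence baseline in Raman.
Cosmic spikes are Raman-only (a CCD phenomenon): Poisson-count
single-channel positive excursions, default rate 1 per spectrum,
magnitude 8 a.u. (~5× the strongest band).

Default study conditions: the 13-point L/S panel 0.25–3.25 in steps of
0.25, 6 replicates per ratio (78 pairs), `scatter_sd = 0.10`,
`noise_sd = 0.011` (FTIR) and `0.0035` (Raman). The noise levels were
calibrated once so that single-modality PLSR lands in the ~0.90 test-R²
regime reported for this kind of measurement, with FTIR the noisier
modality (water obscures much of the mid-IR); after calibration they are
frozen and never tuned per experiment. Pure-lipid endpoint samples carry
non-numeric markers (`pure_L`/`pure_S`) and are excluded from regression
unless explicitly mapped to numeric values.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: composition-dependent band shifts or width
changes (lipid packing), ATR penetration-depth dispersion, instrument
line-shape functions, correlated (pink) noise, day-to-day drift, and any
sample chemistry beyond two components. One consequence is visible in
the results: with strictly linear mixing the two modalities carry largely
redundant information, so low-level fusion reliably helps only when the
modalities are comparably informative. The defaults therefore yield
FTIR ≈ Raman ≈ 0.91 mean R² rather than a clear Raman advantage; the
qualitative fusion ordering (concatenation most accurate, weighted fusion
sharpest) is reproduced, the exact inter-modality gap is not.

## Preprocessing

Fixed chain **despike → baseline offset → SNV**, each step strictly
per-spectrum (no cross-spectrum statistics, so no train/test leakage by
construction).

* **Despike** (Raman only by default): a channel is flagged when its
  deviation from a 5-channel running median exceeds
  `15 × 1.4826 × MAD`. Three non-obvious details, each fixing a concrete
  failure mode at 2 cm⁻¹ sampling:
  (i) the MAD of the deviations is floored by a first-difference robust
  noise estimate — the raw deviation MAD has an atom at zero (the centre
  channel often *is* the window median) and underestimates noise ~3×,
  which would let genuine sharp band tops cross the threshold;
  (ii) detection runs in two passes, the second on a provisionally
  cleaned signal — a spike biases the running median of its neighbours
  and otherwise falsely flags steep flank channels;
  (iii) flagged channels are replaced by linear interpolation from the
  nearest clean channels, and the median window is mirror-padded — median
  replacement is biased by 1–2 channels on steep flanks, and
  edge-replicated padding would make an edge spike its own running
  median and let it through. Residual limitation: a spike that lands
  exactly on a sharp band top destroys that channel; any reconstruction
  is then off by the local curvature (~1–2% of band height).
* **Baseline offset** (FTIR only by default): subtract the intensity at
  the grid point nearest 2500 cm⁻¹ (a feature-free region); exact
  distance ties break toward the lower wavenumber.
* **SNV**: location = mean and scale = sample standard deviation (ddof 1)
  over the anchor region — 850–2000 cm⁻¹ for FTIR (avoids the CO₂ band
  at ~2349 cm⁻¹ and the water-dominated stretch region), full spectrum
  for Raman — applied to all channels. Exactly removes the per-spectrum
  affine scatter (`snv(a·x + b) = snv(x)` for `a > 0`); a
  zero-variance region raises a degenerate-spectrum error.

## PLS1 core

Single-response NIPALS with X mean-centering and y centering, no variance
scaling (SNV already sets the scale). One deflation pass at the maximum
component count yields the regression vectors of all nested models
(`B_k = W_k (P_kᵀ W_k)^{-1} q_k`), so cross-validation over 1–30 LVs and
the 100 bootstrap refits per model cost one fit each, not thirty. If the
residual covariance `‖X_dᵀ y_d‖` collapses below `1e−12` (relative) the
extraction stops and higher component counts reuse the last valid vector;
a constant target therefore yields zero coefficients and predicts the
training mean. Component counts are validated against the rank bound
`min(n − 1, p)`.

Cross-validation: 50 random 80/20 splits of the training pairs (the same
splits reused for every component count, so the per-k curves are
comparable), per-k mean train/test MSE and R². Selection: with
`k* = argmin test MSE`, choose the smallest `k ≤ k*` with
`MSE_k / MSE_{k*} < F(0.95; df, df)`, df = number of CV-test predictions
(splits × split-test size). With ~650 predictions the critical ratio is
≈1.14, i.e. any model within ~14% of the best is accepted, simplest
first. Splits are unstratified (the panel is balanced by design) and
seeded. The deployed model is refit on the full training set at the
selected k.

## Conformal intervals

Jackknife+-after-bootstrap with B = 100 resamples. Implementation
choices: out-of-bag aggregation by mean; quantile convention
`⌈(1−α)(n+1)⌉`-th smallest for the upper bound, `⌊α(n+1)⌋`-th for the
lower, ranks clamped to [1, n]; the reported point prediction is the
full-training-set refit (the interval construction is unchanged by this —
the point may in principle fall outside its own interval, which is a
known property of jackknife+-style methods, not a bug). A training point
contained in every resample has no OOB model; the resample matrix is then
redrawn (bounded retries) — with B = 100 this is practically unreachable.
Determinism: one seed fixes the resample matrix and hence the intervals.

## Fusion

* Low-level: concatenate SNV-processed FTIR then Raman intensities; the
  fused axis is sequential indices, not wavenumbers; the block boundary
  is recorded. PLSR treats the fused vector like any spectrum.
* High-level mean: arithmetic mean of the two models' outputs. Its
  interval is the per-sample mean of the two bounds — equivalent to
  σ = (σ_F + σ_R)/2, the perfectly-correlated combination. Chosen over
  independent-error pooling (σ = √(σ_F² + σ_R²)/2) because the two models
  predict the same quantity from the same sample and their errors are
  strongly correlated; the conservative rule keeps the mean model's
  intervals honest.
* High-level weighted: per-sample inverse-variance weighting of the two
  outputs with σ from each interval's width (σ ≈ width/2z, z = 1.96,
  w = 1/σ²), and pooled σ_fused = (1/σ_F² + 1/σ_R²)^(−1/2) for its own
  symmetric interval. Per-sample (not global-mean) weighting is used; a
  single zero σ gives that modality all weight without division by zero;
  both zero is an error. The pooled width is mathematically ≤ the
  narrower input width — weighted fusion is guaranteed sharpest — but the
  pooling assumes less error correlation than actually present, so its
  coverage should be watched (its ACE runs slightly negative).

## Figures of merit

PINC = 100(1−α)%; PICP with closed interval bounds (boundary hits count
as covered); ACE = PICP − PINC as fractions; PINAW = mean width / R with
R = max − min of the *actual test-set* values (for the default panel,
R = 3.0). MSE and R² are computed from the same point predictions that
the intervals annotate.

## Experiment orchestration

Pairs are split 80/20 once per master seed; all five models share the
identical test set, and the two high-level fusion models consume only the
individual models' test-set outputs and intervals (no refitting). All
randomness (generation, split, CV, bootstrap) derives from the master
seed through fixed stage offsets, so any stage can be varied without
perturbing the others and a report is exactly reproducible. Problem
sizes for the shipped studies — 78 pairs, 50 CV splits, 30 LV maximum,
B = 100, 20 master seeds for the ordering study, 200 Monte-Carlo
replicates for the conformal calibration — keep a full run at about half
a minute on one CPU while leaving the selection and coverage statistics
stable across seeds.

## Known limitations

* The generator's linear mixing makes the two modalities informationally
  redundant; real complementarity (e.g. phosphate bands genuinely absent
  from Raman carrying independent signal) is only structurally, not
  statistically, emulated.
* The F-ratio selection rule treats CV-test residuals as independent,
  which overstates df; with the default sizes the rule is mildly
  conservative (selects small k), consistent with its purpose.
* Weighted-fusion intervals inherit the independence assumption of
  inverse-variance pooling; under strongly correlated modality errors
  they can undercover.
* PICP on a 16-sample test set is quantised in steps of 1/16; ACE values
  at that resolution distinguish calibration only coarsely.
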