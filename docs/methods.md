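# Methods

This note records the models behind `mrcprel`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic data does and
does not emulate.

## Study design being modelled

The package targets a repeated-measures reliability design: three movement
conditions (healthy voluntary, healthy imagined, stroke voluntary) × 10
datasets per condition × 50 cue-locked epochs per dataset; five raters
evaluate every dataset at three sessions (two on one day, one a week
later), accepting/rejecting epochs and labelling the peak negativity (PN)
of the average of the accepted epochs. Intra-rater reliability compares one
rater across sessions (1 vs 2 within-day, 1 vs 3 across days); inter-rater
reliability compares the five raters within a session.

## Signal model and preprocessing

Epochs are 4.5 s of a single "virtual channel" at 500 Hz: 3 s pre-cue and
1.5 s post-cue, cue at 0-based sample index 1500. Preprocessing follows the
standard MRCP chain:

- **Band-pass** 0.05–5 Hz Butterworth, design order 2 (two poles per band
  edge — the conventional reading of a "second-order" band-pass as
  produced by MATLAB/scipy `butter(2, ...)`), applied forward–backward
  (`sosfiltfilt`), so the effective magnitude response is |H(f)|² and the
  phase is exactly zero. Edge transients are handled by `sosfiltfilt`'s
  odd-reflection padding; at the 0.05 Hz edge transients decay over a few
  seconds, which is why amplitude checks in the tests use quadrature
  projection over the central portion of long signals.
- **Large Laplacian**: virtual = Cz − mean(Fz, Pz, C3, C4), uniform
  weights. With the sparse 10–20 montage modelled here (FP1, F3, Fz, F4,
  C3, Cz, C4, P3, Pz, P4) the only electrodes surrounding Cz are Fz, Pz,
  C3, C4, so uniform weighting is the natural choice; the neighbour set is
  configurable. FP1 (an EOG-proxy frontal site) takes no part in the
  Laplacian. Only the Cz-centred virtual channel is produced.
- **Epoching**: cue times in seconds map to samples by
  round-half-away-from-zero; epochs are half-open sample intervals
  `[cue − 1500, cue + 750)`; a cue too close to a recording edge is an
  error listing the offending cues (no partial epochs).

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed.

**Waveform.** Each dataset draws a template: baseline 0, a half-cosine ramp
from a pre-cue onset (−1.75 to −1.5 s depending on condition) down to the
PN, and a half-cosine recovery (1 s) back toward baseline. The drawn PN
latency is snapped to the sample grid so the planted minimum is exact.
Amplitude and latency draws are truncated at ±2 SD to keep amplitudes
inside the physiological −5 to −30 µV range.

**Variability.** Per epoch: amplitude scaling (truncated normal around 1),
latency jitter (integer-sample shift), and additive noise — an equal
mixture of white and 1/f spectra by default. The noise floor scales with
the dataset's drawn amplitude: cortical signal and background EEG share the
same volume-conduction attenuation, so per-participant SNR is much more
stable than raw amplitude. With probability `artefact_prob` (default 0.05)
a blink-like Gaussian bump (SD 200–400 ms, amplitude ≥ 3 × template
amplitude, so it survives the 0.05–5 Hz band-pass) is added and the epoch
is flagged in the ground truth only.

**Condition defaults.** Imagined movement: about half the voluntary
amplitude, larger latency jitter (less defined negativity). Stroke: smaller
amplitudes and ~200 ms longer latencies than healthy voluntary movement.
The per-condition `background_noise_sd` values (16.47 / 13.40 / 12.21 µV)
were calibrated once, by bisection in
`scripts/calibrate_similarity.py`, so the grand mean cosine similarity of
the default arms lands on 0.39 (healthy voluntary), 0.27 (healthy
imagined) and 0.41 (stroke voluntary); they are documented constants, not
tuning knobs. Beyond the fields strictly needed for that calibration the
generator carries `pn_latency_dataset_sd_ms` (between-participant latency
spread — the "true" variance that reliability statistics compare rater
error against), `epoch_scale_sd` and `recovery_ms`; values are choices of
plausible physiological magnitude, not fitted quantities.

**Raters.** Accept decisions are Bernoulli with
logit P(accept) = intercept + slope × cosine similarity, independent
across sessions given similarity (no memory, no learning — a deliberate
simplification; any real within-day training effect is outside the
generative model). PN labels are the automated PN of the average plus a
fixed rater bias plus Gaussian noise, so the implied two-way ICC is
σ²_dataset / (σ²_dataset + σ²_bias + σ²_noise) and parameter-recovery
tests have a closed-form truth. The five default raters have experience
1.5–8 years (mean 4.7) and per-condition acceptance slopes that are
steeper for the morphologically cleaner voluntary conditions.

**Reproducibility.** All randomness flows from one config seed through
SHA-256-keyed `SeedSequence` sub-streams per role (dataset, rater,
session…), so adding raters never perturbs dataset noise and every run is
bit-reproducible.

**What the generator does not emulate.** Realistic spatial topography (the
continuous multi-channel mode injects a scaled template per channel and is
only a thin wrapper for exercising the preprocessing chain), non-stationary
noise, real artefact taxonomies, rater learning or fatigue, and the
presentation-order randomisation of a live labelling session. Passing
tests therefore certify the statistical machinery and the pipeline
plumbing under a plausible generative model — not performance on real EEG.

## Reliability statistics

Ratings form a complete n × k matrix (n datasets; k = 2 sessions for the
intra-rater designs, k = 5 raters for the inter-rater design). A two-way,
one-observation-per-cell ANOVA gives MSR (rows = targets), MSC (columns =
raters/sessions) and MSE. Then

- ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE));
- 95% CI by the F-statistic method with a Satterthwaite denominator df
  (the standard interval for the two-way random-effects, absolute
  agreement, single-measures form; it matches `pingouin`'s ICC2 row, which
  the tests use as an independent cross-check);
- SEM = √MSE in ms.

Numerical conventions: a matrix of identical cells is degenerate and an
error; identical columns with varying rows give ICC = 1 with a point CI;
negative point estimates are reported as computed (never clamped), banded
"poor", because clamping would be untestable against printed values.
Missing cells are an error naming the cell — the design is complete, and
imputation is out of scope. Band boundaries close as: excellent (0.8, 1],
good [0.6, 0.8], moderate [0.4, 0.6), poor below 0.4 (the conventional
band wording overlaps at 0.6 and 0.8; both boundary points land in
"good").

## Association models

Both trend models carry a single random intercept grouped by dataset — the
repeated unit across raters and sessions. Richer crossed structures
(rater, session) are deliberately out of scope; the grouping variable is
configurable.

- **Cosine similarity across conditions**: Gaussian LMM fitted by REML
  (statsmodels `MixedLM` behind the module surface). The optimizer cascade
  lbfgs → powell → cg guards against the boundary case where the
  between-dataset variance estimate hits zero and the default optimizer's
  fixed-effect covariance degenerates. Tukey pairwise contrasts use the
  studentized-range distribution with between-cluster df = n_clusters −
  n_fixed (30 datasets, 3 condition means → df 27), an approximation
  chosen to match the design's natural denominator df.
- **Matched-epoch probability**: logistic GLMM fitted by maximising the
  marginal likelihood with *adaptive* Gauss–Hermite quadrature (default 25
  nodes; the log-likelihood changes by <1e-4 when doubled). Per-group
  posterior modes are found by damped Newton iterations, warm-started
  along the optimisation path; L-BFGS-B optimises (β, τ) with τ ≥ 0, and
  τ < 1e-8 falls back to the exact fixed-effects likelihood, so a boundary
  fit coincides with IRLS logistic regression (verified to 1e-3 in tests;
  the implementation itself was validated against lme4's `glmer`
  (nAGQ = 25), agreeing to ~1e-4 on coefficients, SEs and log-likelihood).
  Wald SEs come from a central-difference Hessian at the optimum.
- **Fixed-effects logistic (IRLS)**: Newton/IRLS to deviance change
  <1e-10; separation is detected either by a diverging coefficient
  (|β| > 30) or by a perfect fit whose coefficients keep drifting, and is
  an error naming the term. The 30 threshold deliberately sits above the
  largest trend magnitudes this analysis produces (~23).
- **Likelihood-ratio test**: χ² = 2Δll with df = parameter-count
  difference; χ² negative within 1e-6·|ll| is clamped to zero and flagged,
  beyond that it raises (a non-convergence signal). Type-I error is
  calibration-tested at the 5% level.
- **Probability curves**: inverse-logit of the linear predictor over a
  grid, covariates at reference values (numeric at means, factors at their
  first level, overridable), CI formed on the logit scale by the delta
  method then transformed; grid points outside the observed predictor
  range are computed but flagged as extrapolation. Condition coding is
  treatment coding with healthy voluntary as reference, so per-condition
  similarity trends are simple slopes (reference slope + interaction).

## Pipeline

Stages run as a strict prefix of simulate → evaluate → reliability →
associations → report. All tables are CSV, structured results JSON, epoch
matrices delimited text — diffable and language-neutral; times are always
ms, amplitudes µV. The report carries provenance (seed, config digest,
package version) and re-running from it reproduces every number. A rater
who rejects all 50 epochs of a dataset still has to label something; the
pipeline falls back to the grand average for that cell and logs it.

## Problem sizes in the tests

The test suite exercises the statistics at the design's own scale where
that is what the property is about (10 datasets × 5 raters for ICC
recovery/coverage at 250 replicates; 30 datasets × 50 epochs × 5 raters
for logistic-trend recovery at 100 replicates; 1000 replicates for LRT
calibration; 1000 random matrices for the ICC oracle equivalence) and at
reduced scale for plumbing tests (3 datasets × 15 epochs in the pipeline
tests), keeping the default run to a few minutes.

## Known limitations

- The logistic GLMM supports exactly one random intercept; no crossed or
  nested random effects, no random slopes.
- Tukey contrasts after the LMM use a df convention, not a Satterthwaite/
  Kenward-Roger computation.
- The EDF reader delegates to `mne` (optional dependency) and is exercised
  only via its error path in the tests, since EDF is binary and no writer
  is available in the test environment; the delimited-text reader is the
  fully tested path.
- Negative-variance pathologies of real rating data (raters *anti*-agreeing)
  produce negative ICC estimates, which are reported, not modelled.
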