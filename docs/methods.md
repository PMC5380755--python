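# Methods

## Scope and model

`nirsload` implements a continuous working-memory-load decoding analysis
for whole-head fNIRS acquired during a driving n-back task, plus the
synthetic-data generator that defines the conditions under which the
pipeline is validated. The decoded label is the induced n-back level
(0–4), treated as constant over each ~20 s trial; decoding operates on
instantaneous HbR samples.

## Synthetic study generator

**Design.** `generate_design` produces 2 repetitions × 5 levels × 10
trials = 100 trials in blocks, block order drawn by rejection sampling
under the no-adjacent-repeat constraint (an explicit error is raised when
the constraint is infeasible, e.g. one level with several repetitions,
unless relaxed). Sign speeds are a per-block permutation of the 9-value
grid topped up with extra draws, so a default 10-trial block shows exactly
9 distinct speeds. Target speeds follow the n-back rule; the block's first
sign speed stands in for the first *n* fill-in trials, matching the
instruction to drive at the first sign when a new block starts. A 5 s
announcement precedes each block and belongs to no trial.

**Trial-wise outcomes.** Each behavioral/cardiac parameter is generated as
baseline + slope·level + participant intercept + residual noise. Baselines
are the 0-back descriptive means and slopes the published per-level fixed
effects (heart rate +0.89 bpm, RMSSD −1.24 ms, reaction time +0.23 s,
time-in-correct-range −6.6 %/level, and the remaining driving parameters
analogously). Heart rate uses participant-intercept SD 12 bpm and residual
SD 12.2 bpm; RMSSD 12/17 ms. For time-in-correct-range the published
level-wise SDs are internally inconsistent (0.04 … 18.6 across levels,
apparently mixed units), so the generator uses intercept SD 2 and residual
SD 3 percentage points — small enough that clipping to [0, 100] is rare
(expected clipping loss ≈ 0.02 points at 0-back, negligible against the
6.6-point slope) and slope recovery stays unbiased. Bounded parameters are
clipped to their physical ranges; reaction time is missing on incorrect
trials. Per-level correctness probabilities (0.99, 0.98, 0.95, 0.88, 0.80)
give the ~8% overall incorrect-trial rate as an emergent property.

**RR intervals.** `generate_rr_series` draws iid Gaussian RR jitter with
SD = target RMSSD/√2, since the RMS of successive differences of iid noise
with SD σ is σ√2. Combinations whose jitter could produce nonpositive
intervals are rejected.

**Forward fNIRS model.** The workload regressor is the per-sample level
boxcar convolved with a canonical double-gamma HRF (peak 6 s, undershoot
16 s, ratio 1:6) normalized to unit DC gain, so `amplitude_per_level`
(default 0.05 µM) is the steady-state HbR decrease per n-back level.
Loadings sit on bilateral inferior-frontal (weight 1.0) and
temporo-occipital (0.7) channels with a weak 0.4 spill-over onto the
forehead channels bordering F5/F6 — so frontal-only decoding is
informative but inferior to whole-head, as observed in real data. HbO is
the sign-flipped counterpart scaled by 2.5. Artifacts are added in
concentration space: cardiac ~1.1 Hz (above the 0.978 Hz Nyquist;
point-sampling the continuous oscillation at acquisition times reproduces
exactly the aliasing an instantaneous-sampling system produces, which is
numerically identical to fine-grid simulation followed by decimation),
respiration 0.3 Hz, Mayer waves 0.098 Hz, two very-low-frequency drift
components, and white noise. Systemic oscillations share a common phase
across channels (with per-channel gain and small phase jitter) because
real systemic physiology is spatially global — this is what makes PCA
denoising effective and prevents trivially easy multichannel averaging.
Raw intensities follow I = I₀·10^(−ΔOD) with ΔOD from the forward modified
Beer–Lambert relation; designated bad channels receive multiplicative
log-normal intensity noise (σ = 0.35 → CV ≈ 36%) so they fail the CV
check. Because artifacts and noise are injected in concentration space,
Beer–Lambert inversion recovers the mean-centered truth exactly (≤ 10⁻⁹
relative error in tests; the session-mean OD reference removes each
channel's temporal mean).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: motion spikes (QC here is variance-only),
scalp/superficial hemodynamics and task-correlated systemic confounds,
optode-coupling drift, nonlinear or saturating hemodynamic responses near
working-memory capacity, inter-individual montage registration error, and
the true spatial correlation structure of cortical activity. Decoding
correlations on the synthetic default conditions (~0.95+) are accordingly
higher than the ~0.6 typical of real recordings.

## Preprocessing

ΔOD uses the whole-session mean intensity as reference (configurable).
The Beer–Lambert system is solved per channel by the analytic 2×2 inverse
with the Gratzer-spectrum extinction coefficients and DPF 7.25 (760 nm) /
6.38 (850 nm); the published phrasing ties the two DPFs to the
chromophores, but DPF is physically per-wavelength, so they are bound to
wavelengths (configurable). Concentrations are carried in mol/l
internally; mmol/l is an I/O convention.

The low-pass filter is an odd-length (121-tap) least-squares FIR with
pass/stop edges at 0.05/0.15 Hz around the 0.1 Hz cutoff at fs = 1.955 Hz,
taps normalized to unit DC gain; reflect padding plus symmetric
convolution gives zero group delay. Channel QC computes CV per wavelength
on unfiltered intensity and rejects a channel when either wavelength
exceeds 20% (the conservative reading of a whole-channel rejection count);
zero-mean channels get infinite CV rather than an exception.

Sample sets label every in-trial sample with the trial's level, drop
samples within ±3 s of any sign passage (both ends of each trial) and all
samples of incorrect trials, and tally every exclusion. A 20 s trial at
1.955 Hz retains ≈ 27 samples.

## Decoding

Folds are assigned to whole trials, not samples: instantaneous samples
within a trial are strongly autocorrelated, and sample-level folds would
leak neighbors between train and test. This is a deliberate strengthening
where the original fold construction is unstated; it yields an honest
generalization estimate.

Per outer fold (default 10), a single λ grid of 50 log-spaced values from
λ_max down to 10⁻³·λ_max is computed from the standardized outer-training
features. The inner loop (default 10 folds over training trials) fits the
PCA basis on inner-training samples only — one eigendecomposition of the
channel covariance serves every k in the grid ({1, 2, 3, 5, 8, 12, 17, 25,
35, 50, all}) — denoises by project-and-backproject, z-scores with
inner-training statistics, and evaluates the whole lasso path. The (k, λ)
pair maximizing pooled inner-validation Pearson r wins; ties break toward
the smallest k, then the largest λ (most parsimonious). The pair is refit
on the full outer-training set and applied once to the held-out trials;
the pooled correlation over all held-out predictions is r_mvr. Component
signs are fixed (largest-magnitude loading positive) for bit-exact
reproducibility; k and λ are searched jointly; predictions are not
smoothed. The peripheral decoder runs the identical machinery on the
(heart rate, RMSSD) trial-wise feature pair.

λ = 0 falls back to least squares (coordinate descent is undefined there);
the sklearn objective (1/2N)·RSS + λ‖β‖₁ matches the implementation's
definition exactly, which the soft-threshold and normal-equation oracle
tests pin down.

## Mapping

r_uvr is the signed per-channel Pearson correlation with the induced level
(for one regressor, regression-then-correlation and direct correlation
coincide up to slope sign). Constant channels are reported missing rather
than erroring. The group map implements the r_mvr-weighted mean exactly;
weights must be positive (all observed decoding correlations were), and
channels missing in some participants are averaged over the rest.
Per-channel p-values are unadjusted two-sided by default, with
Benjamini–Hochberg available downstream of the returned table.

## Behavioral statistics

Mixed models use a single spanning group with variance components for
participant, trial number and target speed — i.e. crossed random
intercepts, one per distinct value of each factor — fit by maximum
likelihood; the LRT compares against the level-free model. Satterthwaite
degrees of freedom are not available in the backend, so df uses the
residual approximation N − (fixed rank) − (number of random-intercept
groups), labeled `df_method="residual"` in results; with ~1200
observations the effect on r = √(t²/(t²+df)) is negligible. Variance
components at the boundary (zero) are expected for generator data and the
optimizer warnings are suppressed; genuinely singular fits are downgraded
by dropping components, recorded in the result.

Outlier removal blanks values more than 3 SDs from the participant's mean,
per parameter, leaving the trial available to other parameters; removals
and fractions are logged. The rule is idempotent only when the bulk is
well-separated from the outliers, which holds at the fixture scales used
in tests. Reaction time is operationalized as the latency until the speed
enters the ±5 km/h band and stays there for the rest of the trial;
lane-change phases are flagged by |lane offset| crossing the lane boundary
minus a 0.25 m hysteresis.

## Problem sizes

Stochastic validation runs at deliberately chosen sizes: slope-recovery
checks use 20 replicates of 12 participants × 100 trials (the study's
cohort and session size); the mixed-model type-I-error check runs 40 null
replicates of 6 participants × 50 trials; decoding property checks use the
full 100-trial session for the permutation null and 50-trial sessions with
coarsened hyperparameter grids for the 10-seed paired frontal comparison.
These sizes give Monte-Carlo error comfortably inside the asserted
tolerances while keeping the default test run fast.

## Known limitations

- The forward model is linear modified Beer–Lambert; no photon-transport
  simulation, no partial-volume or crosstalk effects.
- The montage is schematic: published constraints (78 channels, bilateral
  coverage with a somatomotor gap, mean separation 3.5 cm, a 12-channel
  forehead subset spanning F5–F6/AF7–AF8/AFz/Fpz) are reproduced, but the
  exact emitter–detector pairing is synthesized.
- Statsmodels' variance-component parameterization treats the three random
  factors as crossed within one spanning group; lme4-style profiling may
  differ in degenerate cases.
- HbR is the analysis signal throughout; HbO is generated and converted
  but not decoded.
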