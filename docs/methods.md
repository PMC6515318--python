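# Methods

This note documents the models, the synthetic data, and the numerical
choices behind `distalemg`, in the order the pipeline runs.

## Signal model and preprocessing

All signals are multichannel time series with a known sampling rate
(2 kHz by default). Preprocessing per channel:

1. **Notch** at the mains frequency (default 50 Hz, configurable):
   second-order IIR notch, quality 30, applied forward–backward.
2. **Bandpass** 20–500 Hz: 4th-order Butterworth applied
   forward–backward. The zero-phase realization matters because the
   downstream activation analysis compares onset/offset *timing*; a
   causal filter would delay estimated envelopes relative to measured
   ones. If a band's high edge reaches Nyquist (e.g., the default band
   on a 1 kHz recording), it is clipped to 0.99 × Nyquist with a
   warning rather than rejected.
3. **MAV** with a trailing window of τ = round(fs × 0.1 s) samples
   (200 at 2 kHz). For the first τ−1 samples the average runs over the
   samples available so far; partial-window averaging keeps the output
   the same length as the input without the startup bias that
   zero-padding would cause. Sample indexing is 0-based internally.

## Feature bank

The distal feature matrix stacks, channel-major, the MAV of every band
of the bank: the full 20–500 Hz band first, then 150 Hz-wide windows
stepped by 10 Hz from 20 Hz up (20–170, 30–180, …, 350–500): 35 bands
per channel, 175 features over five channels. Restricting the bank to
the single full band reproduces the plain single-bandpass baseline; the
two pipelines differ only in the band list, so comparisons isolate the
effect of the band decomposition. The filter family/order for the bank
is the package's own choice (the band layout itself is the fixed
design); band edges are validated against Nyquist at the record's rate.

## Estimators

**Affine mixing model** (placement design): L(k) = M·A(k) + b fitted by
least squares over all time steps; rank-deficient designs fall back to
the minimum-norm solution with a warning.

**Gradient tree boosting** (per-muscle envelope estimator): the additive
stagewise recursion with an abstract loss Q — constant initializer
argmin Q, negative-gradient residuals, a regression tree fitted to the
residuals, per-leaf line search, shrinkage-scaled update. The default
and only implemented loss is squared error, for which the initializer is
the target mean and each leaf's line search is its mean residual. Trees
use exact greedy axis-aligned splits maximizing SSE reduction, candidate
thresholds at midpoints of consecutive distinct sorted values, and
deterministic tie-breaking (lowest feature index, then lowest
threshold), so fits are exactly reproducible without randomness; a seed
only matters if optional row subsampling is enabled. Per-feature sort
order is computed once per fit and inherited by child nodes through
filtering, which keeps exact greedy splitting affordable at the sizes
used here. Defaults: H = 100 rounds, shrinkage 0.3, max depth 6,
min 1 sample per leaf — conventional regression-boosting settings, all
exposed. Serialized models hex-encode floats, so reload reproduces
predictions bit-exactly. In tests, predictions are cross-checked against
an independent exact-greedy implementation (xgboost with its
regularization disabled) at identical hyperparameters.

**Training folds.** Two protocols, both derived from record lengths
alone: (a) split-half with swap — every record is halved, models train
on one half of all records and are scored on the other, then swapped,
so every time step is estimated exactly once (used by the placement
search); (b) target-subject pooling — half of the target subject's
record plus the full records of all other subjects train the model that
is scored on the target's complementary half, with the swap, estimates
concatenated in temporal order (used by the estimation-accuracy
experiment).

## Activation analysis

Per trace, the ON threshold is `min + fraction × (max − min)` with
fraction 0.20 by default. "Fraction of the range above the minimum" was
chosen over "fraction of the maximum" because it is invariant to a
baseline offset; the fraction and reference are configurable. Active
intervals are maximal runs strictly above threshold. Tm, Te are total
supra-threshold durations; Tc the duration where both traces are
supra-threshold; Vm, Ve sum each trace's per-interval maxima; Vc sums,
per overlap section, the smaller of the two traces' section maxima.
When several overlap sections fall inside one parent interval this sum
could exceed a trace's total, so Vc is clipped to min(Vm, Ve); the clip
enforces the interpretation of Vc as overlapped volume and guarantees
both accuracies — Tc/(Tm+Te−Tc) and Vc/(Vm+Ve−Vc) — lie in [0, 1],
reaching 1 exactly for identical traces. Flat traces have no active
intervals and degrade to accuracy 0 with a warning.

## Gait cycles

Cycles are delimited by upward crossings of the same range-fraction
threshold (default 0.20; the cycle threshold is a config knob separate
from the activation threshold); incomplete edge cycles are dropped.
Each cycle is resampled by linear interpolation onto 1001 uniform
points over normalized time 0–100 (step 0.1 — the densest uniform grid
consistent with a 0–100 span at millisecond-like resolution) and then
amplitude-mapped to 0–100. Amplitude normalization is applied after
resampling so the output attains 0 and 100 exactly for any input
cycle. Averaging is the pointwise mean and standard deviation across
cycles on the common grid. Constant cycles cannot be
amplitude-normalized and are rejected.

## Synthetic data generator

The generator produces the statistical structure the estimator assumes,
not physiological realism (no motor-unit firing, volume conduction or
impedance modelling):

- **Envelopes**: per muscle, a periodic tapered-cosine (Tukey, taper
  0.5) bump of width `duty × cycle_period` at a muscle-specific phase,
  over a small resting baseline (0.05 of peak), with seeded lognormal
  per-cycle amplitude jitter (σ = 0.10). Defaults place the
  dorsiflexor bump around heel strike and the plantar-flexor bumps in
  stance, duty fractions 0.30–0.40, cycle period 1.1 s. One noiseless
  cycle integrates to `peak·duty·period·(1 − taper/2) +
  baseline·period`. A duty of 1 degenerates to a constant envelope.
- **Carriers**: unit-variance Gaussian noise built in the frequency
  domain with support exactly inside the configured band, so spectral
  containment is exact up to modulation smearing. Each muscle has its
  own band (e.g., tibialis anterior 35–450 Hz, soleus lateral
  20–240 Hz): surface-EMG spectra differ across muscles and are
  reshaped along the propagation path, and that spectral diversity is
  precisely the structure a band-resolved feature bank can exploit. A
  channel is `envelope × carrier`.
- **Mixing**: distal channel j = `saturate(Σ_i g_ji · lowpass_ji(l_i))`
  where the 5×6 gain matrix encodes electrode geometry (A1 dominated by
  tibialis anterior, A3/A4 by the gastrocnemius/soleus group, A2/A5
  intermediate), each path applies a first-order low-pass with cutoff
  `120 + 300·g_ji` Hz (stronger path = shorter distance = milder
  filtering), and the saturation is `s·tanh(x/s)` with s = 2 —
  monotone, 0 → 0, ≈ linear for small signals. With identity
  nonlinearity and zero noise the chain reduces exactly to the
  gain-weighted sum of attenuated sources.
- **Noise**: mains sinusoid (50 Hz, amplitude 0.05, random phase),
  band-limited 0.2–15 Hz motion artifact (amplitude 0.10) and white
  sensor noise (σ = 0.05); targets carry a small mains component
  (0.02) so the notch stage is exercised. These defaults put the
  distal channels at a moderate-crosstalk, ≈20 dB-SNR operating point.

Everything derives from `numpy` `SeedSequence` spawning, so identical
(config, seed) pairs give bit-identical recordings. Because the
generator's crosstalk is smooth and its noise stationary, passing the
cohort-level tests shows the pipeline recovers envelopes under the
assumed mixing structure — it does not certify performance on real
recordings with electrode displacement, impedance drift or sweat.

## Cohort experiments (desk scale)

The study-scale analyses run on a seeded cohort of 4 subjects, one 30 s
calibration recording each at 2 kHz, with per-subject lognormal jitter
(σ = 0.15) on the mixing gains as inter-subject anatomical variation.
Because MAV envelopes vary on the 0.1 s window timescale, feature and
target streams are subsampled by stride 80 (25 samples/s) after
full-rate extraction, and the cohort experiments boost with H = 40,
depth 3; RMSEs are computed on the subsampled grid. The dependability
analysis reuses the same cohort (its generator is stationary across
halves by construction). The placement search uses the single-band MAV
features, scored per subject with split-half swap, subsets ranked by
the median of the per-subject per-muscle correlations (mean and min are
available); selection ties prefer fewer electrodes, then lexicographic
order. Reported p-values for correlations use the standard t-transform
test of zero correlation and never influence selection.

## Known limitations

- Only the squared-error boosting loss is implemented; the loss
  interface exists but quantile/robust losses do not.
- The generator's nonlinearity and attenuation are fixed functional
  forms; no electrode displacement or impedance drift is simulated, so
  dependability results on synthetic data are a null check, not a
  robustness claim.
- Exact-greedy trees scale as O(depth · n · p) per tree; for
  substantially larger calibration sets a histogram-based splitter
  would be needed.
- The activation analysis defines Vc by per-overlap-section minima with
  clipping; other conventions (e.g., pairing intervals) would give
  slightly different spatial accuracies when activity fragments.
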