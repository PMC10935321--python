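# Methods

## Signal model and synthetic sessions

The generator emulates a continuous-wave quadrature radar at 5.8 GHz
(λ ≈ 51.7 mm) observing chest displacement

d(t) = d_resp(t) + d_card(t) + d_burst(t),

mapped to baseband as s(t) = A·exp(j(θ₀ + 4π·d(t)/λ)) + dc(t) + n(t) with
circularly symmetric complex Gaussian noise of RMS `noise_sd` and a complex
DC offset that is constant or drifts linearly across the session.

- **Respiration**: raised-cosine cycles with an asymmetric inhale fraction
  (default 0.4 — inhale shorter than exhale), amplitude `resp_amp`
  (default 4 mm), breath-to-breath duration variability `resp_cycle_var`
  (fractional SD, default 0.03). The asymmetry keeps the inhale/exhale
  duration features non-degenerate.
- **Cardiac micro-motion**: one Gaussian pulse per beat (σ = 30 ms,
  ≈ 80 ms full width; amplitude 0.3 mm), reflecting the mechanical
  (MCG-like) nature of the radar cardiac signal, which has no ECG-like
  waveform morphology.
- **IBI process**: IBI_k = 60000/heart_rate + N(0, `ibi_jitter_sd`),
  floored at 300 ms, giving directly controllable SDNN/RMSSD ground truth.
- **Motion bursts**: Hann-shaped displacement bumps (1 s, ~2 mm) at a
  Poisson rate (`motion_burst_rate`/min) emulating frights and laughs.
- **Reference channels** at 1 kHz share the same physiology: the chest
  band is the respiratory displacement (arbitrary units, mild sensor
  noise); the ECG is a spike train (Gaussian R wave, σ = 8 ms, plus a
  small T wave) at the true beat times.

Emotion-conditioned draws set the class structure the classifier stage
consumes: relative to neutral, *fear* raises breathing and heart rate and
lowers beat-to-beat jitter (lower RMSSD) with frequent bursts; *happiness*
adds laugh-like bursts and breath-duration variability. The directions are
the conventional arousal story; the magnitudes (see
`synth.EMOTION_PARAMS`) are fixture choices, not estimates of any real
population. Each virtual subject also carries stable trait offsets in
rate/jitter so subject-out protocols are meaningful. Sessions default to a
5-min baseline plus 25-min induction, one emotion per subject-day;
scaled-down durations are used throughout the test suite to keep runs
fast, which changes problem size but not the structure of any check.

What the generator does **not** emulate: RF propagation and multipath
clutter beyond a complex DC term, electromyographic/electrodermal
artefacts, respiratory sinus arrhythmia (heart rate is independent of the
breath phase), posture changes, or physiologically validated emotion
signatures. Passing tests therefore demonstrate correctness of the
algorithms under the stated signal model, not field performance on human
subjects.

## Phase recovery

1. **Decimation** to the 100 Hz working rate via a zero-phase polyphase
   FIR with linear edge extension (integer ratios only).
2. **Synchronization** exploits the scripted pre-session breathing pattern
   (three deep breaths, 10-s apnea, slow exhale): the valley ending the
   pattern is detected in each channel as a ≥ 8-s flat segment (rolling SD
   below 15% of the channel SD) followed by the exhale minimum; both
   channels are truncated to start there. If the pattern is absent the lag
   falls back to the cross-correlation peak, and below a normalized
   correlation of 0.3 a warning is issued with zero lag. A manual offset
   can be applied instead by slicing the inputs.
3. **DC-offset estimation** per 10-s window with 50% overlap: minimise the
   radial-variance cost Var_i |s_i − c| over centre candidates c, with the
   search region constrained outside the sample cloud
   (|c − centroid| ≥ cloud RMS radius, enforced as a penalty). The
   constraint is the point of the estimator: an unconstrained circle fit
   collapses to the cloud centroid when a weak signal degenerates from an
   arc to a blob, which would push the arc onto the origin and corrupt the
   arctangent. The constraint is waived only when the samples form a tight
   ring (angular coverage > 270° with radial coefficient of variation
   < 0.2), where the interior is genuinely sample-free — this makes closed
   circles recover their exact centre. The optimiser is Nelder–Mead seeded
   with the algebraic (Kåsa) fit, which is exact on noiseless arcs; the
   cost is evaluated on at most 256 window samples. Window length 10 s
   spans ≥ 2 respiratory cycles at 12 breaths/min; per-window estimates
   are linearly interpolated to every sample and subtracted.
4. **Dynamic arc rotation**: the centred signal is multiplied by
   exp(−jφ_ref(t)), where φ_ref is the circular-mean angle over sliding
   60-s windows, unwrapped and interpolated per sample. The long window is
   deliberate: it spans many breaths, so the reference tracks only slow
   arc drift and does not leach respiratory energy out of the phase
   (shorter references measurably distort the recovered displacement).
   Rotation keeps the arc around 0° and prevents ±π wraps.
5. **Arctangent demodulation**: phase = unwrapped four-quadrant angle;
   displacement = phase·λ/4π.

## Vital-sign separation

- RS: zero-phase FIR low-pass, cutoff 0.5 Hz (below the 0.7 Hz cardiac
  band edge), order 800 — high enough that the transition band stays clear
  of breathing rates (≤ 5% amplitude error at 15 breaths/min).
- CS: 100th-order FIR band-pass 0.7–2 Hz, then an undecimated
  (shift-invariant) wavelet decomposition with db4 at 7 levels; the
  cardiac signal is the sum of detail reconstructions at levels 5 and 6,
  whose dyadic bands at 100 Hz span ≈ 0.78–3.13 Hz. The band-passed
  intermediate is retained because the RS/CS energy-ratio feature (F11) is
  defined against it. Inputs are reflection-padded to the required
  power-of-two length.
- ECG: 15th-order FIR band-pass 6–20 Hz; all FIR stages compensate group
  delay exactly (fractional delays interpolated) so event times are
  comparable across channels.
- Events: local extrema with minimum separations of 0.33 s (cardiac) and
  1.5 s (respiratory) and a prominence threshold adapting to the signal
  (30% of the 90th-percentile absolute deviation from the median); R peaks
  use half the rolling 95th percentile with a 0.33-s refractory period.

## HRV

Conventional IBIs are successive peak differences. The window-median
method computes the median of the IBIs whose *both* endpoints fall inside
a 5-s window advancing by 1.25 s (75% overlap); the 5-s length guarantees
at least 5 peaks (4 IBIs) at a 60 BPM reference. SDNN uses the population
SD (switchable to sample SD by the caller); pNN50 counts successive
differences strictly greater than 50 ms. Frequency-domain HRV is
deliberately out of scope: it compounds FFT windowing with respiratory
coupling and the radar's timing resolution.

## Features

One observation = one minute. Waveform/statistical/spectral features are
computed per minute; cardiac HRV features use 5-min sliding windows at a
1-min pace (the 5-min gold-standard duration), assigned to the window's
central minute — the first/last two observations of a session reuse the
nearest valid window and are flagged, and sessions under 5 min flag all
cardiac HRV features. Respiratory-interval SDNN/RMSSD (F47/F49) stay on
1-min segments. Radar cardiac HRV uses window-median IBIs, reference ECG
uses conventional IBIs (configurable per record).

Numerical choices:

- ApEn: m = 2, r = 0.2·SD, Chebyshev distance, self-matches included,
  computed on a 10 Hz decimated copy of the minute (both RS and CS are
  band-limited well below 5 Hz; this bounds the O(N²) cost).
- PSD: Welch, 30-s mean-removed segments, 50% overlap; band powers by
  rectangle integration; F45 = power(0.1–0.4 Hz)/power(0.5–1.5 Hz).
- F13 peak width: width at half prominence, peaks and valleys pooled.
- DFA2: profile = cumulative sum of the mean-removed IBIs; boxes from both
  ends of the record; order-2 polynomial detrending per box; α = slope of
  log F(n) vs log n over 20–60 beats (α1) and 10–100 beats (α2),
  log-spaced box sizes capped at N/4; α2 requires ≥ 100 IBIs, otherwise
  flagged.
- Poincaré: lagged pairs (IBI_k, IBI_{k+m}) for m = 1 and m = 10 (lagged
  pairs, not sub-sampling); SD1/SD2 as the dispersions across/along the
  identity line, SD12 flagged when SD2 = 0.
- Log transform of F46–F49 uses log(x + ε), ε = 1e-6 ms, covering
  zero-variability minutes.
- Flagged/missing values are imputed with the per-subject median of the
  feature (falling back to the overall median), keeping the matrix
  complete without cross-subject leakage; flags are preserved.

Baseline normalization subtracts the mean of each subject-day's baseline
features from that day's condition observations, removing individual and
day dependencies before selection.

## Selection

The normality vote fits a one-way ANOVA per feature and tests the
residuals with Kolmogorov–Smirnov, Anderson–Darling and Lilliefors at
α = 0.05 (majority rules); the verdicts are recorded and motivate the
rank-based filter, which is applied regardless. Kruskal–Wallis (with tie
correction) keeps features at p < 0.05. Pairwise two-sample t tests per
class pair are run on z-scored features with a one-step Bonferroni
multiplier of 3 (the number of pairs), clipped at 1 — the t test (not a
rank test) mirrors the literal workflow of the original analysis. The
priority queue sorts each pair's column ascending by corrected p and reads
the table row by row, ordering within a row by p (ties by F-number) and
dropping duplicates at first occurrence. Pruning then scans the queue
greedily, keeping a feature iff its absolute Pearson correlation with
every kept feature is below 0.7. Correlations are computed on the
baseline-normalized, z-scored matrix. All tie-breaks are by ascending
F-number, so the pipeline is deterministic given the matrix.

## Classification

SVM (RBF, C = 1, gamma = 1/(n_features·Var)), KNN (k = 5, Euclidean) and
random forest (100 trees, √N features per split, seeded) — conventional
defaults, all overridable. Scaling is fit on the training partition inside
a sklearn pipeline; partitions are shared across models for a given seed
so comparisons are paired. Protocols: leave-one-out CV; stratified 70:30
hold-out repeated 20 times (mean ± SD of accuracy and macro F1); and
leave-one-subject-out, where each subject in turn serves as new data and
the remaining subjects supply the 70:30 partition. Feature selection is
fixed from the full design by default (it precedes classification);
re-running it inside folds is left to the caller.

## Problem sizes

The test suite and the worked example run scaled-down cohorts (2–6
subjects, 2-min baselines, 5–7-min inductions, 40–300-s DSP fixtures,
20-seed Monte-Carlo sweeps) chosen so the full chain is exercised end to
end in about a minute; the structure of every check is size-independent.

## Known limitations

- The DC estimator assumes a single dominant arc; multi-target scenes and
  random-body-motion cancellation beyond DC tracking are out of scope.
- The apnea-pattern detector assumes the scripted preamble is present and
  reasonably clean; heavy motion during the preamble falls back to
  cross-correlation.
- DFA2 exponents on short windows (≈ 240 median IBIs per 5-min window)
  use box sizes capped at N/4 and are noisy at the α2 range's upper end.
- Synthetic emotion effect sizes are free parameters: classifier accuracy
  on the fixture says nothing quantitative about human populations.
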