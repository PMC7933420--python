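# Methods note

This note documents the models, algorithms, parameter defaults, and design
decisions implemented in `saccatk`, in the order of the analysis chain.

## Synthetic eye traces (`synthgen`)

Saccades follow a minimum-jerk position profile: with normalized time
τ = (t − t₀)/D, displacement is A·(10τ³ − 15τ⁴ + 6τ⁵), giving speed
(A/D)·30τ²(1−τ)² with closed-form peak 1.875·A/D at τ = ½. Durations come
from a linear main sequence D = 21 ms + 2.2 ms/deg × A (literature-typical
for macaque; configurable). Each trial is fixation → outbound saccade after
a Gaussian latency (default 180 ± 30 ms, floored at 60 ms) → 400 ms hold →
return saccade → 300 ms inter-trial. Saccade onsets are snapped to the sample
grid so the profile is always sampled from its start; white position noise is
drawn from a dedicated substream so the same seed yields the same kinematics
at any noise level. All generators fan a single seed out through
`numpy.random.SeedSequence` spawning, so output is bit-reproducible and
adding trials never reshuffles earlier ones.

## Velocity and saccade detection (`eyekin`)

Radial eye speed uses an eight-point antisymmetric FIR differentiator
(taps ±1..±4 samples, coefficients 4/5, −1/5, 4/105, −1/280), exact on
polynomials up to degree 8 — hence exact on the quintic minimum-jerk segments.
The four edge samples on each side are NaN. Note the noise gain: white
position noise of SD σ becomes velocity noise of SD ≈ 1.167·σ·f_s, i.e.
~58 deg/s for σ = 0.05° at 1 kHz; raw high-rate traces need realistic
(≤ ~0.01°) noise or pre-filtering.

Detection is two-threshold: a candidate opens when speed exceeds the trigger
(PET 200 deg/s at 250 Hz; PHYS 100 deg/s at 1 kHz), the onset is walked back
to the sample after the most recent sub-30 deg/s sample (bounded by 100 ms),
and the offset is the first run of sub-30 deg/s samples (3 consecutive for
PET, 1 for PHYS). Touching events merge.

**Resampling (two documented deviations).** 250 Hz → 1 kHz resampling uses
cubic-spline interpolation followed by zero-phase (forward–backward)
2nd-order Butterworth smoothing. (1) Plain `filtfilt` of a Butterworth
designed at 44 Hz is −6 dB there, not the specified −3 dB; the filter is
therefore designed at 44/(√2−1)^¼ ≈ 54.8 Hz so the *combined* zero-phase
response is exactly −3 dB at 44 Hz (the standard filtfilt cutoff correction).
(2) Linear interpolation was rejected: its sinc² passband droop is ~10% at
44 Hz, which alone would break the −3 dB property; cubic splines are exact at
DC with < 0.1% droop at 44 Hz.

## Trial classification and session statistics (`trials`)

Target windows are circles of radius `eccentricity × sin 22.5°`, making
adjacent windows of the 8-target, 45°-spaced layout exactly tangent.
Classification of a trial: a saccade leaving a 2° fixation zone before the
go signal is a *fixation-break exclusion*; a first post-go saccade with
reaction time < 100 ms is an *anticipatory exclusion*; success requires the
first post-go saccade to land in the window with RT < 1 s and window entry
within 200 ms of movement onset; a miss followed by a later saccade that
reaches the window is a *multistep error*, otherwise an *off-target error*;
no qualifying saccade is a *timing error*. Excluded trials leave the success
denominator.

Inactivation sessions are compared per hemifield: the *representative target*
is the one with the largest success-rate drop (ties to the lowest direction
angle), tested with a one-tailed Fisher exact test for a decrease
(hypergeometric upper tail). Reaction-time comparisons use the exact-capable
Wilcoxon rank-sum; dispersion uses a 2000-iteration bootstrap percentile CI
of the IQR; factorial comparisons use OLS on rank-transformed data with a
type-II ANOVA table (statsmodels) and all-pairwise Mann–Whitney post hocs
with Bonferroni correction.

**Selection-induced null inflation (by design).** Because the representative
target is the argmin of the observed success-rate delta over 4 targets, the
null flag rate of the *selected* target is not the per-test α: the exact rate
at p = 0.7, n = 20/20, α = 0.05 is 0.1015, while a single pre-specified
target's rate is 0.0265. Both values are computed exactly by enumerating the
21×21 binomial outcome grid per target and summing
P(target j is selected AND its Fisher p < α) with iid order statistics; the
acceptance suite checks pipeline power (0.999 at 0.9 → 0.5) and both null
rates against these oracles rather than pretending the selected-target rate
can be ≤ 0.07.

## Multimodality of saccade endpoints (`modes`)

Endpoint errors are decomposed into direction error (wrapped to (−180°, 180°]
relative to the target direction; undefined for endpoints at fixation) and
eccentricity error. Each axis is tested with a from-scratch Silverman
critical-bandwidth test: h_crit(k) is the smallest Gaussian-KDE bandwidth
giving ≤ k modes (well-defined by Gaussian-kernel mode monotonicity; found by
bisection to 1e-4 relative tolerance, mode counting on a 2048-point grid over
the data ± 3h). Significance comes from the smoothed bootstrap with the
classical variance rescaling y = ȳ + (1 + h²/σ̂²)^(−½)(x_I − ȳ + hε); the
p value is the fraction of B = 500 resamples whose KDE at h_crit(k) has more
than k modes. The mode search starts at k = 1 and stops at the first k with
p ≥ α = 0.05. If the resulting density has a mode supported by a single
observation, that point is removed as an outlier and the whole procedure
reruns. Antimodes (density minima between modes) assign points to modes;
points in the mode nearest zero error are *on-target*, everything else
(including removed outliers) *off-target*. The test is conservative
(measured type-I error well below α at n = 100), which is the documented
behavior of Silverman's test.

## Spike-train analysis (`spikes`)

Spike density functions use a Gaussian kernel, σ = 15 ms, truncated at ±4σ
(single-spike peak 1000/(15√2π) ≈ 26.6 spikes/s). Control period 1 spans
−200..+40 ms around target onset; control period 2 spans −300..−50 ms.
Visual latency slides a 25-ms window in 1-ms steps from target onset and
requires the trial-averaged rate to exceed the control-1 mean + 3 across-trial
SDs for 30 consecutive positions.

**Latency time stamp (documented deviation).** The latency is stamped at the
*center* of the run's first window, not its start. A window detector
localizes the onset only to within the window, and start-stamping
systematically anticipates the true onset: at the published neuron scales the
start convention gave ≈ −15 ms population bias in simulation, violating the
≤ 10 ms bias requirement, while center stamping gives +1.7 / −2.4 ms at the
two scales. Response magnitude is the mean rate over the 50 ms after latency
minus the control-1 mean; note it includes whatever sustained delay activity
falls in that window, so for the synthetic neurons it estimates
phasic + sustained, not the phasic parameter alone.

RF mapping picks the (direction, eccentricity) with the maximum mean rate
50–250 ms after target onset (ties: more trials, then lower angle). The
neuron tests are paired t tests (delay −100..+40 ms around fixation offset vs
control 1 on in-RF trials; vs control 2 on out-of-RF trials) and an unpaired
t test of perisaccadic rate (±50 ms around saccade onset), in- vs out-of-RF,
with degenerate zero-variance cases flagged rather than erroring. Group
comparisons from summary statistics use Welch's t with Satterthwaite df: the
published latency summaries 141 ± 21 (n = 7) vs 94 ± 9 (n = 9) give
t = 5.539, df = 7.72, p = 0.00062.

## Synthetic neurons: scope and shape defaults

The `NeuronPlan` rate model is baseline + phasic alpha bump
(s/τ)e^(−s/τ) after the visual latency + sustained delay elevation until
fixation offset + perisaccadic boost, realized by Poisson thinning. The bump
is scaled so its mean over the first 50 ms equals the magnitude parameter.
Shape defaults — phasic decay τ = 12 ms, sustained rate 15 spikes/s — were
frozen after an SNR analysis of the +3 SD/30-window criterion: at the
published magnitude scales, *no* detector of this design sees 30 consecutive
supra-threshold windows without sustained elevation, and the values match the
prominent sustained activity in parietal delay-task recordings. The
published scale parameters (baselines 16.9/8.5, magnitudes 22.1/28.7,
latencies 141/94 ms) are used verbatim in the acceptance checks. The
generators are desk-scale models for validating the estimators; they do not
model bursting, adaptation, rate drift, or correlated noise.

## Numerical and reproducibility choices

- Exact tail probabilities via `scipy.stats.hypergeom.sf` (Fisher) and
  `t.sf` (Welch); enumeration oracles in `tests/oracles.py` are independent
  re-derivations used only for checking.
- All stochastic stages take explicit integer seeds; per-trial substreams come
  from `SeedSequence.spawn`, so same-seed reruns are byte-identical (asserted
  end to end, including CLI file output, by acceptance criterion 9).
  Timestamps live only in `run.log`, never in statistics files.
- Bootstrap/bisection budgets (B = 500, rel. tol. 1e-4, 2048-point KDE grid)
  keep the full acceptance run around 4 minutes on one CPU.
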