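# Methods

`audbattery` simulates a portable psychoacoustic test battery — six
suprathreshold auditory detection tasks plus a two-condition
speech-in-competition task — together with the virtual listeners who take
it and the statistical analysis that relates the measures. This note
records the models, the parameters that matter, the numerical choices, and
the limits of what the simulation can show.

## Stimuli

All stimuli are two-channel waveforms at 44.1 kHz with 10-ms raised-cosine
onset/offset ramps on each 400-ms observation interval (the ramp duration
is a package choice; ramps are sampled at half-sample offsets so no ramp
endpoint is an exact zero, which keeps silent-gap measurement unambiguous).
Digital calibration maps dB SPL to full-scale RMS exponentially;
by convention 75 dB SPL ↔ RMS 0.05, configurable in `CalibrationMap`.
Level is defined on the steady-state portion of an interval, i.e. the
gating ramps do not count against the calibrated level.

* **FM tones.** A pure tone with carrier roved uniformly in [460, 550] Hz
  per interval (the distribution is unstated in the source literature;
  uniform is assumed), duration 0.4 s, 75 dB SPL, carrying 2-Hz sinusoidal
  phase modulation. The tracked parameter is the peak instantaneous-
  frequency deviation in Hz (phase-modulation index = depth/rate). Diotic
  mode sends bit-identical channels; dichotic mode uses antiphase
  modulation (±φ(t)) in the two ears — the symmetric reading of
  "different FM to the two ears", and configurable.
* **Gap pairs.** Two 4-ms 500-Hz tone bursts with 1-ms raised-cosine ramps
  inside each burst. The gap is the digital silence between the end of the
  first burst's ramp and the start of the second's; gap 0 reproduces the
  contiguous 8-ms standard.
* **Modulated noises (TM/SM/STM).** A bank of 60 equal-amplitude random-
  phase tone carriers per octave, uniformly spaced on log2 frequency over
  200–8000 Hz ("broadband" is unquantified in the source; this band covers
  the speech-relevant range). Carrier *i* at octave offset *u_i* gets the
  time-varying dB gain `depth_db · sin(2π(density·u_i ± rate·t) + φ)`:
  density 2 cyc/oct with rate 0 gives the static spectral ripple (SM),
  density 0 with rate 4 Hz the common broadband envelope (TM), both
  together the drifting ripple (STM, drift direction randomized per trial
  unless pinned). `depth_db` is therefore the peak-to-midline excursion in
  dB of the log-spectrum and/or log-envelope; depth 0 is the flat standard.

Verification is analysis-only and shares no code with synthesis: Hilbert
demodulation and a known-rate sinusoid fit for FM (recovers depth to ≪2%),
longest-silent-run measurement for gaps (±1 sample), band-averaged
periodogram regression over a density grid for SM (density ±0.1 cyc/oct,
depth ±1 dB at 5–20 dB), dB-envelope regression over a rate grid for TM
(rate ±0.25 Hz; the 25-ms smoothing attenuation is corrected by its sinc
factor), and short-time ripple-phase tracking for STM (rate ±0.5 Hz,
density ±0.15, depth ±3 dB — the coarser tolerance reflects window smear
on a drifting ripple over a 0.4-s stimulus).

## Adaptive procedure

Trials are four-interval 2C-2AFC: intervals 1 and 4 are standards, the
target sits in interval 2 or 3 with probability 1/2, 250 ms between
intervals. Tracking is transformed up-down: 2-down-1-up on a logarithmic
scale (log2 ms for the gap, log2 Hz for FM depth, dB for the noise
depths), which converges on the 70.7%-correct point. The cited source
algorithm's constants are not restated in the original report, so the
defaults here are the standard choices — start at 6 Hz deviation (FM),
20 ms (gap), 20 dB (noise depths); initial step 1.0 log2 unit (4 dB for
dB-tracked tasks) halved at each of the first 4 reversals down to 0.25
log2 units (1 dB); stop at 10 reversals or 60 trials; threshold = mean of
the last 6 reversal levels (flagged, not raised, when fewer exist). All
constants live in `AdaptiveConfig`. With a longer track (30 reversals /
200 trials) the median estimate over 100 seeds lands within 0.05 log2
units of the true 70.7% point; the short default track has spread
~0.5 log2 units per run, which is the price of a rapid battery.

Track levels are clamped to per-task bounds; dB-depth tracks floor at
0.1 dB. Near that floor the threshold estimate is upward-biased (the track
cannot overshoot below a listener's true threshold), a real floor effect
that also motivates flooring planted dB thresholds at 0.2 dB, the smallest
value such batteries report.

## Speech task

The speech stage follows the closed-set coordinate-response paradigm:
target callsign CHARLIE, response set 4 colors × 8 numbers (32
alternatives, guess rate 1/32), two masker talkers with distinct other
callsigns and colors/numbers different from the target's. Thresholds use
progressive tracking — TMR from +10 to −10 dB in 2-dB steps, two trials
per step, 22 trials — scored as `10 − #correct` dB, an estimate of the
50%-correct TMR. Each condition is measured as the mean of 2 tracks
(the published threshold precision implies multi-run averaging; the run
count is configurable).

Intelligibility is simulated at the psychometric level: no recorded
corpus is consumed and no speech audio is synthesized. The spatial
renderer used for audio demos and QC replaces measured HRTFs with a
spherical-head model: Woodworth ITD `(a/c)(sinθ + θ)` with radius 8.75 cm
(0.38 ms at ±45°, applied as an integer-sample delay at 44.1 kHz) and a
broadband ILD of `8·sin(θ)` dB split between the ears. TMR is defined
against a single masker's level, both maskers equal.

**Scoring bias, documented.** The progressive score is a coarse
estimator. In closed form, `E[score] = 10 − Σ_t p(t)` over the 22
scheduled TMRs: for a listener with true 50% point θ mid-range this sits
near θ − 1 dB (the schedule effectively integrates to +11 dB, and the
1/32 guess rate adds ~0.5 spurious corrects), and the deficit grows near
the +10 dB ceiling, where only two trials lie above θ — at θ = +8 the
bias cannot be smaller than ~1.5 dB in magnitude for any psychometric
slope. The suite therefore asserts |bias| ≤ 1.5 dB for θ in [−8, +4] and
a bounded negative bias (< 2.2 dB) at θ ∈ {+6, +8}. The bias is common to
both conditions and cancels exactly in SRM = CO − SEP.

## Virtual listeners

Listeners are drawn from a Gaussian copula over [Age, PTA, TGap, DioFM,
DichFM, TM, SM, STM]: age is uniform over 23–80 (matching the recruitment
range; mean 51.5, SD 16.5 — the closest simple family to the reported
moments), linked through the normal CDF, with the latent age column
inflated by the exact attenuation factor `√12/(2√π)` so realized
correlations hit their targets. The default correlation matrix uses the
published pairwise values where printed (e.g. Age–PTA 0.476, TGap–DioFM
0.592, SM–STM 0.691) and modest placeholders (0.15–0.35) for pairs
reported only as non-significant; the matrix is validated positive
semi-definite. Marginal means/SDs are the published descriptives
(e.g. TGap 2.96 ± 0.66 log2 ms). dB-depth thresholds floor at 0.2 dB.

Audiograms (0.25–8 kHz, both ears) are built around the drawn PTA with a
mild upward tilt across the PTA frequencies, an age-dependent
high-frequency slope (up to +10/+25 dB at 4/8 kHz), and interaural
asymmetry capped at 10 dB (the recruitment criterion); the low-frequency
block is recentred so `compute_pta(audiogram)` equals the drawn PTA
exactly. PTA averages the four frequencies over both ears (ear handling
is unstated in the source; both-ear averaging is the package default).

The separated-speech threshold is planted as
`SEP = −7.444 + 0.0887·Age + 0.7148·DioFM + N(0, 3.055)` dB,
calibrated so that corr(SEP, Age) = 0.471, corr(SEP, DioFM) = 0.381 and
SD(SEP) = 3.64 dB — a population R² of 0.296 for the two-predictor
model, i.e. adjusted R² ≈ 0.26–0.30 at n = 41, consistent with the
published final model. The colocated threshold is drawn N(2.23, 1.21²)
independent of every predictor (the null colocated model). The Age–DioFM
latent correlation, not printed in the source (hence |r| < 0.31), is set
to 0.25.

Observers answer through a four-parameter logistic,
`p(x) = γ + (1−γ−λ)·F((x−α)/β + c)`, with γ = 0.5 (2C-2AFC) or 1/32
(speech), lapse λ = 0.02, and the anchor c pinning p(α) to the percent
point each threshold convention tracks (70.7% and 50% respectively), so a
planted α is exactly the quantity its procedure estimates. Default slope
scales: 0.5 log2 units (log2-tracked tasks), 1.5 dB (noise depths),
2.0 dB (speech, ≈12%/dB at midpoint — typical of closed-set speech).

`run_study` drives the full battery at the psychometric level (the
observer model never analyzes waveforms, so no audio is synthesized in
the study loop), with independent seeded streams per listener × task.

## Statistics

Descriptives use the n−1 SD. Pearson correlations (via `scipy`) carry
two-tailed p-values from `t = r√((n−2)/(1−r²))`; the screen evaluates all
55 unordered pairs of the 11 reported variables and returns those with
p < 0.05, uncorrected by default (a Bonferroni flag divides by the number
of comparisons). Backward elimination (via `statsmodels` OLS) drops the
predictor with the largest partial t-test p-value while it exceeds
p_remove (default 0.10; 0.20 exposed), ties broken toward the later
column; a final model with no predictors or adjusted R² ≤ 0 is reported
as "no model", and "Error (dB)" is the residual standard error of the
final model (an interpretation of the published column).

## What the simulation does and does not show

The operating-characteristics experiment (`analysis/04`) makes the power
situation explicit: with effect sizes calibrated to an adjusted R² near
0.29 at n = 41, backward elimination retains *both* true predictors of
SEP in only ~40–50% of replicate cohorts (each needs a partial t of
~2.1–2.6; joint power tops out near 0.70 even at the optimal effect
split), and a predictor-independent CO ends with every predictor
eliminated in only ~40–45% of replicates — with 8 candidates at
p_remove = 0.10 some spurious predictor usually survives. A single
replicate matching the published pattern (Age + DioFM retained, CO empty)
is therefore one draw from a wide selection distribution, not a stable
property of the design.

The generator emulates the *statistical* structure of a real cohort —
marginals, pairwise correlations, a planted speech model — not its
mechanisms: no cognitive variables (attention, working memory), no
audibility-driven link from the audiogram to task performance beyond the
planted correlations, Gaussian abilities with no skew or outliers, and
stationary observers with no learning or fatigue. Passing tests show the
pipeline measures what was planted at the stated precision; they cannot
show that real listeners behave like the plant.

## Problem sizes

Defaults chosen for the analysis scripts and suite: cohorts of n = 41
(the study size) for single runs, n = 1000 for correlation-recovery
checks, 200–500 replicate cohorts for the selection experiments, 100
seeds × 200 trials for staircase convergence. These sizes give Monte
Carlo error comfortably below each asserted tolerance.
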