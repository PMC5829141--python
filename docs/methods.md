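# Methods

This note documents the models, estimators and numerical choices behind
`audlfp`, in the spirit of a package methods appendix: what is computed,
under which assumptions, which knobs matter, and what the synthetic-data
validation does and does not establish.

## Data model

The unit of analysis is an `EpochSet`: a trial × sample matrix of voltages
(µV) cut around a stimulus event, at sampling rate `fs` (default 1000 Hz —
the 1–300 Hz LFP band is fully represented; the rate is configurable
because acquisition hardware varies). Click-train epochs span (−0.5, 1.0) s
around train onset; sound-pair epochs span (−3.5, 1.1) s around the
conditioning (C) onset so that the 1-s control period at [−3, −2] s, both
responses, and the wavelet edge margins all fit inside every trial.
Event-to-sample alignment takes the nearest sample, with exact half-sample
ties resolved toward the earlier sample. Continuous input arrives as EDF
(read via `mne`) or a two-column CSV (`time_s,voltage_uV`, written with
`%.17g` so round trips are bit-exact); epochs are stored in a small
versioned HDF5 layout (root attributes + one `data` dataset, native dtype,
bit-exact round trip).

## Wavelet decomposition, MTP and PLF

Per trial and frequency the signal is convolved with a complex Morlet
wavelet with a constant `n_cycles = 7` (grid 1–100 Hz, step 1 Hz by
default), giving ≈ 11 ms temporal and ≈ 6 Hz spectral resolution at 40 Hz —
matched to a 0.5-s entrained train. Two numerical conventions matter:

* **Normalization.** The wavelet is scaled in the frequency domain so that a
  unit-amplitude sinusoid at the wavelet's centre frequency yields
  `|W| = 1` at every frequency; `|W|²` therefore reads directly as squared
  signal amplitude (µV²), and equal-amplitude tones at different
  frequencies produce equal power. (An energy/L2 normalization would make
  the response fall off as `f^{-1/2}` and was deliberately not used.)
* **Edge handling.** The wavelet support is truncated at ±5σ_t; samples
  closer than half the support to an epoch edge are flagged invalid (NaN)
  per frequency rather than zero-padded, and the flags propagate through
  MTP, PLF and the band summaries. At the defaults the 50–550 ms summary
  window is far from all flagged regions for every frequency ≥ 35 Hz.

MTP is the trial mean of `|W|²`; PLF is the magnitude of the trial mean of
the unit phasors `W/|W|` (undefined for fewer than two trials; cells where
any `|W| = 0` are invalid). PLF is bounded in [0, 1], invariant under
per-trial positive rescaling, and has the Rayleigh floor
`E[PLF] ≈ √π/2 · N^{-1/2}` (≈ 0.081 at N = 120) under random phases — all
three properties are tested, and the transform itself is verified against a
direct time-domain convolution to < 1e-6 relative error. Band summaries are
plain arithmetic means over a closed frequency × time rectangle, excluding
invalid cells. No baseline normalization is applied to MTP (raw power is
averaged); a dB-vs-prestimulus view is easy to add downstream but is not
part of any statistic here.

## Evoked peaks and the T/C ratio

Per sound-pair session the 120 trials are averaged and two deflections are
quantified per stimulus (C at 0 s, T at 0.5 s): negative then positive,
labelled N25/P40 in AC and N35/P70 elsewhere. Search windows bracket the
expected latencies with margin — AC: 10–40 ms (negative) and 25–60 ms
(positive); HP/AMY/PFC: 25–55 ms and 50–95 ms — and are configurable per
region.

The peak statistic is the mean of the averaged waveform over a ±5 ms window,
minus its value at that stimulus's onset (the T baseline mirrors the C
convention at 0.5 s). Peaks are *located* on the ±5 ms boxcar-smoothed
waveform: among strict local extrema of the matching polarity whose
amplitude deviates from baseline in that polarity's direction, the largest
|amplitude| wins, equal depths resolving to the earliest latency; windows
with no interior extremum fall back to the window's extremal sample, flagged
as a boundary result. Measuring the window mean rather than the raw extremal
sample is deliberate: the window mean shrinks C and T by the identical
kernel-shape factor (so T/C is unchanged) while removing most of the upward
bias that picking the extremum of a noisy average introduces.

Significance gating follows the sliding-window construction: the per-trial
response statistic (±5 ms window mean minus the onset sample) is compared
with the identical statistic slid in 10-ms steps through the 1-s control
period 3 s before C (same baseline lag), pooled over trials, via a
two-sided Welch t-test; a peak is accepted at p < 0.01. The paired/pooled
and sidedness details are not dictated by the procedure's usual one-line
description; the Welch two-sided reading is the documented choice here, and
the test's type-I error is verified to sit inside the binomial 95% interval
at α = 0.01 over 200 null sessions (with the latency held fixed — latency
*selection* is a property of the detection step, not of this test).

`T/C = T-amp / C-amp` is emitted per label only when both constituent peaks
are significant and C-amp ≠ 0; otherwise the ratio is NaN (never a silent
zero) and the session drops out of group statistics for that label, as the
acceptance rule prescribes.

## Synthetic LFP generator

Each trial is 1/f (pink) noise — the canonical LFP baseline spectrum,
synthesized spectrally with a deterministic normalization so the *expected*
trace SD equals `noise_amp` — plus a paradigm-specific signal:

* click trains: `amp · cos(2πf_stim(t) + φ_n)` gated over [0, 0.5] s with
  10-ms raised-cosine ramps and per-trial phase jitter
  `φ_n ~ N(0, σ_φ²)`;
* sound pairs: a biphasic kernel of two Gaussian bumps (FWHM 12 ms) at the
  region's latencies, repeated at +500 ms with per-polarity gate factors
  `gateN`, `gateP` — the generative ground truth for T/C.

Presets per region × condition carry the published representative values:
latencies (AC 25/40 ms; HP 39/65, AMY 37/65, PFC 35/75 ms) and gate factors
(AC 0.75/0.90 conscious, 0.72/0.92 anesthetized; HP 0.61/0.51 and
0.58/0.45; AMY 0.50/0.35 and 0.52/0.30; PFC 0.25/0.28 and 0.21/0.23).
Quantities the source does not constrain are nominal and documented as
such: absolute amplitudes (ampN = −40, ampP = +30 µV; ASSR amplitudes
20/10/5/0 µV for AC/HP/AMY/PFC), `noise_amp = 20 µV` chosen so the
single-trial peak SNR is ≈ 2 (recovery is then genuinely statistical, not
trivial), phase jitter 0.4 rad awake, and the anesthesia effect sizes
(ASSR amplitude ×0.4 and jitter ×2; evoked amplitudes ×0.8 — directionally
reported, magnitudes free). Inter-trial intervals (2–4 s trains, 8–10 s
pairs) are honored when rendering continuous recordings.

What the generator does *not* emulate: non-Gaussian artifacts, line noise,
non-stationary states, latency jitter across trials, multi-channel
structure, or any biophysical model of LFP genesis. Passing recovery tests
therefore demonstrates estimator correctness under the stated statistical
model, not robustness to everything real recordings contain.

## Parameter recovery and its known bias

The headline validation (also what `scripts/acceptance.py` recomputes) is:
simulate 20 independent 120-trial sessions per preset at default noise, run
the full IG pipeline, and compare the mean recovered T/C with the
generative gate. At the defaults all nine reported region/condition/label
cases recover to well within ±0.05.

Two residual biases are worth knowing about. First, extremum selection in
a noisy average inflates |amplitude| slightly; the smoothed-window
estimator reduces this to ≲ 0.02 in ratio terms at the default SNR.
Second, and dominant for weak responses: the acceptance rule itself
censors. When the T response is small (≈ 5–7 µV against the averaged-noise
floor), sessions whose T peak fluctuates downward fail the p < 0.01 gate
and drop out, so the surviving ratios are biased upward. For the two
weakest cells (the anesthetized AMY and PFC positive peaks, gated
amplitudes ≈ 5.5 µV) this survivorship pushes the recovered mean ≈ 0.06–0.12
above the generative gate. This is a property of the published procedure,
not of the implementation, and it applies equally to real data: T/C means
for near-threshold responses are conditional on detectability.

## Cohort simulation and group statistics

`run_pipeline --synthetic` (and the `analysis/` scripts) simulate a cohort
of 10 sessions per region × condition cell. Real sessions differ in
electrode placement and state, so the cohort layer adds between-session
heterogeneity *on top of* the fixed presets: gate factors are drawn
per session and condition from a truncated normal around the preset
(sd = 0.20 — the scale implied by the source study reporting
non-significant paired condition differences of ≈ 0.02–0.06 at 64–93
sessions per region), and ASSR amplitudes log-normally with CV 0.3. The
heterogeneity deliberately lives in `CohortSpec`, not in `make_session`,
so single-preset recovery stays exact.

Group inference mirrors the study: classic one-way ANOVA across regions
(conscious sessions) with Tukey HSD over all six region pairs
(studentized-range p-values; the degenerate all-equal case is defined as
F = 0, p = 1), and two-sided paired t-tests conscious vs anesthetized per
region and measure, sessions matched by id and unmatched ones dropped with
a warning. Repeated sessions are treated as independent (no mixed-effects
modelling — a documented limitation), and the several measures are tested
without cross-measure correction, matching the study's practice. One
statistical consequence is worth stating plainly: eight paired T/C tests at
α = 0.05 have a family-wise false-positive rate of ≈ 1 − 0.95⁸ ≈ 0.34 even
when anesthesia truly does nothing, so "no significant T/C change in any
cell" is expected to hold in most, but not all, simulated cohorts; on the
shipped seed it holds, with the regional gradient and the ASSR suppression
strongly significant throughout.

## Problem sizes and determinism

Defaults throughout: 120 trials/session, 20 seeds for recovery means, 200
null sessions for the calibration check, 10 sessions/cell for cohorts —
sizes at which every validation completes in minutes on one CPU while
keeping Monte-Carlo error well below the tolerances tested. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; reruns with the same seed are byte-identical,
including the written result tables.
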