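# Methods

This note records the model, the parameter choices and the numerical
decisions behind `fatiguewave`, and what the synthetic validation does
and does not establish.

## The marker pipeline

**Preprocessing.** Recordings are filtered with a 4th-order Butterworth
band-pass (3–30 Hz) applied forward and backward (`sosfiltfilt`), giving
zero phase, a flat passband and ≥ 20 dB attenuation an octave outside
the corners. Each channel is then z-scored over the *entire* session —
not per epoch — so that amplitude differences between sessions (gel
drying, electrode placement) are removed while within-session band
structure is untouched. The filtered, normalized signal is decimated by
keeping every 4th sample (250 → 62.5 Hz). No anti-alias filter is
needed because the passband already ends at 30 Hz, below the new
31.25 Hz Nyquist; the stage still estimates out-of-band power and warns
if more than 1 % of it would alias. Epochs are 8 s with 50 % overlap;
the trailing partial window is discarded rather than padded, because
padding distorts band energies.

**Why decimate at all.** At 250 Hz a 4-level DWT puts detail level 1 at
62.5–125 Hz, far above any EEG rhythm of interest. At 62.5 Hz the four
detail levels fall at ≈ 15.6–31.2 / 7.8–15.6 / 3.9–7.8 / 2.0–3.9 Hz,
which is the β/α/θ/δ ordering the marker assumes. Decimation by 4 is
the only rate change under which that level-to-band mapping holds.

**Wavelet analysis.** db4, 4 levels, *periodized* boundary handling.
Periodization keeps the transform orthonormal, so coefficient energy
equals signal energy exactly on dyadic lengths — this makes the
Parseval invariant testable at 1e-8 rather than approximately. On the
500-sample epochs the internal padding perturbs energy by < 1 %.

**Denoising.** Per detail level, T_j = mean(|w_j|) + 2·std(|w_j|) with
the population standard deviation, computed on the *absolute*
coefficients: detail coefficients are near zero-mean, so a mean of raw
coefficients would carry no information, and the rule itself operates
on magnitudes. Coefficients strictly above T_j are halved with sign
preserved; the strict inequality keeps the analytic boundary case
(four equal magnitudes plus one outlier, for which T equals the outlier
exactly) stable. Thresholds are recomputed per window, and the
approximation band is never touched. Denoising can only shrink
coefficients, so total energy is non-increasing.

**Entropy.** Relative energies are taken over the four detail bands
only; the approximation (< 2 Hz) is excluded because the 3 Hz high-pass
empties it and no band is assigned to it. The order-2 Rényi entropy is
computed in natural log and normalized by ln 4, mapping a flat profile
to 1 and a one-hot profile to 0. Session aggregation is the arithmetic
mean over windows; per-window values are retained in the output tables
so other aggregates can be computed downstream.

## The synthetic cohort

The generator emulates a nine-subject study with six assessment
sessions (`Day1`–`Day3` daily, then `Day4A`, `Day4B`, `Day5` under
increasing sleep deprivation): 4-channel forehead EEG (AFp7, Fp1h,
Fp2h, AFp8) at 250 Hz, 5 min per session, two 4-min oddball runs
(audio and visual; 80 % standards, 20 % deviants, 1000 ms interval,
50 ms stimuli), a 1–7 sleepiness score and prior sleep minutes.

**EEG model.** Each channel is a sum of four band-limited noise
carriers (white noise restricted to each dyadic band, clipped to the
3–30 Hz passband) plus `1/f` background. Noise carriers rather than
sinusoids are used so that every window sees an independent
realization — the band profile of a pure tone is degenerate across
windows. Each carrier is normalized to unit power *after* the 3–30 Hz
analysis filter, so the in-band relative powers of the sum follow the
programmed band profile; the background contributes a fixed 30 % of
in-band power, enough to be realistic while keeping programmed ratios
recoverable by a periodogram within 15 %.

**Trajectories on the entropy scale.** A session's band profile is
parameterized by its target normalized entropy: an alpha-dominant
resting profile (β, α, θ, δ) = (0.15, 0.70, 0.10, 0.05) is mixed
linearly toward uniform until the target is met (bisection; the
entropy is strictly increasing along the path). The default trajectory
uses the six session levels 0.657, 0.684, 0.661, 0.737, 0.761, 0.841 —
flat across the first three days, rising through sleep deprivation;
`monotone_entropy_targets()` provides the linear 0.65 → 0.84 ramp used
in marker-validity studies. Between-subject offsets (sd 0.15) and
within-subject session jitter (sd 0.03) act on the entropy scale; each
cell's profile is reshaped along the power-sharpening path
p^γ/Σp^γ so a custom trajectory keeps its band ordering. The
within-subject sd is not identifiable from published descriptive
statistics; 0.03 — slightly below the mean session-to-session step of
the default trajectory — was fixed once as a realistic signal-to-noise
regime for a marker reported as strongly significant at n = 9.

**Determinism.** Every generated object is a pure function of the
master seed: per-(subject, session, channel) substreams are derived by
counter-based `SeedSequence` spawn keys, so enlarging the cohort never
changes existing subjects' data, and the whole pipeline is reproducible
byte-for-byte.

**What the generator does not emulate.** No volume conduction or
channel correlation (channels are independent realizations of the same
latent profile), no eye-blink/EMG artifacts, no non-stationarity within
a session, no circadian structure beyond the programmed session means.
Passing closed-loop tests therefore shows that the pipeline recovers
programmed band-profile flattening at realistic noise levels — not that
real prefrontal EEG behaves this way.

**Calibration bias.** Wavelet leakage between adjacent dyadic bands
(db4 filters are not brick-wall) and the near-flat in-band split of the
1/f background both push measured profiles toward uniform: a programmed
session entropy of 0.65 is measured around 0.83, and the programmed
0.65 → 0.84 span compresses to roughly a third. The mapping from
programmed to measured entropy is strictly increasing (verified
numerically over the whole attainable range), so ordering, monotone
trends and detection power are preserved; absolute levels are not
comparable between programmed targets and measured values.

## Statistics

One- and two-way within-subject ANOVA are computed from explicit sums
of squares, each effect tested against its own effect × subject term.
The Greenhouse-Geisser epsilon comes from the orthonormal-contrast
covariance; correction is applied *unconditionally* to every effect,
with Mauchly's test (chi-square approximation with the second-order Box
term, the SPSS/ezANOVA convention) reported as a diagnostic only. With
fewer subjects than contrast dimensions, Mauchly's W is undefined and
returned as NaN rather than a crash. LSD post-hoc p-values are
deliberately unadjusted — that is the named procedure — and the report
flags it. Correlations with prior sleep pool all subject × session
observations (n = 54 by default), which ignores within-subject
dependence; this mirrors the design the summary table documents, and
the report says so.

Numerical details: sums of squares at or below 1e-12 of the total are
snapped to zero so that structurally exact null effects give F = 0
rather than floating-point ratios; a zero error mean-square with a
nonzero effect yields an explicit infinite-F diagnostic; epsilon is
clamped to [1/(k−1), 1].

Under exact sphericity the GG-corrected test is *conservative* at small
n (around 2 % rejection at n = 9, k = 6) because the epsilon estimate
is biased downward; its rejection rate approaches the nominal 5 % as n
grows (≈ 4.5 % at n = 50). The calibration check in the test suite
therefore runs at n = 50, where the epsilon estimator is close to
consistent, and separately asserts conservatism at the study's n = 9.

## Problem sizes in the validation suite

Closed-loop studies scale the cohort down from the 300-s, 4-channel
sessions to keep replication affordable: the monotone-trend study uses
20 cohorts of 120-s recordings with all four channels averaged; the
power and null-specificity studies use 100 replicates of 60-s,
single-channel cohorts. These sizes give the marker *less* data than
the emulated sessions, so detection rates measured with them are not
inflated by the scale-down. The end-to-end determinism check runs the
full default cohort.

## Known limitations

* The entropy normalization (natural log, ln 4) is an interpretation;
  published session means in [0, 1] are consistent with it but do not
  pin down the convention.
* Whether denoising thresholds should be computed per window or per
  recording is not documented anywhere authoritative; per window was
  chosen because the windowed pipeline computes everything else per
  window.
* Reaction-time extraction assigns each press to at most one deviant
  with a 0.1–1.0 s validity window; anticipations below 0.1 s count as
  false alarms and leave the deviant a miss. Alternative conventions
  would change mean RT slightly; hit/miss/false-alarm counts are
  reported so the choice is auditable.
* EDF support is read-only; the package writes only text formats.
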