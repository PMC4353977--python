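# Methods

This note documents the estimators, the generative model behind the
synthetic sessions, the numerical choices, and what the recovery tests do
and do not establish about real recordings.

## Signal model and conventions

A session is a matrix of region channels (microvolts) at a common sampling
rate (1 kHz in the experimental setting; 500 Hz in most simulated test
conditions), with a named event timeline. Time is measured in seconds from
recording start; a period `[start, end)` maps to the half-open sample
interval `[round(start·fs), round(end·fs))`, so adjacent periods (e.g. an
encounter and the following post period) never share a boundary sample.
The 15-s stimulus-transfer window is an ordinary named period ("Stimulus" /
"Transfer"), never inferred from encounter onsets.

Manifests are strict JSON (`schema: thetanet-session-v1`); signal payloads
are CSV (header row of region labels) or EDF. Units are microvolts; a
manifest `scale` factor is honored but never inferred. EDF files are read
through MNE; the package's own EDF writer emits standard 16-bit continuous
EDF, so a write→read round trip is exact only up to the 16-bit physical
quantization step (< 0.01 µV at typical LFP ranges).

## Spectral estimation

**Welch PSD.** Modified periodograms on 1-s windows with 50% overlap, each
window tapered by the index-0 dpss (Slepian) sequence with time-bandwidth
NW = 3, normalized to unit energy. One dpss taper as the Welch window (not
within-window multitaper averaging) matches the common
`pwelch(x, dpss(N,3), ...)` usage; NW = 3 also matches the Chronux-style
TW = 3 used for coherence, keeping the two estimators' bandwidths
consistent. Density scaling is one-sided power/Hz: with a unit-energy taper
the scale factor is 1/fs, interior bins doubled, so the integral of the
linear PSD over [0, fs/2] recovers the variance of a stationary signal
(verified to < 5% for white noise). FFT length equals the window length
(1 Hz resolution at 1-s windows; the reported features sit on integer-Hz
bins); a `pad_factor` is available for smoother change-spectra. dB
conversion is 10·log10 with a floor at −300 dB so arithmetic on dB values
stays finite.

**Theta power.** TP is the maximum PSD value (dB/Hz) over grid frequencies
in the search band — 5–11 Hz for the social analyses, 3–12 Hz generic —
with ties broken toward the lower frequency. ΔTP subtracts the Base-period
TP; any gain common to all periods cancels. Instantaneous ΔTP uses the
spectrogram (same window, hop 0.5 s) per-column band peak minus the mean
per-column Base TP. Averaging spectrogram columns over a period reproduces
the period's Welch PSD exactly (same segmentation and scaling), which is
asserted in tests.

**Band nomenclature.** The low/high sub-band pair used for the
fear-vs-social contrast is 4–8 / 8–12 Hz; the TP search band for the social
paradigm is 5–11 Hz. Both are explicit arguments everywhere and recorded in
outputs.

## Band-pass filtering

The cross-correlation stage band-passes 5–11 Hz with a windowed-sinc
(Hamming) FIR of order 1000 at 1 kHz (≈1-s impulse response; proportionally
shorter at lower rates), applied forward–backward (`filtfilt`) with
reflect padding by one filter length. Zero-phase filtering is a deliberate
choice: a single-pass FIR would delay every channel by half the filter
length and shift every lag estimate by a constant. Filter order must be
even so the impulse response is exactly symmetric.

## Multitaper coherence

Cross- and auto-spectra are averaged over K = 5 dpss tapers (TW = 3) and
over 2-s windows stepped by 200 ms; magnitude coherence is
`|S_xy| / sqrt(S_xx S_yy)`, clipped to [0, 1], defined as 0 where power
vanishes. Full-period coherence averages taper×window estimates across all
window positions of the period (segmented multitaper), giving
`n_avg = K · n_windows`; coherograms average over tapers only. A single
elementary estimate yields coherence ≡ 1 whatever the data, so the
estimator refuses `n_avg < 2`. With non-overlapping windows the squared
null coherency averages ≈ 1/n_avg (the estimator bias floor); the 200-ms
step makes neighboring windows strongly correlated, so n_avg then
overstates the effective number of independent estimates — acceptable here
because only magnitudes, not confidence intervals, are reported. Jackknife
confidence intervals are a known extension, deliberately omitted. "Coherence
at 8 Hz" is the value at the grid frequency nearest the band center (0.5-Hz
grid at 2-s windows); a band-max mode exists as well. Coherence change
between conditions is the signed peak of the difference curve within the
band.

## Per-second cross-correlation

Both channels are filtered once over the whole period (avoiding per-window
filter transients), cut into non-overlapping 1-s windows aligned to the
period start, and the 'coeff'-normalized cross-correlation computed per
window over lags |ℓ| ≤ 0.5 s — at least two theta cycles on either side
while excluding the spurious edge peaks of 1-s windows. Positive lag means
the second channel lags the first. The peak is the maximum of r (not |r|);
exact ties resolve toward smaller |lag|, then the negative lag. Zero-energy
windows are skipped and counted. Period summaries are the arithmetic mean
and sample SD (n−1) of peaks and lags.

## Paradigm statistics

Measure tables are long-format (subject, region, period, measure, value),
one value per cell, no imputation. Paired t contrasts use pre-declared
one-sided directions (habituation Enc1 > Enc4; dishabituation Enc5 > Enc4)
and Bonferroni correction `min(1, p·m)` with the family size m explicit
(default: the 2 planned contrasts within a region). A zero-variance
difference is flagged as a degenerate boundary rather than silently
reported. The one-way repeated-measures ANOVA across encounters and the
2×2 within-subject experiment × band interaction are fitted through
statsmodels' AnovaRM (standard decomposition,
`F = MS_factor / MS_(factor×subject)`), with an explicit zero-variance
guard (F = 0, p = 1) where the fit would be 0/0. No sphericity correction
is applied by default; Greenhouse–Geisser is an option on the one-way test.
Normality screening (Shapiro–Wilk) is reported, never gate-keeping.

## The generative model

Each region is a linear mixture of a few theta sources plus independent
pink noise:

    x_r(t) = Σ_s w_rs · A_s(t) · cos(2π f_s t + φ_s(t − d_rs)) + n_r(t)

- **Sources** are phase-diffusion oscillators: φ follows a Brownian walk
  with rate D (rad²/s), giving a Lorentzian line of HWHM `D/(4π)` Hz
  around f_s. A phase-diffusion oscillator (rather than filtered noise) was
  chosen because the linewidth is a single controllable parameter with a
  closed-form spectrum. Default D = 5 rad²/s (HWHM ≈ 0.4 Hz) — a narrow
  peak of the kind seen in strongly entrained rhythms.
- **Topology**: a "bulb" source feeds MOB (weight 1.0) and AOB (0.9); an
  independent "limbic" source feeds MeA (1.0), LS (0.9), Pir (0.7), NAcc
  (0.5) — two independent theta generators, matching the observed
  dissociation between olfactory-bulb and limbic coherence clusters.
  Fear-recall sessions add a network-wide low-theta source (5 Hz,
  weight 1.0 everywhere). Additional sources and per-region source delays
  (conduction delays, integer samples) are configurable.
- **Noise**: Gaussian background with one-sided density
  `level²/max(f,1)^α` µV²/Hz (α = 1 default), synthesized in the frequency
  domain; `level` is the amplitude density at 1 Hz (default 1 µV/√Hz).
- **Envelopes**: per-period target multipliers; stimulus-onset periods ramp
  linearly over 15 s (the observed rise time of theta power while a
  stimulus is transferred into the arena); post-stimulus periods relax
  exponentially toward baseline with τ = 60 s. No quantitative persistence
  constant is reported for the real data ("slowly fades"), so τ is a free
  parameter with a default on the scale of the 5-min periods. Social
  sessions modulate both generators by novelty (bulb gain 1.05, limbic
  0.7 → ΔTP(Enc1) ≈ 6.2 and ≈ 4.6 dB respectively, the magnitudes of the
  in-vivo effects) with Post persistence; object sessions modulate only the
  bulb source weakly (gain 0.3 → ≈ 2.3 dB) with no persistence. The
  novelty sequence is (1.0, 0.8, 0.65, 0.5, 1.0): habituation across
  Enc1–4, dishabituation rebound at Enc5. Source amplitude default is 5 µV
  so the theta line sits well above the 1/f floor at 8 Hz.
- **Determinism**: every stream (each source's phase walk, each region's
  noise) is keyed by `(seed, crc32(name))`, so regenerating with the same
  config and seed is bit-identical and adding a region never perturbs the
  others.
- **Timelines**: SRM sessions are Base (300 s) then five trials of
  Transfer (15 s) + Enc (300 s) + Post (300 s), with a "Stimulus" period
  marking the first 15 s of Enc1; the 15-min inter-trial breaks are not
  rendered (the timeline records contiguous analysis periods only).
  Fear-recall sessions are Base (300 s) then five 40-s tones at 180-s
  intervals (tone onsets at 300, 520, 740, … s), each tone's first 15 s
  being its Stimulus window. Optional investigation-time annotations
  proportional to novelty are written to session metadata.

**Analytic oracles.** Because mixing is linear and noise independent,
expected spectra and coherence are closed-form: the expected Welch peak is
the Lorentzian convolved with the taper's spectral window (computed
numerically from the expectation formula — valid from window-limited to
line-limited regimes); the expected multitaper coherence at a line center
uses the band-averaged source density over the taper bandwidth
(`fraction (2/π)·atan(2πW/a)` of the line's power spread over 2W) in
`|Σ w_i w_j S_s| / sqrt((Σ w_i² S_s + N_i)(Σ w_j² S_s + N_j))`. Both are
stored in a GroundTruth sidecar per session.

## The fear-vs-social comparison cohort

The paired-cohort configuration makes two deliberate choices beyond the
defaults. First, the social arm places its rhythm at 10.5 Hz — the upper
part of the high-theta (8–12 Hz) range, as during high-arousal sniffing —
and the amplitude ramp runs during the 15-s transfer (arousal rises in
anticipation of the encounter), so the 15-s Stimulus window sees the full
plateau. Second, both arms use weak resting sources (1.2 µV): at 15-s
analysis windows the taper bandwidth is ±3 Hz and a Lorentzian line has
power-law tails, so with very strong sources the off-band leakage tracks
the source change and the low/high bands would no longer dissociate
cleanly; with 1.2 µV sources the off-band tails sit below the 1/f floor.
These are properties of any finite-bandwidth analysis of strong narrow
lines, not of the estimators here. Fear tones multiply the 5-Hz source
amplitude by 5 with a 2-s ramp (fear onset is fast).

Between-animal variability enters as a per-subject multiplicative
effect-size factor, Normal(1, 0.15) truncated at 0.2.

## Problem sizes used in tests and the acceptance script

Estimator-vs-oracle identities use 10-s, 1-kHz signals. Recovery and
calibration runs use 500-Hz sessions with two or three regions:
300-s periods for single-session quantities (ΔTP step, habituation
monotonicity across 100 seeds, onset/decay fits), 60-s baselines with
single encounters for the many-seed cohort runs (100 interaction cohorts of
6 subjects × 2 paradigms), and table-level simulation for the 1000-seed
null calibrations. These sizes give estimator standard errors comfortably
inside the asserted tolerances (e.g. ≈ 0.05 dB on a 300-s TP estimate
against a ±0.5 dB assertion).

## What passing tests do and do not show

The simulator emulates narrow-band rhythms with state-dependent amplitudes,
shared sources, conduction delays and 1/f background. It does not emulate
movement/chewing artifacts, volume conduction with frequency-dependent
phase, nonstationary noise floors, electrode drift, cross-frequency
coupling, or behavioral covariates (locomotion, investigation time is an
annotation only). Parameter recovery therefore validates the estimators and
the statistical pipeline under the stated model, not robustness of
scientific conclusions to real-recording artifacts. Known limitations:
no artifact rejection or re-referencing; no 1/f-vs-oscillation parametric
separation; coherence reported without confidence intervals; per-second
lags have sample resolution (no sub-sample interpolation).
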