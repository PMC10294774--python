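# Methods

## Overview

`freqtag` is a tested re-implementation of the frequency-tagging analysis
used to study cortical tracking of hierarchical linguistic structure in
first- (L1) and second-language (L2) listeners. Because no raw EEG from such
experiments is consumed here, the package pairs the analysis chain with two
generative modules whose ground truth is known exactly: an isochronous
stimulus synthesizer and a phase-locked EEG cohort simulator. Every
statistic the analysis produces can therefore be validated against closed
forms or known simulation parameters.

## Stimulus model

Sentences are four syllables: a two-syllable noun phrase followed by a
two-syllable verb phrase. With every syllable fixed at 250 ms, a sequence of
10 distinct sentences lasts 10 s and tags syllables at 4 Hz, phrases at
2 Hz, and sentences at 1 Hz. The defaults — a 60-sentence pool, 48 sequences
of 10 sentences, 22.05 kHz audio, a 25-ms cosine-squared falling ramp ending
each syllable — are the stimulus-design constants of the paradigm.

Syllables are schematic voiced bursts, not speech: a harmonic complex
(fundamental drawn from 100–200 Hz, eight harmonics with a token-dependent
rolloff and phase pattern), deterministic per token. Three synthesis choices
matter for the intensity spectrum, the one acoustic property the paradigm
depends on:

- **Intra-syllable intensity flattening.** The local RMS trajectory of each
  burst is divided out (5-ms smoothing window) before the ramps are applied.
  Without this, harmonic beating gives every token a signature envelope
  shape; since the same 60 sentences are reused across all sequences, those
  signatures add *coherently* at integer-Hz bins (slot positions repeat with
  period 1 s) and produce a spurious, pool-dependent 1-Hz intensity
  component. Real synthesized-speech stimuli do not carry such a cue, and
  flattening removes it at the source.
- **Level equalization.** All syllables share a common RMS (0.15 full
  scale), as synthesizer output does; token-tied loudness would leak
  sentence identity into the spectrum the same way.
- **Occurrence-level variability.** A per-slot lognormal gain
  (sigma = 0.1, about 1 dB) models natural utterance-to-utterance level
  variation. Because it is drawn per slot rather than per token it is
  incoherent across sequences and leaves the neighbor-bin test calibrated.

The intensity envelope is the RMS in non-overlapping 10-ms frames (100-Hz
envelope rate — enough to resolve 0.5–4.5 Hz); the reported spectrum is the
amplitude spectrum of the mean-removed envelope, averaged across sequences,
on the 0.1-Hz grid set by the 10-s duration. The envelope extractor and the
use of amplitude rather than power are this package's choices; nothing
downstream is sensitive to them. Sample counts round half-to-even
(`round(duration * fs)`); syllable onsets are defined on the exact 250-ms
grid and placed at the nearest sample.

## Cohort model

Each simulated trial of a subject x condition block is

    x_c(t) = g_c * sum_f A_f cos(2 pi f t + theta_{f,trial}) + n_c(t),  t >= 0,

on a −1..10 s epoch at 250 Hz (the recording rate of such experiments is
higher, but decimation is irrelevant below 5 Hz; the rate is configurable).
Trial phases theta are von Mises with concentration kappa, drawn once per
trial per frequency and shared across channels; kappa fixes the population
intertrial phase coherence through R = I1(kappa)/I0(kappa), which is the
analytic oracle for parameter-recovery tests. Channel gains g_c are fixed
multiplicative heterogeneity (sd 0.2); noise is Gaussian 1/f^alpha
(alpha = 1) with a 10% white floor, synthesized in the frequency domain with
an analytic variance normalization, at sd = 1 against component amplitudes
of 0.3–0.6 (single-trial SNR well below 1, while the 0.1-Hz-bin SNR after a
10-s FFT is high, as in steady-state designs).

The design table is **synthetic**: concentrations are calibrated only to
reproduce the qualitative group x condition significance pattern, not any
reported effect size —

| cell | 1 Hz | 2 Hz | 3 Hz | 4 Hz |
|---|---|---|---|---|
| L1 active | 0.8 | 1.0 | 0.6 | 2.0 |
| L1 passive | 0.6 | 0.8 | 0.35 | 1.8 |
| L2 active | 0 | coupled | 0 | 1.8 |
| L2 passive | 0 | 0 | 0 | 1.6 |

The L2 active 2-Hz cell is coupled to a 0–30 proficiency score,
kappa = max(0, 0.1 + 0.035 * proficiency), so the proficiency–tracking
correlation is recoverable by design; the passive 2-Hz cell stays at zero so
that attention gates phrase tracking in L2, matching the qualitative target
pattern. Proficiency is truncated normal on [0, 30] with mean 20.2 and
sd 5.9 (the reported score distribution). A per-subject lognormal scale
(sigma 0.15) on all concentrations and a random per-component subject phase
add between-subject variability without changing population orderings.
Cohorts default to 24 subjects per group, two conditions, 48 trials each;
5 of 24 L2 subjects are labelled left-handed (scaled for other sizes) —
handedness is a pure covariate, the simulator builds in no hemispheric
asymmetry, so lateralization analyses are null by construction.

Seeding: one master seed; `numpy` seed-sequence spawning derives the profile
stream and one stream per subject x condition, so any subset of a cohort is
reproducible independently.

## Analysis chain

1. **Baseline correction**: per trial and channel, subtract the mean of the
   pre-onset interval (default the full −1..0 s; configurable).
2. **FFT**: rectangular-window transform of the 0–10 s post-onset segment.
   The 10-s window gives exactly the 0.1-Hz grid that places every tagged
   rate on a bin; no taper is wanted because the rhythms are exactly
   periodic in the window. The phase convention is the phase of a cosine at
   segment start. The DC bin is excluded (no phase). Whether the original
   analysis transformed 0–10 s or −1–10 s is not stated; 0–10 s is required
   for the 0.1-Hz resolution and is used.
3. **ITPC**: per channel and bin, the mean resultant length of the n trial
   phases, `|mean_r exp(i phi_r)|`. Coefficients with magnitude below 1e-15
   raise rather than contribute arbitrary phase.
4. **Rayleigh Z**: `Z = n * ITPC^2`, the Rayleigh uniformity statistic —
   the standard reading of "Rayleigh's Z transformation" (the small-sample
   corrected variant can be swapped via configuration). At an unlocked bin Z
   is approximately Exp(1) for any n, which makes spectra comparable across
   trial counts; the average of Z over the 62 analysis channels is the
   whole-head tracking measure.
5. **Peak statistics**: the tagged-bin Z is compared with the average of its
   four neighboring bins (two per side, no interpolation, 1e-6-Hz bin
   matching) by a one-tailed paired t across subjects (tagged > neighbors,
   never auto-flipped), Bonferroni-corrected with family size m = 4 (1, 2,
   4 Hz plus the 3-Hz harmonic; the original family size is not stated and
   m is configurable). Zero-variance differences are reported
   deterministically (t = ±inf, p = 0 or 1, flagged) so degenerate synthetic
   fixtures behave predictably.
6. **Derived measures**: attentional gain
   (active − passive)/(active + passive) on the tagged-bin Z; hemispheric
   lateralization as right-minus-left neighbor-corrected peak response with
   hemispheres split by the 10-20 label rule (odd digit left, even right,
   Z-suffix midline — the exact split used originally is not listed);
   Pearson correlation (two-tailed, t transform) between L2 proficiency and
   tagged-bin Z; behavioral independent-sample t (pooled by default, Welch
   by flag) and one-sample t against a scale midpoint.

Mixed ANOVAs with sphericity corrections are deliberately out of scope; the
pipeline exports a tidy long-format table (subject, group, condition,
frequency, Z) for use in any standard statistics environment.

## Montage

The 64-channel quick-cap label set minus the two non-scalp cheek electrodes
(CB1, CB2) gives the 62 analysis channels. Epochs are stored in HDF5 as
`/subjects/<id>/<condition>/data` (trials x channels x samples) with fs,
window and channel labels as attributes.

## Numerical and engineering choices

- Epoch arrays are float32 (a default cohort is ~3 GiB; the pipeline
  streams subjects through the spectral stage and never materializes a full
  cohort). All coherence arithmetic after the FFT is float64.
- The 1/f noise generator draws the half-spectrum directly and scales by the
  analytically computed output variance; a unit test checks the realized sd.
- The 0.2–60 Hz bandpass and 50-Hz notch used on real recordings are
  omitted: synthetic data contain no line noise, and the analysis band is
  0.5–4.5 Hz.
- Pipeline reports contain no timing or environment information, so a rerun
  with the same configuration and seed is bit-identical.

## What the synthetic cohort does and does not show

Passing tests demonstrate that the analysis chain is correct (exact oracles,
null calibration, parameter recovery), that its error rates are nominal
under the phase-level null, and that the pipeline recovers the qualitative
pattern and correlations that were built into the generator. They do not
validate the neurophysiological claims themselves: the simulator has no
dipole geometry, no topography (channel differences are pure gain), no
artifacts, and its concentration table was chosen to produce the target
pattern, not fitted to data. Group-level t statistics from real recordings
are not reproducible and are not targets.

## Problem sizes used in the test suite

Unit tests run on minimal fixtures. The heavier scientific checks use: 48
sequences for the stimulus spectrum (10 extra 16-sequence sets for
calibration), 100 replicates x 4 concentrations for parameter recovery,
10 000 bins for null calibration, 2000 phase-level replicates for the
type-I rate (the peak statistic depends on the data only through Fourier
phases, so trial phases are simulated directly at the cohort's
62-channel/24-subject/48-trial geometry), 20 full default cohorts for the
significance pattern, and 50 replicates of 24 L2 subjects for correlation
recovery.
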