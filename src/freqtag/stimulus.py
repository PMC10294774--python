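"""Isochronous four-syllable sentence stimuli and their intensity spectra.

The stimulus design places linguistic structure at fixed repetition rates:
each sentence is a noun phrase followed by a verb phrase, each phrase two
syllables, every syllable exactly 250 ms.  A ten-sentence sequence therefore
tags syllables at 4 Hz, phrases at 2 Hz and sentences at 1 Hz, while only the
syllabic rate is physically present in the acoustics (verified here through
the RMS intensity spectrum of generated sequences).

Syllables are rendered as seeded harmonic-complex bursts (fundamental
100-200 Hz with a token-dependent spectral shape and peak level) rather than
synthesized speech: only the periodicity of the intensity envelope matters
downstream, not intelligibility.  Every syllable ends in a 25-ms
cosine-squared falling ramp, so the envelope dips once per syllable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import (
    InconsistentInputError,
    InsufficientPoolError,
    InvalidParameterError,
)

DEFAULT_FS_AUDIO = 22050.0
DEFAULT_SYLLABLE_DUR = 0.250
RAMP_DUR = 0.025
_ONSET_RAMP_DUR = 0.005  # short attack to avoid onset clicks
_TARGET_RMS = 0.15  # common syllable level (level-equalized stimuli)
_SLOT_LEVEL_SD = 0.1  # lognormal sigma of per-occurrence level jitter (~1 dB)

_ONSETS = ["b", "p", "m", "f", "d", "t", "n", "l", "g", "k", "h",
           "j", "q", "x", "zh", "ch", "sh", "r", "z", "c", "s", "w", "y"]
_FINALS = ["a", "o", "e", "i", "u", "ai", "ei", "ao", "ou", "an",
           "en", "ang", "eng", "ong", "ia", "ie", "iu", "uan", "uo", "un"]


def _round_samples(x: float) -> int:
    # round-half-to-even, the documented sample-count rounding rule
    return int(np.round(x))


@dataclass(frozen=True)
class SentenceSpec:
    """A four-syllable sentence: two-syllable noun phrase + verb phrase."""

    noun_phrase: tuple[str, str]
    verb_phrase: tuple[str, str]
    id: int

    def __post_init__(self) -> None:
        if len(self.noun_phrase) != 2 or len(self.verb_phrase) != 2:
            raise InvalidParameterError(
                "a sentence is two NP syllables followed by two VP syllables"
            )

    @property
    def syllables(self) -> tuple[str, str, str, str]:
        return (*self.noun_phrase, *self.verb_phrase)


@dataclass(frozen=True)
class SpeechSequence:
    """One isochronous sequence of four-syllable sentences.

    ``boundaries`` holds the nominal syllable onset times (an exact
    arithmetic grid with step ``syllable_dur``); sample placement rounds each
    onset to the nearest audio sample.
    """

    samples: np.ndarray
    fs_audio: float
    sentence_ids: tuple[int, ...]
    syllable_dur: float
    boundaries: np.ndarray
    tokens: tuple[str, ...] = field(default=())

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs_audio

    @property
    def syllable_rate(self) -> float:
        return 1.0 / self.syllable_dur

    @property
    def phrase_rate(self) -> float:
        return 1.0 / (2.0 * self.syllable_dur)

    @property
    def sentence_rate(self) -> float:
        return 1.0 / (4.0 * self.syllable_dur)


@dataclass(frozen=True)
class IntensitySpectrum:
    """Mean amplitude spectrum of the RMS intensity envelope across sequences."""

    freqs: np.ndarray
    amplitude: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise InvalidParameterError("frequency grid must be strictly increasing")
        if np.any(self.amplitude < 0):
            raise InvalidParameterError("spectral amplitude must be non-negative")


def make_sentence_pool(n_sentences: int = 60, seed: int = 0) -> list[SentenceSpec]:
    """Build a pool of synthetic four-syllable sentences.

    Tokens are pinyin-like syllable strings (onset + final + tone digit);
    they carry no lexical content, only a stable identity that fixes each
    syllable's rendered waveform.
    """
    rng = np.random.default_rng(seed)

    def token() -> str:
        return (
            _ONSETS[rng.integers(len(_ONSETS))]
            + _FINALS[rng.integers(len(_FINALS))]
            + str(rng.integers(1, 5))
        )

    return [
        SentenceSpec(noun_phrase=(token(), token()),
                     verb_phrase=(token(), token()), id=i)
        for i in range(n_sentences)
    ]


def token_seed(token: str) -> int:
    """Stable non-negative seed for a syllable token (CRC32 of its text)."""
    return zlib.crc32(token.encode("utf-8")) & 0x7FFFFFFF


def _render_syllable(n_samples: int, fs_audio: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    f0 = rng.uniform(100.0, 200.0)
    n_harm = 8
    rolloff = rng.uniform(0.5, 1.5)
    amps = rng.uniform(0.2, 1.0, n_harm) / np.arange(1, n_harm + 1) ** rolloff
    phases = rng.uniform(0.0, 2.0 * np.pi, n_harm)

    t = np.arange(n_samples) / fs_audio
    wave = np.zeros(n_samples)
    for h in range(n_harm):
        wave += amps[h] * np.cos(2.0 * np.pi * f0 * (h + 1) * t + phases[h])

    n_on = min(_round_samples(_ONSET_RAMP_DUR * fs_audio), n_samples)
    if n_on > 1:
        wave[:n_on] *= np.sin(0.5 * np.pi * np.linspace(0.0, 1.0, n_on)) ** 2
    n_off = min(_round_samples(RAMP_DUR * fs_audio), n_samples)
    if n_off > 1:
        x = np.linspace(0.0, 1.0, n_off)
        # 0.5*(1+cos(pi)) is exactly 0 in IEEE arithmetic: the ramp ends at 0
        wave[-n_off:] *= 0.5 * (1.0 + np.cos(np.pi * x))

    # flatten the intra-syllable intensity trajectory (harmonic beating would
    # otherwise give each token a signature envelope, and the reused sentence
    # pool would imprint that signature coherently on the integer-Hz bins of
    # every sequence); level and ramps stay, spectral identity stays
    local_rms = np.sqrt(uniform_filter1d(wave**2, size=max(3, n_on), mode="nearest"))
    body = slice(n_on, n_samples - n_off)
    wave[body] /= np.maximum(local_rms[body], 0.05 * local_rms.max() + 1e-12)

    # level-equalized to a common RMS, as synthesized speech stimuli are
    rms = np.sqrt(np.mean(wave**2))
    if rms > 0:
        wave *= _TARGET_RMS / rms
    peak = np.max(np.abs(wave))
    if peak > 0.98:
        wave *= 0.98 / peak
    return wave


def synth_syllable(duration_s: float, fs_audio: float, token_seed: int) -> np.ndarray:
    """Render one schematic voiced syllable.

    Returns exactly ``round(duration_s * fs_audio)`` samples (half-to-even
    rounding), ending in a 25-ms cosine-squared falling ramp whose last
    sample is exactly zero.  Identical seeds give identical waveforms.
    """
    if duration_s <= RAMP_DUR:
        raise InvalidParameterError(
            f"syllable duration must exceed the {RAMP_DUR*1e3:.0f}-ms falling ramp"
        )
    if fs_audio < 8000:
        raise InvalidParameterError("audio sampling rate must be >= 8000 Hz")
    n = _round_samples(duration_s * fs_audio)
    return _render_syllable(n, fs_audio, token_seed)


def build_sequence(
    pool: list[SentenceSpec],
    n_sentences: int = 10,
    syllable_dur: float = DEFAULT_SYLLABLE_DUR,
    fs_audio: float = DEFAULT_FS_AUDIO,
    seed: int = 0,
) -> SpeechSequence:
    """Concatenate ``n_sentences`` distinct sentences into one isochronous sequence.

    Sentences are drawn without replacement from ``pool``; every syllable is
    rendered by :func:`synth_syllable` with a seed derived from its token, so
    a given token sounds identical wherever it occurs.  Syllable slots are
    placed on the exact 1/``syllable_dur`` grid, rounded per-onset to the
    nearest sample, so the total sample count equals
    ``round(4 * n_sentences * syllable_dur * fs_audio)``.
    """
    if len(pool) < n_sentences:
        raise InsufficientPoolError(
            f"pool has {len(pool)} sentences, need {n_sentences}"
        )
    ids = [s.id for s in pool]
    if len(set(ids)) != len(ids):
        raise InvalidParameterError("sentence ids in the pool must be unique")
    if syllable_dur <= RAMP_DUR or fs_audio < 8000:
        raise InvalidParameterError("invalid syllable duration or sampling rate")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_sentences, replace=False)
    sentences = [pool[i] for i in chosen]
    tokens: list[str] = []
    for s in sentences:
        tokens.extend(s.syllables)

    n_syll = 4 * n_sentences
    starts = [_round_samples(k * syllable_dur * fs_audio) for k in range(n_syll + 1)]
    samples = np.zeros(starts[-1])
    # natural utterance-to-utterance level variability (~1 dB) is drawn per
    # slot, not per token: each occurrence of a syllable varies slightly
    slot_gain = np.exp(_SLOT_LEVEL_SD * rng.standard_normal(n_syll))
    for k, tok in enumerate(tokens):
        n_k = starts[k + 1] - starts[k]
        samples[starts[k]:starts[k + 1]] = slot_gain[k] * _render_syllable(
            n_k, fs_audio, token_seed(tok)
        )

    return SpeechSequence(
        samples=samples,
        fs_audio=fs_audio,
        sentence_ids=tuple(s.id for s in sentences),
        syllable_dur=syllable_dur,
        boundaries=np.arange(n_syll) * syllable_dur,
        tokens=tuple(tokens),
    )


def intensity_series(seq: SpeechSequence, frame_s: float = 0.010) -> np.ndarray:
    """RMS intensity in non-overlapping frames of ``frame_s`` seconds.

    ``frame_s`` must divide the sequence duration to an integer number of
    frames within one audio sample; frame edges are rounded to the nearest
    sample.
    """
    dur = seq.duration
    if frame_s <= 0 or frame_s > dur:
        raise InvalidParameterError("frame length must be positive and <= duration")
    n_frames = int(round(dur / frame_s))
    if abs(dur - n_frames * frame_s) * seq.fs_audio > 1.0:
        raise InvalidParameterError(
            "frame length must divide the sequence duration (within one sample)"
        )
    edges = np.round(np.arange(n_frames + 1) * frame_s * seq.fs_audio).astype(int)
    edges[-1] = len(seq.samples)
    out = np.empty(n_frames)
    for i in range(n_frames):
        frame = seq.samples[edges[i]:edges[i + 1]]
        out[i] = np.sqrt(np.mean(frame**2))
    return out


def intensity_spectrum_matrix(
    seqs: list[SpeechSequence], frame_s: float = 0.010
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sequence amplitude spectra of the mean-removed intensity envelope.

    Returns ``(freqs, amp)`` with ``amp`` of shape (n_sequences, n_bins) and
    a grid step of ``1 / duration`` (0.1 Hz for the default 10-s sequences).
    """
    if len(seqs) < 2:
        raise InvalidParameterError("need at least two sequences")
    durations = np.array([s.duration for s in seqs])
    fs = seqs[0].fs_audio
    if np.any(np.abs(durations - durations[0]) * fs > 1.0):
        raise InconsistentInputError("sequences must all have the same duration")

    rows = []
    for s in seqs:
        env = intensity_series(s, frame_s)
        env = env - env.mean()
        rows.append(np.abs(np.fft.rfft(env)) * 2.0 / len(env))
    amp = np.vstack(rows)
    freqs = np.arange(amp.shape[1]) / float(durations[0])
    return freqs, amp


def intensity_spectrum(
    seqs: list[SpeechSequence], frame_s: float = 0.010
) -> IntensitySpectrum:
    """Average the per-sequence envelope amplitude spectra over sequences."""
    freqs, amp = intensity_spectrum_matrix(seqs, frame_s)
    return IntensitySpectrum(freqs=freqs, amplitude=amp.mean(axis=0),
                             n_sequences=len(seqs))


def spectral_peak_bin(spec: IntensitySpectrum, lo: float, hi: float) -> float:
    """Frequency of the maximal amplitude bin in [lo, hi]; ties go to the lowest."""
    mask = (spec.freqs >= lo - 1e-9) & (spec.freqs <= hi + 1e-9)
    if not np.any(mask):
        raise InvalidParameterError(f"no spectral bins in [{lo}, {hi}] Hz")
    sub_f = spec.freqs[mask]
    sub_a = spec.amplitude[mask]
    return float(sub_f[int(np.argmax(sub_a))])
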