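"""Frequency-domain transform and intertrial phase coherence (ITPC).

The analysis follows the steady-state frequency-tagging recipe: baseline
correction against the pre-onset interval, a rectangular-window FFT of the
10-s post-onset segment of every trial (grid step 1/10 s = 0.1 Hz, so the
tagged rates fall exactly on bins), and per-channel coherence of the trial
phases,

    ITPC(c, f) = | (1/n) sum_r exp(i * phi_{r,c,f}) |,

the mean resultant length of the n trial phase angles.  ITPC is normalized
to Rayleigh's Z, Z = n * ITPC^2, the Rayleigh uniformity test statistic,
whose null distribution at an unlocked bin is approximately exponential with
mean 1 regardless of trial count; the channel average of Z is the
whole-head tracking measure.

Phase convention: the phase at an exactly on-grid frequency f equals the
phase of a cosine at the start of the analysis segment, i.e. the FFT of
cos(2 pi f t + theta) over t in [0, T) has argument theta at bin f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .epochs import EpochArray
from .errors import (
    InsufficientTrialsError,
    InvalidWindowError,
    MissingBaselineError,
    OffGridError,
    UndefinedPhaseError,
)

#: magnitudes below this are treated as zero (phase undefined)
ZERO_MAG_TOL = 1e-15
#: bin-matching tolerance in Hz (no interpolation between bins)
BIN_TOL = 1e-6


@dataclass
class ComplexSpectrum:
    """Per-trial complex Fourier coefficients on a fixed frequency grid."""

    coeffs: np.ndarray  # trials x channels x bins, complex
    freqs: np.ndarray
    channel_labels: tuple[str, ...]

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    @property
    def delta_f(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @classmethod
    def from_phases(
        cls,
        phases: np.ndarray,
        freqs: np.ndarray | None = None,
        channel_labels: tuple[str, ...] | None = None,
    ) -> "ComplexSpectrum":
        """Build a unit-magnitude spectrum from a trials x channels x bins
        phase-angle array.

        Useful for phase-level simulation: the coherence statistics depend
        on the data only through these angles.
        """
        phases = np.asarray(phases)
        if phases.ndim != 3:
            raise InvalidWindowError("phases must be trials x channels x bins")
        if freqs is None:
            freqs = np.arange(phases.shape[2], dtype=float) * 0.1 + 0.1
        if channel_labels is None:
            channel_labels = tuple(f"CH{i + 1:02d}" for i in range(phases.shape[1]))
        return cls(coeffs=np.exp(1j * phases), freqs=np.asarray(freqs, dtype=float),
                   channel_labels=channel_labels)


@dataclass
class ITPCSpectrum:
    """Mean resultant length of trial phases, per channel and frequency bin."""

    values: np.ndarray  # channels x bins, in [0, 1]
    freqs: np.ndarray
    n_trials: int
    channel_labels: tuple[str, ...]


@dataclass
class ITPCzSpectrum:
    """Rayleigh-Z normalized coherence with its channel (whole-head) average."""

    values: np.ndarray  # channels x bins, >= 0
    freqs: np.ndarray
    n_trials: int
    channel_labels: tuple[str, ...]
    channel_mean: np.ndarray  # bins

    @property
    def delta_f(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def bin_index(self, f: float) -> int:
        idx = int(np.argmin(np.abs(self.freqs - f)))
        if abs(float(self.freqs[idx]) - f) > BIN_TOL:
            raise OffGridError(
                f"{f} Hz is not on the analysis grid (step {self.delta_f} Hz)"
            )
        return idx


def baseline_correct(
    epochs: EpochArray, interval: tuple[float, float] | None = None
) -> EpochArray:
    """Subtract each trial/channel's mean over the pre-onset interval.

    By default the baseline is the full pre-onset part of the epoch window
    (for the default -1..10 s epoch, the second before stimulus onset); an
    explicit pre-onset ``interval`` may be given instead.
    """
    t = epochs.times
    if interval is None:
        pre = t < 0.0
    else:
        b0, b1 = interval
        if b1 > 0.0 or b1 <= b0:
            raise MissingBaselineError("baseline interval must be pre-onset")
        pre = (t >= b0) & (t < b1)
    if not np.any(pre):
        raise MissingBaselineError("epoch window has no pre-onset samples")
    baseline = epochs.data[:, :, pre].mean(axis=2, keepdims=True)
    return EpochArray(
        data=epochs.data - baseline,
        fs=epochs.fs,
        window=epochs.window,
        channel_labels=epochs.channel_labels,
    )


def fft_phase(
    epochs: EpochArray,
    analysis_window: tuple[float, float] = (0.0, 10.0),
    fmax: float | None = None,
) -> ComplexSpectrum:
    """Rectangular-window FFT of each trial over the analysis segment.

    The grid step is 1 / (segment length); a 10-s segment gives exactly
    0.1 Hz.  No taper is applied: the stimulus rhythms are exactly periodic
    in the segment, so tagged components are bin-centered.  ``fmax``
    optionally truncates the returned grid (the transform itself is always
    full-band); the input dtype is preserved (float32 epochs give complex64
    coefficients).
    """
    w0, w1 = analysis_window
    e0, e1 = epochs.window
    half_sample = 0.5 / epochs.fs
    if w0 < e0 - half_sample or w1 > e1 + half_sample or w1 <= w0:
        raise InvalidWindowError(
            f"analysis window {analysis_window} not inside epoch window {epochs.window}"
        )
    i0 = int(round((w0 - e0) * epochs.fs))
    n_seg = int(round((w1 - w0) * epochs.fs))
    segment = np.ascontiguousarray(epochs.data[:, :, i0:i0 + n_seg])
    coeffs = sfft.rfft(segment, axis=2)
    # the DC coefficient is real and carries no phase: excluded from the grid,
    # which is built from the window length so the step is the exact float 1/T
    coeffs = coeffs[:, :, 1:]
    freqs = np.arange(1, coeffs.shape[2] + 1) / (w1 - w0)
    if fmax is not None:
        keep = int(np.searchsorted(freqs, fmax + BIN_TOL))
        coeffs = coeffs[:, :, :keep]
        freqs = freqs[:keep]
    return ComplexSpectrum(coeffs=coeffs, freqs=freqs,
                           channel_labels=epochs.channel_labels)


def compute_itpc(spec: ComplexSpectrum) -> ITPCSpectrum:
    """Mean resultant length of the per-trial Fourier phases.

    Coefficients are unit-normalized per trial, so only phase angles enter;
    a (near-)zero coefficient has no defined phase and raises.
    """
    if spec.n_trials < 2:
        raise InsufficientTrialsError("ITPC requires at least two trials")
    coeffs = np.asarray(spec.coeffs, dtype=np.complex128)
    mags = np.abs(coeffs)
    if np.any(mags < ZERO_MAG_TOL):
        raise UndefinedPhaseError(
            "zero-magnitude Fourier coefficient: phase undefined"
        )
    values = np.abs(np.mean(coeffs / mags, axis=0))
    return ITPCSpectrum(
        values=np.minimum(values, 1.0),
        freqs=spec.freqs,
        n_trials=spec.n_trials,
        channel_labels=spec.channel_labels,
    )


def rayleigh_z(itpc: ITPCSpectrum) -> ITPCzSpectrum:
    """Rayleigh's Z: Z = n * ITPC**2, with the channel (whole-head) average.

    This is the Rayleigh uniformity test statistic; a small-sample corrected
    variant exists (n * R^2 * (1 - 1/(2n))) but the plain form is the
    package default.
    """
    values = itpc.n_trials * itpc.values.astype(np.float64) ** 2
    return ITPCzSpectrum(
        values=values,
        freqs=itpc.freqs,
        n_trials=itpc.n_trials,
        channel_labels=itpc.channel_labels,
        channel_mean=values.mean(axis=0),
    )


def peak_value(spec: ITPCzSpectrum, f: float) -> float:
    """Channel-mean Z at the bin matching f (within 1e-6 Hz; no interpolation)."""
    return float(spec.channel_mean[spec.bin_index(f)])


def itpc_z_from_epochs(
    epochs: EpochArray,
    analysis_window: tuple[float, float] = (0.0, 10.0),
    baseline: bool = True,
) -> ITPCzSpectrum:
    """Full per-block chain: baseline -> FFT -> ITPC -> Rayleigh Z."""
    if baseline:
        epochs = baseline_correct(epochs)
    return rayleigh_z(compute_itpc(fft_phase(epochs, analysis_window)))
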