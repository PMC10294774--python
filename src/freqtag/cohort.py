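"""Synthetic EEG cohorts with known phase locking at tagged frequencies.

Each simulated trial is a sum of stimulus-locked sinusoids at the tagged
rates (1/2/4 Hz plus the 3-Hz harmonic) embedded in 1/f^alpha Gaussian
noise.  The trial-to-trial phase of each component is drawn from a von Mises
distribution with concentration kappa, shared across channels within a
trial; kappa therefore sets the population intertrial phase coherence
through the closed form I1(kappa)/I0(kappa), which makes parameter recovery
directly testable.

Group/condition structure mirrors a two-group (native L1, second-language
L2) by two-condition (active/passive listening) design with 48 trials per
condition, 62 analysis channels and -1..10 s epochs.  The default
concentration table is synthetic: it is calibrated only to reproduce the
qualitative significance pattern (L1 tracks 1/2/4 Hz in both conditions; L2
tracks 4 Hz in both but 2 Hz only when attending, and never 1 Hz), with the
L2 2-Hz concentration in active listening coupled linearly to a 0-30
proficiency score so that the proficiency-tracking correlation is
recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import special, stats

from .epochs import EpochArray
from .errors import InsufficientTrialsError, InvalidParameterError
from .montage import analysis_montage

#: sentinel for a concentration resolved from the proficiency coupling
PROFICIENCY_COUPLED = "proficiency"

_WHITE_FLOOR = 0.1  # white fraction mixed into the 1/f^alpha noise PSD


@dataclass(frozen=True)
class PhaseLockSpec:
    """One phase-locked sinusoidal component.

    ``kappa`` is the von Mises concentration of the trial phases around
    ``mean_phase``; ``locked=True`` (or ``kappa=inf``) means every trial has
    exactly the mean phase.
    """

    freq: float
    amplitude: float
    mean_phase: float = 0.0
    kappa: float = 0.0
    locked: bool = False

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise InvalidParameterError("component frequency must be positive")
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be non-negative")
        if not math.isinf(self.kappa) and self.kappa < 0:
            raise InvalidParameterError("kappa must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian 1/f^exponent background noise with channel gain heterogeneity."""

    exponent: float = 1.0
    sd: float = 1.0
    channel_gain_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.sd < 0 or self.channel_gain_sd < 0:
            raise InvalidParameterError("noise sd parameters must be >= 0")


@dataclass(frozen=True)
class SubjectProfile:
    """Group membership and covariates of one simulated subject."""

    subject_id: str
    group: str  # "L1" or "L2"
    proficiency: float | None  # 0-30 cloze score, L2 only
    handedness: str  # "left" or "right"
    montage: tuple[str, ...] = field(default_factory=analysis_montage)

    def __post_init__(self) -> None:
        if self.group not in ("L1", "L2"):
            raise InvalidParameterError("group must be 'L1' or 'L2'")
        if (self.proficiency is None) != (self.group == "L1"):
            raise InvalidParameterError("proficiency present iff group is L2")
        if self.proficiency is not None and not (0.0 <= self.proficiency <= 30.0):
            raise InvalidParameterError("proficiency must lie in [0, 30]")


def _default_kappa_table() -> dict:
    return {
        ("L1", "active"): {1.0: 0.8, 2.0: 1.0, 3.0: 0.6, 4.0: 2.0},
        ("L1", "passive"): {1.0: 0.6, 2.0: 0.8, 3.0: 0.35, 4.0: 1.8},
        ("L2", "active"): {1.0: 0.0, 2.0: PROFICIENCY_COUPLED, 3.0: 0.0, 4.0: 1.8},
        ("L2", "passive"): {1.0: 0.0, 2.0: 0.0, 3.0: 0.0, 4.0: 1.6},
    }


def _default_amplitude_table() -> dict:
    # amplitudes fall with frequency, echoing the 1/f shape of evoked spectra
    return {1.0: 0.6, 2.0: 0.55, 3.0: 0.3, 4.0: 0.5}


@dataclass(frozen=True)
class CohortDesign:
    """Cohort-level simulation parameters (all concentrations are synthetic)."""

    n_per_group: int = 24
    n_trials: int = 48
    conditions: tuple[str, ...] = ("active", "passive")
    kappa_table: dict = field(default_factory=_default_kappa_table)
    amplitude_table: dict = field(default_factory=_default_amplitude_table)
    proficiency_coupling: tuple[float, float] = (0.1, 0.035)  # (g0, g1)
    kappa_subject_sd: float = 0.15  # lognormal sigma of a per-subject kappa scale
    proficiency_mean: float = 20.2
    proficiency_sd: float = 5.9
    n_left_handed_l2: int = 5
    window: tuple[float, float] = (-1.0, 10.0)
    fs_eeg: float = 250.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise InvalidParameterError("need at least two subjects per group")
        if self.n_trials < 2:
            raise InsufficientTrialsError("need at least two trials per condition")
        for cell, table in self.kappa_table.items():
            for f, k in table.items():
                if k == PROFICIENCY_COUPLED:
                    continue
                if not math.isinf(k) and k < 0:
                    raise InvalidParameterError(f"kappa < 0 in cell {cell} at {f} Hz")


def expected_itpc(kappa: float) -> float:
    """Population mean resultant length of a von Mises sample: I1(k)/I0(k).

    Monotone increasing from 0 (uniform phases) to 1 (perfect locking);
    evaluated with exponentially scaled Bessel functions so large kappa does
    not overflow.
    """
    if math.isinf(kappa):
        return 1.0
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def _one_over_f_noise(
    rng: np.random.Generator,
    lead_shape: tuple[int, ...],
    n_samples: int,
    fs: float,
    exponent: float,
    sd: float,
    dtype=np.float32,
) -> np.ndarray:
    """1/f^exponent Gaussian noise with a white floor, exact target variance.

    Synthesized in the frequency domain: complex Gaussian coefficients with
    amplitude profile sqrt((1 - w) * f^-a / norm + w), zero DC, scaled so
    the analytic time-domain variance equals sd**2.
    """
    m = n_samples // 2 + 1
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    psd = np.zeros(m)
    psd[1:] = f[1:] ** (-exponent)
    psd[1:] /= psd[1:].mean()
    psd[1:] = (1.0 - _WHITE_FLOOR) * psd[1:] + _WHITE_FLOOR
    amp = np.sqrt(psd).astype(dtype)

    re = rng.standard_normal(lead_shape + (m,), dtype=dtype)
    im = rng.standard_normal(lead_shape + (m,), dtype=dtype)
    ctype = np.complex64 if dtype == np.float32 else np.complex128
    spec = np.empty(lead_shape + (m,), dtype=ctype)
    np.multiply(re, amp, out=spec.real)
    np.multiply(im, amp, out=spec.imag)
    spec[..., 0] = 0.0
    nyq_var = 0.0
    if n_samples % 2 == 0:
        # Nyquist coefficient must be real; give it matching variance
        spec[..., -1] = re[..., -1] * (amp[-1] * np.sqrt(2.0))
        nyq_var = 2.0 * float(amp[-1]) ** 2
        interior = amp[1:-1]
    else:
        interior = amp[1:]
    var_analytic = (4.0 * float(np.sum(interior.astype(np.float64) ** 2)) + nyq_var) / n_samples**2
    x = sfft.irfft(spec, n=n_samples, axis=-1)
    x *= dtype(sd / np.sqrt(var_analytic))
    return x


def simulate_epochs(
    specs: list[PhaseLockSpec],
    noise: NoiseModel,
    n_trials: int,
    n_channels: int,
    fs_eeg: float,
    window: tuple[float, float] = (-1.0, 10.0),
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    channel_labels: tuple[str, ...] | None = None,
    dtype=np.float32,
) -> EpochArray:
    """Simulate one trials x channels x samples epoch block.

    Each trial is ``gain_c * sum_f A_f cos(2 pi f tau + theta_{f, trial})``
    for tau >= 0 (components start at stimulus onset) plus 1/f noise.  Trial
    phases are drawn once per trial per component and shared across
    channels; channel gains are a fixed multiplicative heterogeneity.
    """
    if n_trials < 2:
        raise InsufficientTrialsError("need at least two trials")
    if not specs:
        raise InvalidParameterError("need at least one phase-locked component")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    start, end = window
    n_samples = int(round((end - start) * fs_eeg))
    t = start + np.arange(n_samples) / fs_eeg
    onset_mask = (t >= 0.0).astype(np.float64)

    base = np.zeros((n_trials, n_samples))
    for spec in specs:
        if spec.locked or math.isinf(spec.kappa):
            theta = np.full(n_trials, spec.mean_phase)
        elif spec.kappa == 0:
            theta = rng.uniform(-np.pi, np.pi, n_trials)
        else:
            theta = rng.vonmises(spec.mean_phase, spec.kappa, n_trials)
        base += spec.amplitude * np.cos(
            2.0 * np.pi * spec.freq * t[None, :] + theta[:, None]
        ) * onset_mask[None, :]

    gains = 1.0 + noise.channel_gain_sd * rng.standard_normal(n_channels)
    gains = np.clip(gains, 0.1, None).astype(dtype)

    data = gains[None, :, None] * base.astype(dtype)[:, None, :]
    if noise.sd > 0:
        data += _one_over_f_noise(
            rng, (n_trials, n_channels), n_samples, fs_eeg,
            noise.exponent, noise.sd, dtype=dtype,
        )

    if channel_labels is None:
        channel_labels = tuple(f"CH{i + 1:02d}" for i in range(n_channels))
    return EpochArray(data=data, fs=fs_eeg, window=window,
                      channel_labels=channel_labels)


def resolve_kappa(
    design: CohortDesign, group: str, condition: str, freq: float,
    proficiency: float | None,
) -> float:
    """Baseline concentration for a design cell, applying the proficiency coupling."""
    try:
        entry = design.kappa_table[(group, condition)][freq]
    except KeyError as exc:
        raise InvalidParameterError(
            f"no kappa entry for ({group}, {condition}) at {freq} Hz"
        ) from exc
    if entry == PROFICIENCY_COUPLED:
        if proficiency is None:
            raise InvalidParameterError(
                "proficiency-coupled kappa requires a proficiency score"
            )
        g0, g1 = design.proficiency_coupling
        return max(0.0, g0 + g1 * proficiency)
    return float(entry)


def simulate_subject(
    profile: SubjectProfile,
    design: CohortDesign,
    condition: str,
    seed: int | np.random.SeedSequence = 0,
) -> EpochArray:
    """Simulate one subject x condition epoch block from the design tables.

    A per-subject lognormal scale (sigma ``kappa_subject_sd``) multiplies all
    concentrations, and each component gets a subject-specific mean phase;
    neither affects the population coherence ordering across cells.
    """
    if condition not in design.conditions:
        raise InvalidParameterError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    scale = (
        float(np.exp(design.kappa_subject_sd * rng.standard_normal()))
        if design.kappa_subject_sd > 0 else 1.0
    )
    specs: list[PhaseLockSpec] = []
    cell = design.kappa_table[(profile.group, condition)]
    for freq in sorted(cell):
        kappa = resolve_kappa(design, profile.group, condition, freq,
                              profile.proficiency)
        mean_phase = float(rng.uniform(-np.pi, np.pi))
        if kappa <= 0:
            continue
        specs.append(PhaseLockSpec(
            freq=freq,
            amplitude=float(design.amplitude_table.get(freq, 0.5)),
            mean_phase=mean_phase,
            kappa=kappa if math.isinf(kappa) else kappa * scale,
            locked=math.isinf(kappa),
        ))
    if not specs:
        raise InvalidParameterError(
            "all concentrations are zero for this cell; nothing to simulate"
        )
    return simulate_epochs(
        specs, design.noise, design.n_trials, len(profile.montage),
        design.fs_eeg, design.window, seed=rng,
        channel_labels=profile.montage,
    )


def make_profiles(design: CohortDesign) -> list[SubjectProfile]:
    """Draw the subject table: groups, proficiency scores, handedness.

    L2 proficiency is truncated-normal on [0, 30]; handedness marks a
    design-scaled number of L2 subjects as left-handed (the montage carries
    no built-in asymmetry, so handedness is a pure labelling covariate).
    """
    root = np.random.SeedSequence(design.seed)
    prof_ss = root.spawn(1)[0]
    rng = np.random.default_rng(prof_ss)
    montage = analysis_montage()

    profiles = [
        SubjectProfile(f"L1-{i + 1:02d}", "L1", None, "right", montage)
        for i in range(design.n_per_group)
    ]
    a = (0.0 - design.proficiency_mean) / design.proficiency_sd
    b = (30.0 - design.proficiency_mean) / design.proficiency_sd
    scores = stats.truncnorm.rvs(
        a, b, loc=design.proficiency_mean, scale=design.proficiency_sd,
        size=design.n_per_group, random_state=rng,
    )
    n_left = int(round(design.n_left_handed_l2 * design.n_per_group / 24.0))
    n_left = min(n_left, design.n_per_group)
    handed = np.array(["left"] * n_left + ["right"] * (design.n_per_group - n_left))
    handed = handed[rng.permutation(design.n_per_group)]
    profiles.extend(
        SubjectProfile(f"L2-{i + 1:02d}", "L2", float(scores[i]),
                       str(handed[i]), montage)
        for i in range(design.n_per_group)
    )
    return profiles


def _subject_seeds(design: CohortDesign, n_subjects: int) -> list[list[np.random.SeedSequence]]:
    root = np.random.SeedSequence(design.seed)
    root.spawn(1)  # child 0 is consumed by make_profiles
    subj = root.spawn(n_subjects)
    return [s.spawn(len(design.conditions)) for s in subj]


def iter_cohort(
    design: CohortDesign,
) -> Iterator[tuple[SubjectProfile, str, EpochArray]]:
    """Stream (profile, condition, epochs) triples without holding the cohort.

    The epoch seed of each subject x condition is derived from the design
    seed by seed-sequence spawning, so any subset of the stream is
    reproducible independently of the rest.
    """
    profiles = make_profiles(design)
    seeds = _subject_seeds(design, len(profiles))
    for profile, subj_seeds in zip(profiles, seeds):
        for condition, ss in zip(design.conditions, subj_seeds):
            yield profile, condition, simulate_subject(profile, design, condition, ss)


@dataclass
class Cohort:
    """A fully materialized cohort (profiles plus per subject x condition epochs)."""

    design: CohortDesign
    profiles: list[SubjectProfile]
    epochs: dict[tuple[str, str], EpochArray]

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [p.subject_id for p in self.profiles],
                "group": [p.group for p in self.profiles],
                "proficiency": [p.proficiency for p in self.profiles],
                "handedness": [p.handedness for p in self.profiles],
            }
        )


def simulate_cohort(design: CohortDesign) -> Cohort:
    """Materialize the whole cohort in memory.

    Convenient for small designs; a default-size cohort holds ~3 GiB of
    float32 epochs, so large analyses should prefer :func:`iter_cohort`.
    """
    profiles = make_profiles(design)
    epochs: dict[tuple[str, str], EpochArray] = {}
    for profile, condition, arr in iter_cohort(design):
        epochs[(profile.subject_id, condition)] = arr
    return Cohort(design=design, profiles=profiles, epochs=epochs)
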