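"""Tagged-frequency peak statistics, attentional gain, lateralization, correlation.

The central test asks whether the response at a tagged bin stands above the
local spectral background: for each subject the Z value at the tagged bin is
paired with the average of its four neighboring bins (two on each side,
0.1 Hz apart), and a one-tailed paired t test (tagged > neighbors) is run
across subjects with Bonferroni correction over the family of tested bins
(default m = 4: the 1, 2 and 4 Hz tags plus the 3-Hz harmonic).

Attentional gain is the normalized contrast
(active - passive) / (active + passive) of the tagged-bin response, the
hemispheric lateralization effect is the right-minus-left neighbor-corrected
peak response, and the proficiency-tracking association is an ordinary
Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    MontageError,
    OffGridError,
    PairedDataError,
)
from .spectral import BIN_TOL, ITPCzSpectrum

DEFAULT_M_TESTS = 4
DEFAULT_K_PER_SIDE = 2


@dataclass(frozen=True)
class PeakTestResult:
    """One-tailed paired t of tagged-bin response vs neighbor-bin average."""

    freq: float
    t: float
    df: int
    p_raw: float
    p_corrected: float
    n_subjects: int
    degenerate: bool = False  # zero-variance paired differences

    @property
    def significant(self) -> bool:
        return self.p_corrected < 0.05


@dataclass(frozen=True)
class GainResult:
    """Per-subject attentional gains at one frequency with the group summary."""

    freq: float
    gains: np.ndarray
    mean: float
    se: float


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with two-tailed p (t transform, df = n - 2)."""

    r: float
    p: float
    n: int


def neighbor_bins(
    f: float,
    delta_f: float,
    k_per_side: int = DEFAULT_K_PER_SIDE,
    grid: np.ndarray | None = None,
) -> list[float]:
    """The 2k neighboring bin frequencies of f (k on each side), excluding f.

    If ``grid`` is given, every neighbor (and f itself) must lie on it.
    """
    if k_per_side < 1:
        raise InvalidParameterError("k_per_side must be >= 1")
    if delta_f <= 0:
        raise InvalidParameterError("delta_f must be positive")
    offsets = list(range(-k_per_side, 0)) + list(range(1, k_per_side + 1))
    neighbors = [f + k * delta_f for k in offsets]
    if grid is not None:
        for nb in neighbors + [f]:
            if np.min(np.abs(np.asarray(grid) - nb)) > BIN_TOL:
                raise OffGridError(
                    f"neighbor bin {nb:g} Hz falls outside the analysis grid"
                )
    return neighbors


def neighbor_mean(
    spec: ITPCzSpectrum, f: float, k_per_side: int = DEFAULT_K_PER_SIDE
) -> float:
    """Channel-mean Z averaged over the neighbor bins of f."""
    nbs = neighbor_bins(f, spec.delta_f, k_per_side, grid=spec.freqs)
    return float(np.mean([spec.channel_mean[spec.bin_index(nb)] for nb in nbs]))


def peak_test(
    subject_values_at_f: np.ndarray | list,
    subject_neighbor_means: np.ndarray | list,
    m_tests: int = DEFAULT_M_TESTS,
    freq: float = float("nan"),
) -> PeakTestResult:
    """One-tailed paired t across subjects: tagged-bin value > neighbor mean.

    Zero-variance differences are reported deterministically: t = +inf with
    p_raw = 0 for a positive mean, t = -inf with p_raw = 1 for a negative
    mean, and t = 0 with p_raw = 0.5 when every difference is zero; the
    ``degenerate`` flag marks these cases.  Bonferroni:
    p_corrected = min(1, m_tests * p_raw).
    """
    x = np.asarray(subject_values_at_f, dtype=np.float64)
    y = np.asarray(subject_neighbor_means, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise PairedDataError("paired samples must be equal-length 1-d arrays")
    n = len(x)
    if n < 3:
        raise PairedDataError("need at least three subjects for the paired t")
    if m_tests < 1:
        raise InvalidParameterError("m_tests must be >= 1")

    diffs = x - y
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        if mean > 0:
            t, p_raw = math.inf, 0.0
        elif mean < 0:
            t, p_raw = -math.inf, 1.0
        else:
            t, p_raw = 0.0, 0.5
        return PeakTestResult(freq, t, n - 1, p_raw, min(1.0, m_tests * p_raw),
                              n, degenerate=True)

    t = mean / (sd / math.sqrt(n))
    p_raw = float(sps.t.sf(t, df=n - 1))
    return PeakTestResult(freq, float(t), n - 1, p_raw,
                          min(1.0, m_tests * p_raw), n)


def attentional_gain(active: float, passive: float) -> float:
    """Normalized attentional contrast (active - passive) / (active + passive).

    Antisymmetric in its arguments and bounded in [-1, 1] for non-negative
    inputs; undefined when the responses sum to zero.
    """
    denom = active + passive
    if denom == 0:
        raise DegenerateInputError("attentional gain undefined: responses sum to 0")
    return (active - passive) / denom


def attentional_gains(
    active: np.ndarray | list, passive: np.ndarray | list, freq: float = float("nan")
) -> GainResult:
    """Per-subject attentional gains with the group mean and standard error."""
    a = np.asarray(active, dtype=np.float64)
    p = np.asarray(passive, dtype=np.float64)
    if a.shape != p.shape:
        raise PairedDataError("active/passive must be paired per subject")
    gains = np.array([attentional_gain(ai, pi) for ai, pi in zip(a, p)])
    se = float(gains.std(ddof=1) / np.sqrt(len(gains))) if len(gains) > 1 else 0.0
    return GainResult(freq=freq, gains=gains, mean=float(gains.mean()), se=se)


def hemisphere_peak_response(
    spec: ITPCzSpectrum, f: float, channels: tuple[str, ...] | list[str],
    k_per_side: int = DEFAULT_K_PER_SIDE,
) -> float:
    """Neighbor-corrected peak response averaged over a channel set.

    The hemisphere spectrum is the mean Z over the given channels; the
    response is its value at f minus the mean of the four neighboring bins.
    """
    if len(channels) == 0:
        raise InvalidParameterError("channel set must be non-empty")
    idx = []
    for ch in channels:
        try:
            idx.append(spec.channel_labels.index(ch))
        except ValueError as exc:
            raise MontageError(f"channel {ch!r} not in montage") from exc
    hemi = spec.values[idx, :].mean(axis=0)
    nbs = neighbor_bins(f, spec.delta_f, k_per_side, grid=spec.freqs)
    peak = hemi[spec.bin_index(f)]
    neigh = np.mean([hemi[spec.bin_index(nb)] for nb in nbs])
    return float(peak - neigh)


def lateralization_effect(
    spec: ITPCzSpectrum,
    f: float,
    left_channels: tuple[str, ...] | list[str],
    right_channels: tuple[str, ...] | list[str],
    k_per_side: int = DEFAULT_K_PER_SIDE,
) -> float:
    """Right-hemisphere minus left-hemisphere neighbor-corrected peak response."""
    if set(left_channels) & set(right_channels):
        raise InvalidParameterError("left and right channel sets must be disjoint")
    right = hemisphere_peak_response(spec, f, right_channels, k_per_side)
    left = hemisphere_peak_response(spec, f, left_channels, k_per_side)
    return right - left


def pearson_corr(x: np.ndarray | list, y: np.ndarray | list) -> CorrelationResult:
    """Pearson r with two-tailed p via the t transform (df = n - 2)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise PairedDataError("x and y must be equal-length 1-d arrays")
    if len(x) < 3:
        raise PairedDataError("need at least three observations")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


def behavioral_tests(
    scores_g1: np.ndarray | list,
    scores_g2: np.ndarray | list,
    midpoint: float,
    equal_var: bool = True,
) -> dict:
    """Simple behavioral comparisons on rating-scale scores.

    Returns the between-group independent-sample t (pooled variance by
    default, Welch with ``equal_var=False``) and a one-sample t of each
    group against the scale midpoint.
    """
    g1 = np.asarray(scores_g1, dtype=np.float64)
    g2 = np.asarray(scores_g2, dtype=np.float64)
    if len(g1) < 2 or len(g2) < 2:
        raise InvalidParameterError("each group needs at least two scores")

    between = sps.ttest_ind(g1, g2, equal_var=equal_var)
    out = {
        "between": {"t": float(between.statistic), "p": float(between.pvalue),
                    "df": float(between.df)},
    }
    for name, g in (("group1_vs_midpoint", g1), ("group2_vs_midpoint", g2)):
        if g.std(ddof=1) == 0:
            if float(g.mean()) == midpoint:
                out[name] = {"t": 0.0, "p": 1.0, "df": len(g) - 1}
            else:
                raise DegenerateInputError(
                    "zero variance in one-sample test away from the midpoint"
                )
        else:
            one = sps.ttest_1samp(g, midpoint)
            out[name] = {"t": float(one.statistic), "p": float(one.pvalue),
                         "df": len(g) - 1}
    return out
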