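"""Epoched multichannel EEG-like data container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError


@dataclass
class EpochArray:
    """Trials x channels x samples block at a fixed sampling rate.

    ``window`` is the epoch time window in seconds relative to stimulus
    onset (onset at 0 s); the sample count must equal
    ``round((end - start) * fs)``.
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise InvalidParameterError("epoch data must be trials x channels x samples")
        start, end = self.window
        expected = int(round((end - start) * self.fs))
        if self.data.shape[2] != expected:
            raise InvalidParameterError(
                f"window {self.window} at fs={self.fs} implies {expected} samples, "
                f"got {self.data.shape[2]}"
            )
        if len(self.channel_labels) != self.data.shape[1]:
            raise InvalidParameterError("channel label count must match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.window[0] + np.arange(self.data.shape[2]) / self.fs
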