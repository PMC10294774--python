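"""Channel montage: 64-channel quick-cap labels and the 62-channel analysis set.

The recording cap has 64 electrodes; the two cheek/mastoid-adjacent
electrodes CB1 and CB2 do not correspond to 10-20 scalp positions and are
discarded before analysis, leaving 62 channels.  Hemisphere assignment
follows the 10-20 convention: labels ending in an odd digit are left
hemisphere, even digits right, and a ``Z`` suffix marks the midline.
"""

from __future__ import annotations

import re

_QUICKCAP_64 = (
    "FP1", "FPZ", "FP2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)

NON_SCALP = ("CB1", "CB2")


def quickcap_montage() -> tuple[str, ...]:
    """The full 64-channel cap label set (including CB1/CB2)."""
    return _QUICKCAP_64


def analysis_montage(full: tuple[str, ...] | None = None,
                     discard: tuple[str, ...] = NON_SCALP) -> tuple[str, ...]:
    """Drop non-scalp electrodes from a montage (default: CB1/CB2 from the 64-cap)."""
    if full is None:
        full = quickcap_montage()
    return tuple(ch for ch in full if ch not in discard)


def hemisphere_split(
    labels: tuple[str, ...] | list[str],
) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Partition labels into (left, right, midline) by the 10-20 naming rule."""
    left: list[str] = []
    right: list[str] = []
    midline: list[str] = []
    for ch in labels:
        if ch.upper().endswith("Z"):
            midline.append(ch)
            continue
        m = re.search(r"(\d+)$", ch)
        if m is None:
            midline.append(ch)
        elif int(m.group(1)) % 2 == 1:
            left.append(ch)
        else:
            right.append(ch)
    return tuple(left), tuple(right), tuple(midline)
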