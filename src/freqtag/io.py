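"""On-disk formats: HDF5 epoch layout, WAV stimuli, CSV tables.

HDF5 layout (one file per cohort)::

    /subjects/<subject_id>/<condition>/data   trials x channels x samples
        attrs: fs, window, channel_labels
    /subjects/<subject_id>
        attrs: group, handedness, proficiency (NaN for L1)

Everything else (profiles, manifests, spectra, statistics) is plain CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .cohort import SubjectProfile
from .epochs import EpochArray
from .stimulus import SpeechSequence


def write_wav(path: str | Path, seq: SpeechSequence) -> None:
    """Write one sequence as 16-bit PCM WAV."""
    scaled = np.clip(seq.samples, -1.0, 1.0)
    wavfile.write(str(path), int(seq.fs_audio), (scaled * 32767).astype(np.int16))


def write_sequence_manifest(path: str | Path, seqs: list[SpeechSequence]) -> None:
    """CSV manifest: one row per syllable slot (sequence, sentence ids, onsets)."""
    rows = []
    for i, seq in enumerate(seqs):
        for k, onset in enumerate(seq.boundaries):
            rows.append(
                {
                    "sequence": i,
                    "syllable_index": k,
                    "onset_s": float(onset),
                    "token": seq.tokens[k] if seq.tokens else "",
                    "sentence_id": seq.sentence_ids[k // 4],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_intensity_spectrum(path: str | Path, freqs: np.ndarray,
                             amplitude: np.ndarray) -> None:
    pd.DataFrame({"freq_hz": freqs, "amplitude": amplitude}).to_csv(path, index=False)


def _write_epochs(group: h5py.Group, epochs: EpochArray) -> None:
    dset = group.create_dataset("data", data=epochs.data)
    dset.attrs["fs"] = epochs.fs
    dset.attrs["window"] = np.asarray(epochs.window, dtype=np.float64)
    dset.attrs["channel_labels"] = [s.encode() for s in epochs.channel_labels]


def _read_epochs(group: h5py.Group) -> EpochArray:
    dset = group["data"]
    labels = tuple(
        s.decode() if isinstance(s, bytes) else str(s)
        for s in dset.attrs["channel_labels"]
    )
    w = dset.attrs["window"]
    return EpochArray(data=dset[()], fs=float(dset.attrs["fs"]),
                      window=(float(w[0]), float(w[1])), channel_labels=labels)


def save_cohort_h5(
    path: str | Path,
    stream: Iterable[tuple[SubjectProfile, str, EpochArray]],
) -> None:
    """Stream a cohort into the documented HDF5 layout (constant memory)."""
    with h5py.File(path, "w") as f:
        subjects = f.create_group("subjects")
        for profile, condition, epochs in stream:
            if profile.subject_id in subjects:
                sgrp = subjects[profile.subject_id]
            else:
                sgrp = subjects.create_group(profile.subject_id)
                sgrp.attrs["group"] = profile.group
                sgrp.attrs["handedness"] = profile.handedness
                sgrp.attrs["proficiency"] = (
                    np.nan if profile.proficiency is None else profile.proficiency
                )
            _write_epochs(sgrp.create_group(condition), epochs)


def iter_cohort_h5(
    path: str | Path,
) -> Iterator[tuple[SubjectProfile, str, EpochArray]]:
    """Stream (profile, condition, epochs) back from the HDF5 layout."""
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            sgrp = f["subjects"][sid]
            prof_val = float(sgrp.attrs["proficiency"])
            for condition in sorted(sgrp):
                epochs = _read_epochs(sgrp[condition])
                profile = SubjectProfile(
                    subject_id=sid,
                    group=str(sgrp.attrs["group"]),
                    proficiency=None if np.isnan(prof_val) else prof_val,
                    handedness=str(sgrp.attrs["handedness"]),
                    montage=epochs.channel_labels,
                )
                yield profile, condition, epochs


def write_profiles(path: str | Path, profiles: list[SubjectProfile]) -> None:
    pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "group": [p.group for p in profiles],
            "proficiency": [p.proficiency for p in profiles],
            "handedness": [p.handedness for p in profiles],
        }
    ).to_csv(path, index=False)


def read_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df
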