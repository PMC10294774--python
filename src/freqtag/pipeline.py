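"""End-to-end orchestration: stimuli -> cohort -> spectra -> statistics.

Stages communicate through on-disk artifacts (WAV/CSV/HDF5/JSON) so each can
be re-run from the previous stage's outputs alone; :func:`run_pipeline`
chains them, streaming epochs from the simulator straight into the spectral
stage so a full-size cohort never has to be held (or written) in full.

All randomness descends from the single master seed in the run
configuration: the stimulus and cohort stages receive independent child
seeds by seed-sequence spawning, so the whole report is reproducible from
(config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import io as ftio
from .cohort import CohortDesign, SubjectProfile, iter_cohort, make_profiles
from .config import AnalysisConfig, RunConfig
from .epochs import EpochArray
from .montage import hemisphere_split
from .spectral import ITPCzSpectrum, baseline_correct, compute_itpc, fft_phase, rayleigh_z
from .stats import (
    attentional_gains,
    lateralization_effect,
    neighbor_mean,
    peak_test,
    pearson_corr,
)
from .stimulus import (
    build_sequence,
    intensity_spectrum,
    make_sentence_pool,
    spectral_peak_bin,
)

log = logging.getLogger("freqtag")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from the master seed."""
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF)
            for s in np.random.SeedSequence(seed).spawn(n)]


def subject_itpcz(
    epochs: EpochArray, analysis: AnalysisConfig | None = None
) -> ITPCzSpectrum:
    """Baseline-correct, FFT and coherence-normalize one subject x condition block."""
    analysis = analysis or AnalysisConfig()
    corrected = baseline_correct(epochs, analysis.baseline_window)
    spec = fft_phase(corrected, analysis.analysis_window, fmax=analysis.csv_fmax)
    return rayleigh_z(compute_itpc(spec))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_stimulus(config: RunConfig, outdir: str | Path) -> dict:
    """Generate the stimulus set, verify its intensity spectrum, write artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = config.stimulus
    t0 = time.perf_counter()
    pool_seed, seq_seed = _spawn_seeds(config.seed, 2)

    pool = make_sentence_pool(scfg.pool_size, seed=pool_seed)
    seq_seeds = _spawn_seeds(seq_seed, scfg.n_sequences)
    seqs = [
        build_sequence(pool, scfg.sentences_per_sequence, scfg.syllable_dur,
                       scfg.fs_audio, seed=s)
        for s in seq_seeds
    ]
    spec = intensity_spectrum(seqs, scfg.frame_s)
    peak = spectral_peak_bin(spec, 0.5, 4.5)

    ftio.write_sequence_manifest(outdir / "sequence_manifest.csv", seqs)
    ftio.write_intensity_spectrum(outdir / "intensity_spectrum.csv",
                                  spec.freqs, spec.amplitude)
    if scfg.write_wav:
        wav_dir = outdir / "wav"
        wav_dir.mkdir(exist_ok=True)
        for i, seq in enumerate(seqs):
            ftio.write_wav(wav_dir / f"sequence_{i:03d}.wav", seq)

    log.info("stimulus stage: %d sequences, intensity peak at %.1f Hz (%.2fs)",
             len(seqs), peak, time.perf_counter() - t0)
    return {
        "n_sequences": len(seqs),
        "sequence_duration_s": seqs[0].duration,
        "syllable_rate_hz": seqs[0].syllable_rate,
        "phrase_rate_hz": seqs[0].phrase_rate,
        "sentence_rate_hz": seqs[0].sentence_rate,
        "intensity_peak_hz": peak,
    }


def _cohort_stream(config: RunConfig) -> Iterator[tuple[SubjectProfile, str, EpochArray]]:
    _, cohort_seed = _spawn_seeds(config.seed, 2)
    design = CohortDesign(**{**_design_kwargs(config.cohort), "seed": cohort_seed})
    return iter_cohort(design)


def _design_kwargs(design: CohortDesign) -> dict:
    import dataclasses

    return {f.name: getattr(design, f.name) for f in dataclasses.fields(design)}


def stage_simulate(config: RunConfig, outdir: str | Path) -> dict:
    """Simulate the cohort and write the HDF5 epoch file plus the profile table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    _, cohort_seed = _spawn_seeds(config.seed, 2)
    design = CohortDesign(**{**_design_kwargs(config.cohort), "seed": cohort_seed})
    ftio.write_profiles(outdir / "profiles.csv", make_profiles(design))
    ftio.save_cohort_h5(outdir / "cohort.h5", iter_cohort(design))
    log.info("simulate stage: cohort written (%.2fs)", time.perf_counter() - t0)
    return {"n_subjects": 2 * design.n_per_group,
            "n_trials": design.n_trials,
            "conditions": list(design.conditions)}


def spectra_tables(
    stream: Iterable[tuple[SubjectProfile, str, EpochArray]],
    analysis: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce an epoch stream to channel-mean and per-channel Z tables.

    Both tables are truncated to ``analysis.csv_fmax`` (default 5 Hz), which
    covers every tagged bin and its neighbors.
    """
    mean_rows = []
    chan_rows = []
    for profile, condition, epochs in stream:
        z = subject_itpcz(epochs, analysis)
        keep = z.freqs <= analysis.csv_fmax + 1e-9
        freqs = z.freqs[keep]
        mean_rows.append(pd.DataFrame({
            "subject_id": profile.subject_id,
            "group": profile.group,
            "condition": condition,
            "proficiency": (np.nan if profile.proficiency is None
                            else profile.proficiency),
            "handedness": profile.handedness,
            "n_trials": z.n_trials,
            "freq_hz": freqs,
            "itpc_z": z.channel_mean[keep],
        }))
        sub = z.values[:, keep]
        chan_rows.append(pd.DataFrame({
            "subject_id": profile.subject_id,
            "condition": condition,
            "n_trials": z.n_trials,
            "channel": np.repeat(list(z.channel_labels), sub.shape[1]),
            "freq_hz": np.tile(freqs, sub.shape[0]),
            "itpc": np.sqrt(sub / z.n_trials).ravel(),
            "itpc_z": sub.ravel(),
        }))
    return pd.concat(mean_rows, ignore_index=True), pd.concat(chan_rows, ignore_index=True)


def stage_spectra(config: RunConfig, outdir: str | Path,
                  stream=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute ITPC-Z spectra (from a stream or the stage's HDF5 input) and write CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    if stream is None:
        stream = ftio.iter_cohort_h5(outdir / "cohort.h5")
    mean_df, chan_df = spectra_tables(stream, config.analysis)
    mean_df.to_csv(outdir / "spectra_channel_mean.csv", index=False)
    chan_df.to_csv(outdir / "spectra_channels.csv", index=False)
    log.info("spectra stage: %d subject-conditions (%.2fs)",
             mean_df.groupby(["subject_id", "condition"]).ngroups,
             time.perf_counter() - t0)
    return mean_df, chan_df


def _zspec_from_rows(rows: pd.DataFrame) -> ITPCzSpectrum:
    pivot = rows.pivot_table(index="channel", columns="freq_hz",
                             values="itpc_z", sort=True)
    values = pivot.to_numpy()
    return ITPCzSpectrum(
        values=values,
        freqs=pivot.columns.to_numpy(dtype=float),
        n_trials=int(rows["n_trials"].iloc[0]),
        channel_labels=tuple(pivot.index),
        channel_mean=values.mean(axis=0),
    )


def _mean_zspec(rows: pd.DataFrame) -> ITPCzSpectrum:
    rows = rows.sort_values("freq_hz")
    values = rows["itpc_z"].to_numpy()[None, :]
    return ITPCzSpectrum(
        values=values,
        freqs=rows["freq_hz"].to_numpy(dtype=float),
        n_trials=int(rows["n_trials"].iloc[0]),
        channel_labels=("mean",),
        channel_mean=values[0],
    )


def compute_statistics(
    mean_df: pd.DataFrame, chan_df: pd.DataFrame, analysis: AnalysisConfig
) -> dict:
    """All group-level statistics from the spectra tables."""
    results: dict = {"peak_tests": [], "attentional_gain": [],
                     "lateralization": [], "correlations": []}
    groups = sorted(mean_df["group"].unique())
    conditions = sorted(mean_df["condition"].unique())

    # tagged-bin values and neighbor means per subject x condition
    peak_vals: dict = {}
    neigh_vals: dict = {}
    for (sid, cond), rows in mean_df.groupby(["subject_id", "condition"]):
        z = _mean_zspec(rows)
        for f in analysis.test_freqs:
            peak_vals[(sid, cond, f)] = float(z.channel_mean[z.bin_index(f)])
            neigh_vals[(sid, cond, f)] = neighbor_mean(z, f, analysis.k_per_side)

    subj_by_group = {
        g: sorted(mean_df.loc[mean_df["group"] == g, "subject_id"].unique())
        for g in groups
    }

    for g in groups:
        for cond in conditions:
            for f in analysis.test_freqs:
                subj = subj_by_group[g]
                if len(subj) < 3:
                    # too few subjects for a paired t: report the cell as
                    # untestable rather than failing the run
                    results["peak_tests"].append({
                        "group": g, "condition": cond, "freq_hz": f,
                        "t": None, "df": len(subj) - 1, "p_raw": None,
                        "p_corrected": None, "significant": False,
                    })
                    continue
                res = peak_test(
                    [peak_vals[(s, cond, f)] for s in subj],
                    [neigh_vals[(s, cond, f)] for s in subj],
                    m_tests=analysis.m_tests, freq=f,
                )
                results["peak_tests"].append({
                    "group": g, "condition": cond, "freq_hz": f,
                    "t": res.t, "df": res.df, "p_raw": res.p_raw,
                    "p_corrected": res.p_corrected,
                    "significant": bool(res.p_corrected < analysis.alpha),
                })

    if {"active", "passive"} <= set(conditions):
        for g in groups:
            for f in analysis.tagged_freqs:
                gr = attentional_gains(
                    [peak_vals[(s, "active", f)] for s in subj_by_group[g]],
                    [peak_vals[(s, "passive", f)] for s in subj_by_group[g]],
                    freq=f,
                )
                results["attentional_gain"].append({
                    "group": g, "freq_hz": f, "mean": gr.mean, "se": gr.se,
                })

    # hemispheric lateralization from the per-channel table
    labels = tuple(sorted(chan_df["channel"].unique()))
    left, right, _ = hemisphere_split(labels)
    handed = mean_df.drop_duplicates("subject_id").set_index("subject_id")
    lat_rows = []
    for (sid, cond), rows in chan_df.groupby(["subject_id", "condition"]):
        z = _zspec_from_rows(rows)
        for f in analysis.tagged_freqs:
            lat_rows.append({
                "subject_id": sid, "condition": cond, "freq_hz": f,
                "group": handed.loc[sid, "group"],
                "handedness": handed.loc[sid, "handedness"],
                "effect": lateralization_effect(z, f, left, right,
                                                analysis.k_per_side),
            })
    lat_df = pd.DataFrame(lat_rows)
    for (g, cond, f), rows in lat_df.groupby(["group", "condition", "freq_hz"]):
        entry = {
            "group": g, "condition": cond, "freq_hz": float(f),
            "mean_effect": float(rows["effect"].mean()),
            "se": float(rows["effect"].std(ddof=1) / np.sqrt(len(rows))),
        }
        lefties = rows.loc[rows["handedness"] == "left", "effect"]
        righties = rows.loc[rows["handedness"] == "right", "effect"]
        if len(lefties) >= 2 and len(righties) >= 2:
            from scipy import stats as sps

            t_res = sps.ttest_ind(lefties, righties, equal_var=True)
            entry["handedness_t"] = float(t_res.statistic)
            entry["handedness_p"] = float(t_res.pvalue)
        results["lateralization"].append(entry)

    # proficiency correlation in the L2 group
    l2 = mean_df.loc[mean_df["group"] == "L2"].drop_duplicates("subject_id")
    if len(l2) >= 3:
        prof = l2.set_index("subject_id")["proficiency"]
        for cond in conditions:
            for f in (2.0, 4.0):
                if f not in analysis.test_freqs:
                    continue
                sids = sorted(prof.index)
                res = pearson_corr(
                    [prof[s] for s in sids],
                    [peak_vals[(s, cond, f)] for s in sids],
                )
                results["correlations"].append({
                    "condition": cond, "freq_hz": f,
                    "r": res.r, "p": res.p, "n": res.n,
                })

    return results


def export_anova_table(mean_df: pd.DataFrame, analysis: AnalysisConfig) -> pd.DataFrame:
    """Tidy long-format table (subject, group, condition, freq, ITPC-Z).

    Mixed ANOVAs are deliberately left to standard statistical software;
    this export is their input.
    """
    rows = []
    for (sid, cond), sub in mean_df.groupby(["subject_id", "condition"]):
        z = _mean_zspec(sub)
        for f in analysis.tagged_freqs:
            rows.append({
                "subject_id": sid,
                "group": sub["group"].iloc[0],
                "condition": cond,
                "freq_hz": f,
                "itpc_z": float(z.channel_mean[z.bin_index(f)]),
            })
    return pd.DataFrame(rows)


def stage_stats(config: RunConfig, outdir: str | Path,
                tables: tuple[pd.DataFrame, pd.DataFrame] | None = None) -> dict:
    """Group statistics from the spectra CSVs; writes result CSVs and the report."""
    outdir = Path(outdir)
    t0 = time.perf_counter()
    if tables is None:
        mean_df = pd.read_csv(outdir / "spectra_channel_mean.csv")
        chan_df = pd.read_csv(outdir / "spectra_channels.csv")
    else:
        mean_df, chan_df = tables
    results = compute_statistics(mean_df, chan_df, config.analysis)
    for key in ("peak_tests", "attentional_gain", "lateralization", "correlations"):
        pd.DataFrame(results[key]).to_csv(outdir / f"{key}.csv", index=False)
    export_anova_table(mean_df, config.analysis).to_csv(
        outdir / "anova_export.csv", index=False
    )
    log.info("stats stage done (%.2fs)", time.perf_counter() - t0)
    return results


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and return (and write) the machine-readable report.

    Epochs stream directly from the simulator into the spectral stage, so no
    full-cohort HDF5 is materialized; use the ``simulate`` stage explicitly
    if the epoch file itself is wanted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level))
    t0 = time.perf_counter()

    stimulus_summary = stage_stimulus(config, outdir)
    _, cohort_seed = _spawn_seeds(config.seed, 2)
    design = CohortDesign(**{**_design_kwargs(config.cohort), "seed": cohort_seed})
    ftio.write_profiles(outdir / "profiles.csv", make_profiles(design))
    mean_df, chan_df = stage_spectra(config, outdir, stream=iter_cohort(design))
    results = stage_stats(config, outdir, tables=(mean_df, chan_df))

    # timing is logged, not reported: the report must be bit-identical across
    # reruns of the same (config, seed)
    log.info("pipeline done (%.2fs)", time.perf_counter() - t0)
    report = {
        "seed": config.seed,
        "config": config.resolved_dict(),
        "stimulus": stimulus_summary,
        "statistics": results,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
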