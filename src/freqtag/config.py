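"""Run configuration: YAML loading, defaults, and validation.

Every modelling choice that the analysis leaves open is surfaced here with
its documented default: the Rayleigh-Z form, the Bonferroni family size, the
neighbor count per side, the baseline window, and the hemisphere split rule
implied by the montage labels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortDesign, NoiseModel
from .errors import ConfigError

GRID_TOL = 1e-6


@dataclass(frozen=True)
class StimulusConfig:
    pool_size: int = 60
    n_sequences: int = 48
    sentences_per_sequence: int = 10
    syllable_dur: float = 0.250
    fs_audio: float = 22050.0
    frame_s: float = 0.010
    write_wav: bool = False


@dataclass(frozen=True)
class AnalysisConfig:
    analysis_window: tuple[float, float] = (0.0, 10.0)
    baseline_window: tuple[float, float] = (-1.0, 0.0)
    tagged_freqs: tuple[float, ...] = (1.0, 2.0, 4.0)
    harmonic_freqs: tuple[float, ...] = (3.0,)
    k_per_side: int = 2
    m_tests: int = 4
    alpha: float = 0.05
    rayleigh_form: str = "n_r2"
    equal_var_ttest: bool = True
    csv_fmax: float = 5.0

    @property
    def delta_f(self) -> float:
        w0, w1 = self.analysis_window
        return 1.0 / (w1 - w0)

    @property
    def test_freqs(self) -> tuple[float, ...]:
        return tuple(sorted(self.tagged_freqs + self.harmonic_freqs))


@dataclass(frozen=True)
class RunConfig:
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    log_level: str = "INFO"

    def resolved_dict(self) -> dict:
        """JSON-serializable echo of every resolved setting."""

        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {
                    ("/".join(k) if isinstance(k, tuple) else str(k)): convert(v)
                    for k, v in obj.items()
                }
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            return obj

        return convert(self)


def _build(section: dict, cls, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    coerced = {}
    for key, val in section.items():
        if isinstance(val, list):
            val = tuple(val)
        coerced[key] = val
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{name}' section: {exc}") from exc


def validate_config(raw: dict | str | Path | None) -> RunConfig:
    """Build a validated RunConfig from a YAML file, a dict, or nothing.

    An empty/missing file yields the all-defaults configuration.  Raises
    :class:`ConfigError` naming the offending key for: tagged frequencies off
    the analysis grid, negative concentrations, fewer than two trials, or a
    negative/non-integer seed.
    """
    if raw is None:
        data: dict = {}
    elif isinstance(raw, (str, Path)):
        with open(raw) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")

    known_sections = {"stimulus", "cohort", "analysis", "seed", "log_level"}
    unknown = set(data) - known_sections
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    stimulus = _build(data.get("stimulus", {}), StimulusConfig, "stimulus")
    analysis = _build(data.get("analysis", {}), AnalysisConfig, "analysis")

    cohort_raw = dict(data.get("cohort", {}))
    if "noise" in cohort_raw:
        cohort_raw["noise"] = _build(cohort_raw["noise"], NoiseModel, "cohort.noise")
    if "kappa_table" in cohort_raw:
        cohort_raw["kappa_table"] = {
            tuple(k.split("/")): {float(f): v for f, v in tab.items()}
            for k, tab in cohort_raw["kappa_table"].items()
        }
    if "amplitude_table" in cohort_raw:
        cohort_raw["amplitude_table"] = {
            float(f): v for f, v in cohort_raw["amplitude_table"].items()
        }
    cohort = _build(cohort_raw, CohortDesign, "cohort")

    seed = data.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool) or seed < 0:
        raise ConfigError("seed must be a non-negative integer")

    if cohort.n_trials < 2:
        raise ConfigError("cohort.n_trials must be >= 2")

    df = analysis.delta_f
    for f in analysis.test_freqs:
        if abs(f / df - round(f / df)) > GRID_TOL:
            raise ConfigError(
                f"tagged frequency {f} Hz is off the {df:g}-Hz analysis grid"
            )
    w0, w1 = analysis.analysis_window
    e0, e1 = cohort.window
    if w0 < e0 or w1 > e1 or w1 <= w0:
        raise ConfigError("analysis window must lie within the epoch window")
    b0, b1 = analysis.baseline_window
    if b0 < e0 or b1 > 0 or b1 <= b0:
        raise ConfigError("baseline window must be a pre-onset interval in the epoch")

    log_level = str(data.get("log_level", "INFO")).upper()
    if log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        raise ConfigError(f"unknown log level {log_level!r}")

    return RunConfig(stimulus=stimulus, cohort=cohort, analysis=analysis,
                     seed=seed, log_level=log_level)
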