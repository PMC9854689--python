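"""Trial containers and the on-disk CSV dialects.

One trial is a 4.2-s stimulus presentation sampled at 90 Hz: a pupil-diameter
series (mm; the eye tracker itself reports meters, converted on read) and a
paired gaze series (degrees of offset from the fixation cross), both on one
explicit time grid running from -0.2 s (baseline) to 4.0 s (stimulus offset).

On disk, trials live in a long-format CSV: one row per sample, with trial
metadata repeated per row.  Blinks are encoded as empty pupil cells (the
device emits NaN for pupil and zeros for gaze during blinks); on read those
samples get ``valid=False`` on both traces, since the gaze zeros carry no
information.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

SCENES = ("active", "passive")
LOCATIONS = ("top", "bottom", "left", "right", "center")
PATTERNS = ("glare", "halo")

#: metadata columns identifying one trial, in canonical order
TRIAL_KEYS = ["subject", "scene", "location", "pattern", "repetition"]

_GRID_TOL_S = 1e-9


def _check_grid(times_s: np.ndarray, context: str = "") -> float:
    """Validate a uniform time grid, returning the sample interval."""
    if times_s.ndim != 1 or times_s.size < 2:
        raise FormatError(f"time grid must be 1-D with >= 2 samples {context}")
    steps = np.diff(times_s)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > _GRID_TOL_S):
        raise FormatError(f"non-uniform time grid {context}")
    return dt


@dataclass
class PupilTrace:
    """Uniformly sampled pupil-diameter series with a missing-sample mask."""

    times_s: np.ndarray
    diameter_mm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.times_s.shape == self.diameter_mm.shape == self.valid.shape):
            raise FormatError("PupilTrace arrays must share one shape")
        _check_grid(self.times_s, "(pupil trace)")
        if not np.all(np.isfinite(self.diameter_mm[self.valid])):
            raise FormatError("pupil diameter must be finite where valid")

    @property
    def dt_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / self.dt_s

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            self.times_s.copy(), self.diameter_mm.copy(), self.valid.copy()
        )


@dataclass
class GazeTrace:
    """Gaze offset from the fixation-cross center, signed degrees per axis."""

    times_s: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        shapes = {a.shape for a in (self.times_s, self.x_deg, self.y_deg, self.valid)}
        if len(shapes) != 1:
            raise FormatError("GazeTrace arrays must share one shape")
        _check_grid(self.times_s, "(gaze trace)")

    def copy(self) -> "GazeTrace":
        return GazeTrace(
            self.times_s.copy(), self.x_deg.copy(), self.y_deg.copy(), self.valid.copy()
        )


@dataclass
class TrialRecord:
    """One stimulus presentation: design metadata plus paired traces."""

    subject: str
    scene: str
    location: str
    pattern: str
    repetition: int
    pupil: PupilTrace
    gaze: GazeTrace

    def __post_init__(self) -> None:
        if self.scene not in SCENES:
            raise FormatError(f"unknown scene {self.scene!r}; expected one of {SCENES}")
        if self.location not in LOCATIONS:
            raise FormatError(
                f"unknown location {self.location!r}; expected one of {LOCATIONS}"
            )
        if self.pattern not in PATTERNS:
            raise FormatError(
                f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}"
            )
        if not np.allclose(self.pupil.times_s, self.gaze.times_s, atol=_GRID_TOL_S):
            raise FormatError("pupil and gaze must share one time grid")

    @property
    def key(self) -> tuple:
        return (self.subject, self.scene, self.location, self.pattern, self.repetition)


@dataclass
class PreprocessConfig:
    """Parameters of the cleaning cascade and feature windows.

    Defaults follow the published analysis: 0.2-s pre-stimulus baseline,
    4-Hz zero-phase low-pass, 0.001 mm/ms velocity rejection, 3-sigma
    PC1/PC2 distance rejection, 5.035-degree gaze-fixation radius, 30%
    participant-level rejection cutoff, MPCL search up to 1 s and a
    +/-0.1-s early-component window, stimulus offset at 4 s.
    """

    sample_rate_hz: float = 90.0
    baseline_window_s: float = 0.2
    lowpass_cutoff_hz: float = 4.0
    filter_order: int = 3
    velocity_threshold_mm_per_ms: float = 0.001
    pca_sigma: float = 3.0
    pca_scope: str = "participant"  # "participant" | "global"
    pca_rule: str = "mean_plus_sd"  # "mean_plus_sd" | "sd_only"
    gaze_radius_deg: float = 5.035
    participant_reject_ratio: float = 0.30
    mpcl_search_end_s: float = 1.0
    early_halfwidth_s: float = 0.1
    stimulus_end_s: float = 4.0
    auc_scale_dt: bool = False  # True -> AUC in mm*s instead of the plain sum

    def __post_init__(self) -> None:
        for name in (
            "sample_rate_hz",
            "baseline_window_s",
            "lowpass_cutoff_hz",
            "velocity_threshold_mm_per_ms",
            "pca_sigma",
            "gaze_radius_deg",
            "participant_reject_ratio",
            "mpcl_search_end_s",
            "stimulus_end_s",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"PreprocessConfig.{name} must be positive")
        if self.early_halfwidth_s < 0:
            raise ConfigError("PreprocessConfig.early_halfwidth_s must be >= 0")
        if self.lowpass_cutoff_hz >= self.sample_rate_hz / 2.0:
            raise ConfigError(
                "PreprocessConfig.lowpass_cutoff_hz must be below the Nyquist "
                f"frequency ({self.sample_rate_hz / 2.0:g} Hz)"
            )
        if self.mpcl_search_end_s > self.stimulus_end_s:
            raise ConfigError(
                "PreprocessConfig.mpcl_search_end_s must not exceed stimulus_end_s"
            )
        if self.pca_scope not in ("participant", "global"):
            raise ConfigError("PreprocessConfig.pca_scope must be 'participant' or 'global'")
        if self.pca_rule not in ("mean_plus_sd", "sd_only"):
            raise ConfigError("PreprocessConfig.pca_rule must be 'mean_plus_sd' or 'sd_only'")


# ---------------------------------------------------------------------------
# trace CSV dialect

_TRACE_COLUMNS = TRIAL_KEYS + ["time_s", "pupil_mm", "gaze_x_deg", "gaze_y_deg"]


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read trial records from the long-format trace CSV.

    Accepts pupil diameter either as ``pupil_mm`` (millimeters) or
    ``pupil_m`` (meters, the raw device unit — multiplied by 1000 on read).
    Empty pupil cells and literal ``NaN`` strings become missing samples;
    gaze samples coinciding with missing pupil samples are marked invalid,
    since the device substitutes zeros for gaze during blinks.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    pupil_col = None
    scale = 1.0
    if "pupil_mm" in df.columns:
        pupil_col = "pupil_mm"
    elif "pupil_m" in df.columns:
        pupil_col = "pupil_m"
        scale = 1000.0
    required = TRIAL_KEYS + ["time_s", "gaze_x_deg", "gaze_y_deg"]
    missing = [c for c in required if c not in df.columns]
    if pupil_col is None:
        missing.append("pupil_mm (or pupil_m)")
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")

    records: list[TrialRecord] = []
    df = df.sort_values(TRIAL_KEYS + ["time_s"], kind="stable")
    for key, g in df.groupby(TRIAL_KEYS, sort=False):
        times = g["time_s"].to_numpy(dtype=float)
        _check_grid(times, f"(trial {key})")
        pupil_mm = g[pupil_col].to_numpy(dtype=float) * scale
        valid = np.isfinite(pupil_mm)
        gaze_x = g["gaze_x_deg"].to_numpy(dtype=float)
        gaze_y = g["gaze_y_deg"].to_numpy(dtype=float)
        gaze_valid = valid & np.isfinite(gaze_x) & np.isfinite(gaze_y)
        # unit sanity applies to raw diameters only; baseline-corrected
        # traces (median near 0) legitimately leave the physiological range
        with np.errstate(invalid="ignore"):
            raw_like = valid.any() and float(np.median(pupil_mm[valid])) > 1.5
            n_low = int(np.sum(pupil_mm[valid] <= 0.5))
            n_high = int(np.sum(pupil_mm[valid] >= 10.0))
        if raw_like and (n_low or n_high):
            import warnings

            warnings.warn(
                f"trial {key}: {n_low + n_high} pupil samples outside the "
                "physiological range (0.5, 10) mm",
                stacklevel=2,
            )
        subject, scene, location, pattern, repetition = key
        records.append(
            TrialRecord(
                subject=str(subject),
                scene=str(scene),
                location=str(location),
                pattern=str(pattern),
                repetition=int(repetition),
                pupil=PupilTrace(times, pupil_mm, valid),
                gaze=GazeTrace(times, np.where(gaze_valid, gaze_x, 0.0),
                               np.where(gaze_valid, gaze_y, 0.0), gaze_valid),
            )
        )
    return records


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Long-format DataFrame for a set of trials (blinks as empty pupil)."""
    parts = []
    for rec in records:
        n = rec.pupil.times_s.size
        parts.append(
            pd.DataFrame(
                {
                    "subject": np.repeat(rec.subject, n),
                    "scene": np.repeat(rec.scene, n),
                    "location": np.repeat(rec.location, n),
                    "pattern": np.repeat(rec.pattern, n),
                    "repetition": np.repeat(rec.repetition, n),
                    "time_s": rec.pupil.times_s,
                    "pupil_mm": np.where(rec.pupil.valid, rec.pupil.diameter_mm, np.nan),
                    # invalid gaze as empty cells: unlike the device's zeros,
                    # this keeps the mask recoverable on re-read
                    "gaze_x_deg": np.where(rec.gaze.valid, rec.gaze.x_deg, np.nan),
                    "gaze_y_deg": np.where(rec.gaze.valid, rec.gaze.y_deg, np.nan),
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=_TRACE_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trials to the long-format trace CSV (full float precision)."""
    trials_to_frame(records).to_csv(Path(path), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# features and reports

FEATURE_COLUMNS = TRIAL_KEYS + [
    "mpcl_s",
    "early_mm",
    "auc_mm",
    "mean_gaze_y_deg",
    "weak_constriction",
]


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write the per-trial feature table with a deterministic column order."""
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    cols += [c for c in features.columns if c not in cols]
    features[cols].to_csv(Path(path), index=False, float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")


def write_report(report, path: str | Path) -> None:
    """Write a rejection report or an ANOVA result to CSV files.

    Duck-typed on the report's frames to avoid import cycles:

    * a rejection report (``trials`` / ``participants`` / ``stage_counts``)
      becomes ``<path>`` (per-trial flags), ``<stem>_participants.csv`` and
      ``<stem>_stages.csv``;
    * an ANOVA result (``table``) becomes a single seven-effect CSV shaped
      like the published main-effect tables (Effects, df, F, p, partial
      eta squared, plus sphericity diagnostics).
    """
    path = Path(path)
    if hasattr(report, "trials") and hasattr(report, "participants"):
        report.trials.to_csv(path, index=False)
        stem = path.with_suffix("")
        report.participants.to_csv(f"{stem}_participants.csv", index=False)
        pd.DataFrame(
            {"stage": list(report.stage_counts), "rejected": list(report.stage_counts.values())}
        ).to_csv(f"{stem}_stages.csv", index=False)
    elif hasattr(report, "table"):
        report.table.to_csv(path, index=False, float_format="%.17g")
    else:
        raise TypeError(f"cannot write report of type {type(report).__name__}")


def config_from_mapping(mapping: dict, cls=PreprocessConfig):
    """Build a config dataclass from a plain key-value mapping.

    Unknown keys raise a configuration error naming the field, so typos in
    config files fail loudly.
    """
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} field(s): {', '.join(sorted(unknown))}"
        )
    return cls(**mapping)
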