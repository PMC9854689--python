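"""Cleaning cascade for pupil/gaze trials.

Stages, in order:

1. blink interpolation — shape-preserving cubic Hermite (PCHIP) through the
   valid samples, nearest-value extension at the edges;
2. subtractive baseline correction — subtract the mean diameter over the
   0.2 s preceding stimulus onset;
3. zero-phase low-pass filtering — forward-backward Butterworth, 4-Hz
   cutoff (DC gain 1, no phase shift);
4. velocity rejection — a trial whose maximum absolute central-difference
   slope exceeds 0.001 mm/ms is discarded;
5. PCA-distance rejection — trials are stacked as observations x
   timepoints over the stimulus window, mean-centered, projected onto the
   first two principal components, and a trial whose (PC1, PC2) Euclidean
   score distance is extreme relative to 3 sigma of all distances is
   discarded;
6. gaze rejection — a trial whose mean gaze offset during the stimulus
   window lies outside a 5.035-degree radius (the central white area of
   the stimulus) is discarded;
7. participant exclusion — a participant whose rejected-trial ratio
   exceeds 30% is dropped entirely.

Every stage is deterministic; a rejection report records the first stage
that rejected each trial and the per-participant ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

from .errors import ConfigError, DataError
from .features import pupil_slope
from .trace_io import GazeTrace, PreprocessConfig, PupilTrace, TrialRecord, TRIAL_KEYS

logger = logging.getLogger(__name__)

__all__ = [
    "RejectionReport",
    "interpolate_blinks",
    "baseline_correct",
    "lowpass_filter",
    "velocity_flag",
    "pca_outlier_flags",
    "gaze_flag",
    "run_preprocessing",
]

STAGES = ("insufficient_data", "velocity", "pca_distance", "gaze")


@dataclass
class RejectionReport:
    """Per-trial rejection flags and per-participant exclusion summary.

    ``trials`` has one row per input trial with the metadata key, one
    boolean column per stage, and ``stage`` naming the first stage that
    rejected the trial (empty string for surviving trials).
    ``participants`` carries the rejected-trial ratio and the exclusion
    flag; ``stage_counts`` the number of first-rejections per stage.
    """

    trials: pd.DataFrame
    participants: pd.DataFrame
    stage_counts: dict


def interpolate_blinks(trace: PupilTrace) -> PupilTrace:
    """Fill missing samples by shape-preserving piecewise-cubic Hermite
    interpolation through the valid samples.

    Valid samples are returned unchanged; leading/trailing missing runs take
    the nearest valid value (PCHIP is not extrapolated).  Raises a data
    error when fewer than 2 valid samples exist — the pipeline turns that
    into an ``insufficient_data`` rejection.
    """
    if trace.valid.all():
        return trace.copy()
    n_valid = int(trace.valid.sum())
    if n_valid < 2:
        raise DataError("interpolate_blinks: fewer than 2 valid samples")
    t = trace.times_s
    tv = t[trace.valid]
    xv = trace.diameter_mm[trace.valid]
    out = trace.diameter_mm.copy()
    inner = ~trace.valid & (t >= tv[0]) & (t <= tv[-1])
    if inner.any():
        out[inner] = PchipInterpolator(tv, xv)(t[inner])
    out[t < tv[0]] = np.where(trace.valid[t < tv[0]], out[t < tv[0]], xv[0])
    out[t > tv[-1]] = np.where(trace.valid[t > tv[-1]], out[t > tv[-1]], xv[-1])
    return PupilTrace(t, out, np.ones(t.size, dtype=bool))


def baseline_correct(trace: PupilTrace, baseline_window_s: float = 0.2) -> PupilTrace:
    """Subtract the mean diameter over ``[-baseline_window_s, 0)``."""
    if baseline_window_s <= 0:
        raise ConfigError("baseline_window_s must be positive")
    t = trace.times_s
    tol = 0.5e-9
    window = (t >= -baseline_window_s - tol) & (t < -tol)
    if not window.any():
        raise DataError("baseline_correct: no samples in the baseline window")
    baseline = float(trace.diameter_mm[window].mean())
    return PupilTrace(t, trace.diameter_mm - baseline, trace.valid.copy())


def lowpass_filter(
    trace: PupilTrace, cutoff_hz: float = 4.0, order: int = 3
) -> PupilTrace:
    """Zero-phase low-pass: forward-backward Butterworth of the given
    per-pass order.  DC gain is 1 and features are not time-shifted."""
    fs = trace.sample_rate_hz
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2.0 * (1.0 - 1e-9):
        raise ConfigError(
            f"lowpass cutoff {cutoff_hz:g} Hz must lie in (0, {fs / 2.0:g}) Hz"
        )
    if not trace.valid.all():
        raise DataError("lowpass_filter requires a fully valid (interpolated) trace")
    b, a = butter(order, cutoff_hz, fs=fs)
    return PupilTrace(
        trace.times_s, filtfilt(b, a, trace.diameter_mm), trace.valid.copy()
    )


def velocity_flag(
    trace: PupilTrace, threshold_mm_per_ms: float = 0.001
) -> bool:
    """True (reject) iff the peak absolute central-difference pupil slope,
    in mm/ms, exceeds the threshold."""
    slope_mm_per_ms = pupil_slope(trace) / 1000.0
    return bool(np.max(np.abs(slope_mm_per_ms)) > threshold_mm_per_ms)


def pca_outlier_flags(
    traces: np.ndarray | list,
    sigma: float = 3.0,
    rule: str = "mean_plus_sd",
) -> np.ndarray:
    """Flag response-shape outliers by PC1/PC2 score distance.

    ``traces`` is an (n_trials, n_timepoints) stack of equal-length
    baseline-corrected series.  Trials are mean-centered across
    observations and projected onto the first two principal components;
    trial *i*'s distance is the Euclidean norm of its (PC1, PC2) score.
    Under ``mean_plus_sd`` (default) a trial is flagged when its distance
    exceeds ``mean + sigma * SD`` of all distances; ``sd_only`` implements
    the uncentered literal reading (distance > sigma * SD).

    Fewer than 3 trials: no flags, with a warning.
    """
    X = np.asarray(traces, dtype=float)
    if X.ndim != 2:
        raise DataError("pca_outlier_flags expects an (n_trials, n_timepoints) stack")
    n = X.shape[0]
    if n < 3:
        warnings.warn("pca_outlier_flags: fewer than 3 trials, no flags", stacklevel=2)
        return np.zeros(n, dtype=bool)
    Xc = X - X.mean(axis=0, keepdims=True)
    # scores on the leading principal components via SVD of the centered stack
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(2, s.size)
    scores = U[:, :k] * s[:k]
    dist = np.linalg.norm(scores, axis=1)
    sd = float(dist.std(ddof=0))
    if rule == "mean_plus_sd":
        threshold = float(dist.mean()) + sigma * sd
    elif rule == "sd_only":
        threshold = sigma * sd
    else:
        raise ConfigError(f"unknown pca rule {rule!r}")
    return dist > threshold


def gaze_flag(
    gaze: GazeTrace,
    radius_deg: float = 5.035,
    window_start_s: float = 0.0,
    window_end_s: float = 4.0,
) -> bool:
    """True (reject) iff the Euclidean norm of the mean gaze offset over
    the stimulus window exceeds ``radius_deg``.

    The mean is taken over valid samples; a trial with no valid in-window
    gaze raises a data error (``insufficient_data`` at pipeline level).
    """
    t = gaze.times_s
    mask = (t >= window_start_s) & (t <= window_end_s) & gaze.valid
    if not mask.any():
        raise DataError("gaze_flag: no valid gaze samples in the stimulus window")
    mx = float(gaze.x_deg[mask].mean())
    my = float(gaze.y_deg[mask].mean())
    return bool(np.hypot(mx, my) > radius_deg)


def run_preprocessing(
    records: list[TrialRecord], config: PreprocessConfig | None = None
) -> tuple[list[TrialRecord], RejectionReport]:
    """Apply the full cascade and return surviving records plus the report.

    Surviving records carry the processed pupil trace (interpolated,
    baseline-corrected, filtered); gaze traces are passed through with
    their validity masks.  The PCA stage operates within participant by
    default (``config.pca_scope``), over that participant's trials that
    survived the earlier stages.
    """
    config = config or PreprocessConfig()
    n = len(records)
    stage_of = [""] * n
    processed: list[PupilTrace | None] = [None] * n

    for i, rec in enumerate(records):
        try:
            trace = interpolate_blinks(rec.pupil)
            trace = baseline_correct(trace, config.baseline_window_s)
            trace = lowpass_filter(trace, config.lowpass_cutoff_hz, config.filter_order)
        except DataError:
            stage_of[i] = "insufficient_data"
            continue
        processed[i] = trace
        if velocity_flag(trace, config.velocity_threshold_mm_per_ms):
            stage_of[i] = "velocity"

    # PCA stage over the stimulus-window samples of surviving trials
    def _pca_groups():
        if config.pca_scope == "global":
            yield [i for i in range(n) if not stage_of[i]]
        else:
            by_subject: dict[str, list[int]] = {}
            for i in range(n):
                if not stage_of[i]:
                    by_subject.setdefault(records[i].subject, []).append(i)
            yield from by_subject.values()

    for idx in _pca_groups():
        if not idx:
            continue
        t = processed[idx[0]].times_s
        window = (t >= 0) & (t <= config.stimulus_end_s + 0.5e-9)
        stack = np.vstack([processed[i].diameter_mm[window] for i in idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flags = pca_outlier_flags(stack, config.pca_sigma, config.pca_rule)
        for i, flagged in zip(idx, flags):
            if flagged:
                stage_of[i] = "pca_distance"

    for i, rec in enumerate(records):
        if stage_of[i]:
            continue
        try:
            if gaze_flag(rec.gaze, config.gaze_radius_deg, 0.0, config.stimulus_end_s):
                stage_of[i] = "gaze"
        except DataError:
            stage_of[i] = "insufficient_data"

    # participant exclusion on the rejected-trial ratio (strict >)
    trials = pd.DataFrame(
        [dict(zip(TRIAL_KEYS, rec.key)) for rec in records]
    )
    trials["stage"] = stage_of
    for stage in STAGES:
        trials[stage] = [s == stage for s in stage_of]

    grouped = trials.groupby("subject", sort=True)
    participants = grouped.agg(
        n_trials=("stage", "size"), n_rejected=("stage", lambda s: int((s != "").sum()))
    ).reset_index()
    participants["rejected_ratio"] = participants["n_rejected"] / participants["n_trials"]
    participants["excluded"] = participants["rejected_ratio"] > config.participant_reject_ratio
    excluded = set(participants.loc[participants["excluded"], "subject"])

    stage_counts = {stage: int(trials[stage].sum()) for stage in STAGES}
    for stage, count in stage_counts.items():
        logger.info("preprocess: %d trial(s) rejected at stage %s", count, stage)
    if excluded:
        logger.info("preprocess: excluded participant(s): %s", ", ".join(sorted(excluded)))

    clean: list[TrialRecord] = []
    for i, rec in enumerate(records):
        if stage_of[i] or rec.subject in excluded:
            continue
        clean.append(
            TrialRecord(
                rec.subject, rec.scene, rec.location, rec.pattern, rec.repetition,
                processed[i], rec.gaze,
            )
        )
    if records and not clean:
        raise DataError("run_preprocessing: all trials rejected or all participants excluded")

    return clean, RejectionReport(trials, participants, stage_counts)
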