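"""Per-trial pupillometric features.

The pupillary response is split at the maximum pupil constriction latency
(MPCL) — the time of the most negative pupil slope within the first second
of stimulus presentation, with the slope taken by second-order accurate
central differences.  Around the MPCL, the *early component* is the mean
baseline-corrected diameter in a +/-0.1-s window (luminance-driven reflex);
from the MPCL to stimulus offset, the *late component* is the discrete sum

    AUC = sum_{i = MPCL sample}^{last sample <= 4 s} (x_i - x_MPCL)

in mm (a plain sample sum; multiply by the sample interval via
``auc_scale_dt`` for mm*s).  The mean vertical gaze offset over the stimulus
window is extracted alongside, to verify retinal-coordinate equivalence
across conditions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .trace_io import GazeTrace, PreprocessConfig, PupilTrace, TrialRecord

__all__ = [
    "pupil_slope",
    "find_mpcl",
    "early_component",
    "auc",
    "mean_gaze_y",
    "extract_features",
]

#: slopes shallower than this (mm/s) mark an ill-defined MPCL
WEAK_CONSTRICTION_SLOPE = -0.05


def pupil_slope(trace: PupilTrace) -> np.ndarray:
    """Per-sample pupil slope in mm/s by second-order central differences.

    Interior samples use ``(x[i+1] - x[i-1]) / (2 dt)``; the endpoints use
    the matching second-order one-sided stencils (exact for quadratics).
    """
    if trace.times_s.size < 3:
        raise DataError("pupil_slope requires at least 3 samples")
    if not trace.valid.all():
        raise DataError("pupil_slope requires a fully valid (interpolated) trace")
    return np.gradient(trace.diameter_mm, trace.dt_s, edge_order=2)


def find_mpcl(trace: PupilTrace, search_end_s: float = 1.0) -> float:
    """Maximum pupil constriction latency (s).

    The time of the most negative slope among samples with
    ``0 < t <= search_end_s``; ties break toward the earliest sample.  A
    warning is issued when even the steepest in-window slope is shallower
    than ``WEAK_CONSTRICTION_SLOPE``, marking trials without a clear
    constriction; such trials are retained.
    """
    slope = pupil_slope(trace)
    window = (trace.times_s > 0) & (trace.times_s <= search_end_s)
    if not window.any():
        raise DataError("find_mpcl: no samples in (0, search_end_s]")
    sl = slope[window]
    # earliest-time tie-break with a float tolerance so exactly tied slopes
    # (e.g. a linear descent) resolve to the first in-window sample
    m = float(sl.min())
    tol = 1e-9 * max(1.0, abs(m))
    idx = int(np.flatnonzero(sl <= m + tol)[0])
    if sl[idx] > WEAK_CONSTRICTION_SLOPE:
        warnings.warn(
            "weak constriction: minimum in-window slope "
            f"{sl[idx]:.4f} mm/s; MPCL is ill-defined",
            stacklevel=2,
        )
    return float(trace.times_s[window][idx])


def early_component(trace: PupilTrace, mpcl_s: float, halfwidth_s: float = 0.1) -> float:
    """Mean baseline-corrected diameter over ``|t - mpcl_s| <= halfwidth_s``.

    19 samples at 90 Hz when the window is interior; truncated at the trace
    bounds otherwise.
    """
    # half-sample tolerance so inclusive endpoints survive float grids
    tol = 0.5 * trace.dt_s
    mask = np.abs(trace.times_s - mpcl_s) <= halfwidth_s + tol * 1e-6
    if not mask.any():
        raise DataError("early_component: window does not intersect the trace")
    return float(trace.diameter_mm[mask].mean())


def auc(
    trace: PupilTrace,
    mpcl_s: float,
    stimulus_end_s: float = 4.0,
    scale_dt: bool = False,
) -> float:
    """Late-component AUC: sum of (x_i - x_MPCL) from the MPCL sample
    through the last sample at or before ``stimulus_end_s``.

    The MPCL term itself contributes 0 by construction.  With
    ``scale_dt=True`` the sum is multiplied by the sample interval,
    yielding mm*s instead of the plain mm sum.
    """
    if mpcl_s >= stimulus_end_s:
        raise DataError("auc requires mpcl_s < stimulus_end_s")
    t = trace.times_s
    start = int(np.argmin(np.abs(t - mpcl_s)))
    mask = np.zeros(t.size, dtype=bool)
    mask[start:] = True
    mask &= t <= stimulus_end_s + 0.5 * trace.dt_s * 1e-6
    x = trace.diameter_mm[mask]
    total = float(np.sum(x - trace.diameter_mm[start]))
    return total * trace.dt_s if scale_dt else total


def mean_gaze_y(
    gaze: GazeTrace, window_start_s: float = 0.0, window_end_s: float = 4.0
) -> float:
    """Arithmetic mean of the vertical gaze offset over the stimulus window.

    Invalid (blink) samples are excluded from the mean.
    """
    mask = (gaze.times_s >= window_start_s) & (gaze.times_s <= window_end_s) & gaze.valid
    if not mask.any():
        raise DataError("mean_gaze_y: no valid samples in the stimulus window")
    return float(gaze.y_deg[mask].mean())


def extract_features(
    records: list[TrialRecord], config: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Feature table for preprocessed trials, one row per trial.

    Expects fully valid (interpolated, baseline-corrected, filtered) pupil
    traces, as produced by the preprocessing cascade.
    """
    config = config or PreprocessConfig()
    rows = []
    for rec in records:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            mpcl = find_mpcl(rec.pupil, config.mpcl_search_end_s)
            weak = any("weak constriction" in str(w.message) for w in caught)
        early = early_component(rec.pupil, mpcl, config.early_halfwidth_s)
        late = auc(rec.pupil, mpcl, config.stimulus_end_s, config.auc_scale_dt)
        gy = mean_gaze_y(rec.gaze, 0.0, config.stimulus_end_s)
        rows.append(
            {
                "subject": rec.subject,
                "scene": rec.scene,
                "location": rec.location,
                "pattern": rec.pattern,
                "repetition": rec.repetition,
                "mpcl_s": mpcl,
                "early_mm": early,
                "auc_mm": late,
                "mean_gaze_y_deg": gy,
                "weak_constriction": weak,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        # canonical row order, independent of how the records were ordered
        out = out.sort_values(
            ["subject", "scene", "location", "pattern", "repetition"],
            kind="stable",
        ).reset_index(drop=True)
    return out
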