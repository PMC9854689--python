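"""Synthetic VR pupillometry experiments with known ground truth.

The generator reproduces the experimental design — per subject and scene,
5 stimulus locations x 2 luminance patterns (glare / halo) x ``reps_per_cell``
repetitions in randomized order — and a pupillary-light-reflex trace shape on
a 90-Hz grid from -0.2 to 4.0 s:

* baseline diameter per subject (Gaussian across subjects),
* constriction onset after a fixed latency,
* a smooth raised-cosine constriction impulse
  ``h(u) = (1 - cos(pi * u / tau_r)) / 2`` that reaches its full depth (the
  pattern amplitude plus a location modifier) exactly ``tau_r`` seconds
  after onset, with peak constriction velocity mid-descent as in real
  pupillary-light-reflex recordings,
* exponential re-dilation toward baseline with time constant
  ``recovery_tau_s`` after the trough,
* white measurement noise plus a slow AR(1) drift component,

and the artifact classes the cleaning cascade must reject: blink runs
(missing pupil samples, zeroed gaze), sustained step artifacts in the pupil
signal, and off-fixation gaze drift.  Every injection and the implied
noise-free feature values are recorded per trial in the ground truth, so
recovery can be measured against what was actually put in.

The cell-level simulator (`simulate_feature_cells`) generates subject-by-cell
feature means directly (subject intercept + condition effects + within-cell
noise) for calibration studies — type-I error and power — where simulating
thousands of full trace-level experiments would add nothing but runtime.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import features as _features
from .trace_io import (
    GazeTrace,
    LOCATIONS,
    PATTERNS,
    PupilTrace,
    SCENES,
    TrialRecord,
)

__all__ = [
    "SynthConfig",
    "TrialTruth",
    "GroundTruth",
    "plr_trace",
    "inject_artifacts",
    "generate_experiment",
    "simulate_feature_cells",
]


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the package's study conditions.

    Amplitudes are constriction depths in mm below baseline (glare deeper
    than halo, 0.15 mm apart); the trace reaches its trough
    ``latency_s + time_to_peak_s`` = 1.0 s after stimulus onset and is
    partially recovered by stimulus offset.  Noise is white (per-sample)
    plus a slow AR(1) wander so the 4-Hz low-pass has real work to do.
    Artifact rates can be scaled per scene via ``scene_artifact_scale``;
    they default to equal rates in both scenes.
    """

    n_subjects: int = 20
    reps_per_cell: int = 15
    scenes: tuple = SCENES
    sample_rate_hz: float = 90.0
    t_start_s: float = -0.2
    t_end_s: float = 4.0
    baseline_mm: float = 4.0
    baseline_sd_mm: float = 0.3
    latency_s: float = 0.25
    time_to_peak_s: float = 0.75
    constrict_amp_mm: dict = field(
        default_factory=lambda: {"glare": 0.25, "halo": 0.10}
    )
    location_mod_mm: dict = field(
        default_factory=lambda: {loc: 0.0 for loc in LOCATIONS}
    )
    recovery_tau_s: float = 2.0
    noise_sd_mm: float = 0.01
    drift_sd_mm: float = 0.10
    drift_rho: float = 0.997
    blink_rate_hz: float = 0.10
    blink_dur_s: tuple = (0.1, 0.3)
    artifact_prob: float = 0.02
    artifact_step_mm: tuple = (0.3, 0.8)
    gaze_jitter_deg: float = 0.5
    gaze_drift_prob: float = 0.01
    gaze_drift_deg: tuple = (6.0, 9.0)
    scene_artifact_scale: dict = field(
        default_factory=lambda: {"active": 1.0, "passive": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("SynthConfig.n_subjects must be >= 1")
        if self.reps_per_cell < 1:
            raise ConfigError("SynthConfig.reps_per_cell must be >= 1")
        unknown = set(self.scenes) - set(SCENES)
        if unknown:
            raise ConfigError(f"SynthConfig.scenes: unknown scene(s) {sorted(unknown)}")
        if not (self.t_start_s < 0 <= self.t_end_s):
            raise ConfigError("SynthConfig requires t_start_s < 0 <= t_end_s")
        if self.sample_rate_hz <= 0:
            raise ConfigError("SynthConfig.sample_rate_hz must be positive")
        for name in ("baseline_sd_mm", "noise_sd_mm", "drift_sd_mm",
                     "gaze_jitter_deg", "blink_rate_hz"):
            if getattr(self, name) < 0:
                raise ConfigError(f"SynthConfig.{name} must be >= 0")
        for name in ("latency_s", "time_to_peak_s", "recovery_tau_s", "baseline_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"SynthConfig.{name} must be positive")
        for pat in PATTERNS:
            if pat not in self.constrict_amp_mm:
                raise ConfigError(f"SynthConfig.constrict_amp_mm missing pattern {pat!r}")
            if self.constrict_amp_mm[pat] < 0:
                raise ConfigError("SynthConfig.constrict_amp_mm values must be >= 0")
        for loc in LOCATIONS:
            if loc not in self.location_mod_mm:
                raise ConfigError(f"SynthConfig.location_mod_mm missing location {loc!r}")
        for name in ("artifact_prob", "gaze_drift_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"SynthConfig.{name} must be in [0, 1]")
        if not 0 <= self.drift_rho < 1:
            raise ConfigError("SynthConfig.drift_rho must be in [0, 1)")
        for name in ("blink_dur_s", "artifact_step_mm", "gaze_drift_deg"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ConfigError(f"SynthConfig.{name} must be an ordered pair >= 0")

    def time_grid(self) -> np.ndarray:
        dt = 1.0 / self.sample_rate_hz
        n = int(round((self.t_end_s - self.t_start_s) / dt)) + 1
        return self.t_start_s + dt * np.arange(n)


@dataclass
class TrialTruth:
    """Latent state of one generated trial."""

    subject: str
    scene: str
    location: str
    pattern: str
    repetition: int
    baseline_mm: float
    amplitude_mm: float
    blink_intervals: list
    artifact_intervals: list
    gaze_drift: bool
    true_mpcl_s: float
    true_early_mm: float
    true_auc_mm: float


@dataclass
class GroundTruth:
    """One `TrialTruth` per generated trial, aligned with the record order."""

    trials: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            d = dataclasses.asdict(t)
            d["n_blinks"] = len(d.pop("blink_intervals"))
            d["n_artifacts"] = len(d.pop("artifact_intervals"))
            rows.append(d)
        return pd.DataFrame(rows)


def plr_trace(
    times_s: np.ndarray,
    *,
    baseline_mm: float,
    amplitude_mm: float,
    latency_s: float,
    time_to_peak_s: float,
    recovery_tau_s: float,
) -> PupilTrace:
    """Noise-free pupillary-light-reflex trace on a uniform grid.

    The diameter equals ``baseline_mm`` before ``latency_s``; afterwards a
    constriction of depth ``amplitude_mm`` develops along the raised-cosine
    impulse ``h(u) = (1 - cos(pi u / tau_r)) / 2`` (unit peak at
    ``u = tau_r``, steepest constriction at ``u = tau_r / 2``) and
    re-dilates exponentially toward baseline with ``recovery_tau_s``.  The
    re-dilation branch introduces a small slope discontinuity at the trough
    (depth' jumps from 0 to amplitude/recovery_tau); with the default
    parameters this is an order of magnitude below the velocity-rejection
    threshold.
    """
    times_s = np.asarray(times_s, dtype=float)
    depth = plr_depth(times_s, latency_s, time_to_peak_s, recovery_tau_s)
    diameter = baseline_mm - amplitude_mm * depth
    return PupilTrace(times_s, diameter, np.ones(times_s.size, dtype=bool))


def plr_depth(
    times_s: np.ndarray, latency_s: float, time_to_peak_s: float, recovery_tau_s: float
) -> np.ndarray:
    """Unit-amplitude constriction-depth profile (0 before onset, peak 1)."""
    u = np.asarray(times_s, dtype=float) - latency_s
    depth = np.zeros_like(u)
    rise = (u >= 0) & (u <= time_to_peak_s)
    depth[rise] = 0.5 * (1.0 - np.cos(np.pi * u[rise] / time_to_peak_s))
    rec = u > time_to_peak_s
    depth[rec] = np.exp(-(u[rec] - time_to_peak_s) / recovery_tau_s)
    return depth


def inject_artifacts(
    pupil: PupilTrace,
    gaze: GazeTrace,
    config: SynthConfig,
    rng: np.random.Generator,
    rate_scale: float = 1.0,
) -> tuple[PupilTrace, GazeTrace, dict]:
    """Inject blinks, pupil step artifacts, and gaze drift into one trial.

    Returns copies of the traces plus a dict of the injected events
    (``blink_intervals``, ``artifact_intervals``, ``gaze_drift``).  With all
    rates zero the traces are returned unchanged (still as copies).
    """
    pupil = pupil.copy()
    gaze = gaze.copy()
    t = pupil.times_s
    duration = t[-1] - t[0]
    info = {"blink_intervals": [], "artifact_intervals": [], "gaze_drift": False}

    n_blinks = rng.poisson(config.blink_rate_hz * rate_scale * duration)
    for _ in range(n_blinks):
        dur = rng.uniform(*config.blink_dur_s)
        start = rng.uniform(t[0], t[-1] - dur)
        mask = (t >= start) & (t < start + dur)
        if not mask.any():
            continue
        pupil.diameter_mm[mask] = np.nan
        pupil.valid[mask] = False
        gaze.x_deg[mask] = 0.0
        gaze.y_deg[mask] = 0.0
        gaze.valid[mask] = False
        info["blink_intervals"].append((float(start), float(start + dur)))

    if rng.random() < config.artifact_prob * rate_scale:
        # keep the step inside the analyzed window, clear of the trace edge
        onset = rng.uniform(0.0, config.t_end_s - 0.1)
        step = rng.uniform(*config.artifact_step_mm) * rng.choice([-1.0, 1.0])
        mask = t >= onset
        pupil.diameter_mm[mask & pupil.valid] += step
        info["artifact_intervals"].append((float(onset), float(t[-1])))

    if rng.random() < config.gaze_drift_prob * rate_scale:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        r = rng.uniform(*config.gaze_drift_deg)
        gaze.x_deg[gaze.valid] += r * np.cos(theta)
        gaze.y_deg[gaze.valid] += r * np.sin(theta)
        info["gaze_drift"] = True

    return pupil, gaze, info


def _true_features(
    config: SynthConfig, amplitude_mm: float, times_s: np.ndarray
) -> tuple[float, float, float]:
    """Noise-free feature values implied by a latent amplitude.

    Computed by applying the feature definitions to the analytic
    baseline-corrected trace (no noise, no filtering): these are the
    quantities a perfect pipeline would recover.
    """
    corrected = -amplitude_mm * plr_depth(
        times_s, config.latency_s, config.time_to_peak_s, config.recovery_tau_s
    )
    trace = PupilTrace(times_s, corrected, np.ones(times_s.size, dtype=bool))
    if amplitude_mm == 0.0:
        in_window = (times_s > 0) & (times_s <= 1.0)
        mpcl = float(times_s[in_window][0])
    else:
        mpcl = _features.find_mpcl(trace, search_end_s=1.0)
    early = _features.early_component(trace, mpcl, halfwidth_s=0.1)
    auc = _features.auc(trace, mpcl, stimulus_end_s=4.0)
    return mpcl, early, auc


def generate_experiment(config: SynthConfig) -> tuple[list[TrialRecord], GroundTruth]:
    """Generate the full design for every subject and scene.

    Per subject and scene, exactly ``5 locations x 2 patterns x
    reps_per_cell`` trials are produced in a randomized presentation order.
    Randomness is drawn from per-(subject, scene) substreams derived from
    the root seed, so the data for subject *i* do not depend on how many
    subjects are generated.
    """
    times = config.time_grid()
    records: list[TrialRecord] = []
    truths: list[TrialTruth] = []

    true_feature_cache: dict[float, tuple[float, float, float]] = {}

    for si in range(config.n_subjects):
        subject = f"S{si + 1:02d}"
        subj_rng = np.random.default_rng([config.seed, si])
        baseline = config.baseline_mm + config.baseline_sd_mm * subj_rng.standard_normal()
        for sci, scene in enumerate(config.scenes):
            rng = np.random.default_rng([config.seed, si, sci])
            scale = float(config.scene_artifact_scale.get(scene, 1.0))
            cells = [
                (loc, pat, rep)
                for loc in LOCATIONS
                for pat in PATTERNS
                for rep in range(config.reps_per_cell)
            ]
            order = rng.permutation(len(cells))
            for idx in order:
                loc, pat, rep = cells[idx]
                amp = max(
                    0.0, config.constrict_amp_mm[pat] + config.location_mod_mm[loc]
                )
                clean = plr_trace(
                    times,
                    baseline_mm=baseline,
                    amplitude_mm=amp,
                    latency_s=config.latency_s,
                    time_to_peak_s=config.time_to_peak_s,
                    recovery_tau_s=config.recovery_tau_s,
                )
                diameter = clean.diameter_mm.copy()
                if config.noise_sd_mm > 0:
                    diameter += rng.normal(0.0, config.noise_sd_mm, times.size)
                if config.drift_sd_mm > 0:
                    drift = _ar1(times.size, config.drift_rho, config.drift_sd_mm, rng)
                    diameter += drift
                pupil = PupilTrace(times, diameter, np.ones(times.size, dtype=bool))
                gx = rng.normal(0.0, config.gaze_jitter_deg, times.size)
                gy = rng.normal(0.0, config.gaze_jitter_deg, times.size)
                gaze = GazeTrace(times, gx, gy, np.ones(times.size, dtype=bool))
                pupil, gaze, info = inject_artifacts(pupil, gaze, config, rng, scale)
                records.append(
                    TrialRecord(subject, scene, loc, pat, rep, pupil, gaze)
                )
                if amp not in true_feature_cache:
                    true_feature_cache[amp] = _true_features(config, amp, times)
                mpcl, early, auc = true_feature_cache[amp]
                truths.append(
                    TrialTruth(
                        subject, scene, loc, pat, rep,
                        baseline_mm=float(baseline),
                        amplitude_mm=float(amp),
                        blink_intervals=info["blink_intervals"],
                        artifact_intervals=info["artifact_intervals"],
                        gaze_drift=info["gaze_drift"],
                        true_mpcl_s=mpcl,
                        true_early_mm=early,
                        true_auc_mm=auc,
                    )
                )
    return records, GroundTruth(truths)


def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    e = rng.normal(0.0, innov_sd, n)
    e[0] = rng.normal(0.0, sd)
    out = np.empty(n)
    out[0] = e[0]
    for k in range(1, n):
        out[k] = rho * out[k - 1] + e[k]
    return out


def simulate_feature_cells(
    n_subjects: int,
    *,
    pattern_effect_mm: float = 0.0,
    scene_effect_mm: float = 0.0,
    location_effects_mm: dict | None = None,
    subject_sd_mm: float = 0.3,
    cell_sd_mm: float = 0.08,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate subject-by-cell feature means for the 2x5x2 design.

    ``pattern_effect_mm`` is the glare-minus-halo difference (split
    symmetrically), ``scene_effect_mm`` the active-minus-passive difference,
    and ``location_effects_mm`` additive per-location shifts.
    ``cell_sd_mm`` is the within-subject SD of a cell mean.  Returns a long
    DataFrame with columns subject, scene, location, pattern, value.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    rng = np.random.default_rng(rng)
    location_effects_mm = location_effects_mm or {}
    rows = []
    for si in range(n_subjects):
        subject = f"S{si + 1:02d}"
        intercept = rng.normal(0.0, subject_sd_mm)
        for scene in SCENES:
            for loc in LOCATIONS:
                for pat in PATTERNS:
                    mu = (
                        intercept
                        + (0.5 if scene == "active" else -0.5) * scene_effect_mm
                        + (0.5 if pat == "glare" else -0.5) * pattern_effect_mm
                        + location_effects_mm.get(loc, 0.0)
                    )
                    rows.append(
                        (subject, scene, loc, pat, mu + rng.normal(0.0, cell_sd_mm))
                    )
    return pd.DataFrame(rows, columns=["subject", "scene", "location", "pattern", "value"])
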