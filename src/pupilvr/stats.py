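"""Within-subject inferential statistics for the 2 x 5 x 2 design.

The design is fully within-subject: every participant contributes one cell
mean per (scene, location, pattern) combination.  `rm_anova` performs the
complete three-way repeated-measures decomposition — each effect is tested
against its own effect-by-subject interaction:

    F_E = MS_E / MS_{E x subject},   partial eta^2 = SS_E / (SS_E + SS_err)

Sphericity is assessed per effect with Mauchly's test on the covariance of
orthonormalized effect contrasts, and the Greenhouse-Geisser factor

    epsilon = tr(S)^2 / (d * tr(S^2)),    1/d <= epsilon <= 1

(d = number of orthonormal contrasts) rescales both degrees of freedom
whenever Mauchly is significant at 0.05.  Post hoc paired comparisons are
Holm-Bonferroni corrected and report both Cohen's d conventions
(d_z = mean diff / SD of diffs; d_av = mean diff / average level SD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

from .errors import DataError
from .trace_io import LOCATIONS, PATTERNS, SCENES

logger = logging.getLogger(__name__)

__all__ = [
    "DesignTable",
    "AnovaResult",
    "aggregate_cells",
    "rm_anova",
    "gg_epsilon",
    "mauchly_test",
    "holm_adjust",
    "posthoc_pairwise",
]

#: within-subject factors in data-axis order (axis 0 is the subject)
FACTOR_LEVELS = {"scene": SCENES, "location": LOCATIONS, "pattern": PATTERNS}
FACTOR_AXIS = {"scene": 1, "location": 2, "pattern": 3}

#: the seven effects, in the order the main-effect tables print them
EFFECTS = (
    ("scene",),
    ("pattern",),
    ("location",),
    ("scene", "pattern"),
    ("scene", "location"),
    ("pattern", "location"),
    ("scene", "pattern", "location"),
)


def effect_label(effect: tuple) -> str:
    return " x ".join(effect)


@dataclass
class DesignTable:
    """Complete subject-by-cell table of one feature.

    ``data`` has shape (n_subjects, 2 scenes, 5 locations, 2 patterns) with
    factor levels ordered as in `FACTOR_LEVELS`.
    """

    data: np.ndarray
    subjects: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = (len(self.subjects), len(SCENES), len(LOCATIONS), len(PATTERNS))
        if self.data.shape != expected:
            raise DataError(
                f"DesignTable.data shape {self.data.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(self.data)):
            raise DataError("DesignTable requires a complete (finite) crossing")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @classmethod
    def from_long(cls, df: pd.DataFrame, value_col: str = "value") -> "DesignTable":
        """Build from a long table with subject/scene/location/pattern columns.

        Repeated rows per cell are averaged; subjects with any empty cell
        are dropped and logged.
        """
        cell = (
            df.groupby(["subject", "scene", "location", "pattern"], sort=True)[value_col]
            .mean()
        )
        subjects = sorted(df["subject"].unique())
        full_index = pd.MultiIndex.from_product(
            [subjects, list(SCENES), list(LOCATIONS), list(PATTERNS)],
            names=["subject", "scene", "location", "pattern"],
        )
        cell = cell.reindex(full_index)
        wide = cell.unstack(["scene", "location", "pattern"])
        complete = wide.dropna()
        dropped = sorted(set(wide.index) - set(complete.index))
        if dropped:
            logger.info(
                "aggregate_cells: dropped %d subject(s) with incomplete cells: %s",
                len(dropped), ", ".join(map(str, dropped)),
            )
        if complete.empty:
            raise DataError("no subject has a complete design crossing")
        kept = list(complete.index)
        data = np.empty((len(kept), len(SCENES), len(LOCATIONS), len(PATTERNS)))
        for si, sc in enumerate(SCENES):
            for li, loc in enumerate(LOCATIONS):
                for pi, pat in enumerate(PATTERNS):
                    data[:, si, li, pi] = complete[(sc, loc, pat)].to_numpy()
        return cls(data, kept)


def aggregate_cells(features: pd.DataFrame, feature_name: str) -> DesignTable:
    """Per-subject cell means of one feature column over surviving trials."""
    if feature_name not in features.columns:
        raise DataError(f"feature column {feature_name!r} not present")
    return DesignTable.from_long(features, value_col=feature_name)


# ---------------------------------------------------------------------------
# sums-of-squares machinery

def _component_ss(D: np.ndarray, axes_in: tuple) -> float:
    """Sum of squares of the ANOVA component for the axis subset ``axes_in``.

    The component is the Moebius alternating sum of marginal means over all
    subsets of ``axes_in``; its squared sum over the full grid is the SS.
    """
    all_axes = tuple(range(D.ndim))
    comp = np.zeros(tuple(D.shape[ax] if ax in axes_in else 1 for ax in all_axes))
    from itertools import chain, combinations as _comb

    subsets = chain.from_iterable(
        _comb(axes_in, r) for r in range(len(axes_in) + 1)
    )
    for V in subsets:
        other = tuple(ax for ax in all_axes if ax not in V)
        m = D.mean(axis=other, keepdims=True) if other else D
        sign = (-1) ** (len(axes_in) - len(V))
        comp = comp + sign * m
    excluded = [D.shape[ax] for ax in all_axes if ax not in axes_in]
    return float((comp**2).sum() * np.prod(excluded))


def _effect_contrast(effect: tuple) -> np.ndarray:
    """Orthonormal contrast matrix for an effect, Kronecker over its factors."""
    C = np.ones((1, 1))
    for name in ("scene", "location", "pattern"):
        k = len(FACTOR_LEVELS[name])
        if name in effect:
            C = np.kron(C, helmert(k, full=True)[1:])
        else:
            C = np.kron(C, np.full((1, k), 1.0 / k))
    return C


def gg_epsilon(contrast_covariance: np.ndarray, k: int | None = None) -> float:
    """Greenhouse-Geisser epsilon from an orthonormal-contrast covariance.

    ``k`` optionally gives the number of factor levels for a one-factor
    effect (d = k - 1 contrasts); by default d is the covariance dimension.
    Clamped to [1/d, 1]; d = 1 gives exactly 1.
    """
    S = np.atleast_2d(np.asarray(contrast_covariance, dtype=float))
    d = (k - 1) if k is not None else S.shape[0]
    if S.shape[0] != S.shape[1] or S.shape[0] != d:
        raise DataError("contrast covariance must be square of dimension d")
    eig = np.linalg.eigvalsh((S + S.T) / 2.0)
    if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
        raise DataError("contrast covariance must be positive semidefinite")
    if d == 1:
        return 1.0
    tr = float(np.trace(S))
    tr2 = float(np.sum(S * S.T))  # trace(S @ S) for symmetric S
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (d * tr2)
    return float(min(1.0, max(1.0 / d, eps)))


def mauchly_test(contrast_covariance: np.ndarray, n: int) -> tuple[float, float]:
    """Mauchly's sphericity test on an orthonormal-contrast covariance.

    Returns ``(W, p)`` using the standard chi-square approximation with
    ``n - 1`` error degrees of freedom.  Not defined for a single contrast
    (d = 1) or when the sample covariance is rank-deficient; both return
    ``(nan, nan)``.
    """
    S = np.atleast_2d(np.asarray(contrast_covariance, dtype=float))
    d = S.shape[0]
    if d < 2:
        return (float("nan"), float("nan"))
    eig = np.linalg.eigvalsh((S + S.T) / 2.0)
    if eig.min() <= 1e-12 * max(1.0, eig.max()) or n - 1 < d:
        return (float("nan"), float("nan"))
    W = float(np.prod(eig) / (eig.mean() ** d))
    df = d * (d + 1) // 2 - 1
    c = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * c * np.log(max(W, np.finfo(float).tiny))
    p = float(sps.chi2.sf(chi2, df))
    return (W, p)


@dataclass
class AnovaResult:
    """Seven-effect repeated-measures ANOVA table for one feature."""

    table: pd.DataFrame
    n_subjects: int
    feature: str = ""

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(name)
        return rows.iloc[0]


def rm_anova(table: DesignTable, feature: str = "", alpha: float = 0.05) -> AnovaResult:
    """Three-way repeated-measures ANOVA with per-effect sphericity handling.

    Each effect's F uses its effect-by-subject interaction as the error
    term.  Greenhouse-Geisser correction is applied to an effect's reported
    degrees of freedom and p-value when Mauchly's test for that effect is
    significant at ``alpha``; uncorrected values are always reported
    alongside.  A zero-variance error term yields an undefined F (NaN).
    """
    if table.n_subjects < 3:
        raise DataError("rm_anova requires at least 3 complete subjects")
    D = table.data
    n = table.n_subjects
    rows = []
    for effect in EFFECTS:
        axes = tuple(FACTOR_AXIS[f] for f in effect)
        df1 = int(np.prod([len(FACTOR_LEVELS[f]) - 1 for f in effect]))
        df2 = (n - 1) * df1
        ss_eff = _component_ss(D, axes)
        ss_err = _component_ss(D, (0,) + axes)
        if ss_err <= 0:
            F = p = float("nan")
        else:
            F = (ss_eff / df1) / (ss_err / df2)
            p = float(sps.f.sf(F, df1, df2))
        peta2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else float("nan")

        C = _effect_contrast(effect)
        Z = D.reshape(n, -1) @ C.T
        S = np.cov(Z, rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        eps = gg_epsilon(S)
        W, mauchly_p = mauchly_test(S, n)
        applied = bool(df1 > 1 and np.isfinite(mauchly_p) and mauchly_p < alpha)
        df1_gg, df2_gg = eps * df1, eps * df2
        p_gg = float(sps.f.sf(F, df1_gg, df2_gg)) if np.isfinite(F) else float("nan")
        rows.append(
            {
                "effect": effect_label(effect),
                "df_num": float(df1),
                "df_den": float(df2),
                "F": F,
                "p_uncorrected": p,
                "partial_eta2": peta2,
                "mauchly_W": W,
                "mauchly_p": mauchly_p,
                "gg_epsilon": eps,
                "sphericity_applied": applied,
                "df_num_gg": df1_gg,
                "df_den_gg": df2_gg,
                "p_gg": p_gg,
                "p": p_gg if applied else p,
                "df_num_reported": df1_gg if applied else float(df1),
                "df_den_reported": df2_gg if applied else float(df2),
            }
        )
    return AnovaResult(pd.DataFrame(rows), n, feature)


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataError("holm_adjust expects a 1-D array of p-values")
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise DataError("p-values must lie in [0, 1]")
    adjusted = np.full_like(p, np.nan)
    idx = np.where(finite)[0]
    m = idx.size
    if m == 0:
        return adjusted
    order = idx[np.argsort(p[idx], kind="stable")]
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adjusted[i] = min(1.0, running)
    return adjusted


def posthoc_pairwise(table: DesignTable, factor: str) -> pd.DataFrame:
    """Paired comparisons between all level pairs of one factor.

    Subject means per level are obtained by collapsing (averaging over) the
    other two factors.  Holm correction is applied across the factor's
    pairs.  A pair whose paired differences are identically zero reports
    t = 0, p = 1, d = 0; a pair with zero-variance nonzero differences has
    an undefined t (NaN), reported as such.
    """
    if factor not in FACTOR_LEVELS:
        raise DataError(f"unknown factor {factor!r}")
    levels = FACTOR_LEVELS[factor]
    axis = FACTOR_AXIS[factor]
    other_axes = tuple(ax for ax in (1, 2, 3) if ax != axis)
    means = table.data.mean(axis=other_axes)  # (n, k)
    n = table.n_subjects
    rows = []
    for (i, a), (j, b) in combinations(enumerate(levels), 2):
        diff = means[:, i] - means[:, j]
        sd_diff = float(diff.std(ddof=1))
        md = float(diff.mean())
        if np.allclose(diff, 0.0):
            t, p, dz = 0.0, 1.0, 0.0
        elif sd_diff <= 1e-12 * max(1.0, abs(md)):
            t, p, dz = float("nan"), float("nan"), float("nan")
        else:
            t = md / (sd_diff / np.sqrt(n))
            p = float(2.0 * sps.t.sf(abs(t), n - 1))
            dz = md / sd_diff
        sd_a = float(means[:, i].std(ddof=1))
        sd_b = float(means[:, j].std(ddof=1))
        d_av = md / ((sd_a + sd_b) / 2.0) if (sd_a + sd_b) > 0 else (
            0.0 if md == 0 else float("nan")
        )
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": md,
                "t": t,
                "df": n - 1,
                "p_raw": p,
                "cohen_dz": dz,
                "cohen_dav": d_av,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out
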