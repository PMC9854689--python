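"""Repeated-measures ANOVA, sphericity machinery, Holm adjustment, post hocs.

The ANOVA implementation is checked against two independent routes: a
naive textbook sums-of-squares oracle written with explicit marginal-mean
formulas (below), and statsmodels' AnovaRM.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pupilvr.errors import DataError
from pupilvr.stats import (
    DesignTable,
    EFFECTS,
    aggregate_cells,
    effect_label,
    gg_epsilon,
    holm_adjust,
    mauchly_test,
    posthoc_pairwise,
    rm_anova,
)
from pupilvr.synth import simulate_feature_cells
from pupilvr.trace_io import LOCATIONS, PATTERNS, SCENES


def naive_rm_anova_F(D):
    """Textbook three-way within-subject F statistics from explicit marginal
    means.  Axes: (subject, A, B, C)."""
    n, a, b, c = D.shape
    g = D.mean()
    mS = D.mean(axis=(1, 2, 3))
    mA = D.mean(axis=(0, 2, 3))
    mB = D.mean(axis=(0, 1, 3))
    mC = D.mean(axis=(0, 1, 2))
    mAS = D.mean(axis=(2, 3))  # (n, a)
    mBS = D.mean(axis=(1, 3))
    mCS = D.mean(axis=(1, 2))
    mAB = D.mean(axis=(0, 3))  # (a, b)
    mAC = D.mean(axis=(0, 2))
    mBC = D.mean(axis=(0, 1))
    mABS = D.mean(axis=3)  # (n, a, b)
    mACS = D.mean(axis=2)
    mBCS = D.mean(axis=1)
    mABC = D.mean(axis=0)  # (a, b, c)

    ss = {}
    ss["A"] = n * b * c * np.sum((mA - g) ** 2)
    ss["B"] = n * a * c * np.sum((mB - g) ** 2)
    ss["C"] = n * a * b * np.sum((mC - g) ** 2)
    ss["AxS"] = b * c * np.sum((mAS - mA[None, :] - mS[:, None] + g) ** 2)
    ss["BxS"] = a * c * np.sum((mBS - mB[None, :] - mS[:, None] + g) ** 2)
    ss["CxS"] = a * b * np.sum((mCS - mC[None, :] - mS[:, None] + g) ** 2)
    ss["AB"] = n * c * np.sum((mAB - mA[:, None] - mB[None, :] + g) ** 2)
    ss["AC"] = n * b * np.sum((mAC - mA[:, None] - mC[None, :] + g) ** 2)
    ss["BC"] = n * a * np.sum((mBC - mB[:, None] - mC[None, :] + g) ** 2)
    ss["ABxS"] = c * np.sum(
        (
            mABS
            - mAB[None, :, :]
            - mAS[:, :, None]
            - mBS[:, None, :]
            + mA[None, :, None]
            + mB[None, None, :]
            + mS[:, None, None]
            - g
        )
        ** 2
    )
    ss["ACxS"] = b * np.sum(
        (
            mACS
            - mAC[None, :, :]
            - mAS[:, :, None]
            - mCS[:, None, :]
            + mA[None, :, None]
            + mC[None, None, :]
            + mS[:, None, None]
            - g
        )
        ** 2
    )
    ss["BCxS"] = a * np.sum(
        (
            mBCS
            - mBC[None, :, :]
            - mBS[:, :, None]
            - mCS[:, None, :]
            + mB[None, :, None]
            + mC[None, None, :]
            + mS[:, None, None]
            - g
        )
        ** 2
    )
    ss["ABC"] = n * np.sum(
        (
            mABC
            - mAB[:, :, None]
            - mAC[:, None, :]
            - mBC[None, :, :]
            + mA[:, None, None]
            + mB[None, :, None]
            + mC[None, None, :]
            - g
        )
        ** 2
    )
    ss["ABCxS"] = np.sum(
        (
            D
            - mABS[:, :, :, None]
            - mACS[:, :, None, :]
            - mBCS[:, None, :, :]
            - mABC[None, :, :, :]
            + mAB[None, :, :, None]
            + mAC[None, :, None, :]
            + mBC[None, None, :, :]
            + mAS[:, :, None, None]
            + mBS[:, None, :, None]
            + mCS[:, None, None, :]
            - mA[None, :, None, None]
            - mB[None, None, :, None]
            - mC[None, None, None, :]
            - mS[:, None, None, None]
            + g
        )
        ** 2
    )

    dfs = {"A": a - 1, "B": b - 1, "C": c - 1,
           "AB": (a - 1) * (b - 1), "AC": (a - 1) * (c - 1),
           "BC": (b - 1) * (c - 1), "ABC": (a - 1) * (b - 1) * (c - 1)}
    F = {}
    for eff in dfs:
        err = ss[eff + "xS"]
        F[eff] = (ss[eff] / dfs[eff]) / (err / ((n - 1) * dfs[eff]))
    return F


# maps package effect labels to the oracle's A/B/C naming
_EFFECT_TO_ORACLE = {
    "scene": "A", "location": "B", "pattern": "C",
    "scene x location": "AB", "scene x pattern": "AC",
    "pattern x location": "BC", "scene x pattern x location": "ABC",
}


def random_table(rng, n=6):
    data = rng.normal(size=(n, 2, 5, 2))
    return DesignTable(data, [f"S{i:02d}" for i in range(n)])


class TestRmAnova:
    def test_matches_naive_oracle_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            table = random_table(rng, n=int(rng.integers(4, 9)))
            res = rm_anova(table)
            oracle = naive_rm_anova_F(table.data)
            for _, row in res.table.iterrows():
                want = oracle[_EFFECT_TO_ORACLE[row["effect"]]]
                assert row["F"] == pytest.approx(want, abs=1e-9, rel=1e-9)

    def test_two_level_effect_equals_paired_t_squared(self):
        rng = np.random.default_rng(14)
        table = random_table(rng, n=8)
        res = rm_anova(table)
        # pattern: subject means per pattern level, collapsing scene/location
        means = table.data.mean(axis=(1, 2))  # (n, 2)
        t, _ = sps.ttest_rel(means[:, 0], means[:, 1])
        row = res.effect("pattern")
        assert row["F"] == pytest.approx(t**2, rel=1e-9)
        assert (row["df_num"], row["df_den"]) == (1.0, 7.0)
        assert row["gg_epsilon"] == 1.0 and not row["sphericity_applied"]

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(15)
        table = random_table(rng, n=6)
        rows = []
        for si, subj in enumerate(table.subjects):
            for a, sc in enumerate(SCENES):
                for b, loc in enumerate(LOCATIONS):
                    for c, pat in enumerate(PATTERNS):
                        rows.append((subj, sc, loc, pat, table.data[si, a, b, c]))
        long = pd.DataFrame(rows, columns=["subject", "scene", "location", "pattern", "y"])
        sm = AnovaRM(long, "y", "subject", within=["scene", "location", "pattern"]).fit()
        res = rm_anova(table)
        sm_tab = sm.anova_table
        for sm_name, name in [
            ("scene", "scene"), ("location", "location"), ("pattern", "pattern"),
            ("scene:location", "scene x location"),
            ("scene:pattern", "scene x pattern"),
            ("location:pattern", "pattern x location"),
            ("scene:location:pattern", "scene x pattern x location"),
        ]:
            assert res.effect(name)["F"] == pytest.approx(
                sm_tab.loc[sm_name, "F Value"], rel=1e-8
            )

    def test_partial_eta_squared_bounds_and_effect_count(self):
        rng = np.random.default_rng(16)
        res = rm_anova(random_table(rng))
        assert len(res.table) == 7
        assert res.table["partial_eta2"].between(0, 1).all()
        assert (res.table["F"] >= 0).all()

    def test_strong_pattern_effect_detected(self):
        df = simulate_feature_cells(
            12, pattern_effect_mm=0.5, subject_sd_mm=0.2, cell_sd_mm=0.05, rng=17
        )
        res = rm_anova(DesignTable.from_long(df))
        assert res.effect("pattern")["p"] < 1e-4
        assert res.effect("scene")["p"] > 0.01

    def test_too_few_subjects_raises(self):
        rng = np.random.default_rng(18)
        with pytest.raises(DataError):
            rm_anova(random_table(rng, n=2))

    def test_zero_variance_error_term_reported_undefined(self):
        data = np.zeros((4, 2, 5, 2))
        res = rm_anova(DesignTable(data, list("abcd")))
        assert res.table["F"].isna().all()

    def test_permutation_invariance_of_omnibus_F(self):
        rng = np.random.default_rng(19)
        table = random_table(rng)
        res1 = rm_anova(table)
        perm = [2, 0, 4, 1, 3]  # relabel the location levels
        table2 = DesignTable(table.data[:, :, perm, :], table.subjects)
        res2 = rm_anova(table2)
        assert res1.effect("location")["F"] == pytest.approx(
            res2.effect("location")["F"], rel=1e-12
        )


class TestSphericity:
    def test_epsilon_is_one_for_two_levels(self):
        assert gg_epsilon(np.array([[2.5]])) == 1.0
        assert gg_epsilon(np.array([[2.5]]), k=2) == 1.0

    def test_epsilon_is_one_for_identity(self):
        assert gg_epsilon(np.eye(4)) == pytest.approx(1.0)

    def test_epsilon_lower_bound_for_rank_one(self):
        S = np.diag([1.0, 0.0, 0.0, 0.0])
        assert gg_epsilon(S, k=5) == pytest.approx(0.25)

    def test_epsilon_bounds_on_random_psd(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            A = rng.normal(size=(4, 4))
            S = A @ A.T
            eps = gg_epsilon(S)
            assert 1.0 / 4.0 - 1e-12 <= eps <= 1.0 + 1e-12

    def test_non_psd_rejected(self):
        with pytest.raises(DataError):
            gg_epsilon(np.diag([1.0, -0.5, 1.0, 1.0]))

    def test_mauchly_on_spherical_data_is_calibrated(self):
        """Under perfect sphericity Mauchly should rarely reject."""
        rng = np.random.default_rng(21)
        rejections = 0
        for _ in range(100):
            Z = rng.normal(size=(18, 4))
            S = np.cov(Z, rowvar=False)
            W, p = mauchly_test(S, 18)
            assert 0 < W <= 1 + 1e-12
            rejections += p < 0.05
        assert rejections <= 15

    def test_mauchly_undefined_for_single_contrast(self):
        W, p = mauchly_test(np.array([[1.0]]), 10)
        assert np.isnan(W) and np.isnan(p)


class TestHolm:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06], atol=1e-12
        )

    def test_single_p_unchanged_and_cap(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(22)
        p = rng.uniform(size=15)
        _, want, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), want, atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=10)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_invalid_p_raises(self):
        with pytest.raises(DataError):
            holm_adjust([0.5, 1.5])

    @settings(derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_holm_invariants(self, p):
        """Adjusted p-values dominate the raw ones, stay in [0, 1], and
        preserve the significance ordering."""
        p = np.asarray(p)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all((0.0 <= adj) & (adj <= 1.0))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPosthoc:
    def test_identical_levels_give_null_result(self):
        data = np.random.default_rng(24).normal(size=(6, 2, 5, 2))
        data[:, :, :, 1] = data[:, :, :, 0]  # make patterns identical
        table = DesignTable(data, list("abcdef"))
        out = posthoc_pairwise(table, "pattern")
        assert len(out) == 1
        row = out.iloc[0]
        assert row["t"] == 0.0 and row["p_raw"] == 1.0 and row["cohen_dz"] == 0.0

    def test_location_has_ten_pairs(self):
        table = DesignTable(
            np.random.default_rng(25).normal(size=(5, 2, 5, 2)), list("abcde")
        )
        out = posthoc_pairwise(table, "location")
        assert len(out) == 10
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()

    def test_constant_shift_recovered_exactly(self):
        rng = np.random.default_rng(26)
        base = np.zeros((10, 2, 5, 2)) + rng.normal(size=(10, 1, 1, 1))
        delta = 0.3
        base[:, :, 0, :] += delta  # shift the "top" location for every subject
        out = posthoc_pairwise(DesignTable(base, [f"s{i}" for i in range(10)]), "location")
        row = out[(out.level_a == "top") & (out.level_b == "bottom")].iloc[0]
        assert row["mean_diff"] == pytest.approx(delta, abs=1e-12)
        # noise-free constant shift: zero-variance differences, t undefined
        assert np.isnan(row["t"])

    def test_shift_with_noise_drives_p_to_zero(self):
        rng = np.random.default_rng(27)
        data = rng.normal(scale=0.01, size=(30, 2, 5, 2))
        data[:, :, 0, :] += 0.5
        out = posthoc_pairwise(DesignTable(data, [f"s{i}" for i in range(30)]), "location")
        row = out[(out.level_a == "top") & (out.level_b == "center")].iloc[0]
        assert row["p_holm"] < 1e-10
        assert row["cohen_dz"] > 5


class TestAggregate:
    def test_cell_means(self):
        df = simulate_feature_cells(3, rng=28)
        df = pd.concat([df, df], ignore_index=True)  # duplicate trials average out
        table = DesignTable.from_long(df)
        assert table.n_subjects == 3
        single = DesignTable.from_long(simulate_feature_cells(3, rng=28))
        np.testing.assert_allclose(table.data, single.data)

    def test_small_cell_mean(self):
        rows = []
        for sc in SCENES:
            for loc in LOCATIONS:
                for pat in PATTERNS:
                    rows += [("S01", sc, loc, pat, 0.1), ("S01", sc, loc, pat, 0.3)]
        df = pd.DataFrame(rows, columns=["subject", "scene", "location", "pattern", "value"])
        table = DesignTable.from_long(df)
        np.testing.assert_allclose(table.data, 0.2)

    def test_incomplete_subject_dropped(self, caplog):
        df = simulate_feature_cells(3, rng=29)
        df = df[~((df.subject == "S02") & (df.location == "top") & (df.pattern == "glare")
                  & (df.scene == "active"))]
        import logging

        with caplog.at_level(logging.INFO, logger="pupilvr.stats"):
            table = DesignTable.from_long(df)
        assert table.n_subjects == 2
        assert "S02" not in table.subjects
        assert any("S02" in m for m in caplog.messages)

    def test_feature_column_aggregation(self):
        df = simulate_feature_cells(4, rng=30).rename(columns={"value": "early_mm"})
        table = aggregate_cells(df, "early_mm")
        assert table.data.shape == (4, 2, 5, 2)
        with pytest.raises(DataError):
            aggregate_cells(df, "missing_column")
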