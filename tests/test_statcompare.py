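import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from gaitpert.statcompare import (
    ConditionMatrix,
    bonferroni_posthoc,
    friedman,
    full_report,
    rm_anova_oneway,
    rm_anova_twoway,
    shapiro_wilk,
)


def random_matrix(n=10, k=4, seed=0, scale=0.05):
    rng = np.random.default_rng(seed)
    return ConditionMatrix(
        rng.normal(0.8, scale, (n, k)), tuple(f"c{i}" for i in range(k))
    )


class TestConditionMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            ConditionMatrix(np.zeros((2, 2)), ("a", "b"))  # too few splits
        with pytest.raises(ValueError):
            ConditionMatrix(np.zeros((5, 1)), ("a",))
        bad = np.zeros((5, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            ConditionMatrix(bad, ("a", "b"))

    def test_from_results_pivot(self):
        df = pd.DataFrame(
            {
                "condition": ["A", "A", "A", "B", "B", "B"],
                "split_id": [0, 1, 2, 0, 1, 2],
                "f1": [0.8, 0.9, 0.85, 0.7, 0.75, 0.72],
            }
        )
        m = ConditionMatrix.from_results(df, conditions=["B", "A"])
        assert m.conditions == ("B", "A")
        assert m.values[0, 0] == 0.7


class TestShapiro:
    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([0.5] * 10)

    def test_statistic_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            rep = shapiro_wilk(rng.normal(size=12))
            assert rep.statistic <= 1.0

    def test_two_point_mixture_less_normal(self):
        # paired simulation: a +/-1 two-point sample should look less
        # normal than a matched-variance Gaussian sample on average
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(40):
            normal = rng.normal(0, 1, 10)
            mixture = rng.choice([-1.0, 1.0], 10) + rng.normal(0, 0.01, 10)
            diffs.append(shapiro_wilk(normal).p - shapiro_wilk(mixture).p)
        assert np.mean(diffs) > 0

    def test_matches_scipy(self):
        x = np.random.default_rng(3).normal(size=15)
        rep = shapiro_wilk(x)
        w, p = stats.shapiro(x)
        assert rep.statistic == pytest.approx(w)
        assert rep.p == pytest.approx(p)


class TestOneWayRmAnova:
    def test_identical_columns_give_zero_f(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=8)
        m = ConditionMatrix(np.tile(col[:, None], (1, 3)), ("a", "b", "c"))
        rep = rm_anova_oneway(m)
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_toy_matrix_manual_decomposition(self):
        # independent oracle: hand-computed sums of squares
        y = np.array(
            [[0.80, 0.85, 0.90],
             [0.70, 0.78, 0.82],
             [0.75, 0.80, 0.88],
             [0.68, 0.74, 0.79]]
        )
        grand = y.mean()
        ss_cond = 4 * sum((y[:, j].mean() - grand) ** 2 for j in range(3))
        ss_subj = 3 * sum((y[i].mean() - grand) ** 2 for i in range(4))
        ss_tot = ((y - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        f_manual = (ss_cond / 2) / (ss_err / 6)
        rep = rm_anova_oneway(ConditionMatrix(y, ("a", "b", "c")))
        assert rep.statistic == pytest.approx(f_manual, rel=1e-6)
        assert rep.effect_size == pytest.approx(
            ss_cond / (ss_cond + ss_err), rel=1e-6
        )

    def test_matches_pingouin(self):
        m = random_matrix(n=12, k=5, seed=4)
        long = (
            m.to_frame().reset_index().melt(
                id_vars="index", var_name="cond", value_name="y"
            )
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="index")
        rep = rm_anova_oneway(m)
        assert rep.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        p_col = next(c for c in ref.columns if c.replace("-", "_") == "p_unc")
        if rep.correction is None:
            assert rep.p == pytest.approx(float(ref[p_col].iloc[0]), rel=1e-6)

    def test_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        m = random_matrix(n=9, k=4, seed=5)
        long = (
            m.to_frame().reset_index().melt(
                id_vars="index", var_name="cond", value_name="y"
            )
        )
        ref = AnovaRM(long, "y", "index", within=["cond"]).fit().anova_table
        rep = rm_anova_oneway(m)
        assert rep.statistic == pytest.approx(float(ref["F Value"].iloc[0]), rel=1e-6)

    def test_location_invariance(self):
        m = random_matrix(seed=6)
        shifted = ConditionMatrix(m.values + 5.0, m.conditions)
        assert rm_anova_oneway(m).statistic == pytest.approx(
            rm_anova_oneway(shifted).statistic, rel=1e-9
        )

    def test_huynh_feldt_applied_when_sphericity_violated(self):
        # construct strong sphericity violation: one pair highly correlated
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, (20, 1))
        y = np.hstack([base, base + rng.normal(0, 0.01, (20, 1)),
                       rng.normal(0, 3, (20, 2))])
        rep = rm_anova_oneway(ConditionMatrix(y, ("a", "b", "c", "d")))
        assert rep.sphericity_p <= 0.05
        assert rep.correction == "huynh-feldt"
        assert rep.df[0] < 3  # epsilon-shrunk


class TestTwoWayRmAnova:
    def _cells(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(0.8, 0.05, (n, 2, 3))

    def test_duplicate_sensor_block_zero_main_effect(self):
        rng = np.random.default_rng(1)
        block = rng.normal(0.8, 0.05, (8, 3))
        cells = np.stack([block, block], axis=1)
        reps = rm_anova_twoway(
            cells, ("stype", ["ao", "ag"]), ("pos", ["L", "RHA", "LHA"])
        )
        assert reps["stype"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_zero_error_flagged(self):
        # 2x2 with identical rows: cell means known, zero error variance
        cells = np.tile(np.array([[1.0, 2.0], [3.0, 5.0]]), (6, 1, 1))
        reps = rm_anova_twoway(cells, ("a", ["a1", "a2"]), ("b", ["b1", "b2"]))
        for rep in reps.values():
            assert not np.isfinite(rep.statistic) or rep.statistic == 0.0
        assert any(
            rep.correction and "degenerate" in rep.correction
            for rep in reps.values()
        )

    def test_matches_pingouin_two_way(self):
        cells = self._cells(n=12, seed=3)
        rows = []
        for s in range(12):
            for i, a in enumerate(["ao", "ag"]):
                for j, b in enumerate(["L", "RHA", "LHA"]):
                    rows.append((s, a, b, cells[s, i, j]))
        long = pd.DataFrame(rows, columns=["subj", "stype", "pos", "y"])
        ref = pg.rm_anova(
            data=long, dv="y", within=["stype", "pos"], subject="subj"
        ).set_index("Source")
        reps = rm_anova_twoway(
            cells, ("stype", ["ao", "ag"]), ("pos", ["L", "RHA", "LHA"])
        )
        assert reps["stype"].statistic == pytest.approx(
            float(ref.loc["stype", "F"]), rel=1e-6
        )
        assert reps["pos"].statistic == pytest.approx(
            float(ref.loc["pos", "F"]), rel=1e-6
        )
        assert reps["stype * pos"].statistic == pytest.approx(
            float(ref.loc["stype * pos", "F"]), rel=1e-6
        )

    def test_incomplete_factorial_rejected(self):
        cells = self._cells()
        cells[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_twoway(cells, ("a", ["x", "y"]), ("b", ["1", "2", "3"]))


class TestFriedman:
    def test_identical_columns(self):
        m = ConditionMatrix(np.tile(np.arange(4.0)[:, None], (1, 3)), ("a", "b", "c"))
        rep = friedman(m)
        assert rep.statistic == 0.0

    def test_strict_ordering_toy(self):
        # hand computation: 12/(4*3*4) * (16+64+144) - 3*4*4 = 8.0
        y = np.array([[1.0, 2.0, 3.0]] * 4) + np.arange(4)[:, None] * 10
        rep = friedman(ConditionMatrix(y, ("a", "b", "c")))
        assert rep.statistic == pytest.approx(8.0, abs=1e-12)
        assert rep.df == (2,)

    def test_permutation_invariance(self):
        m = random_matrix(seed=8)
        perm = ConditionMatrix(m.values[:, ::-1], m.conditions[::-1])
        assert friedman(m).statistic == pytest.approx(
            friedman(perm).statistic, abs=1e-12
        )

    def test_matches_scipy(self):
        m = random_matrix(n=9, k=4, seed=9)
        chi2, p = stats.friedmanchisquare(*[m.values[:, j] for j in range(4)])
        rep = friedman(m)
        assert rep.statistic == pytest.approx(chi2)
        assert rep.p == pytest.approx(p)


class TestBonferroni:
    def test_pair_count(self):
        m = random_matrix(k=5, seed=10)
        table = bonferroni_posthoc(m)
        assert len(table) == 5 * 4 // 2

    def test_adjustment_definition(self):
        m = random_matrix(k=4, seed=11)
        table = bonferroni_posthoc(m)
        for _, row in table.iterrows():
            assert row.p_adjusted == pytest.approx(min(1.0, row.p_raw * len(table)))

    def test_single_pair_unchanged(self):
        m = random_matrix(k=3, seed=12)
        table = bonferroni_posthoc(m, pairs=[("c0", "c1")])
        assert table.iloc[0].p_adjusted == pytest.approx(table.iloc[0].p_raw)

    def test_matches_scipy_ttest(self):
        m = random_matrix(k=3, seed=13)
        table = bonferroni_posthoc(m, pairs=[("c0", "c2")])
        t, p = stats.ttest_rel(m.values[:, 0], m.values[:, 2])
        assert table.iloc[0].statistic == pytest.approx(t)
        assert table.iloc[0].p_raw == pytest.approx(p)

    def test_zero_variance_flagged(self):
        y = random_matrix(k=3, seed=14).values
        y[:, 1] = y[:, 0]
        m = ConditionMatrix(y, ("a", "b", "c"))
        table = bonferroni_posthoc(m)
        row = table[(table.a == "a") & (table.b == "b")].iloc[0]
        assert row.degenerate
        assert np.isnan(row.p_adjusted)

    def test_wilcoxon_branch(self):
        m = random_matrix(k=3, seed=15)
        table = bonferroni_posthoc(m, method="wilcoxon")
        assert len(table) == 3
        assert table.p_raw.between(0, 1).all()


class TestFullReport:
    def test_emits_expected_tests(self):
        m = random_matrix(n=10, k=4, seed=16)
        reports, text = full_report(m, header="demo")
        names = [r.test for r in reports]
        assert names.count("shapiro_wilk") == 4
        assert names[-1] in ("rm_anova_oneway", "friedman")
        assert "repeated-measures subject: split index" in text
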