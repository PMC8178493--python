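"""Validation-statistics tests: SHI scoring, reliability, and the test battery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apeqol.validation import (
    ClinicalProfile,
    chi_square,
    cronbach_alpha,
    fisher_exact,
    mann_whitney,
    mixed_prepost,
    pearson,
    score_shi,
    shi_table,
    t_test,
    trend_regression,
    two_way_anova,
)


class TestScoreShi:
    def test_all_zero(self):
        rec = score_shi([0] * 30)
        assert (rec.total, rec.speech, rec.psychosocial) == (0, 0, 0)

    def test_all_four(self):
        rec = score_shi([4] * 30)
        assert rec.speech == 56 and rec.psychosocial == 56
        assert rec.total == 120

    def test_all_ones(self):
        rec = score_shi([1] * 30)
        assert rec.total == 30

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="30"):
            score_shi([1] * 29)

    def test_out_of_range_rejected(self):
        items = [1] * 30
        items[4] = 5
        with pytest.raises(ValueError, match="scale"):
            score_shi(items)

    def test_domain_permutation_invariance(self):
        rng = np.random.default_rng(0)
        items = rng.integers(0, 5, 30)
        rec = score_shi(items)
        shuffled = items.copy()
        shuffled[:14] = rng.permutation(items[:14])  # within the speech domain
        rec2 = score_shi(shuffled)
        assert rec.speech == rec2.speech and rec.total == rec2.total

    def test_shi_table_matches_scalar_scoring(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(
            rng.integers(0, 5, (5, 30)),
            columns=[f"item_{i:02d}" for i in range(1, 31)],
            index=[f"s{i}" for i in range(5)],
        )
        table = shi_table(mat)
        assert table.loc["s0", "shi_total"] == score_shi(mat.loc["s0"].to_numpy()).total


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        # tau-equivalent items (equal variance, r = 1) give alpha exactly 1
        base = np.array([1.0, 2.0, 5.0, 7.0])
        mat = np.column_stack([base, base + 3, base - 1])
        assert cronbach_alpha(mat) == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_two_items(self):
        mat = np.array([[1, 2], [2, 1], [3, 4], [4, 3]], dtype=float)
        assert cronbach_alpha(mat) == pytest.approx(0.75, abs=1e-12)

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(0, 1, (1000, 30))
        assert abs(cronbach_alpha(mat)) < 0.1

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(0, 1, (50, 10))
        assert cronbach_alpha(mat + 7.0) == pytest.approx(cronbach_alpha(mat), abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        latent = rng.normal(0, 1, 60)
        mat = latent[:, None] + rng.normal(0, 0.8, (60, 8))
        expected = pg.cronbach_alpha(pd.DataFrame(mat))[0]
        assert cronbach_alpha(mat) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_missing(self):
        assert np.isnan(cronbach_alpha(np.ones((5, 4))))


def _fisher_enumeration(table):
    """Independent oracle: enumerate the hypergeometric support and sum the
    probabilities of tables no more likely than the observed one."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    probs = {x: stats.hypergeom.pmf(x, n, r1, c1) for x in support}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-10))


class TestContingency:
    def test_reconstruction_balance_table(self):
        # cohort-balance check: 18/2 vs 9/4 reconstructed by gender
        out = fisher_exact([[18, 2], [9, 4]])
        assert out["p"] == pytest.approx(0.182, abs=5e-4)
        assert out["p"] == pytest.approx(_fisher_enumeration([[18, 2], [9, 4]]), abs=1e-10)

    def test_flap_balance_table(self):
        out = fisher_exact([[15, 3], [8, 1]])
        assert out["p"] > 0.999
        assert out["p"] == pytest.approx(_fisher_enumeration([[15, 3], [8, 1]]), abs=1e-10)

    def test_fisher_agrees_with_enumeration_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            table = rng.integers(0, 11, (2, 2))
            if table.sum() == 0 or table.sum() > 40:
                continue
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            ours = fisher_exact(table)["p"]
            assert ours == pytest.approx(_fisher_enumeration(table), abs=1e-9)

    def test_chi_square_runs(self):
        out = chi_square([[10, 5], [8, 7], [3, 9]])
        assert out["df"] == 2
        assert 0 <= out["p"] <= 1

    def test_fisher_requires_2x2(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestTwoSample:
    def test_mann_whitney_exact_enumeration(self):
        # U = 0; exact one-tailed p = 1 / C(6,3) = 0.05
        out = mann_whitney([1, 2, 3], [4, 5, 6], tails=1, alternative="less")
        assert out["statistic"] == 0.0
        assert out["p"] == pytest.approx(0.05, abs=1e-12)
        assert out["method"] == "exact"

    def test_mann_whitney_large_uses_asymptotic(self):
        rng = np.random.default_rng(0)
        out = mann_whitney(rng.normal(0, 1, 30), rng.normal(0.5, 1, 30))
        assert out["method"] == "asymptotic"

    def test_t_test_zero_variance_missing(self):
        out = t_test([1, 1, 1], [1, 1, 1])
        assert np.isnan(out["p"])

    def test_pearson_zero_variance_missing(self):
        out = pearson([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(out["p"])

    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1, 12)
        ours = t_test(x, y, paired=True)
        t, p = stats.ttest_rel(x, y)
        assert ours["statistic"] == pytest.approx(t)
        assert ours["p"] == pytest.approx(p)


class TestTrendRegression:
    def test_exact_line(self):
        out = trend_regression([0.90, 0.95, 1.00, 1.05], [1, 2, 3, 4])
        assert out["slope"] == pytest.approx(0.05, abs=1e-12)
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_null_coverage(self):
        # slope CI covers 0 in about 95% of null replicates
        rng = np.random.default_rng(0)
        t = np.tile([1, 2, 3, 4], 100)
        covered = 0
        for _ in range(200):
            y = rng.normal(0, 1, len(t))
            lo, hi = trend_regression(y, t)["ci95"]
            covered += lo <= 0 <= hi
        assert 0.92 <= covered / 200 <= 0.98

    def test_constant_outcome_degenerate(self):
        out = trend_regression([1.0] * 8, [1, 2, 3, 4] * 2)
        assert out["degenerate"]
        assert out["slope"] == 0.0 and out["r_squared"] == 0.0

    def test_needs_three_t_classes(self):
        with pytest.raises(ValueError):
            trend_regression([1, 2, 3, 4], [1, 1, 2, 2])

    def test_generator_stage_trend_recovered(self):
        # pre-op FCR rises with T class at the default calibration
        from apeqol.synthetic import CohortConfig, simulate_cohort

        hits = 0
        for s in range(15):
            c = simulate_cohort(CohortConfig(seed=40 + s))
            pre = c.sessions[
                (c.sessions.cohort == "patient") & (c.sessions.timepoint == "pre")
            ]
            out = trend_regression(pre.true_fcr, pre.t_class)
            hits += out["slope"] > 0 and out["p"] < 0.05
        assert hits >= 14  # >= 90%


class TestTwoWayAnova:
    def test_additive_effect_on_a_only(self):
        a = np.repeat(["lo", "hi"], 10)
        b = np.tile(np.repeat(["x", "y"], 5), 2)
        y = np.where(a == "hi", 1.0, 0.0)
        table = two_way_anova(y, a, b)
        assert table.loc["A", "PR(>F)"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["B", "PR(>F)"] == pytest.approx(1.0)
        assert table.loc["AxB", "PR(>F)"] == pytest.approx(1.0)

    def test_planted_interaction_only(self):
        rng = np.random.default_rng(0)
        a = np.repeat(["a1", "a2"], 40)
        b = np.tile(np.repeat(["b1", "b2"], 20), 2)
        y = np.where((a == "a2") & (b == "b2"), 1.0, 0.0) - 0.25
        # sum-to-zero interaction contrast only after centering both mains:
        y = np.where((a == "a2") ^ (b == "b2"), -0.5, 0.5) + rng.normal(0, 0.1, 80)
        table = two_way_anova(y, a, b)
        assert table.loc["AxB", "PR(>F)"] < 1e-6
        assert table.loc["A", "PR(>F)"] > 0.05
        assert table.loc["B", "PR(>F)"] > 0.05

    def test_unbalanced_design_handled(self):
        rng = np.random.default_rng(1)
        a = np.array(["a1"] * 30 + ["a2"] * 10)
        b = np.tile(["b1", "b2"], 20)
        y = rng.normal(0, 1, 40)
        table = two_way_anova(y, a, b)
        assert set(table.index) == {"A", "B", "AxB", "Residual"}

    def test_empty_cell_named(self):
        a = ["a1"] * 4 + ["a2"] * 2
        b = ["b1", "b2"] * 2 + ["b1", "b1"]
        with pytest.raises(ValueError, match="a2.*b2|empty cell"):
            two_way_anova([1, 2, 3, 4, 5, 6], a, b)


def _prepost_frame(n_subj, levels, effects=None, noise=1.0, seed=0, drop_post=()):
    """Balanced pre/post data with a subject random intercept."""
    rng = np.random.default_rng(seed)
    rows = []
    effects = effects or {}
    for i in range(n_subj):
        lev = levels[i % len(levels)]
        intercept = rng.normal(0, 1)
        for tp in ("pre", "post"):
            if tp == "post" and i in drop_post:
                continue
            y = intercept + rng.normal(0, noise)
            if tp == "post":
                y += effects.get(lev, 0.0)
            rows.append(dict(subject=f"s{i}", timepoint=tp, level=lev, y=y))
    return pd.DataFrame(rows)


class TestMixedPrePost:
    def test_planted_interaction_in_one_level(self):
        df = _prepost_frame(
            24, ["T1", "T2", "T3", "T4"], effects={"T4": 3.0}, noise=0.05, seed=1
        )
        res = mixed_prepost(df, "y", "level")
        effects = res.effects.set_index("effect")
        assert effects.loc["time x level", "p"] < 1e-6
        sig = res.pairwise.set_index("level")["significant"]
        assert sig["T4"]
        assert not sig[["T1", "T2", "T3"]].any()

    def test_reduces_to_paired_t_test(self):
        # one factor level, complete data: same p as the paired t-test
        df = _prepost_frame(15, ["only"], effects={"only": 0.6}, noise=0.8, seed=2)
        res = mixed_prepost(df, "y", "level")
        wide = df.pivot(index="subject", columns="timepoint", values="y")
        t, p = stats.ttest_rel(wide["post"], wide["pre"])
        p_mixed = res.effects.set_index("effect").loc["time", "p"]
        assert p_mixed == pytest.approx(p, rel=1e-4)

    def test_dropout_tolerated(self):
        df = _prepost_frame(12, ["a", "b"], effects={"b": 2.0}, seed=3, drop_post=(5,))
        res = mixed_prepost(df, "y", "level")
        assert len(res.pairwise) == 2

    def test_single_subject_level_excluded(self, caplog):
        df = _prepost_frame(9, ["a", "b", "lone"], seed=4)
        df = df[~((df.level == "lone") & (df.subject != "s2"))]
        with caplog.at_level("WARNING"):
            res = mixed_prepost(df, "y", "level")
        assert "lone" in res.excluded_levels
        assert set(res.pairwise.level) == {"a", "b"}

    def test_generator_postop_increase_power(self):
        # subtotal/total glossectomy adds a large post-op FCR shift
        from apeqol.synthetic import CohortConfig, simulate_cohort

        hits = 0
        for s in range(10):
            c = simulate_cohort(CohortConfig(seed=60 + s))
            pat = c.sessions[c.sessions.cohort == "patient"].rename(
                columns={"true_fcr": "FCR"}
            )
            res = mixed_prepost(pat, "FCR", "resection")
            row = res.pairwise.set_index("level").loc["STG/TG"]
            hits += bool(row["significant"] and row["post_minus_pre"] > 0)
        assert hits >= 8  # power >= 80%


class TestClinicalProfile:
    def test_control_cannot_have_resection(self):
        with pytest.raises(ValueError):
            ClinicalProfile(age=50, gender="male", t_class=0, resection="PG")

    def test_flap_implies_reconstruction(self):
        with pytest.raises(ValueError):
            ClinicalProfile(age=50, gender="male", t_class=2, flap="ALT")

    def test_valid_patient(self):
        p = ClinicalProfile(
            age=55, gender="female", t_class=3, resection="HG", reconstruction=True, flap="ALT"
        )
        assert p.t_class == 3
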