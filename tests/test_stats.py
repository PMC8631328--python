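import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from fatiguewave.errors import DegenerateInputError, SchemaError
from fatiguewave.stats import (
    WithinSubjectTable,
    lsd_posthoc,
    mauchly,
    pearson,
    rm_anova_oneway,
    rm_anova_twoway,
)
from oracles import naive_rm_anova_oneway, naive_rm_anova_twoway


class TestWithinSubjectTable:
    def test_from_long_one_factor(self):
        df = pd.DataFrame({
            "subj": [0, 0, 1, 1], "cond": ["a", "b", "a", "b"],
            "y": [1.0, 2.0, 3.0, 4.0],
        })
        t = WithinSubjectTable.from_long(df, dv="y", within="cond", subject="subj")
        assert t.values.shape == (2, 2)
        assert t.factors["cond"] == ["a", "b"]

    def test_incomplete_design_rejected(self):
        df = pd.DataFrame({
            "subj": [0, 0, 1], "cond": ["a", "b", "a"], "y": [1.0, 2.0, 3.0],
        })
        with pytest.raises(SchemaError, match="crossed"):
            WithinSubjectTable.from_long(df, dv="y", within="cond", subject="subj")

    def test_single_subject_rejected(self):
        with pytest.raises(SchemaError):
            WithinSubjectTable(values=np.zeros((1, 4)))


class TestMauchly:
    def test_two_levels_trivially_spherical(self):
        res = mauchly(np.random.default_rng(0).standard_normal((10, 2)))
        assert res.W == 1.0 and res.p == 1.0

    def test_compound_symmetry_w_near_one(self):
        # exchangeable covariance satisfies sphericity: W ~ 1, p not small
        rng = np.random.default_rng(1)
        n, k = 500, 4
        shared = rng.standard_normal((n, 1))
        data = shared + rng.standard_normal((n, k))
        res = mauchly(data)
        assert res.W > 0.95
        assert res.p > 0.01

    def test_dominant_eigenvalue_w_near_zero(self):
        rng = np.random.default_rng(2)
        n, k = 60, 4
        factor = rng.standard_normal((n, 1)) @ np.array([[1.0, -1.0, 0.5, -0.5]])
        data = factor + 0.01 * rng.standard_normal((n, k))
        res = mauchly(data)
        assert res.W < 0.05

    def test_insufficient_subjects_returns_diagnostic(self):
        res = mauchly(np.random.default_rng(3).standard_normal((3, 6)))
        assert np.isnan(res.W) and np.isnan(res.p)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        data = rng.standard_normal((12, 5))
        long = pd.DataFrame({
            "y": data.ravel(),
            "subj": np.repeat(np.arange(12), 5),
            "cond": np.tile(np.arange(5), 12),
        })
        ours = mauchly(data)
        theirs = pg.sphericity(long, dv="y", within="cond", subject="subj")
        assert ours.W == pytest.approx(theirs.W, rel=1e-9)
        assert ours.p == pytest.approx(theirs.pval, rel=1e-9)


class TestOneWayRMANOVA:
    def test_identical_conditions_give_zero_f(self):
        data = np.tile(np.arange(6.0)[:, None], (1, 4))
        res = rm_anova_oneway(data)
        assert res.F == 0.0 and res.p == 1.0

    def test_k2_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((12, 2))
        res = rm_anova_oneway(data)
        t, _ = sp_stats.ttest_rel(data[:, 0], data[:, 1])
        assert res.F == pytest.approx(t**2, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((6, 4)) + rng.standard_normal((6, 1))
        res = rm_anova_oneway(data)
        f_o, eps_o, p_o = naive_rm_anova_oneway(data)
        assert res.F == pytest.approx(f_o, abs=1e-9)
        assert res.epsilon_gg == pytest.approx(eps_o, abs=1e-9)
        assert res.p == pytest.approx(p_o, abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        data = rng.standard_normal((9, 6))
        long = pd.DataFrame({
            "y": data.ravel(),
            "subj": np.repeat(np.arange(9), 6),
            "cond": np.tile(np.arange(6), 9),
        })
        res = rm_anova_oneway(data)
        theirs = pg.rm_anova(long, dv="y", within="cond", subject="subj",
                             correction=True)
        assert res.F == pytest.approx(float(theirs["F"].iloc[0]), rel=1e-9)
        assert res.epsilon_gg == pytest.approx(float(theirs["eps"].iloc[0]),
                                               rel=1e-9)
        assert res.p == pytest.approx(float(theirs["p_GG_corr"].iloc[0]),
                                      rel=1e-9)

    def test_epsilon_bounds_and_sphericity(self):
        rng = np.random.default_rng(7)
        k = 5
        data = rng.standard_normal((200, k))
        res = rm_anova_oneway(data)
        assert 1.0 / (k - 1) - 1e-12 <= res.epsilon_gg <= 1.0 + 1e-12
        # exactly spherical population covariance: epsilon estimate near 1
        assert res.epsilon_gg > 0.9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((8, 5))
        res = rm_anova_oneway(data)
        perm = rng.permutation(8)
        res_p = rm_anova_oneway(data[perm][:, rng.permutation(5)])
        assert res.F == pytest.approx(res_p.F, rel=1e-9)
        assert res.p == pytest.approx(res_p.p, rel=1e-9)

    def test_zero_error_infinite_f_diagnostic(self):
        # perfectly additive subject + condition structure, no noise
        data = np.arange(4.0)[None, :] + np.arange(5.0)[:, None]
        res = rm_anova_oneway(data)
        assert np.isinf(res.F) and res.p == 0.0


class TestTwoWayRMANOVA:
    def test_constant_channel_dimension_zero_f(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal((7, 1, 5))
        data = np.repeat(base, 4, axis=1)  # identical across 'channels'
        res = rm_anova_twoway(data)["channel"]
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_additive_construction_zero_interaction(self):
        subj = np.arange(6.0)[:, None, None]
        time = np.arange(5.0)[None, None, :]
        data = np.broadcast_to(subj + time, (6, 4, 5)).copy()
        res = rm_anova_twoway(data)
        assert res["channel*timepoint"].F == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((9, 4, 6))
        res = rm_anova_twoway(data)
        oracle = naive_rm_anova_twoway(data)
        assert res["channel"].F == pytest.approx(oracle["a"][0], abs=1e-8)
        assert res["timepoint"].F == pytest.approx(oracle["b"][0], abs=1e-8)
        assert res["channel*timepoint"].F == pytest.approx(oracle["ab"][0],
                                                           abs=1e-8)

    def test_incomplete_crossing_rejected(self):
        with pytest.raises(SchemaError):
            rm_anova_twoway(np.zeros((5, 4)))


class TestLSD:
    def test_all_pairs_present(self):
        rng = np.random.default_rng(10)
        table = lsd_posthoc(rng.standard_normal((9, 6)))
        assert len(table) == 15  # 6*5/2

    def test_identical_pair(self):
        data = np.random.default_rng(11).standard_normal((8, 2))
        data[:, 1] = data[:, 0]
        row = lsd_posthoc(data).iloc[0]
        assert row["mean_diff"] == 0.0 and row["p_uncorrected"] == 1.0

    def test_t_squared_equals_pairwise_f(self):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((10, 4))
        table = lsd_posthoc(data)
        for _, row in table.iterrows():
            i = int(row["level_a"]); j = int(row["level_b"])
            f_pair = rm_anova_oneway(data[:, [i, j]]).F
            assert row["t"] ** 2 == pytest.approx(f_pair, abs=1e-9)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r, _ = pearson(np.array([1, 2, 3, 4]), np.array([1, 3, 2, 4]))
        assert r == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson(np.ones(5), np.arange(5.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.arange(4.0), np.arange(5.0))
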