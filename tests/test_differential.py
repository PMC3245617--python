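"""Two-class differential analysis: SAM statistic, permutation machinery,
t-tests, fold changes and Benjamini-Hochberg adjustment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirlineage import (bh_adjust, differential_analysis, fold_change,
                        sam_permutation, sam_statistic, select_differential,
                        ttest_two_class)
from mirlineage.errors import GroupingError, ValidationError

from conftest import make_matrix, make_probe_map

C1 = ["s0", "s1"]
C2 = ["s2", "s3"]


class TestSamStatistic:
    def test_hand_worked_pooled_se(self):
        # class1=[2,4], class2=[1,3]: diff 1, pooled var 2, s = sqrt(2) -> d
        m = make_matrix([[2.0, 4.0, 1.0, 3.0]])
        out, s0 = sam_statistic(m, C1, C2, s0=0)
        assert out["s"].iloc[0] == pytest.approx(np.sqrt(2))
        assert out["d"].iloc[0] == pytest.approx(1 / np.sqrt(2))

    def test_s0_zero_equals_t_statistic(self, preprocessed):
        norm = preprocessed[0]
        c1 = norm.sample_ids[:10]
        c2 = norm.sample_ids[10:25]
        d, _ = sam_statistic(norm, c1, c2, s0=0)
        t = ttest_two_class(norm, c1, c2)["t"]
        np.testing.assert_allclose(d["d"], t, rtol=1e-10)

    def test_equal_means_give_zero_d(self):
        m = make_matrix([[1.0, 3.0, 2.0, 2.0]])
        for s0 in (0.0, 0.5, "auto"):
            out, _ = sam_statistic(m, C1, C2, s0=s0)
            assert out["d"].iloc[0] == 0.0

    def test_auto_s0_is_median_standard_error(self, preprocessed):
        norm = preprocessed[0]
        c1, c2 = norm.sample_ids[:8], norm.sample_ids[8:20]
        out, s0 = sam_statistic(norm, c1, c2, s0="auto")
        assert s0 == pytest.approx(float(np.median(out["s"])))

    def test_overlapping_classes_raise(self):
        m = make_matrix(np.ones((2, 4)))
        with pytest.raises(GroupingError):
            sam_statistic(m, ["s0", "s1"], ["s1", "s2"])


class TestSamPermutation:
    def test_exhaustive_p_matches_enumeration_oracle(self, caplog):
        """Single probe, n1 = n2 = 3: with fewer distinct label assignments
        than requested permutations the exact permutation p is returned."""
        rng = np.random.default_rng(5)
        vals = np.array([[4.1, 3.8, 4.5, 1.2, 0.9, 1.5]])
        m = make_matrix(vals)
        c1, c2 = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        with caplog.at_level("WARNING"):
            out = sam_permutation(m, c1, c2, n_perm=100, seed=0, s0=0)
        assert "exhaustive" in caplog.text

        # independent oracle: enumerate all C(6,3) splits, equal-var t
        x = vals[0]
        d_obs = stats.ttest_ind(x[:3], x[3:]).statistic
        count = 0
        splits = list(itertools.combinations(range(6), 3))
        for cols in splits:
            rest = [i for i in range(6) if i not in cols]
            t = stats.ttest_ind(x[list(cols)], x[rest]).statistic
            if abs(t) >= abs(d_obs) - 1e-12:
                count += 1
        assert out["perm_p"].iloc[0] == pytest.approx(count / len(splits))

    def test_extreme_probe_gets_minimum_p_and_zero_q(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=(80, 12))
        planted = np.concatenate([np.full(6, 8.0), np.zeros(6)])[None, :]
        m = make_matrix(np.vstack([planted, null + 0.01 * rng.normal(size=(80, 12))]))
        c1, c2 = [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)]
        out = sam_permutation(m, c1, c2, n_perm=200, seed=1)
        top = out.iloc[0]
        assert top["d"] == out["d"].abs().max()
        assert top["perm_q"] == 0.0
        assert top["perm_p"] <= 1.5 / 201

    def test_q_monotone_in_abs_d(self, preprocessed):
        norm = preprocessed[0]
        sub = norm.subset_probes(norm.probe_ids[:150])
        c1, c2 = norm.sample_ids[:8], norm.sample_ids[8:20]
        out = sam_permutation(sub, c1, c2, n_perm=150, seed=3)
        ordered = out.sort_values("d", key=np.abs, ascending=False)
        assert (np.diff(ordered["perm_q"]) >= -1e-12).all()

    def test_n_perm_floor(self):
        m = make_matrix(np.ones((2, 6)))
        with pytest.raises(ValidationError):
            sam_permutation(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                            n_perm=50)


class TestTTest:
    def test_hand_worked_example(self):
        m = make_matrix([[2.0, 4.0, 1.0, 3.0]])
        out = ttest_two_class(m, C1, C2)
        assert out["t"].iloc[0] == pytest.approx(1 / np.sqrt(2))
        assert out["ttest_p"].iloc[0] == pytest.approx(
            2 * stats.t.sf(1 / np.sqrt(2), 2))
        # and agrees with the reference implementation
        ref = stats.ttest_ind([2.0, 4.0], [1.0, 3.0])
        assert out["t"].iloc[0] == pytest.approx(ref.statistic)
        assert out["ttest_p"].iloc[0] == pytest.approx(ref.pvalue)

    def test_identical_classes_give_t0_p1(self):
        m = make_matrix([[5.0, 5.0, 5.0, 5.0]])
        out = ttest_two_class(m, C1, C2)
        assert out["t"].iloc[0] == 0.0
        assert out["ttest_p"].iloc[0] == 1.0
        assert not out["undefined"].iloc[0]

    def test_zero_variance_unequal_means_flagged(self):
        m = make_matrix([[5.0, 5.0, 2.0, 2.0]])
        out = ttest_two_class(m, C1, C2)
        assert out["undefined"].iloc[0]
        assert np.isnan(out["ttest_p"].iloc[0])

    def test_class_swap_negates_t_keeps_p(self):
        m = make_matrix(np.random.default_rng(2).normal(size=(20, 4)))
        a = ttest_two_class(m, C1, C2)
        b = ttest_two_class(m, C2, C1)
        np.testing.assert_allclose(a["t"], -b["t"])
        np.testing.assert_allclose(a["ttest_p"], b["ttest_p"])


class TestFoldChange:
    @pytest.mark.parametrize("m1,m2,fc,direction", [
        (4.0, 1.0, 8.0, "up-in-class1"),
        (2.0, 2.0, 1.0, "up-in-class1"),
        (1.0, 4.0, 8.0, "up-in-class2"),
    ])
    def test_reported_ratio_and_direction(self, m1, m2, fc, direction):
        m = make_matrix([[m1, m1, m2, m2]])
        out = fold_change(m, C1, C2)
        assert out["fold_change"].iloc[0] == pytest.approx(fc)
        assert out["direction"].iloc[0] == direction


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 60))
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1],
                atol=1e-12)

    def test_definitional_properties(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(1e-8, 1.0, size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
            with pytest.raises(ValidationError):
                bh_adjust(bad)


class TestSelectDifferential:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["probe", "feature", "perm_p",
                                           "perm_q", "direction"])

    def test_default_cutoffs(self):
        res = self._frame([("p1", "f1", 0.02, 0.0, "up-in-class1"),
                           ("p2", "f2", 0.005, 0.0, "up-in-class1"),
                           ("p3", "f2", 0.005, 0.1, "up-in-class1")])
        hits, feats = select_differential(res)
        assert list(hits["probe"]) == ["p2"]        # p=0.02 and q=0.1 excluded
        assert list(feats["feature"]) == ["f2"]
        assert feats["n_probes"].iloc[0] == 1

    def test_empty_result_allowed(self):
        hits, feats = select_differential(self._frame([]))
        assert hits.empty and feats.empty


def test_probe_ranking_s0_zero_equals_t_ranking(preprocessed):
    """With s0 = 0 the SAM pipeline ranks probes exactly like the t statistic."""
    norm = preprocessed[0]
    c1, c2 = norm.sample_ids[:12], norm.sample_ids[12:30]
    d, _ = sam_statistic(norm, c1, c2, s0=0)
    t = ttest_two_class(norm, c1, c2)["t"]
    assert list(np.argsort(-np.abs(d["d"].to_numpy()), kind="stable")) == \
        list(np.argsort(-np.abs(t.to_numpy()), kind="stable"))
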