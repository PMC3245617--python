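"""miRNA-mRNA integration: sample matching, the Pearson screen, Fisher
enrichment with its enumeration oracle, consensus targets and the
correlation-distribution shift."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirlineage import (consensus_targets, correlation_shift,
                        declare_left_shift, fisher_enrichment, integrate_all,
                        match_samples, pearson_screen)
from mirlineage.errors import InsufficientOverlapError, ValidationError
from mirlineage.integration import EnrichmentResult

from conftest import make_matrix


def enumeration_fisher_p(a, b, c, d):
    """Exact one-sided enrichment p by summing hypergeometric point masses
    over all tables with the observed margins and a' >= a."""
    n_genes = a + b + c + d
    n_target = a + c
    n_negative = a + b
    total = Fraction(comb(n_genes, n_negative))
    p = Fraction(0)
    for a2 in range(a, min(n_target, n_negative) + 1):
        b2 = n_negative - a2
        if b2 > n_genes - n_target:
            continue
        p += Fraction(comb(n_target, a2) * comb(n_genes - n_target, b2))
    return p / total


class TestMatchSamples:
    def test_identical_sample_sets(self):
        a = make_matrix(np.ones((2, 6)))
        b = make_matrix(np.zeros((3, 6)))
        ma, mb = match_samples(a, b)
        assert ma.sample_ids == mb.sample_ids == a.sample_ids

    def test_intersection_with_missing_samples(self, default_dataset):
        mirna, mrna, *_ = default_dataset
        assert mirna.n_samples == 47 and mrna.n_samples == 45
        ma, mb = match_samples(mirna, mrna)
        assert ma.sample_ids == mb.sample_ids
        assert len(ma.sample_ids) == 45

    def test_disjoint_sets_raise(self):
        a = make_matrix(np.ones((2, 6)), samples=[f"a{i}" for i in range(6)])
        b = make_matrix(np.ones((2, 6)), samples=[f"b{i}" for i in range(6)])
        with pytest.raises(InsufficientOverlapError):
            match_samples(a, b)


class TestPearsonScreen:
    def test_hand_worked_r(self):
        # the classic 3/5 covariance pattern, duplicated to satisfy n >= 5
        x = pd.Series([1.0, 2, 3, 4, 1, 2, 3, 4],
                      index=[f"s{i}" for i in range(8)])
        y = make_matrix([[2.0, 1, 4, 3, 2, 1, 4, 3]])
        out = pearson_screen(x, y)
        assert out["r"].iloc[0] == pytest.approx(0.6)
        ref = stats.pearsonr(x.to_numpy(), y.values.iloc[0].to_numpy())
        assert out["p"].iloc[0] == pytest.approx(ref.pvalue)

    def test_perfect_anticorrelation_is_negative(self):
        x = pd.Series(np.arange(6.0), index=[f"s{i}" for i in range(6)])
        y = make_matrix([-np.arange(6.0) + 3.0])
        out = pearson_screen(x, y)
        assert out["r"].iloc[0] == pytest.approx(-1.0)
        assert out["p"].iloc[0] < 1e-12
        assert bool(out["is_negative"].iloc[0])

    def test_weak_negative_fails_the_conjunction(self):
        # weak downward trend drowned in an alternating pattern: r < 0 but
        # far from the p <= 0.001 screen at n = 8
        x = pd.Series(np.arange(8.0), index=[f"s{i}" for i in range(8)])
        y = (-0.2 * x.to_numpy()
             + np.array([2.0, -2.0] * 4))[None, :]
        out = pearson_screen(x, make_matrix(y))
        assert -0.9 < out["r"].iloc[0] < 0
        assert out["p"].iloc[0] > 0.001
        assert not bool(out["is_negative"].iloc[0])

    def test_constant_probe_excluded(self, caplog):
        x = pd.Series(np.arange(6.0), index=[f"s{i}" for i in range(6)])
        y = make_matrix([[1.0] * 6, list(-np.arange(6.0))])
        with caplog.at_level("WARNING"):
            out = pearson_screen(x, y)
        assert bool(out["excluded"].iloc[0])
        assert np.isnan(out["r"].iloc[0])
        assert not bool(out["is_negative"].iloc[0])

    def test_p_matches_permutation_null(self):
        """The t-transform p agrees with a label-shuffle permutation p
        within Monte-Carlo error (n = 20)."""
        rng = np.random.default_rng(12)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        r_obs = stats.pearsonr(x, y).statistic
        xs = pd.Series(x, index=[f"s{i}" for i in range(20)])
        out = pearson_screen(xs, make_matrix(y[None, :]))
        n_shuffle = 10000
        count = 0
        for _ in range(n_shuffle):
            r = stats.pearsonr(rng.permutation(x), y).statistic
            if abs(r) >= abs(r_obs):
                count += 1
        p_perm = (count + 1) / (n_shuffle + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_shuffle)
        assert abs(out["p"].iloc[0] - p_perm) < 3 * se + 1e-4


class TestFisherEnrichment:
    def _screen(self, neg_flags, probes=None):
        n = len(neg_flags)
        probes = probes or [f"m{i}" for i in range(n)]
        return pd.DataFrame({
            "r": [-0.5 if f else 0.1 for f in neg_flags],
            "p": [1e-5 if f else 0.5 for f in neg_flags],
            "is_negative": neg_flags,
            "excluded": [False] * n,
        }, index=probes)

    def test_two_by_two_hand_example(self):
        # a=2, b=0, c=0, d=2 -> one-sided p = 1/C(4,2) = 1/6
        screen = self._screen([True, True, False, False])
        gene_map = pd.Series([f"g{i}" for i in range(4)],
                             index=[f"m{i}" for i in range(4)])
        a, b, c, d, p, sig, cands = fisher_enrichment(
            screen, {"g0", "g1"}, gene_map)
        assert (a, b, c, d) == (2, 0, 0, 2)
        assert p == pytest.approx(1 / 6)
        assert cands == {"g0", "g1"}

    def test_no_negative_genes_gives_p_one(self):
        screen = self._screen([False] * 6)
        gene_map = pd.Series([f"g{i}" for i in range(6)],
                             index=[f"m{i}" for i in range(6)])
        *_, p, sig, cands = fisher_enrichment(screen, {"g0", "g1"}, gene_map)
        assert p == 1.0 and not sig and cands == frozenset()

    def test_gene_level_collapse_any_probe(self):
        # two probes of one gene, one negative -> gene negative once
        screen = self._screen([True, False, False],
                              probes=["m0a", "m0b", "m1"])
        gene_map = pd.Series(["g0", "g0", "g1"], index=["m0a", "m0b", "m1"])
        a, b, c, d, *_ = fisher_enrichment(screen, {"g1"}, gene_map)
        assert a + b + c + d == 2                  # genes, not probes
        assert (a, b) == (0, 1)

    def test_empty_mapped_targets_raise(self):
        screen = self._screen([True, False])
        gene_map = pd.Series(["g0", "g1"], index=["m0", "m1"])
        with pytest.raises(ValidationError):
            fisher_enrichment(screen, {"not-a-gene"}, gene_map)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            a, b, c, d = (int(rng.integers(0, 13)) for _ in range(4))
            if a + b + c + d == 0:
                continue
            ours = float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c,
                                            a + b))
            oracle = float(enumeration_fisher_p(a, b, c, d))
            assert abs(min(ours, 1.0) - oracle) < 1e-12
            # and agrees with the library's Fisher implementation
            ref = stats.fisher_exact([[a, b], [c, d]],
                                     alternative="greater")[1]
            assert min(ours, 1.0) == pytest.approx(ref, abs=1e-12)


class TestConsensusTargets:
    def _res(self, genes):
        return EnrichmentResult(mirna_probe="p", mirna_feature="m",
                                a=0, b=0, c=0, d=0, fisher_p=1.0,
                                significant=False,
                                candidate_genes=frozenset(genes))

    def test_intersection_across_probes(self):
        out = consensus_targets([self._res({"A", "B", "C"}),
                                 self._res({"B", "C", "D"})])
        assert out == {"B", "C"}

    def test_single_probe_identity(self):
        assert consensus_targets([self._res({"A", "B"})]) == {"A", "B"}

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            consensus_targets([])


class TestCorrelationShift:
    def test_identical_distributions_give_zero_d(self):
        r = np.array([-0.5, 0.0, 0.5])
        d, p, curve = correlation_shift(r, r)
        assert d == 0.0
        assert set(curve["which"]) == {"all", "targets"}

    def test_complete_separation_gives_d_one(self):
        d, p, _ = correlation_shift([-0.5, 0.0, 0.5], [-0.9, -0.8, -0.7])
        assert d == 1.0

    def test_declaration_requires_both_conditions(self):
        rng = np.random.default_rng(5)
        all_r = rng.normal(0, 0.2, size=500)
        slightly = all_r[:4] - 0.01          # mean-shifted but tiny sample
        assert np.mean(slightly) < np.mean(all_r)
        assert not declare_left_shift(all_r, slightly)
        strongly = rng.normal(-0.6, 0.1, size=100)
        assert declare_left_shift(all_r, strongly)


class TestIntegrateAll:
    def test_empty_subset_raises(self, preprocessed, default_dataset):
        norm, _, mrna_f = preprocessed
        _, _, _, pmap, targets, _ = default_dataset
        with pytest.raises(ValidationError):
            integrate_all(norm, mrna_f, pmap, targets, [])

    def test_table_margins_count_screened_genes(self, preprocessed,
                                                default_dataset):
        norm, _, mrna_f = preprocessed
        _, _, _, pmap, targets, truth = default_dataset
        mirnas = sorted(set(targets["mirna"]))[:3]
        enrichment, consensus = integrate_all(norm, mrna_f, pmap, targets,
                                              mirnas)
        gene_map = pmap.set_index("probe")["feature"]
        n_genes = gene_map.reindex(mrna_f.values.index).nunique()
        totals = enrichment[["a", "b", "c", "d"]].sum(axis=1)
        assert (totals == n_genes).all()
        assert set(enrichment["mirna"]) <= set(mirnas)
        # sorted by Fisher p
        assert (np.diff(enrichment["fisher_p"]) >= -1e-15).all()
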