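"""HWE test, Fisher r x 2, Yates chi-square, pair tables and the scan."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hapscan as hs
from oracles import fisher_rx2_enumeration, hwe_exact_enumeration


class TestHWE:
    def test_monomorphic_marker_p_one(self):
        assert hs.hwe_test({(1, 1): 10}).p == 1.0

    def test_biallelic_matches_enumeration_oracle(self):
        counts = {(1, 1): 25, (1, 2): 50, (2, 2): 25}
        res = hs.hwe_test(counts)
        assert res.method == "exact-enumeration"
        assert res.p == pytest.approx(hwe_exact_enumeration(counts), rel=1e-9)

    def test_triallelic_exact_matches_oracle(self):
        counts = {(1, 1): 3, (1, 2): 4, (2, 2): 2, (1, 3): 1, (2, 3): 1, (3, 3): 1}
        res = hs.hwe_test(counts)
        assert res.method == "exact-enumeration"
        assert res.p == pytest.approx(hwe_exact_enumeration(counts), rel=1e-9)

    def test_monte_carlo_within_3_se_of_exact(self):
        counts = {(1, 1): 3, (1, 2): 4, (2, 2): 2, (1, 3): 1, (2, 3): 1, (3, 3): 1}
        exact = hs.hwe_test(counts).p
        mc = hs.hwe_test(counts, enum_limit=1, mc_reps=20_000, seed=3)
        assert mc.method == "monte-carlo"
        assert abs(mc.p - exact) <= 3 * mc.mc_se

    def test_array_input_and_missing_excluded(self):
        res = hs.hwe_test(np.array([[1, 1], [1, 2], [-1, -1], [2, 2]]))
        assert sum(res.genotype_counts.values()) == 3

    def test_strong_deviation_small_p(self):
        # all heterozygotes, no homozygotes: extreme HWE departure
        res = hs.hwe_test({(1, 2): 30})
        assert res.p < 0.01


class TestFisher:
    def test_balanced_table_p_one(self):
        assert hs.fisher_exact_rx2([[5, 5], [5, 5]]).p == pytest.approx(1.0)

    def test_two_extreme_tables(self):
        res = hs.fisher_exact_rx2([[5, 0], [0, 5]])
        assert res.p == pytest.approx(2 / math.comb(10, 5), rel=1e-12)

    def test_3x2_matches_enumeration_oracle(self):
        table = [[6, 1], [3, 4], [1, 5]]
        res = hs.fisher_exact_rx2(table)
        assert res.method == "enumeration"
        assert res.p == pytest.approx(fisher_rx2_enumeration(table), rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_2x2_reduces_to_classical_fisher(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 12, size=(2, 2))
        t[t.sum(axis=0) == 0, :] += 1  # avoid empty columns
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            t = t + 1
        ours = hs.fisher_exact_rx2(t).p
        scipy_p = stats.fisher_exact(t, alternative="two-sided")[1]
        assert ours == pytest.approx(scipy_p, abs=1e-10)

    def test_monte_carlo_agrees_with_enumeration(self):
        table = [[30, 12], [11, 25], [9, 13]]
        exact = hs.fisher_exact_rx2(table).p
        mc = hs.fisher_exact_rx2(table, enum_limit=1, mc_reps=40_000, seed=7)
        assert mc.method == "monte-carlo"
        assert abs(mc.p - exact) <= 4 * mc.mc_se

    @pytest.mark.parametrize("seed", range(6))
    def test_zero_count_row_never_changes_p(self, seed):
        rng = np.random.default_rng(40 + seed)
        t = rng.integers(1, 10, size=(3, 2))
        with_zero = np.vstack([t, [0, 0]])
        assert hs.fisher_exact_rx2(with_zero).p == pytest.approx(
            hs.fisher_exact_rx2(t).p, rel=1e-12
        )

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            hs.fisher_exact_rx2([[1, 0], [2, 0]])   # empty column
        with pytest.raises(ValueError):
            hs.fisher_exact_rx2([[1, -1], [2, 3]])  # negative count
        with pytest.raises(ValueError):
            hs.fisher_exact_rx2([[1, 2]])           # r < 2


class TestChi2:
    def test_yates_zero_when_observed_equals_expected(self):
        chi2, df = hs.yates_chi2([[5, 5], [5, 5]])
        assert chi2 == 0.0 and df == 1

    def test_yates_direct_formula_2x2(self):
        # E = 5 in every cell, |O-E| = 5 -> 4 * (4.5^2 / 5)
        chi2, df = hs.yates_chi2([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(4 * (4.5**2 / 5), rel=1e-12)
        assert df == 1

    def test_yates_3x2_hand_computed(self):
        table = np.array([[8, 2], [4, 6], [3, 7]])
        E = np.outer(table.sum(1), table.sum(0)) / table.sum()
        expect = float((np.maximum(np.abs(table - E) - 0.5, 0) ** 2 / E).sum())
        chi2, df = hs.yates_chi2(table)
        assert chi2 == pytest.approx(expect, rel=1e-12)
        assert df == 2

    def test_pearson_matches_scipy(self):
        table = np.array([[8, 2], [4, 6], [3, 7]])
        chi2, df = hs.pearson_chi2(table)
        expect = stats.chi2_contingency(table, correction=False)[0]
        assert chi2 == pytest.approx(expect, rel=1e-12)


class TestPairTable:
    def test_hand_counted_unambiguous(self):
        # four individuals, two haplotypes, fully phase-unambiguous
        ga = np.array([[1, 1], [1, 1], [2, 2], [2, 2]])
        gb = np.array([[1, 1], [1, 1], [2, 2], [2, 2]])
        model = hs.em_pair(ga, gb)
        groups = np.array(["high", "high", "low", "low"])
        table = hs.build_pair_table(model, ga, gb, groups, min_freq=0.05)
        assert table.haplotypes == [(1, 1), (2, 2)]
        assert table.counts.tolist() == [[4, 0], [0, 4]]
        assert table.testable and table.df == 1

    def test_minor_haplotype_removed(self):
        # haplotype 2-1 occurs once in 26: frequency 0.038 < 5%
        ga = np.array([[1, 1]] * 12 + [[1, 2]])
        gb = np.array([[1, 1]] * 12 + [[1, 1]])
        model = hs.em_pair(ga, gb)
        groups = np.array(["high"] * 6 + ["low"] * 7)
        table = hs.build_pair_table(model, ga, gb, groups, min_freq=0.05)
        assert (2, 1) not in table.haplotypes
        assert table.n_dropped >= 1

    def test_three_major_one_minor_fixture(self):
        rng = np.random.default_rng(7)
        # haplotype pool: three at >=5%, one at 2%
        haps = [(1, 1), (1, 2), (2, 1), (2, 2)]
        probs = [0.5, 0.28, 0.20, 0.02]
        draws = rng.choice(4, size=(50, 2), p=probs)
        ga = np.sort(np.array([[haps[h][0] for h in d] for d in draws]), axis=1)
        gb = np.sort(np.array([[haps[h][1] for h in d] for d in draws]), axis=1)
        model = hs.em_pair(ga, gb)
        groups = np.array(["high"] * 25 + ["low"] * 25)
        table = hs.build_pair_table(model, ga, gb, groups, min_freq=0.05)
        assert len(table.haplotypes) == 3
        assert set(table.haplotypes) == {(1, 1), (1, 2), (2, 1)}
        # rows ordered by descending combined frequency
        assert list(table.retained_freq) == sorted(table.retained_freq, reverse=True)
        # column sums cannot exceed two haplotypes per individual
        assert (table.counts.sum(axis=0) <= 2 * 25).all()


class TestScan:
    def test_identical_groups_p_one(self):
        # same genotype composition in both groups at every marker
        ga = np.array([[1, 1], [2, 2]] * 6)
        n = len(ga)
        ids = [f"i{k}" for k in range(n)]
        gmap = hs.GeneticMap(pd.DataFrame(
            {"marker": ["m1", "m2"], "chromosome": ["1", "1"],
             "position_cm": [0.0, 5.0]}))
        alleles = np.stack([ga, ga], axis=1)
        gm = hs.GenotypeMatrix(ids, ["m1", "m2"], alleles)
        groups = pd.Series(["high"] * 6 + ["low"] * 6, index=ids)
        res = hs.scan(gm, gmap, groups, run_hwe=False)
        assert res.pairs["p"].iloc[0] == pytest.approx(1.0)
        assert not res.pairs["genome_significant"].any()

    def test_fully_unambiguous_fixture_matches_hand_table(self):
        # 12 individuals, 2 markers, all homozygous: counts by hand
        a_codes = [1] * 5 + [2] * 1 + [1] * 1 + [2] * 5
        b_codes = [1] * 5 + [2] * 1 + [1] * 1 + [2] * 5
        ids = [f"i{k}" for k in range(12)]
        alleles = np.array(
            [[[a, a], [b, b]] for a, b in zip(a_codes, b_codes)]
        )
        gmap = hs.GeneticMap(pd.DataFrame(
            {"marker": ["m1", "m2"], "chromosome": ["1", "1"],
             "position_cm": [0.0, 5.0]}))
        gm = hs.GenotypeMatrix(ids, ["m1", "m2"], alleles)
        groups = pd.Series(["high"] * 6 + ["low"] * 6, index=ids)
        res = hs.scan(gm, gmap, groups, run_hwe=False)
        hand_table = [[10, 2], [2, 10]]
        assert res.pairs["p"].iloc[0] == pytest.approx(
            hs.fisher_exact_rx2(hand_table).p, rel=1e-12
        )

    def test_thresholds_are_bonferroni(self, small_study, small_tails):
        res = hs.scan(small_study.genotypes, small_study.map, small_tails.groups,
                      run_hwe=False)
        assert res.genome_threshold == pytest.approx(0.05 / res.n_tests)
        for chrom, thr in res.chromosome_thresholds.items():
            sub = res.pairs[res.pairs["chromosome"] == chrom]
            assert thr == pytest.approx(0.05 / sub["testable"].sum())

    def test_df_within_expected_range(self, small_study, small_tails):
        res = hs.scan(small_study.genotypes, small_study.map, small_tails.groups,
                      run_hwe=False)
        sub = res.pairs[res.pairs["testable"]]
        assert sub["df"].between(1, 9).all()

    def test_invariant_to_marker_renaming_and_individual_order(
        self, small_study, small_tails
    ):
        res1 = hs.scan(small_study.genotypes, small_study.map, small_tails.groups,
                       run_hwe=False, seed=9)
        mapping = {m: f"X_{m}" for m in small_study.genotypes.markers}
        gm2 = small_study.genotypes.rename_markers(mapping)
        table2 = small_study.map.table
        table2["marker"] = table2["marker"].map(mapping)
        gmap2 = hs.GeneticMap(table2)
        # also permute individual order
        rng = np.random.default_rng(0)
        order = list(rng.permutation(gm2.ids))
        gm2 = gm2.subset_individuals(order)
        res2 = hs.scan(gm2, gmap2, small_tails.groups, run_hwe=False, seed=9)
        np.testing.assert_allclose(
            res1.pairs["p"].to_numpy(), res2.pairs["p"].to_numpy(), rtol=1e-12
        )

    def test_hwe_screen_reports_but_retains(self, small_study, small_tails):
        res = hs.scan(small_study.genotypes, small_study.map, small_tails.groups,
                      run_hwe=True, hwe_mc_reps=500)
        assert set(res.hwe["group"]) <= {"high", "low", "combined"}
        # retained by default: every mapped polymorphic pair still tested
        res_off = hs.scan(small_study.genotypes, small_study.map,
                          small_tails.groups, run_hwe=False)
        assert res.n_tests == res_off.n_tests

    def test_signal_detected_near_causal(self):
        cfg = hs.SimConfig(seed=4)
        study = hs.simulate_population(cfg)
        tails = hs.select_tails(study.phenotypes, study.sires, 42, 42)
        res = hs.scan(study.genotypes, study.map, tails.groups, run_hwe=False)
        top = res.top_pair()
        assert top["chromosome"] == study.truth.causal_chromosome
        assert abs(top["midpoint_cm"] - study.truth.causal_position_cm) <= 10.0
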