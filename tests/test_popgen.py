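"""chi2prime LD, Sved Ne regression, and genomic-control lambda."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hapscan as hs
from hapscan.haplo_em import PairHaplotypeResults


def _model_from_freq(freq: np.ndarray) -> PairHaplotypeResults:
    k, l = freq.shape
    return PairHaplotypeResults(
        alleles_a=np.arange(1, k + 1), alleles_b=np.arange(1, l + 1),
        freq=freq, loglike=0.0, iterations=0, converged=True, n=0,
    )


class TestChi2Prime:
    def test_independence_gives_zero(self):
        p = np.array([0.5, 0.3, 0.2])
        q = np.array([0.6, 0.4])
        assert hs.chi2prime(_model_from_freq(np.outer(p, q))) == pytest.approx(0.0, abs=1e-12)

    def test_complete_biallelic_ld_gives_one(self):
        f = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert hs.chi2prime(_model_from_freq(f)) == pytest.approx(1.0)

    def test_3x2_matches_direct_formula(self):
        f = np.array([[0.30, 0.10], [0.05, 0.25], [0.20, 0.10]])
        p = f.sum(1)
        q = f.sum(0)
        direct = 0.0
        for i in range(3):
            for j in range(2):
                D = f[i, j] - p[i] * q[j]
                direct += D * D / (p[i] * q[j])
        direct /= min(3 - 1, 2 - 1)
        assert hs.chi2prime(_model_from_freq(f)) == pytest.approx(direct, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_biallelic_equals_r_squared(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(4)).reshape(2, 2)
        p = f.sum(1)
        q = f.sum(0)
        D = f[0, 0] - p[0] * q[0]
        r2 = D * D / (p[0] * p[1] * q[0] * q[1])
        assert hs.chi2prime(_model_from_freq(f)) == pytest.approx(r2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_and_relabel_invariant(self, seed):
        rng = np.random.default_rng(50 + seed)
        f = rng.dirichlet(np.ones(6)).reshape(3, 2)
        v = hs.chi2prime(_model_from_freq(f))
        assert hs.chi2prime(_model_from_freq(f.T)) == pytest.approx(v, rel=1e-12)
        perm = rng.permutation(3)
        assert hs.chi2prime(_model_from_freq(f[perm])) == pytest.approx(v, rel=1e-12)
        assert 0.0 <= v <= 1.0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            hs.chi2prime(_model_from_freq(np.array([[0.6], [0.4]])))


class TestWindowPairs:
    def _matrix(self, markers, n=40, seed=0):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(1, 4, size=(n, len(markers), 2))
        return hs.GenotypeMatrix([f"i{k}" for k in range(n)], markers, alleles)

    def test_pair_count_two_chromosomes(self):
        gmap = hs.GeneticMap(pd.DataFrame({
            "marker": ["a1", "a2", "a3", "b1", "b2", "b3"],
            "chromosome": ["1"] * 3 + ["2"] * 3,
            "position_cm": [0.0, 5.0, 10.0, 0.0, 5.0, 10.0],
        }))
        gm = self._matrix(gmap.markers)
        rec = hs.ld_window_pairs(gm, gmap, window_cm=15)
        assert len(rec) == 6  # C(3,2) per chromosome

    def test_pair_beyond_window_excluded(self):
        gmap = hs.GeneticMap(pd.DataFrame({
            "marker": ["a1", "a2"], "chromosome": ["1", "1"],
            "position_cm": [0.0, 20.0],
        }))
        rec = hs.ld_window_pairs(self._matrix(gmap.markers), gmap, window_cm=15)
        assert len(rec) == 0

    def test_x_excluded_by_default(self):
        gmap = hs.GeneticMap(pd.DataFrame({
            "marker": ["a1", "a2", "x1", "x2"],
            "chromosome": ["1", "1", "X", "X"],
            "position_cm": [0.0, 5.0, 0.0, 5.0],
        }))
        gm = self._matrix(gmap.markers)
        assert len(hs.ld_window_pairs(gm, gmap)) == 1
        assert len(hs.ld_window_pairs(gm, gmap, autosomes_only=False)) == 2

    def test_count_matches_brute_force_on_study(self, small_study):
        rec = hs.ld_window_pairs(small_study.genotypes, small_study.map,
                                 window_cm=15)
        # brute force: all qualifying polymorphic pairs
        gmap = small_study.map
        gm = small_study.genotypes
        def poly(m):
            col = gm.pair(m)
            col = col[(col >= 0).all(axis=1)]
            return len(np.unique(col)) > 1
        expected = 0
        for chrom in gmap.chromosomes:
            names, pos = gmap.chromosome_markers(chrom)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    if pos[j] - pos[i] <= 15 and poly(names[i]) and poly(names[j]):
                        expected += 1
        assert len(rec) == expected
        assert rec["chi2prime"].between(0, 1).all()
        np.testing.assert_allclose(rec["c"], rec["distance_cm"] / 100.0)


class TestSvedFit:
    def test_noiseless_exact_recovery(self):
        c = np.arange(0.01, 0.151, 0.01)
        y = 1.0 / (1.0 + 4.0 * 30.0 * c) + 0.05
        fit = hs.SvedLDModel(c, y).fit()
        assert fit.ne == pytest.approx(30.0, abs=1e-6)
        assert fit.e == pytest.approx(0.05, abs=1e-8)
        assert fit.rss < 1e-12

    def test_noisy_recovery_within_band(self):
        rng = np.random.default_rng(42)
        c = rng.uniform(0.005, 0.15, size=5000)
        y = 1.0 / (1.0 + 120.0 * c) + 0.05 + rng.normal(0, 0.05, size=5000)
        fit = hs.SvedLDModel(c, y).fit()
        assert 24.0 <= fit.ne <= 36.0

    def test_noiseless_ne_100_and_monotonicity(self):
        c = np.arange(0.01, 0.151, 0.01)
        y100 = 1.0 / (1.0 + 400.0 * c)
        assert hs.SvedLDModel(c, y100).fit().ne == pytest.approx(100.0, rel=1e-6)
        # estimated Ne decreases as the LD level rises
        nes = []
        for ne_true in (200.0, 60.0, 20.0, 5.0):
            y = 1.0 / (1.0 + 4.0 * ne_true * c)
            nes.append(hs.SvedLDModel(c, y).fit().ne)
        assert nes == sorted(nes, reverse=True)

    def test_consistency_error_shrinks_with_n(self):
        errs = {}
        for n in (100, 10_000):
            errors = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                c = rng.uniform(0.005, 0.15, size=n)
                y = 1.0 / (1.0 + 120.0 * c) + rng.normal(0, 0.1, size=n)
                errors.append(abs(hs.SvedLDModel(c, y).fit().ne - 30.0))
            errs[n] = np.mean(errors)
        assert errs[10_000] < errs[100]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            hs.SvedLDModel([0.1, 0.1, 0.1], [0.2, 0.3, 0.1]).fit()
        with pytest.raises(ValueError):
            hs.SvedLDModel([0.1, 0.2], [0.2, 0.1]).fit()


class TestGenomicControl:
    def test_lambda_one_at_null_median(self):
        med = stats.chi2.ppf(0.5, 1)
        rep = hs.genomic_control_lambda([(med, 1)] * 1000)
        assert rep.overall == pytest.approx(1.0, rel=1e-12)

    def test_scaling_doubles_lambda(self):
        rng = np.random.default_rng(5)
        tests = [(v, 1) for v in stats.chi2.rvs(1, size=500, random_state=rng)]
        tests += [(v, 4) for v in stats.chi2.rvs(4, size=200, random_state=rng)]
        base = hs.genomic_control_lambda(tests).overall
        doubled = hs.genomic_control_lambda([(2 * v, d) for v, d in tests]).overall
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_null_simulation_near_one(self):
        rng = np.random.default_rng(123)
        tests = [(v, 1) for v in stats.chi2.rvs(1, size=1000, random_state=rng)]
        tests += [(v, 4) for v in stats.chi2.rvs(4, size=122, random_state=rng)]
        rep = hs.genomic_control_lambda(tests)
        assert 0.9 <= rep.overall <= 1.1
        # weighted-mean identity
        w = (rep.per_df["lam"] * rep.per_df["n_tests"]).sum() / rep.per_df["n_tests"].sum()
        assert rep.overall == pytest.approx(w)

    def test_lower_median_convention(self):
        # even count: lower of the two central order statistics
        rep = hs.genomic_control_lambda([(1.0, 1), (2.0, 1), (3.0, 1), (4.0, 1)])
        assert rep.per_df["observed_median"].iloc[0] == 2.0
        rep_mid = hs.genomic_control_lambda(
            [(1.0, 1), (2.0, 1), (3.0, 1), (4.0, 1)], median="mid"
        )
        assert rep_mid.per_df["observed_median"].iloc[0] == 2.5

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            hs.genomic_control_lambda([(1.0, 0)])
        with pytest.raises(ValueError):
            hs.genomic_control_lambda([])
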