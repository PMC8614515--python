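"""Single-step GWAS: back-solution, p-values, window variance, thresholds."""

import numpy as np
import pandas as pd
import pytest

from ch4herd import kinship, simdata, ssgwas
from ch4herd.legendre_rr import LegendreBasis, SolutionSet


def _solution(bv, caa=None):
    m, k = bv.shape
    return SolutionSet(
        beta=np.zeros(1), fixed_names=["mu"], bv=bv, pe=None,
        animal_ids=np.arange(1, m + 1), pe_ids=None, caa=caa,
        sigma_e2=1.0, minus2_restricted_ll=0.0,
    )


@pytest.fixture(scope="module")
def toy_geno():
    ped = simdata.simulate_pedigree(5, 0, 1, 1, seed=40)
    return simdata.simulate_genotypes(ped, 50, 2, seed=41)


class TestAggregateEbv:
    def test_intercept_only_coefficient_scales_by_phi0(self):
        basis = LegendreBasis(2, 5, 305)
        bv = np.zeros((4, 3))
        bv[:, 0] = [1.0, -2.0, 0.5, 0.0]
        agg = ssgwas.aggregate_ebv(_solution(bv), basis)
        assert np.allclose(agg, bv[:, 0] / np.sqrt(2.0))

    def test_linearity(self):
        basis = LegendreBasis(2, 5, 305)
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        s = ssgwas.aggregate_ebv(_solution(a + b), basis)
        assert np.allclose(
            s,
            ssgwas.aggregate_ebv(_solution(a), basis)
            + ssgwas.aggregate_ebv(_solution(b), basis),
        )

    def test_coefficient_passthrough(self):
        basis = LegendreBasis(2, 5, 305)
        bv = np.arange(12.0).reshape(4, 3)
        assert np.allclose(
            ssgwas.aggregate_ebv(_solution(bv), basis, coefficient=1), bv[:, 1]
        )

    def test_empty_dim_range_rejected(self):
        basis = LegendreBasis(2, 5, 305)
        with pytest.raises(ValueError):
            ssgwas.aggregate_ebv(_solution(np.zeros((2, 3))), basis, (100, 99))


class TestBacksolve:
    def test_zero_ebv_gives_zero_effects(self, toy_geno):
        Z, d = ssgwas.centered_genotypes(toy_geno)
        G = kinship.build_G(toy_geno)
        u = ssgwas.backsolve_snp_effects(G, Z, np.zeros(5), d)
        assert np.allclose(u, 0.0)

    def test_projection_identity_on_full_rank_G(self, toy_geno):
        # base-population frequencies keep G full rank (observed-frequency
        # centering always leaves the ones vector in the null space)
        rng = np.random.default_rng(1)
        Z, d = ssgwas.centered_genotypes(toy_geno, allele_freq=toy_geno.base_freq)
        G = kinship.build_G(toy_geno, allele_freq=toy_geno.base_freq)
        a = rng.standard_normal(5)
        u = ssgwas.backsolve_snp_effects(G, Z, a, d, ridge=0.0)
        assert np.allclose(Z @ u, a, atol=1e-8)

    def test_single_snp_regression_form(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 3, size=(30, 1)).astype(float)
        snp_map = pd.DataFrame({"snp_id": ["s"], "chrom": ["1"], "pos": [1]})
        g = simdata.GenotypeMatrix(counts=counts, snp_map=snp_map,
                                   animal_ids=np.arange(30))
        Z, d = ssgwas.centered_genotypes(g)
        G = kinship.build_G(g)
        a = 0.3 * Z[:, 0] + rng.normal(0, 0.01, 30)
        u = ssgwas.backsolve_snp_effects(G, Z, a, d, ridge=0.0)
        expect = (Z[:, 0] @ a) / (Z[:, 0] @ Z[:, 0])
        assert u[0] == pytest.approx(expect, rel=1e-8)


class TestPvalues:
    @pytest.fixture()
    def setup(self, toy_geno):
        rng = np.random.default_rng(3)
        Z, d = ssgwas.centered_genotypes(toy_geno)
        G = kinship.build_G(toy_geno)
        Gb = kinship.blend_G(G, np.eye(5), 0.95)
        var_ebv = 0.5 * Gb
        a = rng.standard_normal(5)
        u = ssgwas.backsolve_snp_effects(G, Z, a, d)
        return Z, d, G, var_ebv, u

    def test_zero_effect_gives_p_one(self, setup):
        Z, d, G, var_ebv, u = setup
        u0 = np.zeros_like(u)
        p, se, flag = ssgwas.snp_pvalues(u0, Z, G, var_ebv, d)
        assert np.allclose(p, 1.0)

    def test_sign_flip_leaves_p_unchanged(self, setup):
        Z, d, G, var_ebv, u = setup
        p1, *_ = ssgwas.snp_pvalues(u, Z, G, var_ebv, d)
        p2, *_ = ssgwas.snp_pvalues(-u, Z, G, var_ebv, d)
        assert np.allclose(p1, p2)

    def test_degenerate_variance_flagged(self, setup):
        Z, d, G, _, u = setup
        p, se, flag = ssgwas.snp_pvalues(u, Z, G, np.zeros((5, 5)), d)
        assert np.all(p[flag] == 1.0)


class TestVarianceExplained:
    def test_zero_effects_zero_percent(self, toy_geno):
        Z, _ = ssgwas.centered_genotypes(toy_geno)
        pct = ssgwas.snp_variance_explained(Z, np.zeros(Z.shape[1]),
                                            np.arange(5.0))
        assert np.allclose(pct, 0.0)

    def test_single_causal_snp_explains_everything(self, toy_geno):
        Z, _ = ssgwas.centered_genotypes(toy_geno)
        j = int(np.argmax(np.var(Z, axis=0)))
        u = np.zeros(Z.shape[1])
        u[j] = 1.3
        a = Z[:, j] * 1.3
        pct = ssgwas.snp_variance_explained(Z, u, a)
        assert pct[j] == pytest.approx(100.0)
        assert np.all(pct >= 0)


class TestWindows:
    def _scores_input(self, n_snps=60, n_animals=25, seed=4):
        ped = simdata.simulate_pedigree(n_animals, 0, 1, 1, seed=seed)
        g = simdata.simulate_genotypes(ped, n_snps, 1, seed=seed + 1)
        Z, d = ssgwas.centered_genotypes(g)
        return g, Z

    def test_count_mode_window_count(self):
        g, Z = self._scores_input()
        rng = np.random.default_rng(5)
        u = rng.standard_normal(60) * 0.01
        a = Z @ u
        win = ssgwas.window_variance(Z, u, a, g.snp_map, window_snps=50)
        assert len(win) == 60 - 50 + 1

    def test_zero_effects_zero_windows(self):
        g, Z = self._scores_input()
        win = ssgwas.window_variance(Z, np.zeros(60), np.arange(25.0),
                                     g.snp_map, window_snps=10)
        assert np.allclose(win.pct_var, 0.0)

    def test_causal_window_captures_all_variance(self):
        g, Z = self._scores_input()
        j = 30
        u = np.zeros(60)
        u[j] = 1.0
        a = Z[:, j]
        win = ssgwas.window_variance(Z, u, a, g.snp_map, window_snps=10)
        containing = win[(win.first_snp <= j + 1) & (win.first_snp + 9 >= j + 1)]
        assert np.allclose(containing.pct_var, 100.0)

    def test_short_chromosome_truncated_with_flag(self):
        g, Z = self._scores_input()
        win = ssgwas.window_variance(Z, np.zeros(60), np.arange(25.0),
                                     g.snp_map, window_snps=100)
        assert len(win) == 1 and bool(win.truncated.iloc[0])

    def test_length_mode_one_window_per_anchor(self):
        g, Z = self._scores_input()
        win = ssgwas.window_variance(Z, np.zeros(60), np.arange(25.0),
                                     g.snp_map, window_snps=None, window_bp=70_000)
        assert len(win) == 60
        assert (win.n_snps >= 1).all()

    def test_disjoint_window_sums_match_chromosome_total(self):
        # linkage-equilibrium scores: disjoint window percents add up to the
        # chromosome aggregate within sampling error
        ped = simdata.simulate_pedigree(400, 0, 1, 1, seed=8)
        g = simdata.simulate_genotypes(ped, 100, 1, seed=9)
        Z, d = ssgwas.centered_genotypes(g)
        rng = np.random.default_rng(10)
        u = rng.standard_normal(100) * 0.05
        a = Z @ u
        win = ssgwas.window_variance(Z, u, a, g.snp_map, window_snps=20)
        disjoint = win[win.first_snp.isin([1, 21, 41, 61, 81])]
        total = Z @ u
        pct_total = 100.0 * np.var(total) / np.var(a)
        assert disjoint.pct_var.sum() == pytest.approx(pct_total, rel=0.15)


class TestThresholds:
    def test_study_scale_bonferroni(self):
        assert round(ssgwas.bonferroni_threshold(0.05, 39269), 1) == 5.9

    def test_small_count_values(self):
        assert ssgwas.bonferroni_threshold(0.05, 1) == pytest.approx(1.301, abs=1e-3)
        assert ssgwas.bonferroni_threshold(0.05, 100) == pytest.approx(3.301, abs=1e-3)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            ssgwas.bonferroni_threshold(1.5, 10)

    def test_significant_hits_boundary_and_order(self):
        tbl = pd.DataFrame(
            {"snp_id": ["a", "b", "c"], "neglog10p": [2.0, 5.9, 7.0]}
        )
        out = ssgwas.significant_hits(tbl, 5.9)
        assert list(out.snp_id) == ["c", "b"]  # >= kept, sorted descending
        empty = ssgwas.significant_hits(tbl.assign(neglog10p=0.0), 5.9)
        assert empty.empty
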