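"""Synthetic herd generator: pedigree, gene dropping, effects, records."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ch4herd import simdata
from ch4herd.kinship import build_A, build_G
from ch4herd.legendre_rr import LegendreBasis


class TestSimulatePedigree:
    def test_forced_trio_structure(self, trio_pedigree):
        ped = trio_pedigree
        assert len(ped) == 3
        child = ped.iloc[2]
        assert {child.sire_id, child.dam_id} == {1, 2}
        assert (ped.iloc[:2][["sire_id", "dam_id"]] == 0).all().all()

    @given(
        nf=st.integers(2, 12), gens=st.integers(0, 3),
        mat=st.integers(1, 6), off=st.integers(1, 3),
    )
    def test_count_formula_and_ordering(self, nf, gens, mat, off):
        ped = simdata.simulate_pedigree(nf, gens, mat, off, seed=3)
        assert len(ped) == nf + gens * mat * off
        pos = {a: i for i, a in enumerate(ped.animal_id)}
        for _, r in ped.iterrows():
            for p in (r.sire_id, r.dam_id):
                if p != simdata.UNKNOWN_PARENT:
                    assert pos[p] < pos[r.animal_id]

    def test_same_seed_reproduces_pedigree(self):
        a = simdata.simulate_pedigree(10, 3, 5, 2, seed=5)
        b = simdata.simulate_pedigree(10, 3, 5, 2, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_founders_rejected(self):
        with pytest.raises(ValueError):
            simdata.simulate_pedigree(1, 1, 1, 1, seed=0)

    def test_sire_pool_restricts_sires(self):
        ped = simdata.simulate_pedigree(
            30, 2, 40, 2, seed=1, n_sires_per_generation=3
        )
        for g in (1, 2):
            assert ped.loc[ped.generation == g, "sire_id"].nunique() <= 3


class TestSimulateGenotypes:
    def test_fixation_propagates_through_gene_dropping(self):
        # wherever every founder is homozygous, every descendant must be too
        ped = simdata.simulate_pedigree(4, 2, 4, 2, seed=1)
        g = simdata.simulate_genotypes(ped, 200, 2, maf_low=0.5, maf_high=0.5,
                                       seed=1)
        founders = (ped.sire_id == 0).to_numpy()
        fixed = np.flatnonzero((g.counts[founders] == 2.0).all(axis=0))
        assert fixed.size > 0
        assert np.all(g.counts[:, fixed] == 2.0)

    def test_parent_offspring_share_an_allele(self, small_herd):
        ped, geno = small_herd["ped"], small_herd["geno"]
        pos = {a: i for i, a in enumerate(ped.animal_id)}
        offspring = ped[ped.sire_id != 0].head(10)
        for _, r in offspring.iterrows():
            c = geno.counts[pos[r.animal_id]]
            s = geno.counts[pos[r.sire_id]]
            # a homozygous parent always passes that allele
            assert not np.any((s == 2) & (c == 0))
            assert not np.any((s == 0) & (c == 2))

    def test_founder_mean_allele_count_matches_binomial(self):
        ped = simdata.simulate_pedigree(2000, 0, 1, 1, seed=2)
        g = simdata.simulate_genotypes(
            ped, 4, 2, maf_low=0.3, maf_high=0.3, seed=3
        )
        se = np.sqrt(2 * 0.3 * 0.7 / 2000)
        means = g.counts.mean(axis=0)
        assert np.all(np.abs(means - 0.6) < 3 * se)

    def test_map_sorted_and_chromosome_counts(self, small_herd):
        m = small_herd["geno"].snp_map
        for _, grp in m.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
        assert m["chrom"].nunique() == 5

    def test_more_chromosomes_than_snps_rejected(self, trio_pedigree):
        with pytest.raises(ValueError):
            simdata.simulate_genotypes(trio_pedigree, 3, 5, seed=0)


class TestTrueEffects:
    def test_zero_genetic_covariance_gives_zero_bv(self, small_herd):
        eff = simdata.simulate_true_effects(
            small_herd["ped"], None, np.zeros((3, 3)), np.eye(3), seed=1
        )
        assert np.all(eff.bv == 0.0)

    def test_pedigree_mode_variance_and_inheritance(self):
        # many independent trios: founder variance and parent-offspring
        # covariance of the order-0 coefficient
        ped = simdata.simulate_pedigree(3000, 1, 1500, 1, seed=4)
        K = np.diag([4.0, 1.0, 0.5])
        eff = simdata.simulate_true_effects(ped, None, K, K, seed=5)
        founders = eff.bv[:3000, 0]
        assert abs(np.var(founders) - 4.0) < 3 * 4.0 * np.sqrt(2 / 3000)
        pos = {a: i for i, a in enumerate(ped.animal_id)}
        kids = ped[ped.sire_id != 0]
        ks = eff.bv[[pos[a] for a in kids.animal_id], 0]
        ss = eff.bv[[pos[a] for a in kids.sire_id], 0]
        cov = np.cov(ks, ss)[0, 1]
        assert abs(cov - 2.0) < 3 * 4.0 / np.sqrt(len(kids))  # 0.5 * K[0,0]

    def test_genotype_mode_matches_target_scale(self, small_herd):
        eff = simdata.simulate_true_effects(
            small_herd["ped"], small_herd["geno"], small_herd["K_a"],
            small_herd["K_p"], seed=6,
        )
        assert eff.snp_effects is not None
        v = np.var(eff.bv[:, 0], ddof=1)
        assert 0.3 * 8.0 < v < 3.0 * 8.0  # right order of magnitude

    def test_non_psd_covariance_rejected(self, small_herd):
        bad = np.array([[1.0, 2.0, 0], [2.0, 1.0, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError):
            simdata.simulate_true_effects(small_herd["ped"], None, bad, np.eye(3), 0)


class TestSimulateRecords:
    def test_zero_variances_reduce_to_fixed_effects(self, trio_pedigree):
        basis = LegendreBasis(2, 5, 305)
        eff = simdata.simulate_true_effects(
            trio_pedigree, None, np.zeros((3, 3)), np.zeros((3, 3)), seed=0
        )
        fx = simdata.FixedSpec(curve_coeffs=(0, 0, 0, 0), fyw_sd=0.0, lac2_effect=0.0)
        rec = simdata.simulate_records(
            trio_pedigree, eff, fixed_spec=fx,
            diurnal_spec=simdata.DiurnalSpec(harmonics=()),
            schedule_spec=simdata.ScheduleSpec(n_days_per_cow=5, mean_visits_per_day=1.0),
            sigma_e=0.0, seed=1, basis=basis,
        )
        means = {"farm1": 505.0, "farm2": 517.0}
        for _, r in rec.iterrows():
            assert r.ch4_ppm == pytest.approx(means[r.farm])

    def test_diurnal_amplitude_recovered_by_regression(self, trio_pedigree):
        basis = LegendreBasis(2, 5, 305)
        eff = simdata.simulate_true_effects(
            trio_pedigree, None, np.zeros((3, 3)), np.zeros((3, 3)), seed=0
        )
        fx = simdata.FixedSpec(curve_coeffs=(0, 0, 0, 0), fyw_sd=0.0, lac2_effect=0.0)
        rec = simdata.simulate_records(
            trio_pedigree, eff, fixed_spec=fx,
            diurnal_spec=simdata.DiurnalSpec(harmonics=((30.0, 0.0),)),
            schedule_spec=simdata.ScheduleSpec(n_days_per_cow=60, mean_visits_per_day=3.0),
            sigma_e=0.0, seed=2, basis=basis,
        )
        t = rec["time_h"].to_numpy()
        X = np.column_stack([np.ones_like(t), np.sin(2 * np.pi * t / 24)])
        beta, *_ = np.linalg.lstsq(X, rec["ch4_ppm"].to_numpy(), rcond=None)
        assert beta[1] == pytest.approx(30.0, abs=1e-6)

    def test_same_seed_identical_tables(self, small_herd):
        kw = dict(sigma_e=3.0, basis=small_herd["basis"])
        a = simdata.simulate_records(small_herd["ped"], small_herd["eff"], seed=9, **kw)
        b = simdata.simulate_records(small_herd["ped"], small_herd["eff"], seed=9, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_dim_windows_respected_per_farm(self, small_herd):
        rec = small_herd["records"]
        assert rec.loc[rec.farm == "farm1", "dim"].min() >= 15
        assert rec.loc[rec.farm == "farm2", "dim"].min() >= 5
        assert rec["dim"].max() <= 305
        assert (rec["ch4_ppm"] > 0).all() and (rec["co2_ppm"] > 0).all()


class TestGeneDropConsistency:
    def test_genomic_relationship_converges_to_pedigree(self):
        """G on many gene-dropped SNPs approximates the pedigree A."""
        ped = simdata.simulate_pedigree(16, 2, 17, 1, seed=11)
        geno = simdata.simulate_genotypes(ped, 20000, 5, seed=12)
        A = build_A(ped)
        # base-population frequencies: the scale on which E[G] = A
        G = build_G(geno, allele_freq=geno.base_freq)
        mad = np.mean(np.abs(G - A))
        assert mad < 0.05

    def test_phenotypic_variance_decomposition(self):
        """var(y) ~ phi'K_a phi + phi'K_p phi + sigma_e^2 across the herd."""
        ped = simdata.simulate_pedigree(2000, 0, 1, 1, seed=13)
        K_a = np.diag([6.0, 0.0, 0.0])
        K_p = np.diag([4.0, 0.0, 0.0])
        eff = simdata.simulate_true_effects(ped, None, K_a, K_p, seed=14)
        basis = LegendreBasis(2, 5, 305)
        fx = simdata.FixedSpec(curve_coeffs=(0, 0, 0, 0), fyw_sd=0.0, lac2_effect=0.0)
        rec = simdata.simulate_records(
            ped, eff, fixed_spec=fx,
            diurnal_spec=simdata.DiurnalSpec(harmonics=()),
            schedule_spec=simdata.ScheduleSpec(n_days_per_cow=2, mean_visits_per_day=1.0),
            sigma_e=np.sqrt(5.0), seed=15, basis=basis,
        )
        phi0 = 1.0 / np.sqrt(2.0)
        expected = phi0**2 * (6.0 + 4.0) + 5.0
        # farm means and lactation shifts are absent by construction
        v = rec.groupby("farm")["ch4_ppm"].var().mean()
        assert abs(v - expected) / expected < 0.15


def test_writers_round_trip(tmp_path, small_herd):
    simdata.write_pedigree_csv(small_herd["ped"], tmp_path / "ped.csv")
    back = simdata.read_pedigree_csv(tmp_path / "ped.csv")
    assert list(back.animal_id) == list(small_herd["ped"].animal_id)
    simdata.write_gas_records_csv(small_herd["records"], tmp_path / "rec.csv")
    from ch4herd.phenotypes import read_gas_records_csv

    rec = read_gas_records_csv(tmp_path / "rec.csv")
    assert len(rec) == len(small_herd["records"])
    assert np.allclose(rec["ch4_ppm"], small_herd["records"]["ch4_ppm"])
    simdata.write_run_manifest(tmp_path / "manifest.json", 3, {"n": 5})
    import json

    man = json.loads((tmp_path / "manifest.json").read_text())
    assert man["seed"] == 3
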