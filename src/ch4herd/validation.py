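"""Simulation experiments validating the estimation machinery.

These are the package's own operating-characteristic checks, run end-to-end
through the public API on synthetic herds of known truth:

* heritability recovery — does random-regression AI-REML on the combined
  relationship matrix recover the DIM-averaged h2 of a herd simulated under
  the model?
* GWAS calibration — are back-solved SNP p-values uniform under a polygenic
  (no-QTL) truth?
* GWAS power — does a planted QTL's 50-SNP window rank at the top of the
  window variance decomposition?

Problem sizes default to desk scale (hundreds of cows, a few thousand SNPs)
so a full experiment runs in minutes on one core; the statistical conditions
(genotyped fraction, repeated records, variance magnitudes) mirror the
two-farm study design the package targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from . import kinship, legendre_rr, phenotypes, simdata, ssgwas

__all__ = [
    "TRUE_K_A",
    "TRUE_K_P",
    "TRUE_SIGMA_E2",
    "true_mean_h2",
    "h2_recovery_replicate",
    "h2_recovery_experiment",
    "gwas_null_calibration",
    "gwas_power_replicate",
    "gwas_power_experiment",
]

# Truth for the recovery experiment: intercept-dominated coefficient
# covariances giving a DIM-averaged h2 near 0.21 at sigma_e2 = 12 — the
# magnitude regime of daily methane concentration phenotypes (scaled down).
TRUE_K_A = np.array([[8.0, 1.0, 0.0], [1.0, 1.5, 0.3], [0.0, 0.3, 0.5]])
TRUE_K_P = np.array([[10.0, 0.0, 0.0], [0.0, 1.5, 0.0], [0.0, 0.0, 0.5]])
TRUE_SIGMA_E2 = 12.0


def true_mean_h2(
    K_a=TRUE_K_A, K_p=TRUE_K_P, sigma_e2=TRUE_SIGMA_E2, basis=None
) -> float:
    basis = basis or legendre_rr.LegendreBasis(2, 5, 305)
    dims = np.arange(basis.dim_min, basis.dim_max + 1)
    va = legendre_rr.variance_trajectory(K_a, basis, dims)
    vp = legendre_rr.variance_trajectory(K_p, basis, dims)
    return float(np.mean(va / (va + vp + sigma_e2)))


def h2_recovery_replicate(
    seed: int,
    n_founders: int = 80,
    n_generations: int = 3,
    matings: int = 115,
    offspring: int = 2,
    n_sires: int = 18,
    n_snps: int = 2000,
    n_chromosomes: int = 10,
    n_days_per_cow: int = 45,
    genotyped_fraction: float = 330.0 / 483.0,
    K_a=TRUE_K_A,
    K_p=TRUE_K_P,
    sigma_e2: float = TRUE_SIGMA_E2,
    max_iter: int = 200,
    ltol: float = 1e-4,
    truth: str = "genomic",
) -> dict:
    """Simulate one herd under the model and re-estimate its components.

    The full chain is exercised: gene-dropped genotypes drive the true
    breeding values (genotype mode), gas records carry a diurnal rhythm that
    is removed by the Fourier correction, and the REML fit uses the combined
    relationship of a partially genotyped herd.  The default pedigree uses a
    small sire pool per generation, giving the large paternal half-sib
    families that identify the genetic/permanent-environment partition in
    commercial dairy designs.  Non-phenotyped relatives are absorbed exactly
    by fitting on the phenotyped-cow block of H.
    """
    ss = np.random.SeedSequence(seed)
    r_ped, r_gen, r_eff, r_rec, r_sel = [np.random.default_rng(c) for c in ss.spawn(5)]
    basis = legendre_rr.LegendreBasis(2, 5, 305)
    ped = simdata.simulate_pedigree(
        n_founders, n_generations, matings, offspring, r_ped,
        n_sires_per_generation=n_sires,
    )
    geno = simdata.simulate_genotypes(ped, n_snps, n_chromosomes, seed=r_gen)
    eff = simdata.simulate_true_effects(
        ped, geno if truth == "genomic" else None, K_a, K_p, seed=r_eff
    )
    records = simdata.simulate_records(
        ped, eff,
        fixed_spec=simdata.FixedSpec(
            curve_coeffs=(-4.0, 1.5, -0.6, 0.2), fyw_sd=3.0, lac2_effect=2.5
        ),
        diurnal_spec=simdata.DiurnalSpec(harmonics=((2.0, 1.0), (0.8, 0.4))),
        schedule_spec=simdata.ScheduleSpec(
            n_days_per_cow=n_days_per_cow, mean_visits_per_day=1.0
        ),
        sigma_e=float(np.sqrt(sigma_e2)), seed=r_rec, basis=basis,
    )
    models = phenotypes.fit_diurnal_fourier(records, 2)
    daily = phenotypes.daily_average(phenotypes.correct_diurnal(records, models))
    cows = np.sort(daily["cow_id"].unique())
    n_geno = int(round(genotyped_fraction * len(cows)))
    genotyped = simdata.choose_genotyped(cows, n_geno, r_sel)
    rel = kinship.build_relationships(ped, geno.subset_animals(genotyped), 0.95)
    pos = {a: i for i, a in enumerate(rel.animal_ids)}
    cidx = np.array([pos[c] for c in cows])
    H_cc_inv = np.linalg.inv(rel.H[np.ix_(cidx, cidx)])
    design = legendre_rr.build_design(
        daily, legendre_rr.LegendreBasis(4, 5, 305), basis, "ppm",
        animal_ids=cows,
    )
    vc, _ = legendre_rr.reml_fit(design, H_cc_inv, max_iter=max_iter, ltol=ltol)
    traj = legendre_rr.heritability_trajectory(vc, basis)
    return {
        "seed": seed,
        "n_cows": int(len(cows)),
        "n_records": int(len(daily)),
        "h2_est": traj.attrs["mean_h2"],
        "h2_true": true_mean_h2(K_a, K_p, sigma_e2, basis),
        "n_iter": vc.n_iter,
    }


def h2_recovery_experiment(n_replicates: int = 20, seed: int = 1, **kwargs) -> pd.DataFrame:
    """Replicated heritability recovery; returns one row per replicate.

    The DataFrame ``.attrs`` report the fraction of replicates with
    ``|h2_est - h2_true| <= 0.05``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = [h2_recovery_replicate(int(s), **kwargs) for s in seeds]
    out = pd.DataFrame(rows)
    err = (out["h2_est"] - out["h2_true"]).abs()
    out.attrs["n_within_005"] = int((err <= 0.05).sum())
    out.attrs["mean_abs_error"] = float(err.mean())
    out.attrs["mean_h2_est"] = float(out["h2_est"].mean())
    out.attrs["h2_true"] = float(out["h2_true"].iloc[0])
    return out


# ---------------------------------------------------------------------------
# single-record GBLUP designs for the GWAS experiments
# ---------------------------------------------------------------------------


def _gblup_design(y: np.ndarray) -> legendre_rr.ModelDesign:
    """Intercept-only single-record design: y = mu + a + e, one coeff/animal."""
    n = len(y)
    ids = np.arange(1, n + 1)
    Z = sparse.identity(n, format="csr")
    return legendre_rr.ModelDesign(
        y=y, X=np.ones((n, 1)), Z_a=Z, Z_p=None, animal_ids=ids, pe_ids=None,
        n_coeff=1, fixed_names=["mu"],
    )


def _unrelated_genotyped_herd(rng, n_animals, n_snps, n_chromosomes):
    ped = simdata.simulate_pedigree(n_animals, 0, 1, 1, rng)
    geno = simdata.simulate_genotypes(ped, n_snps, n_chromosomes, seed=rng)
    return ped, geno


def gwas_null_calibration(
    seed: int = 1,
    n_animals: int = 200,
    n_snps: int = 1000,
    n_chromosomes: int = 5,
    h2: float = 0.3,
    alpha: float = 0.05,
    n_replicates: int = 5,
) -> dict:
    """Empirical type-I behaviour of ssGWAS p-values under a polygenic null.

    Every SNP carries an infinitesimal effect (the null model of the
    back-solution p-value machinery); no variant has a large effect.
    P-values are pooled over ``n_replicates`` independent herds — the
    per-herd rejection rate has extra-binomial spread because the SNP tests
    share one realized EBV vector, so a single herd is a noisy estimate of
    the type-I rate.  Reports the pooled fraction of SNPs rejected at
    ``alpha``.
    """
    pooled = []
    for child in np.random.SeedSequence(seed).spawn(n_replicates):
        pooled.append(
            _null_calibration_once(child, n_animals, n_snps, n_chromosomes, h2)
        )
    p = np.concatenate(pooled)
    return {
        "seed": seed,
        "n_snps": int(p.size),
        "rejection_rate": float(np.mean(p < alpha)),
        "pvalues": p,
    }


def _null_calibration_once(seedseq, n_animals, n_snps, n_chromosomes, h2):
    rng = np.random.default_rng(seedseq)
    ped, geno = _unrelated_genotyped_herd(rng, n_animals, n_snps, n_chromosomes)
    sigma_a2 = 1.0
    eff = simdata.simulate_true_effects(
        ped, geno, np.array([[sigma_a2]]), np.array([[0.0]]), seed=rng
    )
    a = eff.bv[:, 0]
    sigma_e2 = sigma_a2 * (1.0 - h2) / h2
    y = 3.0 + a + rng.normal(0.0, np.sqrt(sigma_e2), n_animals)

    G_raw = kinship.build_G(geno)
    G_b = kinship.blend_G(G_raw, np.eye(n_animals), 0.95)
    sols = legendre_rr.solve_mme(
        _gblup_design(y), np.linalg.inv(G_b), np.array([[sigma_a2]]), None, sigma_e2
    )
    ebv = sols.bv[:, 0]
    Z, d = ssgwas.centered_genotypes(geno)
    u = ssgwas.backsolve_snp_effects(G_raw, Z, ebv, d)
    pev = sols.caa[:, 0, :, 0]
    var_ebv = sigma_a2 * G_b - pev
    p, _, _ = ssgwas.snp_pvalues(u, Z, G_raw, var_ebv, d)
    return p


def gwas_power_replicate(
    seed: int,
    n_animals: int = 800,
    n_snps: int = 1000,
    n_chromosomes: int = 5,
    qtl_variance_fraction: float = 0.3,
    h2: float = 0.45,
    window_snps: int = 50,
    top_fraction: float = 0.01,
) -> dict:
    """Plant one QTL and test whether its 50-SNP window tops the ranking.

    The QTL explains ``qtl_variance_fraction`` of the genetic variance on top
    of a polygenic background; success = some window containing the QTL ranks
    within the top ``top_fraction`` of all windows by percent of genetic
    variance.  The default heritability of 0.45 is the repeatability-adjusted
    reliability of a cow's mean over a lactation of repeated daily records
    (a single-record h2 near 0.2 with a comparable permanent-environment
    share), and the herd size is chosen so the back-solution has the EBV
    accuracy at which window ranking is informative.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ped, geno = _unrelated_genotyped_herd(rng, n_animals, n_snps, n_chromosomes)
    eff = simdata.simulate_true_effects(
        ped, geno, np.array([[1.0 - qtl_variance_fraction]]),
        np.array([[0.0]]), seed=rng,
    )
    poly = eff.bv[:, 0]
    Z, d = ssgwas.centered_genotypes(geno)
    qtl = int(rng.integers(0, n_snps))
    zq = Z[:, qtl]
    if np.var(zq) < 1e-12:  # monomorphic draw; take a neighbour
        qtl = int(np.argmax(np.var(Z, axis=0)))
        zq = Z[:, qtl]
    beta = np.sqrt(qtl_variance_fraction / np.var(zq))
    a = poly + beta * zq
    sigma_e2 = (1.0 - h2) / h2  # genetic variance is ~1 by construction
    y = 3.0 + a + rng.normal(0.0, np.sqrt(sigma_e2), n_animals)

    G_raw = kinship.build_G(geno)
    G_b = kinship.blend_G(G_raw, np.eye(n_animals), 0.95)
    sols = legendre_rr.solve_mme(
        _gblup_design(y), np.linalg.inv(G_b), np.array([[1.0]]), None, sigma_e2,
        compute_pev=False,
    )
    ebv = sols.bv[:, 0]
    u = ssgwas.backsolve_snp_effects(G_raw, Z, ebv, d)
    win = ssgwas.window_variance(Z, u, ebv, geno.snp_map, window_snps=window_snps)
    order = np.argsort(-win["pct_var"].to_numpy())
    rank = np.full(len(win), len(win))
    rank[order] = np.arange(len(win))
    qtl_chrom = geno.snp_map["chrom"].iloc[qtl]
    qtl_pos = geno.snp_map["pos"].iloc[qtl]
    contains = (
        (win["chrom"] == qtl_chrom)
        & (win["start"] <= qtl_pos)
        & (win["end"] >= qtl_pos)
    ).to_numpy()
    best_rank = int(rank[contains].min())
    n_top = max(1, int(np.ceil(top_fraction * len(win))))
    return {
        "seed": seed,
        "n_windows": int(len(win)),
        "qtl_best_rank": best_rank,
        "in_top": bool(best_rank < n_top),
    }


def gwas_power_experiment(n_replicates: int = 20, seed: int = 1, **kwargs) -> pd.DataFrame:
    seeds = np.random.SeedSequence(seed + 10_000).generate_state(n_replicates) % (2**31)
    rows = [gwas_power_replicate(int(s), **kwargs) for s in seeds]
    out = pd.DataFrame(rows)
    out.attrs["success_fraction"] = float(out["in_top"].mean())
    return out
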