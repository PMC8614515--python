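"""End-to-end orchestration: config validation, stage execution, manifests.

A run takes either real input paths (pedigree CSV, PED/MAP genotypes,
gas-record CSV) or a simulation block, and executes the stages

    simdata? -> phenotypes -> snp_qc -> kinship -> legendre_rr (per trait)
    -> ssgwas

writing every stage's tables into the run directory together with a manifest
(seed, parameters, package version).  Identical config + seed reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinship, legendre_rr, phenotypes, simdata, snp_qc, ssgwas

_pkg_version = "0.1.0"

log = logging.getLogger("ch4herd")

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; ``.stage`` names it, partial outputs stay on disk."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def default_simulation_block() -> dict:
    """Demo-scale herd: ~300 cows over two farms, 2,000 SNPs."""
    return {
        "n_founders": 120,
        "n_generations": 2,
        "matings_per_generation": 120,
        "offspring_per_mating": 2,
        "n_snps": 2000,
        "n_chromosomes": 10,
        "maf_low": 0.05,
        "maf_high": 0.5,
        "genotyped_fraction": 330 / 483,
        "n_days_per_cow": 30,
        "mean_visits_per_day": 2.0,
        "sigma_e": 150.0,
        "K_a": [[5856.0, 500.0, 0.0], [500.0, 1200.0, 0.0], [0.0, 0.0, 400.0]],
        "K_p": [[19664.0, 0.0, 0.0], [0.0, 2000.0, 0.0], [0.0, 0.0, 800.0]],
    }


@dataclass
class RunConfig:
    """Validated, fully defaulted run configuration."""

    outdir: str = "ch4herd_run"
    seed: int = 1
    traits: list = field(default_factory=lambda: ["ppm"])
    simulate: dict | None = None
    pedigree_csv: str | None = None
    ped: str | None = None
    map: str | None = None
    records_csv: str | None = None
    dim_min: int = 5
    dim_max: int = 305
    n_harmonics: int = 2
    fixed_order: int = 4
    random_order: int = 2
    hwe_alpha: float = 1e-6
    snp_call_rate: float = 0.95
    animal_call_rate: float = 0.9
    blend_alpha: float = 0.95
    reml_max_iter: int = 200
    reml_ltol: float = 1e-6
    gwas_alpha: float = 0.05
    window_snps: int = 50
    window_kb: float = 70.0


def validate_config(config: dict | RunConfig | None) -> RunConfig:
    """Normalize a raw config mapping, reporting every violation at once."""
    if isinstance(config, RunConfig):
        config = dataclasses.asdict(config)
    raw = dict(config or {})
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})

    real_paths = [cfg.pedigree_csv, cfg.ped, cfg.map, cfg.records_csv]
    has_real = any(p is not None for p in real_paths)
    if has_real and cfg.simulate is not None:
        errors.append("config has both real-input paths and a simulation block")
    if has_real and not all(p is not None for p in real_paths):
        errors.append("real-input mode needs pedigree_csv, ped, map and records_csv")
    if not has_real and cfg.simulate is None:
        cfg.simulate = default_simulation_block()
    if cfg.simulate is not None:
        block = default_simulation_block()
        for key in cfg.simulate:
            if key not in block:
                errors.append(f"unknown simulation key {key!r}")
        block.update({k: v for k, v in cfg.simulate.items() if k in block})
        cfg.simulate = block

    for name, val, lo, hi in (
        ("hwe_alpha", cfg.hwe_alpha, 0.0, 1.0),
        ("snp_call_rate", cfg.snp_call_rate, 0.0, 1.0),
        ("animal_call_rate", cfg.animal_call_rate, 0.0, 1.0),
        ("gwas_alpha", cfg.gwas_alpha, 0.0, 1.0),
    ):
        if not (lo <= float(val) <= hi):
            errors.append(f"{name} = {val} outside [{lo}, {hi}]")
    if not 0.0 < cfg.blend_alpha <= 1.0:
        errors.append(f"blend_alpha = {cfg.blend_alpha} outside (0, 1]")
    if cfg.dim_max <= cfg.dim_min:
        errors.append("dim_max must exceed dim_min")
    if cfg.window_snps < 1 or cfg.window_kb <= 0:
        errors.append("window sizes must be positive")
    bad_traits = [t for t in cfg.traits if t not in ("ppm", "gday")]
    if bad_traits:
        errors.append(f"unknown traits {bad_traits}; choose from ['ppm', 'gday']")
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _simulate_inputs(cfg: RunConfig, outdir: Path):
    sim = cfg.simulate
    ss = np.random.SeedSequence(cfg.seed)
    s_ped, s_geno, s_eff, s_rec, s_sel = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]
    ped = simdata.simulate_pedigree(
        sim["n_founders"], sim["n_generations"], sim["matings_per_generation"],
        sim["offspring_per_mating"], seed=s_ped,
    )
    geno_all = simdata.simulate_genotypes(
        ped, sim["n_snps"], sim["n_chromosomes"], sim["maf_low"],
        sim["maf_high"], seed=s_geno,
    )
    effects = simdata.simulate_true_effects(
        ped, geno_all, np.array(sim["K_a"]), np.array(sim["K_p"]), seed=s_eff
    )
    basis = legendre_rr.LegendreBasis(
        max_order=cfg.random_order, dim_min=cfg.dim_min, dim_max=cfg.dim_max
    )
    records = simdata.simulate_records(
        ped, effects,
        schedule_spec=simdata.ScheduleSpec(
            n_days_per_cow=sim["n_days_per_cow"],
            mean_visits_per_day=sim["mean_visits_per_day"],
        ),
        sigma_e=sim["sigma_e"], seed=s_rec, basis=basis,
    )
    cows = np.sort(records["cow_id"].unique())
    n_gen = max(2, int(round(sim["genotyped_fraction"] * len(cows))))
    genotyped = simdata.choose_genotyped(cows, min(n_gen, len(cows)), seed=s_sel)
    geno = geno_all.subset_animals(genotyped)

    simdata.write_pedigree_csv(ped, outdir / "pedigree.csv")
    simdata.write_gas_records_csv(records, outdir / "gas_records.csv")
    snp_qc.write_ped_map(geno, outdir / "genotypes.ped", outdir / "genotypes.map")
    simdata.write_run_manifest(
        outdir / "simulation_manifest.json", cfg.seed, dict(sim)
    )
    return ped, geno, records


def _load_inputs(cfg: RunConfig):
    ped = simdata.read_pedigree_csv(cfg.pedigree_csv)
    if "sex" not in ped.columns:
        ped["sex"] = "F"
    if "generation" not in ped.columns:
        ped["generation"] = 0
    geno = snp_qc.read_ped_map(cfg.ped, cfg.map)
    records = phenotypes.read_gas_records_csv(cfg.records_csv)
    return ped, geno, records


def run_pipeline(config: dict | RunConfig | None) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure raises :class:`PipelineError` naming the stage; the
    outputs of completed stages remain in the run directory.
    """
    cfg = validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    def _stage(name, fn):
        t0 = time.time()
        try:
            out = fn()
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(name, str(err)) from err
        log.info("stage %-10s done in %6.2f s", name, time.time() - t0)
        return out

    if cfg.simulate is not None:
        ped, geno, records = _stage("simdata", lambda: _simulate_inputs(cfg, outdir))
    else:
        ped, geno, records = _stage("load", lambda: _load_inputs(cfg))
    log.info(
        "herd: %d pedigree animals, %d genotyped, %d raw records",
        len(ped), geno.n_animals, len(records),
    )

    def _pheno():
        models = phenotypes.fit_diurnal_fourier(records, cfg.n_harmonics)
        corrected = phenotypes.correct_diurnal(records, models)
        windows = {
            f: (max(lo, cfg.dim_min), min(hi, cfg.dim_max))
            for f, (lo, hi) in phenotypes.DEFAULT_DIM_WINDOWS.items()
        }
        for farm in corrected["farm"].unique():
            windows.setdefault(str(farm), (cfg.dim_min, cfg.dim_max))
        daily = phenotypes.daily_average(corrected, windows)
        summary = phenotypes.cohort_summary(daily, "ch4_ppm_d")
        phenotypes.write_daily_phenotypes_tsv(daily, outdir / "daily_phenotypes.tsv")
        with open(outdir / "cohort_summary.tsv", "w") as fh:
            fh.write("# columns: farm\tmean\tsd\tn\n")
            fh.write(f"# bartlett_stat={summary.attrs['bartlett_stat']:.6g}\t")
            fh.write(f"bartlett_p={summary.attrs['bartlett_p']:.6g}\n")
            fh.write(f"# welch_t={summary.attrs['welch_t']:.6g}\t")
            fh.write(f"welch_p={summary.attrs['welch_p']:.6g}\n")
            summary.to_csv(fh, sep="\t", index=False)
        return daily

    daily = _stage("phenotypes", _pheno)

    def _qc():
        filtered, report = snp_qc.qc_filter(
            geno, cfg.hwe_alpha, cfg.snp_call_rate, cfg.animal_call_rate
        )
        snp_qc.write_qc_report_tsv(report, outdir / "qc_report.tsv")
        return filtered

    geno_qc = _stage("snp_qc", _qc)

    def _kin():
        rel = kinship.build_relationships(ped, geno_qc, cfg.blend_alpha)
        scores, pct = kinship.pca_G(rel.G_raw, n_components=10)
        pca = pd.DataFrame(
            scores[:, :10], columns=[f"PC{i+1}" for i in range(scores.shape[1])]
        )
        pca.insert(0, "animal_id", rel.genotyped_ids)
        with open(outdir / "pca_G.tsv", "w") as fh:
            fh.write("# PCA of the genomic relationship matrix\n")
            fh.write(
                "# pct_var: "
                + " ".join(f"{v:.3f}" for v in pct[: scores.shape[1]])
                + "\n"
            )
            pca.to_csv(fh, sep="\t", index=False)
        return rel

    rel = _stage("kinship", _kin)

    basis_f = legendre_rr.LegendreBasis(cfg.fixed_order, cfg.dim_min, cfg.dim_max)
    basis_r = legendre_rr.LegendreBasis(cfg.random_order, cfg.dim_min, cfg.dim_max)
    for trait in cfg.traits:

        def _reml(trait=trait):
            design = legendre_rr.build_design(
                daily, basis_f, basis_r, trait, animal_ids=rel.animal_ids
            )
            vc, sols = legendre_rr.reml_fit(
                design, rel.H_inv, max_iter=cfg.reml_max_iter, ltol=cfg.reml_ltol
            )
            traj = legendre_rr.heritability_trajectory(vc, basis_r)
            legendre_rr.write_variance_components(
                vc, outdir / f"variance_components_{trait}.tsv"
            )
            legendre_rr.write_trajectory(traj, outdir / f"trajectory_{trait}.tsv")
            legendre_rr.write_ebv(sols, outdir / f"ebv_{trait}.tsv")
            return vc, sols

        vc, sols = _stage(f"reml[{trait}]", _reml)

        def _gwas(trait=trait, vc=vc, sols=sols):
            gidx = rel.genotyped_index
            c = ssgwas.aggregate_weights(basis_r)
            ebv_all = sols.bv @ c
            ebv_g = ebv_all[gidx]
            Z, d = ssgwas.centered_genotypes(geno_qc)
            u = ssgwas.backsolve_snp_effects(rel.G_raw, Z, ebv_g, d)
            sigma2_agg = float(c @ vc.K_a @ c)
            var_ebv = ssgwas.ebv_prior_variance(
                sigma2_agg, rel.G_blended
            ) - ssgwas.aggregate_pev(sols, c, gidx)
            p, se, _ = ssgwas.snp_pvalues(u, Z, rel.G_raw, var_ebv, d)
            pct = ssgwas.snp_variance_explained(Z, u, ebv_g)
            table = ssgwas.gwas_table(geno_qc, u, p, se, pct)
            thresh = ssgwas.bonferroni_threshold(cfg.gwas_alpha, geno_qc.n_snps)
            hits = ssgwas.significant_hits(table, thresh)
            win_cnt = ssgwas.window_variance(
                Z, u, ebv_g, geno_qc.snp_map, window_snps=cfg.window_snps
            )
            win_len = ssgwas.window_variance(
                Z, u, ebv_g, geno_qc.snp_map, window_snps=None,
                window_bp=int(cfg.window_kb * 1000),
            )
            with open(outdir / f"gwas_snp_{trait}.tsv", "w") as fh:
                fh.write("# columns: chrom\tpos\tsnp_id\teffect\tse\tp\tneglog10p\tpct_var\n")
                fh.write(f"# bonferroni_neglog10_threshold={thresh:.4f}\tn_hits={len(hits)}\n")
                table.to_csv(fh, sep="\t", index=False)
            for tag, win in (("snp50", win_cnt), ("len", win_len)):
                with open(outdir / f"gwas_windows_{tag}_{trait}.tsv", "w") as fh:
                    fh.write(
                        "# columns: chrom\tstart\tend\tfirst_snp\tn_snps\tpct_var\ttruncated\n"
                    )
                    win.to_csv(fh, sep="\t", index=False)

        _stage(f"gwas[{trait}]", _gwas)

    manifest = {
        "version": _pkg_version,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "elapsed_s": round(time.time() - t_start, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return outdir
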