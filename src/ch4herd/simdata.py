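"""Synthetic dairy-herd generator: pedigree, genotypes, effects, gas records.

Emulates the structure of a two-farm commercial herd monitored with an
in-parlour gas analyzer: ~483 lactating Holstein-Friesian cows, ~330 of them
genotyped at a ~39k-SNP chip, with repeated within-day CH4/CO2 concentration
measurements during milking, days in milk 5-305 and lactations 1-8.  The
generated data carry exactly the statistical structure the downstream
random-regression model assumes — additive-genetic and permanent-environment
regression coefficient vectors on a normalized Legendre basis, farm-year-week
contemporary groups, a Fourier diurnal rhythm, and i.i.d. residual noise —
so every pipeline stage is testable without the (non-public) farm data.

Genotypes are produced by gene dropping down the pedigree, so the realized
genomic relationships converge to the pedigree expectations as the number of
SNPs grows.  True breeding-value coefficients can be drawn either from the
pedigree (founder ~ N(0, K_a); offspring = parent average + Mendelian
sampling) or from the genotypes themselves (per-SNP effects summed over
centered allele counts and rescaled to the target coefficient covariance).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN_PARENT",
    "GenotypeMatrix",
    "TrueEffects",
    "FarmProfile",
    "FixedSpec",
    "DiurnalSpec",
    "ScheduleSpec",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_true_effects",
    "simulate_records",
    "choose_genotyped",
    "write_pedigree_csv",
    "read_pedigree_csv",
    "write_gas_records_csv",
    "write_run_manifest",
]

UNKNOWN_PARENT = 0


def _chrom_key(label: str) -> int:
    """Numeric chromosomes in order, then sex/unassigned labels."""
    try:
        return int(label)
    except ValueError:
        return 1000 + sum(map(ord, label))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Allele-count matrix (animals x SNPs) with a sorted physical map.

    ``counts`` uses float storage with ``nan`` for missing genotypes;
    non-missing entries are 0/1/2 counts of the alternate allele.  The map
    has columns ``snp_id, chrom, pos`` and is sorted by (chromosome,
    position); chromosome labels are strings ("1".."29", "X", "Y", "0").
    """

    counts: np.ndarray
    snp_map: pd.DataFrame
    animal_ids: np.ndarray
    base_freq: np.ndarray | None = None  # simulation-truth founder frequencies

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.animal_ids = np.asarray(self.animal_ids)
        if self.counts.shape != (len(self.animal_ids), len(self.snp_map)):
            raise ValueError("counts shape inconsistent with ids/map")
        valid = self.counts[~np.isnan(self.counts)]
        if valid.size and (valid.min() < 0 or valid.max() > 2):
            raise ValueError("allele counts must be in {0, 1, 2}")
        m = self.snp_map.reset_index(drop=True)
        ckey = np.array([_chrom_key(c) for c in m["chrom"].astype(str)])
        order = np.lexsort((m["pos"].to_numpy(), ckey))
        if not np.array_equal(order, np.arange(len(m))):
            m = m.iloc[order].reset_index(drop=True)
            self.counts = self.counts[:, order]
            if self.base_freq is not None:
                self.base_freq = np.asarray(self.base_freq)[order]
        self.snp_map = m

    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.counts, axis=0) / 2.0

    def subset_animals(self, animal_ids) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([pos[a] for a in animal_ids])
        return GenotypeMatrix(
            counts=self.counts[idx].copy(),
            snp_map=self.snp_map.copy(),
            animal_ids=np.asarray(animal_ids),
            base_freq=None if self.base_freq is None else self.base_freq.copy(),
        )


@dataclass
class TrueEffects:
    """True per-animal regression-coefficient effects used to build records."""

    animal_ids: np.ndarray
    bv: np.ndarray  # (n_animals, k) genetic coefficients
    pe: np.ndarray  # (n_animals, k) permanent-environment coefficients
    snp_effects: np.ndarray | None = None  # (n_snps, k) when genotype-driven

    def __post_init__(self):
        if self.bv.shape != self.pe.shape or self.bv.shape[0] != len(self.animal_ids):
            raise ValueError("effect dimensions inconsistent with herd")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    matings_per_generation: int,
    offspring_per_mating: int,
    seed: int | np.random.Generator = 0,
    n_sires_per_generation: int | None = None,
) -> pd.DataFrame:
    """Simulate a discrete-generation pedigree.

    Founders (generation 0) have unknown parents and alternating sexes (M,
    F, M, ...), guaranteeing at least one mating pair whenever
    ``n_founders >= 2``.  Each later generation draws
    ``matings_per_generation`` sire/dam pairs from all previous generations
    and produces ``offspring_per_mating`` offspring per pair, with sexes
    again alternating.  ``n_sires_per_generation`` restricts each
    generation's sires to a small sampled pool, mimicking the heavy use of
    few AI bulls (large paternal half-sib families) typical of commercial
    dairy herds.  Total size is
    ``n_founders + n_generations * matings_per_generation * offspring_per_mating``.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 0 or matings_per_generation < 1 or offspring_per_mating < 1:
        raise ValueError("generation/mating/offspring counts must be positive")
    if n_sires_per_generation is not None and n_sires_per_generation < 1:
        raise ValueError("n_sires_per_generation must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rows = []
    nid = 0
    for _ in range(n_founders):
        nid += 1
        rows.append((nid, UNKNOWN_PARENT, UNKNOWN_PARENT, 0, "M" if nid % 2 else "F"))
    for gen in range(1, n_generations + 1):
        males = [r[0] for r in rows if r[4] == "M"]
        females = [r[0] for r in rows if r[4] == "F"]
        if not males or not females:
            raise ValueError("mating impossible: a sex pool is empty")
        if n_sires_per_generation is not None:
            pool = rng.choice(
                males, size=min(n_sires_per_generation, len(males)), replace=False
            )
        else:
            pool = males
        for _ in range(matings_per_generation):
            sire = int(rng.choice(pool))
            dam = int(rng.choice(females))
            for _ in range(offspring_per_mating):
                nid += 1
                rows.append((nid, sire, dam, gen, "M" if nid % 2 else "F"))
    return pd.DataFrame(
        rows, columns=["animal_id", "sire_id", "dam_id", "generation", "sex"]
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _snp_positions(n_snps: int, n_chromosomes: int, chrom_length_bp: int):
    """Evenly spaced positions; chromosome density mimics a 50k chip."""
    per = np.full(n_chromosomes, n_snps // n_chromosomes)
    per[: n_snps % n_chromosomes] += 1
    chroms, pos = [], []
    for c, cnt in enumerate(per, start=1):
        spacing = chrom_length_bp // (cnt + 1)
        chroms += [str(c)] * cnt
        pos += [spacing * (i + 1) for i in range(cnt)]
    return chroms, pos


def simulate_genotypes(
    pedigree: pd.DataFrame,
    n_snps: int,
    n_chromosomes: int = 29,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
    chrom_length_bp: int = 100_000_000,
) -> GenotypeMatrix:
    """Gene-drop biallelic genotypes down a pedigree.

    Founder haplotype alleles are Bernoulli draws at per-SNP frequencies
    uniform on ``[maf_low, maf_high]``; every non-founder inherits one
    uniformly chosen allele from each parent, independently per SNP, so the
    realized genomic relationships track the pedigree.  Optionally masks a
    fraction of calls as missing.
    """
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if n_snps < n_chromosomes:
        raise ValueError("need at least one SNP per chromosome")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    ids = pedigree["animal_id"].to_numpy()
    pos_of = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    p = rng.uniform(maf_low, maf_high, size=n_snps)
    h1 = np.zeros((n, n_snps), dtype=np.int8)
    h2 = np.zeros((n, n_snps), dtype=np.int8)
    sires = pedigree["sire_id"].to_numpy()
    dams = pedigree["dam_id"].to_numpy()
    for i in range(n):
        s, d = sires[i], dams[i]
        if s == UNKNOWN_PARENT:
            h1[i] = rng.random(n_snps) < p
        else:
            si = pos_of[s]
            pick = rng.integers(0, 2, size=n_snps, dtype=np.int8)
            h1[i] = np.where(pick == 0, h1[si], h2[si])
        if d == UNKNOWN_PARENT:
            h2[i] = rng.random(n_snps) < p
        else:
            di = pos_of[d]
            pick = rng.integers(0, 2, size=n_snps, dtype=np.int8)
            h2[i] = np.where(pick == 0, h1[di], h2[di])
    counts = (h1 + h2).astype(float)
    if missing_rate > 0:
        mask = rng.random(counts.shape) < missing_rate
        counts[mask] = np.nan

    chroms, bppos = _snp_positions(n_snps, n_chromosomes, chrom_length_bp)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{i+1}" for i in range(n_snps)],
            "chrom": chroms,
            "pos": bppos,
        }
    )
    return GenotypeMatrix(
        counts=counts, snp_map=snp_map, animal_ids=ids, base_freq=p
    )


def choose_genotyped(
    cow_ids, n_genotyped: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Random genotyped subset of the phenotyped cows (order preserved)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cow_ids = np.asarray(cow_ids)
    if n_genotyped > len(cow_ids):
        raise ValueError("cannot genotype more cows than exist")
    sel = np.sort(rng.choice(len(cow_ids), size=n_genotyped, replace=False))
    return cow_ids[sel]


# ---------------------------------------------------------------------------
# true effects
# ---------------------------------------------------------------------------


def _psd_sqrt(K: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (K + K.T))
    if w.min() < -1e-10 * max(1.0, abs(w).max()):
        raise ValueError("covariance matrix is not positive semidefinite")
    return (V * np.sqrt(np.clip(w, 0, None))) @ V.T


def simulate_true_effects(
    pedigree: pd.DataFrame,
    genotypes: GenotypeMatrix | None,
    K_a_true: np.ndarray,
    K_p_true: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> TrueEffects:
    """Draw true genetic and permanent-environment coefficient vectors.

    Pedigree mode (``genotypes=None``): founders ~ N(0, K_a); offspring are
    the parent average plus a Mendelian-sampling term with variance
    0.5/0.75/1.0 x K_a for both/one/no known parents (parental inbreeding
    ignored).  Genotype mode: per-SNP coefficient effects are drawn i.i.d.
    N(0, K_a / d) with d the VanRaden denominator and summed over
    frequency-centered allele counts, so that conditional on the genotypes
    the coefficient covariance across animals is exactly the genomic
    relationship times ``K_a_true`` — the realized herd covariance targets
    ``K_a_true``.  Permanent environment is always i.i.d. N(0, K_p).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    K_a = np.atleast_2d(np.asarray(K_a_true, dtype=float))
    K_p = np.atleast_2d(np.asarray(K_p_true, dtype=float))
    k = K_a.shape[0]
    if K_p.shape != (k, k):
        raise ValueError("K_a and K_p dimensions differ")
    La = _psd_sqrt(K_a)
    Lp = _psd_sqrt(K_p)
    ids = pedigree["animal_id"].to_numpy()
    n = len(ids)
    pos = {a: i for i, a in enumerate(ids)}
    snp_effects = None

    if np.allclose(K_a, 0.0):
        bv = np.zeros((n, k))
    elif genotypes is None:
        sires = pedigree["sire_id"].to_numpy()
        dams = pedigree["dam_id"].to_numpy()
        bv = np.zeros((n, k))
        for i in range(n):
            s, d = sires[i], dams[i]
            known = int(s != UNKNOWN_PARENT) + int(d != UNKNOWN_PARENT)
            mean = np.zeros(k)
            if s != UNKNOWN_PARENT:
                mean += 0.5 * bv[pos[s]]
            if d != UNKNOWN_PARENT:
                mean += 0.5 * bv[pos[d]]
            msv = {0: 1.0, 1: 0.75, 2: 0.5}[known]
            bv[i] = mean + np.sqrt(msv) * (La @ rng.standard_normal(k))
    else:
        if not np.array_equal(genotypes.animal_ids, ids):
            raise ValueError("genotype animals must match the pedigree")
        p = genotypes.allele_freq()
        denom = 2.0 * float(np.sum(p * (1.0 - p)))
        if denom <= 0:
            raise ValueError("cannot draw genotype-driven effects: no polymorphism")
        Z = genotypes.counts - 2.0 * p
        Z[np.isnan(Z)] = 0.0
        snp_effects = rng.standard_normal((genotypes.n_snps, k)) @ La.T / np.sqrt(denom)
        bv = Z @ snp_effects

    pe = rng.standard_normal((n, k)) @ Lp.T
    return TrueEffects(animal_ids=ids, bv=bv, pe=pe, snp_effects=snp_effects)


# ---------------------------------------------------------------------------
# gas records
# ---------------------------------------------------------------------------


@dataclass
class FarmProfile:
    """Per-farm fixed conditions, defaults on the scale of the study herds."""

    name: str
    mean_ppm: float
    dim_min: int
    dim_max: int
    live_weight_mean: float
    live_weight_sd: float
    milk_mean: float
    milk_sd: float
    start_date: _dt.date
    n_weeks: int


def _default_farms() -> tuple[FarmProfile, FarmProfile]:
    return (
        FarmProfile(
            name="farm1", mean_ppm=505.0, dim_min=15, dim_max=305,
            live_weight_mean=544.0, live_weight_sd=115.0,
            milk_mean=33.7, milk_sd=6.82,
            start_date=_dt.date(2014, 12, 2), n_weeks=60,
        ),
        FarmProfile(
            name="farm2", mean_ppm=517.0, dim_min=5, dim_max=305,
            live_weight_mean=669.0, live_weight_sd=73.0,
            milk_mean=36.6, milk_sd=8.79,
            start_date=_dt.date(2016, 2, 5), n_weeks=6,
        ),
    )


@dataclass
class FixedSpec:
    """Fixed-effect layer: farm means, lactation contrast, DIM curve, FYW."""

    farms: tuple = field(default_factory=_default_farms)
    lac2_effect: float = 25.0  # ppm shift of lactation class 2+
    curve_coeffs: tuple = (-40.0, 15.0, -6.0, 2.0)  # Legendre orders 1..4, ppm
    fyw_sd: float = 30.0  # sd of farm-year-week effects, ppm


@dataclass
class DiurnalSpec:
    """Fourier diurnal rhythm; harmonic k has period 24/k hours.

    ``harmonics`` lists (sine, cosine) amplitudes.  The default of two
    harmonics reflects the strong 24 h feeding/milking cycle with a weaker
    12 h overtone.
    """

    harmonics: tuple = ((20.0, 10.0), (8.0, 4.0))

    def evaluate(self, time_h: np.ndarray) -> np.ndarray:
        t = np.asarray(time_h, dtype=float)
        out = np.zeros_like(t)
        for kk, (a_sin, a_cos) in enumerate(self.harmonics, start=1):
            out += a_sin * np.sin(2 * np.pi * kk * t / 24.0)
            out += a_cos * np.cos(2 * np.pi * kk * t / 24.0)
        return out


@dataclass
class ScheduleSpec:
    """Visit schedule and cow-level covariate generation."""

    n_days_per_cow: int = 60
    mean_visits_per_day: float = 2.5
    farm_share: tuple = (0.9, 0.1)  # fraction of cows per farm (record counts ~ 31k/3k)
    lactation_probs: tuple = (0.45, 0.25, 0.14, 0.08, 0.04, 0.02, 0.013, 0.007)
    conception_dim: int = 85
    co2_ratio_mean: float = 0.1
    co2_ratio_sd: float = 0.01


def simulate_records(
    pedigree: pd.DataFrame,
    true_effects: TrueEffects,
    fixed_spec: FixedSpec | None = None,
    diurnal_spec: DiurnalSpec | None = None,
    schedule_spec: ScheduleSpec | None = None,
    sigma_e: float = 150.0,
    seed: int | np.random.Generator = 0,
    cow_ids=None,
    basis=None,
) -> pd.DataFrame:
    """Generate within-day CH4/CO2 gas records for the herd's cows.

    Each cow (by default every female in the pedigree) is assigned a farm,
    lactation number (1-8), calving date and a set of measurement days inside
    the farm's DIM window; every milking visit yields one record

        ch4_ppm = farm mean + LAC effect + fixed DIM curve + FYW effect
                  + phi(dim)'a_i + phi(dim)'pe_i + diurnal(t) + N(0, sigma_e^2)

    CO2 ppm is the CH4 concentration divided by a per-cow ratio ~
    N(0.1, 0.01^2) truncated positive, so the CH4:CO2 ratio used for the
    g/d phenotype has a configurable mean.  Live weight, milk and pregnancy
    day follow the per-farm profiles.
    """
    if sigma_e < 0:
        raise ValueError("sigma_e must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fixed = fixed_spec or FixedSpec()
    diurnal = diurnal_spec or DiurnalSpec()
    sched = schedule_spec or ScheduleSpec()
    if basis is None:
        from .legendre_rr import LegendreBasis

        basis = LegendreBasis(max_order=2, dim_min=5, dim_max=305)

    ids = pedigree["animal_id"].to_numpy()
    pos = {a: i for i, a in enumerate(ids)}
    if cow_ids is None:
        cow_ids = pedigree.loc[pedigree["sex"] == "F", "animal_id"].to_numpy()
    cow_ids = np.asarray(cow_ids)
    if cow_ids.size == 0:
        raise ValueError("no cows to generate records for")

    farms = fixed.farms
    share = np.asarray(sched.farm_share, dtype=float)
    share = share / share.sum()
    farm_idx = rng.choice(len(farms), size=len(cow_ids), p=share)
    lact = rng.choice(
        np.arange(1, 9), size=len(cow_ids),
        p=np.asarray(sched.lactation_probs) / np.sum(sched.lactation_probs),
    )

    fyw_effects: dict[str, float] = {}
    rows = []
    for ci, cow in enumerate(cow_ids):
        farm = farms[farm_idx[ci]]
        ai = pos[cow]
        a_co = true_effects.bv[ai]
        p_co = true_effects.pe[ai]
        lw = max(rng.normal(farm.live_weight_mean, farm.live_weight_sd), 300.0)
        milk_base = max(rng.normal(farm.milk_mean, farm.milk_sd), 5.0)
        ratio = abs(rng.normal(sched.co2_ratio_mean, sched.co2_ratio_sd))
        ratio = max(ratio, 1e-3)

        lo = max(farm.dim_min, basis.dim_min)
        hi = min(farm.dim_max, basis.dim_max)
        n_days = min(sched.n_days_per_cow, hi - lo + 1)
        dims = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_days, replace=False))
        calving_offset = int(rng.integers(0, max(farm.n_weeks * 7 - 1, 1)))
        calving = farm.start_date + _dt.timedelta(days=calving_offset - int(dims[0]))
        phi = basis.evaluate(dims)
        lac_class_eff = fixed.lac2_effect if lact[ci] >= 2 else 0.0
        curve = phi_fixed_curve(basis, dims, fixed.curve_coeffs)

        for di, dim in enumerate(dims):
            date = calving + _dt.timedelta(days=int(dim))
            iso = date.isocalendar()
            key = f"{farm.name}-{iso.year}-W{iso.week:02d}"
            if key not in fyw_effects:
                fyw_effects[key] = (
                    rng.normal(0.0, fixed.fyw_sd) if fixed.fyw_sd > 0 else 0.0
                )
            base = (
                farm.mean_ppm
                + lac_class_eff
                + curve[di]
                + fyw_effects[key]
                + phi[di] @ a_co
                + phi[di] @ p_co
            )
            n_visits = 1 + (
                rng.poisson(sched.mean_visits_per_day - 1.0)
                if sched.mean_visits_per_day > 1.0
                else 0
            )
            times = np.sort(rng.uniform(0.0, 24.0, size=n_visits))
            for t in times:
                ch4 = base + diurnal.evaluate(np.array([t]))[0]
                if sigma_e > 0:
                    ch4 += rng.normal(0.0, sigma_e)
                ch4 = max(ch4, 1.0)
                milk = max(milk_base + rng.normal(0.0, 1.0), 1.0)
                rows.append(
                    (
                        int(cow), farm.name, date, float(t), int(lact[ci]),
                        int(dim), float(ch4), float(ch4 / ratio), float(milk),
                        float(lw), int(max(0, dim - sched.conception_dim)),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "cow_id", "farm", "date", "time_h", "lactation", "dim",
            "ch4_ppm", "co2_ppm", "milk_kg_day", "live_weight_kg",
            "pregnancy_day",
        ],
    )
    return df


def phi_fixed_curve(basis, dims, coeffs) -> np.ndarray:
    """Fixed lactation curve: Legendre orders 1..len(coeffs) at the DIMs."""
    from .legendre_rr import LegendreBasis

    full = LegendreBasis(
        max_order=len(coeffs), dim_min=basis.dim_min, dim_max=basis.dim_max
    )
    phi = full.evaluate(dims)[:, 1:]
    return phi @ np.asarray(coeffs, dtype=float)


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------


def write_pedigree_csv(pedigree: pd.DataFrame, path) -> None:
    pedigree[["animal_id", "sire_id", "dam_id"]].to_csv(path, index=False)


def read_pedigree_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"animal_id", "sire_id", "dam_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"pedigree CSV must have columns {sorted(need)}")
    return df


def write_gas_records_csv(records: pd.DataFrame, path) -> None:
    """Gas-record CSV with an ISO-8601 timestamp column."""
    out = records.copy()
    ts = []
    for d, t in zip(out["date"], out["time_h"]):
        hh = int(t)
        mm = int(round((t - hh) * 60)) % 60
        ts.append(f"{pd.Timestamp(d).date().isoformat()}T{hh:02d}:{mm:02d}:00")
    out.insert(2, "timestamp", ts)
    out = out.drop(columns=["date", "time_h"])
    out.to_csv(path, index=False)


def write_run_manifest(path, seed: int, params: dict) -> None:
    """Echo the seed and generator parameters next to every emitted dataset."""

    def _clean(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, _dt.date):
            return v.isoformat()
        return v

    payload = {"seed": int(seed), "params": {k: _clean(v) for k, v in params.items()}}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
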