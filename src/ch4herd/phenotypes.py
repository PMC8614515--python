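"""Daily methane phenotypes from raw within-day gas records.

Two analysis traits are built from in-parlour gas-analyzer records:

* **CH4 ppm/d** — per-record CH4 concentrations are corrected for the diurnal
  rhythm with a per-farm Fourier-series fit (intercept retained), then
  averaged per cow per day inside the farm's DIM window.
* **CH4 g/d** — the daily mean CH4:CO2 concentration ratio multiplied by the
  cow's predicted daily CO2 exhalation volume (from heat production via live
  weight, energy-corrected milk and pregnancy stage) and by the density of
  methane, 0.668 g/L at 20 degC and 101.325 kPa.

The module also produces the between-farm comparison statistics: per-farm
summaries, the Bartlett variance-equality test, and Welch's two-sample t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiurnalModel",
    "fit_diurnal_fourier",
    "correct_diurnal",
    "daily_average",
    "predict_co2_liters_per_day",
    "ch4_grams_per_day",
    "cohort_summary",
    "welch_from_summaries",
    "bartlett_from_summaries",
    "read_gas_records_csv",
    "write_daily_phenotypes_tsv",
    "MAX_LACTATION",
    "CH4_DENSITY_G_PER_L",
]

MAX_LACTATION = 8
CH4_DENSITY_G_PER_L = 0.668

# Heat-production convention (watts): a * weight^0.75 + b * ECM + c * preg^3,
# with 1 heat-producing unit (HPU) = 1000 W exhaling 180 L CO2 per hour.
HP_WEIGHT_COEF = 5.6
HP_ECM_COEF = 22.0
HP_PREG_COEF = 1.6e-5
CO2_L_PER_HPU_HOUR = 180.0


@dataclass
class DiurnalModel:
    """Per-farm Fourier fit of concentration on time of day.

    Harmonic k has period 24/k hours; ``sin_coeff[k-1]`` / ``cos_coeff[k-1]``
    are its fitted amplitudes.
    """

    farm: str
    intercept: float
    sin_coeff: np.ndarray
    cos_coeff: np.ndarray

    @property
    def n_harmonics(self) -> int:
        return len(self.sin_coeff)

    def deviation(self, time_h) -> np.ndarray:
        """Fitted diurnal deviation (without the intercept)."""
        t = np.asarray(time_h, dtype=float)
        out = np.zeros_like(t)
        for k in range(1, self.n_harmonics + 1):
            w = 2 * np.pi * k * t / 24.0
            out += self.sin_coeff[k - 1] * np.sin(w)
            out += self.cos_coeff[k - 1] * np.cos(w)
        return out


def _design(time_h: np.ndarray, n_harmonics: int) -> np.ndarray:
    cols = [np.ones_like(time_h)]
    for k in range(1, n_harmonics + 1):
        w = 2 * np.pi * k * time_h / 24.0
        cols += [np.sin(w), np.cos(w)]
    return np.column_stack(cols)


def fit_diurnal_fourier(
    records: pd.DataFrame, n_harmonics: int = 2, value_col: str = "ch4_ppm"
) -> dict[str, DiurnalModel]:
    """Least-squares Fourier fit of concentration on clock time, per farm."""
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    models = {}
    for farm, grp in records.groupby("farm", sort=True):
        t = grp["time_h"].to_numpy(dtype=float)
        y = grp[value_col].to_numpy(dtype=float)
        if len(grp) < 2 * n_harmonics + 1 or np.unique(np.round(t, 9)).size < 2:
            raise ValueError(
                f"farm {farm!r}: too few records/distinct times for "
                f"{n_harmonics} harmonics"
            )
        X = _design(t, n_harmonics)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"farm {farm!r}: rank-deficient diurnal design")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        models[farm] = DiurnalModel(
            farm=str(farm),
            intercept=float(beta[0]),
            sin_coeff=beta[1::2].copy(),
            cos_coeff=beta[2::2].copy(),
        )
    return models


def correct_diurnal(
    records: pd.DataFrame,
    models: dict[str, DiurnalModel],
    value_col: str = "ch4_ppm",
) -> pd.DataFrame:
    """Subtract each record's fitted diurnal deviation (intercept retained).

    The deviation is centered over the corrected sample per farm, so the
    farm mean of the series is preserved exactly on any input.
    """
    out = records.copy()
    corrected = np.empty(len(out))
    for farm, grp in out.groupby("farm", sort=False):
        if farm not in models:
            raise ValueError(f"no diurnal model for farm {farm!r}")
        mod = models[farm]
        if mod.farm != str(farm):
            raise ValueError(f"diurnal model labelled {mod.farm!r} used on {farm!r}")
        idx = out.index.get_indexer(grp.index)
        dev = mod.deviation(grp["time_h"].to_numpy(dtype=float))
        corrected[idx] = grp[value_col].to_numpy(dtype=float) - (dev - dev.mean())
    out[value_col] = corrected
    return out


DEFAULT_DIM_WINDOWS = {"farm1": (15, 305), "farm2": (5, 305)}


def daily_average(
    records: pd.DataFrame,
    farm_dim_windows: dict[str, tuple[int, int]] | None = None,
    compute_g_per_day: bool = True,
    fpcm_is_raw_milk: bool = False,
) -> pd.DataFrame:
    """Collapse corrected records to one row per cow per date.

    Rows outside the farm's DIM window are dropped; lactation numbers above 8
    are rejected.  The farm-year-week label is ``farm-ISOyear-Wweek``.  The
    g/d trait needs live weight, milk and pregnancy day; where any covariate
    is missing the value is left absent rather than imputed.
    """
    windows = farm_dim_windows or DEFAULT_DIM_WINDOWS
    df = records.copy()
    if (df["lactation"] > MAX_LACTATION).any():
        bad = df.loc[df["lactation"] > MAX_LACTATION, "cow_id"].unique()
        raise ValueError(
            f"records beyond lactation {MAX_LACTATION} (cows {bad[:5].tolist()})"
        )
    keep = np.ones(len(df), dtype=bool)
    for farm, (lo, hi) in windows.items():
        sel = df["farm"] == farm
        keep &= ~sel | ((df["dim"] >= lo) & (df["dim"] <= hi))
    unknown = ~df["farm"].isin(windows)
    if unknown.any():
        raise ValueError(
            f"no DIM window configured for farms {sorted(df.loc[unknown, 'farm'].unique())}"
        )
    df = df.loc[keep]
    if fpcm_is_raw_milk:
        warnings.warn(
            "treating raw milk kg as fat-protein-corrected milk", stacklevel=2
        )

    df = df.assign(ratio=df["ch4_ppm"] / df["co2_ppm"])
    grouped = df.groupby(["cow_id", "date"], sort=True)
    agg = grouped.agg(
        farm=("farm", "first"),
        dim=("dim", "first"),
        lactation=("lactation", "first"),
        ch4_ppm_d=("ch4_ppm", "mean"),
        ratio=("ratio", "mean"),
        milk_kg_day=("milk_kg_day", "mean"),
        live_weight_kg=("live_weight_kg", "mean"),
        pregnancy_day=("pregnancy_day", "first"),
    ).reset_index()

    iso = pd.to_datetime(agg["date"]).dt.isocalendar()
    agg["fyw"] = (
        agg["farm"].astype(str)
        + "-"
        + iso["year"].astype(str)
        + "-W"
        + iso["week"].astype(int).map("{:02d}".format)
    )
    agg["lac_class"] = np.where(agg["lactation"] >= 2, "2+", "1")

    if compute_g_per_day:
        ok = (
            np.isfinite(agg["live_weight_kg"])
            & np.isfinite(agg["milk_kg_day"])
            & np.isfinite(agg["pregnancy_day"])
            & np.isfinite(agg["ratio"])
        )
        g = np.full(len(agg), np.nan)
        co2_l = predict_co2_liters_per_day(
            agg.loc[ok, "live_weight_kg"].to_numpy(),
            agg.loc[ok, "milk_kg_day"].to_numpy(),
            agg.loc[ok, "pregnancy_day"].to_numpy(),
        )
        g[np.flatnonzero(ok)] = agg.loc[ok, "ratio"].to_numpy() * co2_l * CH4_DENSITY_G_PER_L
        agg["ch4_g_d"] = g
    else:
        agg["ch4_g_d"] = np.nan

    return agg[
        [
            "cow_id", "date", "farm", "dim", "lactation", "lac_class", "fyw",
            "ch4_ppm_d", "ch4_g_d", "milk_kg_day", "live_weight_kg",
            "pregnancy_day",
        ]
    ]


def predict_co2_liters_per_day(live_weight_kg, ecm_kg_day, pregnancy_day):
    """Predicted CO2 exhalation (L/day) from heat production.

    Heat production in watts is ``5.6 * weight^0.75 + 22 * ECM +
    1.6e-5 * pregnancy_day^3``; one heat-producing unit (1000 W) exhales
    180 L CO2 per hour.
    """
    w = np.asarray(live_weight_kg, dtype=float)
    m = np.asarray(ecm_kg_day, dtype=float)
    p = np.asarray(pregnancy_day, dtype=float)
    if np.any(w < 0) or np.any(m < 0) or np.any(p < 0):
        raise ValueError("inputs must be non-negative")
    watts = HP_WEIGHT_COEF * w**0.75 + HP_ECM_COEF * m + HP_PREG_COEF * p**3
    hpu = watts / 1000.0
    out = CO2_L_PER_HPU_HOUR * hpu * 24.0
    return out if out.ndim else float(out)


def ch4_grams_per_day(ch4_ppm, co2_ppm, co2_liters_day):
    """CH4 mass output: (CH4/CO2 concentration ratio) x CO2 L/day x 0.668 g/L."""
    co2 = np.asarray(co2_ppm, dtype=float)
    if np.any(co2 <= 0):
        raise ValueError("co2_ppm must be positive")
    out = (
        np.asarray(ch4_ppm, dtype=float) / co2
    ) * np.asarray(co2_liters_day, dtype=float) * CH4_DENSITY_G_PER_L
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# farm comparison
# ---------------------------------------------------------------------------


def welch_from_summaries(mean1, sd1, n1, mean2, sd2, n2):
    """Welch two-sample t with Satterthwaite df from (mean, SD, n) summaries."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(res.statistic), float(res.pvalue)


def bartlett_from_summaries(sds, ns):
    """Bartlett variance-equality statistic from per-group (SD, n)."""
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = len(sds)
    if k < 2 or np.any(ns < 2):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    v = ns - 1
    sp2 = np.sum(v * sds**2) / v.sum()
    num = v.sum() * np.log(sp2) - np.sum(v * np.log(sds**2))
    corr = 1 + (np.sum(1 / v) - 1 / v.sum()) / (3 * (k - 1))
    statistic = num / corr
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), p


def cohort_summary(
    daily_phenotypes: pd.DataFrame | None = None,
    trait: str = "ch4_ppm_d",
    summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-farm summary plus Bartlett and Welch farm-comparison tests.

    Either raw daily phenotypes or a pre-aggregated table with columns
    ``farm, mean, sd, n`` may be supplied.  Tests compare the first two farms
    (this study design has exactly two); the test results land in the
    DataFrame ``.attrs`` (``bartlett_stat``, ``bartlett_p``, ``welch_t``,
    ``welch_p``).
    """
    if summaries is not None:
        summ = summaries.copy()
        samples = None
    else:
        if daily_phenotypes is None:
            raise ValueError("supply daily phenotypes or summaries")
        df = daily_phenotypes.loc[
            np.isfinite(daily_phenotypes[trait].to_numpy(dtype=float))
        ]
        groups = df.groupby("farm", sort=True)[trait]
        summ = groups.agg(mean="mean", sd="std", n="count").reset_index()
        samples = [g.to_numpy(dtype=float) for _, g in groups]
    if len(summ) < 2:
        raise ValueError("need at least two farms to compare")
    if (summ["n"] < 2).any():
        raise ValueError("each farm needs at least 2 records")

    if samples is not None:
        b_stat, b_p = stats.bartlett(*samples)
        w = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        w_t, w_p = float(w.statistic), float(w.pvalue)
    else:
        b_stat, b_p = bartlett_from_summaries(summ["sd"], summ["n"])
        w_t, w_p = welch_from_summaries(
            summ["mean"].iloc[0], summ["sd"].iloc[0], summ["n"].iloc[0],
            summ["mean"].iloc[1], summ["sd"].iloc[1], summ["n"].iloc[1],
        )
    summ.attrs.update(
        bartlett_stat=float(b_stat), bartlett_p=float(b_p),
        welch_t=float(w_t), welch_p=float(w_p), trait=trait,
    )
    return summ


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------


def read_gas_records_csv(path) -> pd.DataFrame:
    """Read the gas-record CSV written by the herd generator."""
    df = pd.read_csv(path)
    if "timestamp" in df.columns:
        ts = pd.to_datetime(df["timestamp"])
        df["date"] = ts.dt.date
        df["time_h"] = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
        df = df.drop(columns=["timestamp"])
    need = {"cow_id", "farm", "date", "time_h", "lactation", "dim", "ch4_ppm", "co2_ppm"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"gas-record CSV missing columns {sorted(missing)}")
    return df


def write_daily_phenotypes_tsv(daily: pd.DataFrame, path) -> None:
    cols = ["cow_id", "date", "dim", "lac_class", "fyw", "ch4_ppm_d", "ch4_g_d"]
    with open(path, "w") as fh:
        fh.write("# columns: " + "\t".join(cols) + "\n")
        daily[cols].to_csv(fh, sep="\t", index=False)
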