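"""Genotype quality control for chip data.

Filters are applied in a fixed, documented order: sex/unassigned chromosome
removal, animal call rate (animals strictly below 0.9 removed), SNP call rate
(only SNPs strictly above 0.95 kept), monomorphic removal, and a
Hardy-Weinberg-equilibrium goodness-of-fit rejection at a configurable alpha
(default 1e-6, the conventional chip-QC level).  Missing genotypes stay
missing after QC; imputation is the kinship module's concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GenotypeMatrix

__all__ = [
    "QcReport",
    "hwe_test",
    "qc_filter",
    "read_ped_map",
    "write_ped_map",
    "read_counts_csv",
    "write_qc_report_tsv",
    "SEX_CHROMOSOMES",
    "UNASSIGNED_CHROMOSOMES",
]

SEX_CHROMOSOMES = {"X", "Y", "XY", "30", "31"}
UNASSIGNED_CHROMOSOMES = {"0", "UN", "NA"}


@dataclass
class QcReport:
    """What quality control removed, step by step."""

    n_snps_in: int
    n_animals_in: int
    n_snps_out: int = 0
    n_animals_out: int = 0
    removed: dict = field(default_factory=dict)  # rule -> count
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("snps_in", self.n_snps_in), ("animals_in", self.n_animals_in)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows += [("snps_out", self.n_snps_out), ("animals_out", self.n_animals_out)]
        return pd.DataFrame(rows, columns=["step", "count"])


def hwe_test(n_AA: int, n_Aa: int, n_aa: int):
    """Hardy-Weinberg goodness-of-fit chi-square (1 df).

    Expected genotype counts come from the estimated allele frequency.
    Monomorphic input has no degrees of freedom: the test is skipped and
    ``(nan, nan)`` returned.
    """
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(obs < 0):
        raise ValueError("genotype counts must be non-negative")
    n = obs.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * obs[0] + obs[1]) / (2 * n)
    if p in (0.0, 1.0):
        return float("nan"), float("nan")
    exp = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    return statistic, float(stats.chi2.sf(statistic, df=1))


def _snp_hwe_pvalues(counts: np.ndarray) -> np.ndarray:
    out = np.full(counts.shape[1], np.nan)
    for j in range(counts.shape[1]):
        col = counts[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        n_aa = int(np.sum(col == 0))
        n_het = int(np.sum(col == 1))
        n_AA = int(np.sum(col == 2))
        _, p = hwe_test(n_AA, n_het, n_aa)
        out[j] = p
    return out


def qc_filter(
    genotypes: GenotypeMatrix,
    hwe_alpha: float = 1e-6,
    snp_call_rate_min: float = 0.95,
    animal_call_rate_min: float = 0.9,
    excluded_chromosomes=None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply all QC rules in order and report the per-rule removals.

    Boundary readings are strict on both axes: a SNP call rate must exceed
    ``snp_call_rate_min`` to survive, and an animal call rate below
    ``animal_call_rate_min`` removes the animal (exactly at the threshold is
    kept).
    """
    for name, thr in (("hwe_alpha", hwe_alpha), ("snp_call_rate_min", snp_call_rate_min),
                      ("animal_call_rate_min", animal_call_rate_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    excl = (
        SEX_CHROMOSOMES | UNASSIGNED_CHROMOSOMES
        if excluded_chromosomes is None
        else set(map(str, excluded_chromosomes))
    )
    counts = genotypes.counts.copy()
    snp_map = genotypes.snp_map.copy()
    animal_ids = genotypes.animal_ids.copy()
    report = QcReport(
        n_snps_in=counts.shape[1],
        n_animals_in=counts.shape[0],
        thresholds={
            "hwe_alpha": hwe_alpha,
            "snp_call_rate_min": snp_call_rate_min,
            "animal_call_rate_min": animal_call_rate_min,
            "excluded_chromosomes": sorted(excl),
        },
    )

    keep_chrom = ~snp_map["chrom"].astype(str).isin(excl).to_numpy()
    report.removed["chromosome"] = int((~keep_chrom).sum())
    counts, snp_map = counts[:, keep_chrom], snp_map.loc[keep_chrom].reset_index(drop=True)

    if counts.shape[1] == 0:
        raise ValueError("no SNPs remain after chromosome exclusion")
    animal_cr = 1.0 - np.isnan(counts).mean(axis=1)
    keep_animal = animal_cr >= animal_call_rate_min  # strictly below removed
    report.removed["animal_call_rate"] = int((~keep_animal).sum())
    counts, animal_ids = counts[keep_animal], animal_ids[keep_animal]
    if counts.shape[0] == 0:
        raise ValueError("no animals remain after call-rate filtering")

    snp_cr = 1.0 - np.isnan(counts).mean(axis=0)
    keep_cr = snp_cr > snp_call_rate_min  # strictly above kept
    report.removed["snp_call_rate"] = int((~keep_cr).sum())
    counts, snp_map = counts[:, keep_cr], snp_map.loc[keep_cr].reset_index(drop=True)

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(counts, axis=0) / 2.0 if counts.shape[1] else np.array([])
    keep_poly = (freq > 0.0) & (freq < 1.0)
    report.removed["monomorphic"] = int((~keep_poly).sum())
    counts, snp_map = counts[:, keep_poly], snp_map.loc[keep_poly].reset_index(drop=True)

    if counts.shape[1]:
        pvals = _snp_hwe_pvalues(counts)
        keep_hwe = ~(pvals < hwe_alpha)  # nan (undefined) kept
        report.removed["hwe"] = int((~keep_hwe).sum())
        counts, snp_map = counts[:, keep_hwe], snp_map.loc[keep_hwe].reset_index(drop=True)
    else:
        report.removed["hwe"] = 0

    if counts.shape[1] == 0:
        raise ValueError("no SNPs remain after quality control")
    report.n_snps_out = counts.shape[1]
    report.n_animals_out = counts.shape[0]
    filtered = GenotypeMatrix(counts=counts, snp_map=snp_map, animal_ids=animal_ids)
    return filtered, report


# ---------------------------------------------------------------------------
# PLINK PED/MAP text dialect
# ---------------------------------------------------------------------------


def write_ped_map(genotypes: GenotypeMatrix, ped_path, map_path, sex=None) -> None:
    """Write the whitespace PED/MAP text dialect (alleles A/B, missing 0)."""
    m = genotypes.snp_map
    with open(map_path, "w") as fh:
        for _, r in m.iterrows():
            fh.write(f"{r['chrom']}\t{r['snp_id']}\t0\t{int(r['pos'])}\n")
    code = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    sex = sex or {}
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(genotypes.animal_ids):
            sx = {"M": "1", "F": "2"}.get(sex.get(aid, ""), "0")
            fields = [str(aid), str(aid), "0", "0", sx, "-9"]
            row = genotypes.counts[i]
            fields += [code.get(c, "0 0") if not np.isnan(c) else "0 0" for c in row]
            fh.write(" ".join(fields) + "\n")


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read the PED/MAP text dialect back into allele counts (count of B)."""
    snp_map = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )[["snp_id", "chrom", "pos"]]
    ids, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(int(parts[1]) if parts[1].isdigit() else parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * len(snp_map):
                raise ValueError(
                    f"PED row for {parts[1]} has {len(alleles)} alleles, "
                    f"expected {2 * len(snp_map)}"
                )
            a = np.array(alleles).reshape(-1, 2)
            miss = np.any(a == "0", axis=1)
            cnt = np.sum(a == "B", axis=1).astype(float)
            cnt[miss] = np.nan
            rows.append(cnt)
    return GenotypeMatrix(
        counts=np.vstack(rows), snp_map=snp_map, animal_ids=np.array(ids)
    )


def read_counts_csv(path) -> GenotypeMatrix:
    """Read a 0/1/2 matrix CSV: first column animal_id, then one column per SNP.

    SNP columns named ``chrom:pos:snp_id`` carry map information; plain
    names get chromosome "1" and serial positions.
    """
    df = pd.read_csv(path)
    ids = df.iloc[:, 0].to_numpy()
    cols = list(df.columns[1:])
    chroms, poss, names = [], [], []
    for j, c in enumerate(cols):
        parts = str(c).split(":")
        if len(parts) == 3:
            chroms.append(parts[0]); poss.append(int(parts[1])); names.append(parts[2])
        else:
            chroms.append("1"); poss.append(j + 1); names.append(str(c))
    snp_map = pd.DataFrame({"snp_id": names, "chrom": chroms, "pos": poss})
    return GenotypeMatrix(
        counts=df.iloc[:, 1:].to_numpy(dtype=float), snp_map=snp_map,
        animal_ids=ids,
    )


def write_qc_report_tsv(report: QcReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: step\tcount\n")
        for k, v in report.thresholds.items():
            fh.write(f"# threshold {k} = {v}\n")
        report.to_frame().to_csv(fh, sep="\t", index=False)
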