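"""Chip QC, relationship matrices and the population-structure check.

Applies the chip quality-control rules (call rates, monomorphics,
Hardy-Weinberg, sex/unassigned chromosomes), builds the pedigree (A),
genomic (G) and combined (H) relationship matrices, and runs PCA on G.
"""

import numpy as np

from ch4herd import kinship, simdata, snp_qc

ped = simdata.simulate_pedigree(30, 2, 30, 2, seed=5, n_sires_per_generation=5)
geno = simdata.simulate_genotypes(ped, 1500, 10, seed=6, missing_rate=0.02)

filtered, report = snp_qc.qc_filter(geno)
print(report.to_frame().to_string(index=False))

cows = ped.loc[ped.sex == "F", "animal_id"].to_numpy()
genotyped = simdata.choose_genotyped(cows, int(0.68 * len(cows)), seed=7)
rel = kinship.build_relationships(ped, filtered.subset_animals(genotyped), 0.95)

print(f"\nA: {rel.A.shape}, mean diagonal {np.diag(rel.A).mean():.3f}")
print(f"G: {rel.G_raw.shape}, mean diagonal {np.diag(rel.G_raw).mean():.3f}")
print(f"H: {rel.H.shape}; genotyped block == blended G: "
      f"{np.allclose(rel.H[np.ix_(rel.genotyped_index, rel.genotyped_index)], rel.G_blended)}")

scores, pct = kinship.pca_G(rel.G_raw)
print(f"\nPCA on G: PC1 {pct[0]:.1f}%, PC2 {pct[1]:.1f}% of variance")
# Small leading percentages (a few percent) indicate family structure rather
# than discrete subpopulations — the expected picture within one breed.
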