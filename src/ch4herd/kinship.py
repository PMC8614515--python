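"""Pedigree (A), genomic (G) and combined single-step (H) relationship matrices.

A is built with the tabular method over an ancestor-ordered pedigree.  G is
the allele-frequency-centered cross-product ``Z Z' / (2 * sum p_j (1 - p_j))``
with mean imputation of missing genotypes.  H merges the two over the
genotyped/ungenotyped partition:

    H11 = A11 + A12 A22^-1 (G - A22) A22^-1 A21
    H12 = A12 A22^-1 G
    H22 = G

and its inverse is A^-1 plus the genotyped-block correction G^-1 - A22^-1.
Dense linear algebra throughout; the target scale is herds of at most a few
thousand animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix, UNKNOWN_PARENT

__all__ = [
    "RelationshipSet",
    "build_A",
    "build_G",
    "blend_G",
    "build_H",
    "build_H_inverse",
    "pca_G",
    "build_relationships",
    "write_matrix_tsv",
]


@dataclass
class RelationshipSet:
    """All relationship matrices of one analysis, with the id bookkeeping.

    ``animal_ids`` orders A and H; ``genotyped_ids`` (a subset, in the same
    relative order) orders G.  ``H_inv`` is the quantity the mixed-model
    equations consume.
    """

    animal_ids: np.ndarray
    genotyped_ids: np.ndarray
    A: np.ndarray
    G_raw: np.ndarray
    G_blended: np.ndarray
    H: np.ndarray
    H_inv: np.ndarray
    blend_alpha: float

    @property
    def genotyped_index(self) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        return np.array([pos[g] for g in self.genotyped_ids])


def build_A(pedigree: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    Requires parents to precede offspring in the row order; unknown parents
    (``0``) contribute nothing.  Diagonal is ``1 + 0.5 * a(sire, dam)``.
    """
    ids = pedigree["animal_id"].to_numpy()
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    sires = pedigree["sire_id"].to_numpy()
    dams = pedigree["dam_id"].to_numpy()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sires[i], dams[i]
        si = pos.get(s, -1) if s != UNKNOWN_PARENT else -1
        di = pos.get(d, -1) if d != UNKNOWN_PARENT else -1
        if (s != UNKNOWN_PARENT and si < 0) or (d != UNKNOWN_PARENT and di < 0):
            raise ValueError(f"parent of animal {ids[i]} missing from pedigree")
        if si >= i or di >= i:
            raise ValueError(
                f"parent of animal {ids[i]} appears at or after the offspring"
            )
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    return A


def build_G(
    genotypes: GenotypeMatrix, allele_freq: np.ndarray | None = None
) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    Genotype counts are centered by ``2 p_j``; missing counts are set to the
    column mean (zero after centering).  Frequencies default to those observed
    in the genotyped set; a base-population vector may be supplied instead.
    """
    counts = np.asarray(genotypes.counts, dtype=float)
    p = genotypes.allele_freq() if allele_freq is None else np.asarray(allele_freq, float)
    if p.shape != (counts.shape[1],):
        raise ValueError("allele_freq length does not match SNP count")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: zero centering denominator")
    Z = counts - 2.0 * p
    Z[np.isnan(Z)] = 0.0  # mean imputation after centering
    G = (Z @ Z.T) / denom
    return 0.5 * (G + G.T)


def blend_G(G_mat: np.ndarray, A22: np.ndarray, alpha: float = 0.95) -> np.ndarray:
    """Convex blend ``alpha*G + (1-alpha)*A22`` for numerical invertibility."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    G_mat = np.asarray(G_mat, float)
    A22 = np.asarray(A22, float)
    if G_mat.shape != A22.shape:
        raise ValueError("G and A22 dimensions differ")
    if alpha == 1.0:
        return G_mat.copy()
    return alpha * G_mat + (1.0 - alpha) * A22


def _partition(A: np.ndarray, genotyped_index: np.ndarray):
    n = A.shape[0]
    g = np.asarray(genotyped_index)
    u = np.setdiff1d(np.arange(n), g)
    return u, g


def build_H(
    A: np.ndarray, genotyped_index: np.ndarray, G_blended: np.ndarray
) -> np.ndarray:
    """Combined relationship matrix over all animals, in A's animal order.

    The genotyped block of the result equals ``G_blended`` exactly; the
    ungenotyped blocks are the pedigree expectations conditioned on the
    genomic information.
    """
    A = np.asarray(A, float)
    u, g = _partition(A, genotyped_index)
    if G_blended.shape != (len(g), len(g)):
        raise ValueError("G dimension does not match genotyped set")
    A22 = A[np.ix_(g, g)]
    try:
        A22_inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("A22 block is singular") from err
    A12 = A[np.ix_(u, g)]
    B = A12 @ A22_inv  # A12 A22^-1
    H = np.empty_like(A)
    H[np.ix_(u, u)] = A[np.ix_(u, u)] + B @ (G_blended - A22) @ B.T
    H12 = B @ G_blended
    H[np.ix_(u, g)] = H12
    H[np.ix_(g, u)] = H12.T
    H[np.ix_(g, g)] = G_blended
    return 0.5 * (H + H.T)


def build_H_inverse(
    A_inv: np.ndarray,
    A22_inv: np.ndarray,
    G_inv: np.ndarray,
    genotyped_index: np.ndarray,
) -> np.ndarray:
    """H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1] on the genotyped block."""
    A_inv = np.asarray(A_inv, float)
    g = np.asarray(genotyped_index)
    if A22_inv.shape != (len(g), len(g)) or G_inv.shape != (len(g), len(g)):
        raise ValueError("block dimensions do not match genotyped index")
    H_inv = A_inv.copy()
    H_inv[np.ix_(g, g)] += G_inv - A22_inv
    return 0.5 * (H_inv + H_inv.T)


def pca_G(G_mat: np.ndarray, n_components: int | None = None):
    """Principal components of the double-centered genomic relationship.

    Returns ``(scores, pct_var)``: eigenvector scores scaled by the square
    root of each eigenvalue, and the percent of (centered) variance per
    component in descending order.  Used as a population-stratification check.
    """
    G_mat = np.asarray(G_mat, float)
    if G_mat.ndim != 2 or G_mat.shape[0] != G_mat.shape[1] or G_mat.shape[0] < 2:
        raise ValueError("G must be square with at least 2 animals")
    if not np.allclose(G_mat, G_mat.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    n = G_mat.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Gc = J @ G_mat @ J
    w, V = np.linalg.eigh(0.5 * (Gc + Gc.T))
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0.0, None)
    keep = n - 1 if n_components is None else min(n_components, n - 1)
    total = w.sum()
    if total <= 0:
        raise ValueError("G has no variance after centering")
    scores = V[:, :keep] * np.sqrt(w[:keep])
    pct = 100.0 * w[:keep] / total
    return scores, pct


def build_relationships(
    pedigree: pd.DataFrame,
    genotypes: GenotypeMatrix,
    blend_alpha: float = 0.95,
) -> RelationshipSet:
    """One-call construction of A, G, H and H^-1 for an analysis.

    ``genotypes.animal_ids`` defines the genotyped subset; all of them must
    appear in the pedigree.
    """
    ids = pedigree["animal_id"].to_numpy()
    pos = {a: i for i, a in enumerate(ids)}
    missing = [int(a) for a in genotypes.animal_ids if a not in pos]
    if missing:
        raise ValueError(f"genotyped animals absent from pedigree: {missing[:5]}")
    gidx = np.array([pos[a] for a in genotypes.animal_ids])
    A = build_A(pedigree)
    A22 = A[np.ix_(gidx, gidx)]
    G_raw = build_G(genotypes)
    G_b = blend_G(G_raw, A22, blend_alpha)
    H = build_H(A, gidx, G_b)
    A_inv = np.linalg.inv(A)
    A22_inv = np.linalg.inv(A22)
    G_inv = np.linalg.inv(G_b)
    H_inv = build_H_inverse(A_inv, A22_inv, G_inv, gidx)
    return RelationshipSet(
        animal_ids=ids,
        genotyped_ids=np.asarray(genotypes.animal_ids),
        A=A,
        G_raw=G_raw,
        G_blended=G_b,
        H=H,
        H_inv=H_inv,
        blend_alpha=blend_alpha,
    )


def write_matrix_tsv(M: np.ndarray, ids, path) -> None:
    df = pd.DataFrame(M, index=ids, columns=ids)
    with open(path, "w") as fh:
        fh.write("# square relationship matrix; row/column labels are animal ids\n")
        df.to_csv(fh, sep="\t")
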