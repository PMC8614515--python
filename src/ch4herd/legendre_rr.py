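"""Random-regression test-day model on Legendre polynomials, fitted by REML.

The model for a daily methane phenotype :math:`y_{ijkl}` of cow *i* in
lactation class *j* on day-in-milk (DIM) *k* in farm-year-week *l* is

.. math::

    y_{ijkl} = LAC_j + \\sum_{n=1}^{4} \\beta_n \\phi_n(DIM_k) + FYW_l
             + \\phi(DIM_k)' a_i + \\phi(DIM_k)' p_i + e_{ijkl}

where :math:`\\phi` collects normalized Legendre polynomials of standardized
DIM, :math:`a_i` and :math:`p_i` are the additive-genetic and
permanent-environment regression-coefficient vectors of cow *i*, and the
covariance structure is

.. math::

    \\mathrm{var}(a) = H \\otimes K_a,\\quad
    \\mathrm{var}(p) = I \\otimes K_p,\\quad
    \\mathrm{var}(e) = I \\sigma_e^2,

with *H* a (combined pedigree-genomic) relationship matrix over animals and
:math:`K_a`, :math:`K_p` the coefficient covariance matrices.  Coefficients
are stacked animal-major (the coefficient index varies fastest within an
animal block).

Variance components are estimated by average-information REML with
expectation-maximization fallback steps; the mixed-model equations are dense,
targeting herds of up to a few thousand animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "LegendreBasis",
    "ModelDesign",
    "VarianceComponents",
    "SolutionSet",
    "ConvergenceError",
    "build_design",
    "solve_mme",
    "reml_fit",
    "variance_trajectory",
    "heritability_trajectory",
    "write_variance_components",
    "write_trajectory",
    "write_ebv",
]


class ConvergenceError(RuntimeError):
    """REML failed to converge; ``.trace`` holds the per-iteration record."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class LegendreBasis:
    """Normalized Legendre polynomial basis on a DIM window.

    Order-*n* basis function: ``phi_n(x) = sqrt((2n+1)/2) * P_n(x)`` with
    ``x = 2*(t - dim_min)/(dim_max - dim_min) - 1``, so the functions are
    orthonormal on [-1, 1].  ``max_order`` of 2 gives the 3-coefficient
    random-regression basis; the fixed lactation curve uses orders 1-4.
    """

    max_order: int
    dim_min: int = 5
    dim_max: int = 305

    def __post_init__(self):
        if self.dim_max <= self.dim_min:
            raise ValueError("dim_max must exceed dim_min")
        if self.max_order < 0:
            raise ValueError("max_order must be non-negative")

    @property
    def n_coeff(self) -> int:
        return self.max_order + 1

    def standardize(self, dim) -> np.ndarray:
        t = np.asarray(dim, dtype=float)
        if np.any(t < self.dim_min) or np.any(t > self.dim_max):
            raise ValueError(
                f"DIM outside basis window [{self.dim_min}, {self.dim_max}]"
            )
        return 2.0 * (t - self.dim_min) / (self.dim_max - self.dim_min) - 1.0

    def evaluate(self, dim) -> np.ndarray:
        """Evaluate all basis functions; returns shape ``(n_points, n_coeff)``."""
        x = np.atleast_1d(self.standardize(dim))
        out = np.empty((x.size, self.n_coeff))
        for n in range(self.n_coeff):
            coef = np.zeros(n + 1)
            coef[n] = 1.0
            out[:, n] = np.sqrt((2 * n + 1) / 2.0) * npleg.legval(x, coef)
        return out


@dataclass
class ModelDesign:
    """Assembled design for one trait: response, fixed design, incidences.

    ``Z_a`` places the random-regression basis at the animal's coefficient
    block (all animals of the relationship matrix, in ``animal_ids`` order);
    ``Z_p`` does the same for permanent environment over phenotyped animals
    only and may be ``None`` for models without a pe term.
    """

    y: np.ndarray
    X: np.ndarray
    Z_a: sparse.csr_matrix
    Z_p: sparse.csr_matrix | None
    animal_ids: np.ndarray
    pe_ids: np.ndarray | None
    n_coeff: int
    fixed_names: list[str] = field(default_factory=list)
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        n = len(self.y)
        if self.X.shape[0] != n or self.Z_a.shape[0] != n:
            raise ValueError("row counts of y, X, Z_a differ")
        if self.Z_p is not None and self.Z_p.shape[0] != n:
            raise ValueError("row counts of y and Z_p differ")
        if self.Z_a.shape[1] != len(self.animal_ids) * self.n_coeff:
            raise ValueError("Z_a column count inconsistent with animal_ids")

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_pe(self) -> int:
        return 0 if self.pe_ids is None else len(self.pe_ids)


@dataclass
class VarianceComponents:
    """REML estimates: coefficient covariances, residual variance, fit info."""

    K_a: np.ndarray
    K_p: np.ndarray | None
    sigma_e2: float
    log_likelihood: float
    trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        self.K_a = np.asarray(self.K_a, dtype=float)
        if self.K_p is not None:
            self.K_p = np.asarray(self.K_p, dtype=float)
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")
        for name, K in (("K_a", self.K_a), ("K_p", self.K_p)):
            if K is not None and np.min(np.linalg.eigvalsh(_sym(K))) < -1e-8 * (
                1 + np.trace(K)
            ):
                raise ValueError(f"{name} is not positive semidefinite")


@dataclass
class SolutionSet:
    """Mixed-model-equation solutions at a set of variance components."""

    beta: np.ndarray
    fixed_names: list[str]
    bv: np.ndarray  # (n_animals, n_coeff) genetic regression coefficients
    pe: np.ndarray | None  # (n_pe, n_coeff)
    animal_ids: np.ndarray
    pe_ids: np.ndarray | None
    caa: np.ndarray | None  # (m, k, m, k) PEV of genetic coefficients
    sigma_e2: float
    minus2_restricted_ll: float


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def _check_psd(K: np.ndarray, name: str) -> None:
    w = np.linalg.eigvalsh(_sym(np.asarray(K, dtype=float)))
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError(f"{name} must be symmetric positive semidefinite")


def _safe_inv(K: np.ndarray, jitter_scale: float = 1e-10) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a (possibly near-singular) PSD matrix.

    A diagonal jitter proportional to the trace keeps boundary estimates
    (variances collapsing to zero) numerically invertible.
    """
    K = _sym(np.asarray(K, dtype=float))
    k = K.shape[0]
    jit = jitter_scale * max(np.trace(K) / k, 1.0)
    for _ in range(12):
        try:
            cf = cho_factor(K + jit * np.eye(k), lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            return cho_solve(cf, np.eye(k)), logdet
        except np.linalg.LinAlgError:
            jit *= 100.0
    raise np.linalg.LinAlgError("covariance matrix could not be inverted")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

TRAIT_COLUMNS = {"ppm": "ch4_ppm_d", "gday": "ch4_g_d"}


def build_design(
    phenotypes: pd.DataFrame,
    basis_fixed: LegendreBasis,
    basis_random: LegendreBasis,
    trait: str = "ppm",
    animal_ids=None,
    fixed_curve: str = "legendre",
) -> ModelDesign:
    """Build the model design from daily phenotypes.

    Parameters
    ----------
    phenotypes
        Daily phenotype table with columns ``cow_id, dim, lac_class, fyw`` and
        the trait column (``ch4_ppm_d`` or ``ch4_g_d``).  Rows with a missing
        response are dropped.
    basis_fixed, basis_random
        Bases for the fixed lactation curve (orders 1..max) and the random
        regressions (orders 0..max).
    trait
        ``"ppm"`` or ``"gday"``, or directly a column name.
    animal_ids
        Ordering of all animals covered by the relationship matrix.  Defaults
        to the sorted phenotyped cows.
    fixed_curve
        ``"legendre"`` (default) or ``"monomial"`` for a raw polynomial
        lactation curve in standardized DIM.
    """
    col = TRAIT_COLUMNS.get(trait, trait)
    if col not in phenotypes.columns:
        raise ValueError(f"trait column {col!r} not in phenotype table")
    df = phenotypes.loc[np.isfinite(phenotypes[col].to_numpy(dtype=float))].copy()
    if df.empty:
        raise ValueError(f"no records with non-missing {col}")

    y = df[col].to_numpy(dtype=float)
    dim = df["dim"].to_numpy()
    n = len(df)

    blocks, names = [], []
    lac = df["lac_class"].astype(str).to_numpy()
    for lvl in sorted(np.unique(lac)):
        blocks.append((lac == lvl).astype(float)[:, None])
        names.append(f"LAC[{lvl}]")
    x = basis_fixed.standardize(dim)
    if fixed_curve == "legendre":
        phi_f = basis_fixed.evaluate(dim)[:, 1:]  # order 0 absorbed by LAC
        names += [f"leg{o}" for o in range(1, basis_fixed.max_order + 1)]
    elif fixed_curve == "monomial":
        phi_f = np.column_stack([x**o for o in range(1, basis_fixed.max_order + 1)])
        names += [f"dim^{o}" for o in range(1, basis_fixed.max_order + 1)]
    else:
        raise ValueError("fixed_curve must be 'legendre' or 'monomial'")
    blocks.append(phi_f)
    fyw = df["fyw"].astype(str).to_numpy()
    fyw_levels = sorted(np.unique(fyw))
    for lvl in fyw_levels[1:]:  # reference level dropped
        blocks.append((fyw == lvl).astype(float)[:, None])
        names.append(f"FYW[{lvl}]")
    X = np.hstack(blocks)

    rank = np.linalg.matrix_rank(X)
    if X.shape[0] >= X.shape[1] and rank < X.shape[1]:
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(X, mode="economic", pivoting=True)
        dep = [names[j] for j in piv[rank:]]
        raise ValueError(f"fixed design rank-deficient; dependent columns: {dep}")

    cows = df["cow_id"].to_numpy()
    pe_ids = np.array(sorted(pd.unique(cows)))
    if animal_ids is None:
        animal_ids = pe_ids
    animal_ids = np.asarray(animal_ids)
    apos = {a: i for i, a in enumerate(animal_ids)}
    missing = [c for c in pe_ids if c not in apos]
    if missing:
        raise ValueError(f"phenotyped cows absent from animal_ids: {missing[:5]}")
    ppos = {a: i for i, a in enumerate(pe_ids)}

    k = basis_random.n_coeff
    phi_r = basis_random.evaluate(dim)
    rows = np.repeat(np.arange(n), k)
    acols = np.concatenate([np.arange(apos[c] * k, apos[c] * k + k) for c in cows])
    pcols = np.concatenate([np.arange(ppos[c] * k, ppos[c] * k + k) for c in cows])
    data = phi_r.ravel()
    Z_a = sparse.csr_matrix((data, (rows, acols)), shape=(n, len(animal_ids) * k))
    Z_p = sparse.csr_matrix((data, (rows, pcols)), shape=(n, len(pe_ids) * k))

    meta = df[["cow_id", "dim"]].reset_index(drop=True)
    return ModelDesign(
        y=y, X=X, Z_a=Z_a, Z_p=Z_p, animal_ids=animal_ids, pe_ids=pe_ids,
        n_coeff=k, fixed_names=names, meta=meta,
    )


# ---------------------------------------------------------------------------
# mixed-model equations and REML
# ---------------------------------------------------------------------------


class _MME:
    """Workspace for repeated MME solves on one design + relationship."""

    def __init__(self, design: ModelDesign, rel_inv: np.ndarray, use_pe: bool):
        self.design = design
        self.k = design.n_coeff
        self.m = design.n_animals
        self.q = design.n_pe if use_pe else 0
        self.use_pe = use_pe and design.Z_p is not None and self.q > 0
        self.n = design.n_records
        self.p = design.X.shape[1]
        rel_inv = np.asarray(rel_inv, dtype=float)
        if rel_inv.shape != (self.m, self.m):
            raise ValueError(
                f"relationship inverse is {rel_inv.shape}, expected "
                f"({self.m}, {self.m})"
            )
        self.Hinv = _sym(rel_inv)
        sign, ld = np.linalg.slogdet(self.Hinv)
        if sign <= 0:
            raise ValueError("relationship inverse must be positive definite")
        self.logdet_H = -ld

        mats = [sparse.csr_matrix(design.X), design.Z_a]
        if self.use_pe:
            mats.append(design.Z_p)
        self.W = sparse.hstack(mats).tocsr()
        self.WtW = np.asarray((self.W.T @ self.W).todense())
        self.Wty = np.asarray(self.W.T @ design.y).ravel()
        self.yty = float(design.y @ design.y)
        self.dim = self.p + self.m * self.k + (self.q * self.k if self.use_pe else 0)
        self.a0 = self.p
        self.p0 = self.p + self.m * self.k
        self._H = None

    @property
    def H(self) -> np.ndarray:
        if self._H is None:
            self._H = np.linalg.inv(self.Hinv)
        return self._H

    def assemble(self, K_a, K_p, sigma_e2):
        k, m, q = self.k, self.m, self.q
        Kainv, ld_Ka = _safe_inv(K_a)
        C = self.WtW / sigma_e2
        Ga_inv = np.kron(self.Hinv, Kainv)
        C[self.a0 : self.p0, self.a0 : self.p0] += Ga_inv
        if self.use_pe:
            Kpinv, ld_Kp = _safe_inv(K_p)
            Gp_inv = np.kron(np.eye(q), Kpinv)
            C[self.p0 :, self.p0 :] += Gp_inv
        else:
            Kpinv, ld_Kp, Gp_inv = None, 0.0, None
        cf = cho_factor(C, lower=True)
        sol = cho_solve(cf, self.Wty / sigma_e2)
        logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))
        yPy = (self.yty - sol @ self.Wty) / sigma_e2
        m2ll = (
            logdet_C
            + self.n * np.log(sigma_e2)
            + k * self.logdet_H
            + m * ld_Ka
            + (q * ld_Kp if self.use_pe else 0.0)
            + yPy
        )
        return {
            "cf": cf, "sol": sol, "m2ll": m2ll, "Ga_inv": Ga_inv,
            "Gp_inv": Gp_inv, "Kainv": Kainv, "Kpinv": Kpinv,
            "sigma_e2": sigma_e2,
        }

    def solution_set(self, state, compute_pev=True) -> SolutionSet:
        d, k = self.design, self.k
        sol = state["sol"]
        beta = sol[: self.p]
        bv = sol[self.a0 : self.p0].reshape(self.m, k)
        pe = sol[self.p0 :].reshape(self.q, k) if self.use_pe else None
        caa = None
        if compute_pev:
            Cinv = cho_solve(state["cf"], np.eye(self.dim))
            caa = Cinv[self.a0 : self.p0, self.a0 : self.p0].reshape(
                self.m, k, self.m, k
            )
        return SolutionSet(
            beta=beta, fixed_names=list(d.fixed_names), bv=bv, pe=pe,
            animal_ids=d.animal_ids,
            pe_ids=d.pe_ids if self.use_pe else None, caa=caa,
            sigma_e2=state["sigma_e2"], minus2_restricted_ll=state["m2ll"],
        )


def solve_mme(
    design: ModelDesign,
    relationship_inv: np.ndarray,
    K_a: np.ndarray,
    K_p: np.ndarray | None,
    sigma_e2: float,
    compute_pev: bool = True,
) -> SolutionSet:
    """Solve the mixed-model equations at fixed variance components.

    ``K_p=None`` (or an all-zero matrix) drops the permanent-environment term
    — the single-record GBLUP case.  Returns fixed-effect estimates, genetic
    and pe regression coefficients, and (optionally) the prediction-error
    covariance of the genetic coefficients.
    """
    K_a = _sym(np.asarray(K_a, dtype=float))
    _check_psd(K_a, "K_a")
    use_pe = K_p is not None and np.any(np.asarray(K_p) != 0)
    if use_pe:
        K_p = _sym(np.asarray(K_p, dtype=float))
        _check_psd(K_p, "K_p")
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    mme = _MME(design, relationship_inv, use_pe)
    state = mme.assemble(K_a, K_p if use_pe else None, sigma_e2)
    return mme.solution_set(state, compute_pev=compute_pev)


def _vech_indices(k: int):
    return [(i, j) for i in range(k) for j in range(i, k)]


def _min_eig_ok(K: np.ndarray) -> bool:
    return float(np.linalg.eigvalsh(_sym(K)).min()) >= 1e-8 * max(
        abs(np.trace(K)), 1e-3
    )


def _project_psd(K: np.ndarray, floor: float = 0.0) -> np.ndarray:
    w, V = np.linalg.eigh(_sym(K))
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def reml_fit(
    design: ModelDesign,
    relationship_inv: np.ndarray,
    init: tuple | None = None,
    max_iter: int = 200,
    rtol: float = 1e-8,
    ltol: float = 1e-6,
    method: str = "ai",
    burn_in: int = 2,
    verbose: bool = False,
) -> tuple[VarianceComponents, SolutionSet]:
    """Estimate variance components by average-information REML.

    After ``burn_in`` expectation-maximization steps (which tame a crude
    start), the free parameters (lower triangles of ``K_a`` and ``K_p`` plus
    the residual variance) are updated with AI steps.  Proposals are bent
    back onto the positive-semidefinite cone (eigenvalue floor) and the step
    halved up to 10 times; if no AI proposal improves the restricted
    likelihood the iteration falls back to an EM update, which cannot leave
    the parameter space.  ``method="em"`` forces pure EM (slower, monotone).

    Returns the converged :class:`VarianceComponents` (with per-iteration
    trace) and the :class:`SolutionSet` at convergence.  Raises
    :class:`ConvergenceError` carrying the trace if ``max_iter`` is exhausted.
    """
    use_pe = design.Z_p is not None
    mme = _MME(design, relationship_inv, use_pe)
    k, m, q, n = mme.k, mme.m, mme.q, mme.n
    y = design.y

    vary = float(np.var(y, ddof=1))
    if init is None:
        # decreasing weight on higher orders: most variance sits on the
        # intercept coefficient for lactation-curve traits
        scale = 0.1 * vary * np.array([1.0 / 4.0**o for o in range(k)])
        K_a = np.diag(scale)
        K_p = np.diag(scale) if use_pe else None
        sigma_e2 = 0.8 * vary
    else:
        K_a, K_p, sigma_e2 = init
        K_a = _sym(np.asarray(K_a, dtype=float))
        K_p = _sym(np.asarray(K_p, dtype=float)) if (use_pe and K_p is not None) else None

    idx = _vech_indices(k)
    nv = len(idx)
    floor = 1e-10 * vary

    def pack(K_a, K_p, s2):
        th = [K_a[i, j] for i, j in idx]
        if use_pe:
            th += [K_p[i, j] for i, j in idx]
        th.append(s2)
        return np.array(th)

    def unpack(th):
        Ka = np.zeros((k, k))
        for t, (i, j) in enumerate(idx):
            Ka[i, j] = Ka[j, i] = th[t]
        Kp = None
        if use_pe:
            Kp = np.zeros((k, k))
            for t, (i, j) in enumerate(idx):
                Kp[i, j] = Kp[j, i] = th[nv + t]
        return Ka, Kp, th[-1]

    # AI steps are taken on Cholesky factors K = L L', which makes the PSD
    # cone unconstrained: boundary solutions (singular K) are ordinary
    # stationary points there, where the plain-K gradient cannot vanish.
    pairsL = [(a, b) for a in range(k) for b in range(a + 1)]

    def chol_of(K):
        return np.linalg.cholesky(_sym(K) + max(floor, 1e-12) * np.eye(k))

    def jac(L):
        J = np.zeros((nv, len(pairsL)))
        for tK, (i, j) in enumerate(idx):
            for tL, (a, b) in enumerate(pairsL):
                v = 0.0
                if i == a:
                    v += L[j, b]
                if j == a:
                    v += L[i, b]
                J[tK, tL] = v
        return J

    def full_jac(La, Lp):
        size = nv * (2 if use_pe else 1) + 1
        J = np.zeros((size, size))
        J[:nv, :nv] = jac(La)
        if use_pe:
            J[nv : 2 * nv, nv : 2 * nv] = jac(Lp)
        J[-1, -1] = 1.0
        return J

    def addL(L, delta):
        out = L.copy()
        for tL, (a, b) in enumerate(pairsL):
            out[a, b] += delta[tL]
        return out

    La = chol_of(K_a)
    Lp = chol_of(K_p) if use_pe else None
    trace: list[dict] = []
    lam = 1e-2  # Marquardt damping, adapted across iterations
    state = mme.assemble(K_a, K_p, sigma_e2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s2 = sigma_e2
        grad, AI, em = _score_ai_em(mme, state)
        J = full_jac(La, Lp)
        grad_L = J.T @ grad
        AI_L = _sym(J.T @ AI @ J)

        theta = pack(K_a, K_p, s2)
        m2ll = state["m2ll"]
        # Newton decrement in factor space: the AI-quadratic estimate of the
        # remaining restricted-logL gain; vanishes at boundary optima
        decrement = 0.5 * float(
            grad_L @ np.linalg.pinv(AI_L, rcond=1e-10, hermitian=True) @ grad_L
        )
        trace.append(
            {"iter": it, "m2ll": m2ll, "theta": theta.copy(), "decrement": decrement}
        )
        if verbose:
            print(f"iter {it:3d}  -2logL = {m2ll:.6f}  decrement = {decrement:.3g}")

        new_state = None
        if method == "ai" and it > burn_in:
            D = np.diag(np.clip(np.diag(AI_L), 1e-10 * max(np.diag(AI_L).max(), 1e-30), None))
            while lam <= 1e8:
                try:
                    step = np.linalg.solve(AI_L + lam * D, grad_L)
                except np.linalg.LinAlgError:
                    lam = max(lam * 10.0, 1e-4)
                    continue
                La_c = addL(La, step[:nv])
                Lp_c = addL(Lp, step[nv : 2 * nv]) if use_pe else None
                s2_c = s2 + step[-1]
                Ka_c = La_c @ La_c.T
                Kp_c = Lp_c @ Lp_c.T if use_pe else None
                st = None
                if s2_c > 0:
                    try:
                        st = mme.assemble(Ka_c, Kp_c, s2_c)
                    except np.linalg.LinAlgError:
                        st = None
                if st is not None and st["m2ll"] < m2ll:
                    new_state = st
                    K_a, K_p, sigma_e2 = Ka_c, Kp_c, s2_c
                    La, Lp = La_c, Lp_c
                    lam = max(lam / 5.0, 1e-4)
                    break
                lam = max(lam * 10.0, 1e-4)
        if new_state is None:
            # EM update (guaranteed inside the parameter space)
            K_a = _project_psd(em["K_a"], floor)
            if use_pe:
                K_p = _project_psd(em["K_p"], floor)
            sigma_e2 = float(em["sigma_e2"])
            La = chol_of(K_a)
            Lp = chol_of(K_p) if use_pe else None
            new_state = mme.assemble(K_a, K_p, sigma_e2)

        theta_new = pack(K_a, K_p, sigma_e2)
        dpar = np.linalg.norm(theta_new - theta) / max(np.linalg.norm(theta), 1e-12)
        dll = abs(new_state["m2ll"] - m2ll)
        state = new_state
        if dpar < rtol or dll < ltol:
            converged = True
            trace.append(
                {"iter": it + 1, "m2ll": state["m2ll"], "theta": theta_new.copy()}
            )
            break

    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", trace
        )

    vc = VarianceComponents(
        K_a=_project_psd(K_a, 0.0),
        K_p=_project_psd(K_p, 0.0) if use_pe else None,
        sigma_e2=float(sigma_e2),
        log_likelihood=-0.5 * state["m2ll"],
        trace=trace,
        converged=True,
        n_iter=it,
    )
    sols = mme.solution_set(state, compute_pev=True)
    return vc, sols


def _score_ai_em(mme: _MME, state: dict):
    """REML score vector, average-information matrix and EM proposals.

    Parameter order: vech(K_a), then vech(K_p) if present, then sigma_e2.
    All quantities come from mixed-model-equation identities:
    ``Z'PZ = G^-1 - G^-1 C^uu G^-1`` for the trace terms and an MME solve of
    each working vector ``dV/dtheta . Py`` for the AI matrix.
    """
    design = mme.design
    k, m, q, n = mme.k, mme.m, mme.q, mme.n
    use_pe = mme.use_pe
    y = design.y
    s2 = state["sigma_e2"]
    cf, sol = state["cf"], state["sol"]
    idx = _vech_indices(k)
    nv = len(idx)

    Cinv = cho_solve(cf, np.eye(mme.dim))
    Caa = Cinv[mme.a0 : mme.p0, mme.a0 : mme.p0]
    Caa4 = Caa.reshape(m, k, m, k)
    if use_pe:
        Cpp = Cinv[mme.p0 :, mme.p0 :]
        Cpp4 = Cpp.reshape(q, k, q, k)
    tr_CinvWtW = float(np.sum(Cinv * mme.WtW))

    e = y - mme.W @ sol
    Py = e / s2
    U = sol[mme.a0 : mme.p0].reshape(m, k)
    Ta = np.asarray(design.Z_a.T @ Py).reshape(m, k)
    HTa = mme.H @ Ta
    QA = Ta.T @ HTa
    Ga_inv = state["Ga_inv"]
    Na = Ga_inv - Ga_inv @ Caa @ Ga_inv
    Na4 = Na.reshape(m, k, m, k)
    Ma = np.einsum("ab,bjai->ji", mme.H, Na4)
    if use_pe:
        P_ = sol[mme.p0 :].reshape(q, k)
        Tp = np.asarray(design.Z_p.T @ Py).reshape(q, k)
        QP = Tp.T @ Tp
        Gp_inv = state["Gp_inv"]
        Np = Gp_inv - Gp_inv @ Cpp @ Gp_inv
        Np4 = Np.reshape(q, k, q, k)
        Mp = np.einsum("ajai->ji", Np4)

    grad = np.zeros(nv * (2 if use_pe else 1) + 1)
    for t, (i, j) in enumerate(idx):
        tr_term = Ma[i, i] if i == j else (Ma[j, i] + Ma[i, j])
        quad = QA[i, j] if i == j else 2.0 * QA[i, j]
        grad[t] = -0.5 * (tr_term - quad)
        if use_pe:
            tr_p = Mp[i, i] if i == j else (Mp[j, i] + Mp[i, j])
            quad_p = QP[i, j] if i == j else 2.0 * QP[i, j]
            grad[nv + t] = -0.5 * (tr_p - quad_p)
    trP = (n - mme.dim + _tr_correction(state, Caa, Cpp if use_pe else None)) / s2
    grad[-1] = -0.5 * (trP - float(Py @ Py))

    F = np.zeros((n, grad.size))
    for t, (i, j) in enumerate(idx):
        E = np.zeros((k, k))
        E[i, j] = E[j, i] = 1.0
        F[:, t] = design.Z_a @ (HTa @ E).ravel()
        if use_pe:
            F[:, nv + t] = design.Z_p @ (Tp @ E).ravel()
    F[:, -1] = Py
    th_f = cho_solve(cf, np.asarray(mme.W.T @ F) / s2)
    PF = (F - mme.W @ th_f) / s2
    AI = _sym(0.5 * (F.T @ PF))

    em = {
        "K_a": (U.T @ mme.Hinv @ U + np.einsum("ab,aibj->ij", mme.Hinv, Caa4)) / m,
        "sigma_e2": float((e @ e + tr_CinvWtW) / n),
    }
    if use_pe:
        em["K_p"] = (P_.T @ P_ + np.einsum("aiaj->ij", Cpp4)) / q
    return grad, AI, em


def _tr_correction(state, Caa, Cpp):
    """tr(C^{aa} G_a^{-1}) + tr(C^{pp} G_p^{-1}) for the tr(P) identity."""
    out = float(np.sum(Caa * state["Ga_inv"]))
    if Cpp is not None:
        out += float(np.sum(Cpp * state["Gp_inv"]))
    return out


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def variance_trajectory(K: np.ndarray, basis: LegendreBasis, dims) -> np.ndarray:
    """Evaluate v(t) = phi(t)' K phi(t) on a DIM grid."""
    K = _sym(np.asarray(K, dtype=float))
    if K.shape != (basis.n_coeff, basis.n_coeff):
        raise ValueError("K dimension does not match basis")
    phi = basis.evaluate(dims)
    return np.einsum("ti,ij,tj->t", phi, K, phi)


def heritability_trajectory(
    vc: VarianceComponents, basis: LegendreBasis, dims=None
) -> pd.DataFrame:
    """Per-DIM variance partition and heritability.

    h2(t) = var_a(t) / (var_a(t) + var_pe(t) + sigma_e2).  The DataFrame's
    ``.attrs`` carry the window means (``mean_h2``, ``mean_var_a``, ...),
    defined as plain averages over the integer-DIM grid.
    """
    if dims is None:
        dims = np.arange(basis.dim_min, basis.dim_max + 1)
    dims = np.asarray(dims)
    va = variance_trajectory(vc.K_a, basis, dims)
    vp = (
        variance_trajectory(vc.K_p, basis, dims)
        if vc.K_p is not None
        else np.zeros_like(va)
    )
    total = va + vp + vc.sigma_e2
    if np.any(total <= 0):
        raise ValueError("zero total variance on the trajectory")
    h2 = va / total
    out = pd.DataFrame(
        {"dim": dims, "var_a": va, "var_pe": vp, "var_e": vc.sigma_e2, "h2": h2}
    )
    out.attrs["mean_h2"] = float(h2.mean())
    out.attrs["mean_var_a"] = float(va.mean())
    out.attrs["mean_var_pe"] = float(vp.mean())
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_variance_components(vc: VarianceComponents, path) -> None:
    k = vc.K_a.shape[0]
    rows = []
    for i in range(k):
        for j in range(i + 1):
            rows.append(("K_a", i, j, vc.K_a[i, j]))
    if vc.K_p is not None:
        for i in range(k):
            for j in range(i + 1):
                rows.append(("K_p", i, j, vc.K_p[i, j]))
    rows.append(("sigma_e2", 0, 0, vc.sigma_e2))
    rows.append(("log_likelihood", 0, 0, vc.log_likelihood))
    df = pd.DataFrame(rows, columns=["component", "row", "col", "value"])
    with open(path, "w") as fh:
        fh.write("# columns: component\trow\tcol\tvalue\n")
        df.to_csv(fh, sep="\t", index=False)


def write_trajectory(traj: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: dim\tvar_a\tvar_pe\tvar_e\th2\n")
        traj.to_csv(fh, sep="\t", index=False)


def write_ebv(sols: SolutionSet, path) -> None:
    k = sols.bv.shape[1]
    df = pd.DataFrame(sols.bv, columns=[f"coeff{i}" for i in range(k)])
    df.insert(0, "animal_id", sols.animal_ids)
    with open(path, "w") as fh:
        fh.write("# columns: animal_id\t" + "\t".join(df.columns[1:]) + "\n")
        df.to_csv(fh, sep="\t", index=False)
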