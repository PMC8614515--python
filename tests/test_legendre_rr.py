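"""Random-regression model: basis, design, MME solve, AI-REML, trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ch4herd import kinship, legendre_rr as lr, simdata


class TestLegendreBasis:
    def test_order_zero_is_constant_normalizer(self):
        b = lr.LegendreBasis(2, 5, 305)
        vals = b.evaluate([5, 100, 305])[:, 0]
        assert np.allclose(vals, np.sqrt(0.5))
        assert vals[0] == pytest.approx(0.70711, abs=1e-5)

    def test_order_one_at_window_end(self):
        b = lr.LegendreBasis(2, 5, 305)
        assert b.evaluate([305])[0, 1] == pytest.approx(np.sqrt(1.5), abs=1e-10)
        assert b.evaluate([305])[0, 1] == pytest.approx(1.22474, abs=1e-5)

    def test_orthonormality_by_quadrature(self):
        b = lr.LegendreBasis(4, 5, 305)
        x, w = np.polynomial.legendre.leggauss(16)
        dims = (x + 1) / 2 * 300 + 5
        phi = b.evaluate(dims)
        gram = (phi * w[:, None]).T @ phi
        assert np.allclose(gram, np.eye(5), atol=1e-10)

    def test_dim_outside_window_rejected(self):
        b = lr.LegendreBasis(2, 5, 305)
        with pytest.raises(ValueError):
            b.evaluate([4])
        with pytest.raises(ValueError):
            b.evaluate([306])


def _daily(n_cows=6, days=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_cows + 1):
        lact = 5 if c == 1 else 1
        for d in range(days):
            dim = int(rng.integers(5, 306))
            rows.append(
                (c, pd.Timestamp("2015-06-01") + pd.Timedelta(days=d), dim,
                 "2+" if lact >= 2 else "1",
                 f"farm1-2015-W{20 + d % 2}", 500.0 + rng.normal(0, 20), np.nan)
            )
    return pd.DataFrame(
        rows, columns=["cow_id", "date", "dim", "lac_class", "fyw",
                       "ch4_ppm_d", "ch4_g_d"],
    )


class TestBuildDesign:
    def test_random_incidence_row_is_basis_at_dim(self):
        df = _daily(n_cows=1, days=1)
        bf, br = lr.LegendreBasis(4, 5, 305), lr.LegendreBasis(2, 5, 305)
        d = lr.build_design(df, bf, br, "ppm")
        row = d.Z_a[0].toarray().ravel()
        assert np.allclose(row[:3], br.evaluate(df.dim.to_numpy())[0])

    def test_lactation_five_lands_in_class_two_plus(self):
        df = _daily()
        bf, br = lr.LegendreBasis(4, 5, 305), lr.LegendreBasis(2, 5, 305)
        d = lr.build_design(df, bf, br, "ppm")
        col = d.fixed_names.index("LAC[2+]")
        rows = np.flatnonzero(df.cow_id.to_numpy() == 1)
        assert np.all(d.X[rows, col] == 1.0)

    def test_duplicate_record_adds_row_not_column(self):
        df = _daily()
        bf, br = lr.LegendreBasis(4, 5, 305), lr.LegendreBasis(2, 5, 305)
        d1 = lr.build_design(df, bf, br, "ppm")
        d2 = lr.build_design(pd.concat([df, df.iloc[[0]]]), bf, br, "ppm")
        assert d2.X.shape == (d1.X.shape[0] + 1, d1.X.shape[1])

    def test_missing_response_rows_dropped(self):
        df = _daily()
        df.loc[0, "ch4_ppm_d"] = np.nan
        bf, br = lr.LegendreBasis(4, 5, 305), lr.LegendreBasis(2, 5, 305)
        d = lr.build_design(df, bf, br, "ppm")
        assert d.n_records == len(df) - 1

    def test_monomial_fixed_curve_option(self):
        df = _daily()
        bf, br = lr.LegendreBasis(4, 5, 305), lr.LegendreBasis(2, 5, 305)
        d = lr.build_design(df, bf, br, "ppm", fixed_curve="monomial")
        assert "dim^4" in d.fixed_names


def _toy_design(rng, m=30, k=2, nrec=120, related=True):
    if related:
        B = rng.standard_normal((m, m))
        H = B @ B.T / m + np.eye(m)
    else:
        H = np.eye(m)
    basis = lr.LegendreBasis(k - 1, 5, 305)
    dims = rng.integers(5, 306, nrec)
    phi = basis.evaluate(dims)
    cows = rng.integers(0, m, nrec)
    rows = np.repeat(np.arange(nrec), k)
    cols = np.concatenate([np.arange(c * k, c * k + k) for c in cows])
    Z = sparse.csr_matrix((phi.ravel(), (rows, cols)), shape=(nrec, m * k))
    X = np.column_stack([np.ones(nrec), rng.standard_normal(nrec)])
    return H, basis, X, Z, dims


class TestRemlMachinery:
    def test_restricted_likelihood_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        m, k = 12, 2
        H, basis, X, Z, _ = _toy_design(rng, m=m, k=k, nrec=50)
        Ka = np.array([[2.0, 0.3], [0.3, 1.0]])
        Kp = np.diag([1.0, 0.5])
        s2 = 3.0
        y = X @ [1.0, 2.0] + rng.standard_normal(50)
        d = lr.ModelDesign(y=y, X=X, Z_a=Z, Z_p=Z.copy(),
                           animal_ids=np.arange(m), pe_ids=np.arange(m), n_coeff=k)
        mme = lr._MME(d, np.linalg.inv(H), True)
        st = mme.assemble(Ka, Kp, s2)
        n = len(y)
        V = (Z @ np.kron(H, Ka) @ Z.T.toarray()
             + Z @ np.kron(np.eye(m), Kp) @ Z.T.toarray() + s2 * np.eye(n))
        Vi = np.linalg.inv(V)
        XtVX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XtVX) @ X.T @ Vi
        direct = (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtVX)[1] + y @ P @ y)
        assert st["m2ll"] == pytest.approx(direct, abs=1e-6)

    def test_score_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        m, k = 10, 2
        H, basis, X, Z, _ = _toy_design(rng, m=m, k=k, nrec=60)
        d = lr.ModelDesign(
            y=rng.standard_normal(60) * 2 + 1, X=X, Z_a=Z, Z_p=Z.copy(),
            animal_ids=np.arange(m), pe_ids=np.arange(m), n_coeff=k,
        )
        mme = lr._MME(d, np.linalg.inv(H), True)
        Ka = np.array([[2.0, 0.3], [0.3, 1.0]])
        Kp = np.diag([1.0, 0.5])
        s2 = 3.0
        grad, AI, _ = lr._score_ai_em(mme, mme.assemble(Ka, Kp, s2))
        th0 = np.array([2.0, 0.3, 1.0, 1.0, 0.0, 0.5, 3.0])

        def ll(th):
            Ka_ = np.array([[th[0], th[1]], [th[1], th[2]]])
            Kp_ = np.array([[th[3], th[4]], [th[4], th[5]]])
            return -0.5 * mme.assemble(Ka_, Kp_, th[6])["m2ll"]

        num = np.array(
            [
                (ll(th0 + h * e) - ll(th0 - h * e)) / (2 * h)
                for h, e in ((1e-6, np.eye(7)[i]) for i in range(7))
            ]
        )
        assert np.allclose(grad, num, rtol=1e-4, atol=1e-5)
        assert np.linalg.eigvalsh(AI).min() > 0

    def test_em_iteration_is_monotone_in_likelihood(self):
        rng = np.random.default_rng(5)
        m, k = 20, 2
        H, basis, X, Z, _ = _toy_design(rng, m=m, k=k, nrec=200)
        L = np.linalg.cholesky(np.kron(H, np.diag([2.0, 0.5])))
        y = (X @ [3.0, 1.0] + Z @ (L @ rng.standard_normal(m * k))
             + rng.standard_normal(200))
        d = lr.ModelDesign(y=y, X=X, Z_a=Z, Z_p=Z.copy(),
                           animal_ids=np.arange(m), pe_ids=np.arange(m), n_coeff=k)
        try:
            vc, _ = lr.reml_fit(d, np.linalg.inv(H), method="em", max_iter=40,
                                ltol=1e-3)
            lls = [t["m2ll"] for t in vc.trace]
        except lr.ConvergenceError as err:  # EM is slow; monotonicity is the point
            lls = [t["m2ll"] for t in err.trace]
        assert len(lls) > 5
        assert all(b <= a + 1e-6 for a, b in zip(lls, lls[1:]))

    def test_zero_genetic_variance_recovered_at_boundary(self):
        # pe-only truth on a family-structured pedigree: the genetic share
        # of the fitted variance must collapse to the boundary
        rng = np.random.default_rng(6)
        ped = simdata.simulate_pedigree(40, 2, 70, 2, seed=26,
                                        n_sires_per_generation=6)
        m = len(ped)
        A = kinship.build_A(ped)
        k, nrec_per = 2, 12
        basis = lr.LegendreBasis(k - 1, 5, 305)
        cows = np.repeat(np.arange(m), nrec_per)
        dims = rng.integers(5, 306, len(cows))
        phi = basis.evaluate(dims)
        rows = np.repeat(np.arange(len(cows)), k)
        cols = np.concatenate([np.arange(c * k, c * k + k) for c in cows])
        Z = sparse.csr_matrix((phi.ravel(), (rows, cols)),
                              shape=(len(cows), m * k))
        X = np.ones((len(cows), 1))
        pe = rng.standard_normal((m, k)) @ np.diag([np.sqrt(2.0), np.sqrt(0.5)])
        y = 3.0 + Z @ pe.ravel() + rng.standard_normal(len(cows))
        d = lr.ModelDesign(y=y, X=X, Z_a=Z, Z_p=Z.copy(),
                           animal_ids=ped.animal_id.to_numpy(),
                           pe_ids=ped.animal_id.to_numpy(), n_coeff=k)
        vc, _ = lr.reml_fit(d, np.linalg.inv(A), max_iter=150, ltol=1e-4)
        total = np.trace(vc.K_a) + np.trace(vc.K_p) + vc.sigma_e2
        assert np.trace(vc.K_a) / total < 0.05

    def test_intercept_only_matches_direct_gblup(self):
        """ssGBLUP with one coefficient equals a GLS/GBLUP solve."""
        rng = np.random.default_rng(7)
        n = 100
        ped = simdata.simulate_pedigree(n, 0, 1, 1, seed=17)
        geno = simdata.simulate_genotypes(ped, 600, 4, seed=18)
        G = kinship.blend_G(kinship.build_G(geno), np.eye(n), 0.95)
        s2a, s2e = 1.0, 2.0
        y = 3.0 + rng.multivariate_normal(np.zeros(n), s2a * G) \
            + rng.normal(0, np.sqrt(s2e), n)
        X = np.ones((n, 1))
        Z = sparse.identity(n, format="csr")
        d = lr.ModelDesign(y=y, X=X, Z_a=Z, Z_p=None,
                           animal_ids=np.arange(n), pe_ids=None, n_coeff=1)
        sols = lr.solve_mme(d, np.linalg.inv(G), np.array([[s2a]]), None, s2e)
        V = s2a * G + s2e * np.eye(n)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        a_direct = s2a * G @ Vi @ (y - X @ beta)
        assert sols.beta[0] == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(sols.bv[:, 0], a_direct, atol=1e-8)


class TestTrajectories:
    def test_zero_matrix_gives_zero_variance(self):
        b = lr.LegendreBasis(2, 5, 305)
        assert np.all(lr.variance_trajectory(np.zeros((3, 3)), b, [5, 150, 305]) == 0)

    def test_identity_matrix_gives_basis_norm(self):
        b = lr.LegendreBasis(2, 5, 305)
        dims = np.array([5, 100, 305])
        v = lr.variance_trajectory(np.eye(3), b, dims)
        phi = b.evaluate(dims)
        assert np.allclose(v, (phi**2).sum(axis=1))

    def test_psd_matrix_nonnegative_trajectory(self, small_herd):
        b = small_herd["basis"]
        v = lr.variance_trajectory(small_herd["K_a"], b, np.arange(5, 306))
        assert np.all(v >= 0)

    def test_equal_variance_ratio_gives_constant_heritability(self):
        b = lr.LegendreBasis(0, 5, 305)
        K = np.array([[2.0]])  # phi0^2 * 2 = 1 at every t
        vc = lr.VarianceComponents(
            K_a=K, K_p=K, sigma_e2=2.0, log_likelihood=0.0
        )
        traj = lr.heritability_trajectory(vc, b)
        assert np.allclose(traj["h2"], 0.25)

    def test_heritability_bounded_and_scale_invariant(self, small_herd):
        b = small_herd["basis"]
        vc1 = lr.VarianceComponents(
            K_a=small_herd["K_a"], K_p=small_herd["K_p"], sigma_e2=12.0,
            log_likelihood=0.0,
        )
        c = 3.7
        vc2 = lr.VarianceComponents(
            K_a=c * small_herd["K_a"], K_p=c * small_herd["K_p"],
            sigma_e2=c * 12.0, log_likelihood=0.0,
        )
        t1 = lr.heritability_trajectory(vc1, b)
        t2 = lr.heritability_trajectory(vc2, b)
        assert np.all((t1["h2"] >= 0) & (t1["h2"] <= 1))
        assert np.allclose(t1["h2"], t2["h2"])
        # window mean equals mean of the per-DIM trajectory
        assert t1.attrs["mean_h2"] == pytest.approx(float(t1["h2"].mean()))

    def test_writers_emit_schema_headers(self, tmp_path, small_herd):
        vc = lr.VarianceComponents(
            K_a=small_herd["K_a"], K_p=small_herd["K_p"], sigma_e2=12.0,
            log_likelihood=-1.0,
        )
        b = small_herd["basis"]
        lr.write_variance_components(vc, tmp_path / "vc.tsv")
        lr.write_trajectory(lr.heritability_trajectory(vc, b), tmp_path / "tr.tsv")
        assert (tmp_path / "vc.tsv").read_text().startswith("# columns:")
        assert "h2" in (tmp_path / "tr.tsv").read_text()
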