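"""Variance-component REML: closed forms, oracle equivalence,
invariances, and the LOD test's boundary behaviour."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import chi2

from ibdscan.relatedness import global_ibd_matrix, phi_from_field
from ibdscan.simdata import (StructuredSpec, generate_structured_fixture,
                             simulate_phenotypes)
from ibdscan.vc import (VCModelSpec, VarianceComponentModel, fit_reml,
                        lod_test, mixture_pvalue, restricted_loglik)

from oracles import grid_polish_reml


def iid_spec(n=50, p=2, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y = X @ np.arange(1, p + 1, dtype=float) + rng.standard_normal(n)
    eye = sp.identity(n, format="csr")
    return VCModelSpec(y=y, X=X, psi=eye, phi=eye)


def random_structured_model(n, seed, with_phi=True):
    rng = np.random.default_rng(seed)
    fields, kin = generate_structured_fixture(
        n, StructuredSpec(cluster_sizes={2: max(1, n // 10),
                                         3: max(1, n // 15)},
                          related_fraction=0.2),
        seed=seed)
    psi = global_ibd_matrix(kin, [f"S{i:05d}" for i in range(n)])
    phi = phi_from_field(fields[0], n) if with_phi else None
    y = simulate_phenotypes(psi, None, 1, seed=seed + 1)[0]
    return VarianceComponentModel(y, psi, phi)


class TestRestrictedLoglik:
    def test_identity_limit_closed_form(self):
        """With Psi = Phi = I the REML log-likelihood must equal the
        closed form for i.i.d. N(X beta, (sa2+sq2+se2) I)."""
        spec = iid_spec(n=60, p=3, seed=1)
        n, p = 60, 3
        sa, sq, se = 0.4, 0.3, 0.8
        s = sa + sq + se
        beta = np.linalg.solve(spec.X.T @ spec.X, spec.X.T @ spec.y)
        r = spec.y - spec.X @ beta
        expected = (-0.5 * (n - p) * np.log(2 * np.pi)
                    - 0.5 * n * np.log(s)
                    - 0.5 * np.linalg.slogdet(spec.X.T @ spec.X / s)[1]
                    - 0.5 * r @ r / s)
        assert restricted_loglik(spec, sa, sq, se) == pytest.approx(
            expected, abs=1e-10)

    def test_block_equals_dense_computation(self):
        """Block-wise evaluation must agree with a dense whole-matrix
        evaluation of the same formula."""
        model = random_structured_model(30, seed=3)
        sa, sq, se = 0.5, 0.7, 1.1
        V = (sa * model.psi.toarray() + sq * model.phi.toarray()
             + se * np.eye(30))
        X, y = model.exog, model.endog
        Vi = np.linalg.inv(V)
        M = X.T @ Vi @ X
        beta = np.linalg.solve(M, X.T @ Vi @ y)
        r = y - X @ beta
        n, p = 30, X.shape[1]
        expected = (-0.5 * (n - p) * np.log(2 * np.pi)
                    - 0.5 * np.linalg.slogdet(V)[1]
                    - 0.5 * np.linalg.slogdet(M)[1]
                    - 0.5 * r @ Vi @ r)
        assert model.loglike(sa, sq, se) == pytest.approx(expected, abs=1e-8)

    def test_translation_invariance(self):
        spec = iid_spec(n=40, seed=5)
        base = restricted_loglik(spec, 0.2, 0.1, 1.0)
        shifted = VCModelSpec(y=spec.y + 17.3, X=spec.X, psi=spec.psi,
                              phi=spec.phi)
        assert restricted_loglik(shifted, 0.2, 0.1, 1.0) == pytest.approx(
            base, abs=1e-8)


class TestFitReml:
    def test_iid_null_recovery(self):
        """Data with sigma_a2 = sigma_Q2 = 0, sigma_e2 = 1: the fitted
        total variance lands within 10% of 1 and equals the REML
        closed form RSS/(n-1) exactly."""
        rng = np.random.default_rng(7)
        n = 500
        y = rng.standard_normal(n)
        eye = sp.identity(n, format="csr")
        fit = fit_reml(VCModelSpec(y=y, X=np.ones((n, 1)), psi=eye, phi=eye))
        total = fit.sigma_a2 + fit.sigma_q2 + fit.sigma_e2
        assert total == pytest.approx(np.var(y, ddof=1), rel=1e-4)
        assert total == pytest.approx(1.0, rel=0.15)
        # with Psi = Phi = I the split is unidentified but the sum is not
        assert fit.converged

    def test_simulation_recovery(self):
        """Mean REML estimates over replicates track the generating
        variances on an informative fixture."""
        n = 200
        fields, kin = generate_structured_fixture(
            n, StructuredSpec(cluster_sizes={2: 40, 3: 15, 4: 8},
                              related_fraction=0.8, related_kinship=0.25),
            seed=21)
        psi = global_ibd_matrix(kin, [f"S{i:05d}" for i in range(n)])
        phi = phi_from_field(fields[0], n)
        rng = np.random.default_rng(22)
        n_reps = 60
        sa, sq, se = 0.5, 0.5, 1.0
        # draw from the exact model: y = a + q + e
        import scipy.linalg as sla
        La = np.linalg.cholesky(psi.toarray() + 1e-10 * np.eye(n))
        Lq = np.linalg.cholesky(phi.toarray() + 1e-10 * np.eye(n))
        est = []
        model = None
        for _ in range(n_reps):
            y = (np.sqrt(sa) * La @ rng.standard_normal(n)
                 + np.sqrt(sq) * Lq @ rng.standard_normal(n)
                 + np.sqrt(se) * rng.standard_normal(n))
            model = (VarianceComponentModel(y, psi, phi) if model is None
                     else model.with_endog(y))
            f = model.fit(fast=True)
            est.append(f.variances)
        est = np.array(est)
        mean = est.mean(axis=0)
        sem = est.std(axis=0, ddof=1) / np.sqrt(n_reps)
        for k, truth in enumerate((sa, sq, se)):
            assert abs(mean[k] - truth) < 3 * sem[k] + 0.02, (k, mean, sem)

    def test_nesting_null_never_exceeds_alternative(self):
        for seed in range(5):
            model = random_structured_model(60, seed=seed + 30)
            alt = model.fit()
            null = model.null_model().fit()
            assert alt.loglik >= null.loglik - 1e-8

    def test_matches_grid_polish_oracle(self):
        """REML optimum within 1e-5 log-likelihood of an independent
        dense-grid-plus-polish optimizer on random small instances."""
        for seed in range(8):
            n = 20 + (seed % 3) * 5
            model = random_structured_model(n, seed=seed + 50)
            fit = model.fit()
            oracle = grid_polish_reml(model, include_local=True)
            assert fit.loglik == pytest.approx(oracle, abs=1e-5)

    def test_scale_equivariance(self):
        model = random_structured_model(50, seed=77)
        fit1 = model.fit()
        c = 3.7
        fit2 = model.with_endog(c * model.endog).fit()
        assert fit2.sigma_a2 == pytest.approx(c ** 2 * fit1.sigma_a2,
                                              rel=1e-4, abs=1e-8)
        assert fit2.sigma_e2 == pytest.approx(c ** 2 * fit1.sigma_e2,
                                              rel=1e-4, abs=1e-8)
        w1 = model.lod_test().W
        w2 = model.with_endog(c * model.endog).lod_test().W
        assert w2 == pytest.approx(w1, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        n = 30
        X = np.column_stack([np.ones(n), np.ones(n)])
        eye = sp.identity(n, format="csr")
        with pytest.raises(ValueError):
            VarianceComponentModel(np.zeros(n), eye, None, X)


class TestLodTest:
    @pytest.mark.parametrize("w,expected", [
        (0.0, 1.0),
        (3.841458820694124, 0.025),   # chi2_1 95% quantile -> half its tail
        (2.705543454095404, 0.05),    # chi2_1 90% quantile
    ])
    def test_mixture_pvalue(self, w, expected):
        assert mixture_pvalue(w) == pytest.approx(expected, abs=1e-6)

    def test_boundary_gives_exact_zero_and_p_one(self):
        # a trait orthogonal to the cluster structure: sigma_Q2 -> 0
        model = random_structured_model(80, seed=101)
        res = model.lod_test()
        if res.W == 0.0:
            assert res.p_value == 1.0
            assert res.alt_fit.sigma_q2 == 0.0

    def test_warm_start_equals_cold_start(self):
        model = random_structured_model(60, seed=55)
        null = model.null_model().fit()
        res_warm = model.lod_test(null_fit=null)
        res_cold = model.lod_test()
        assert res_warm.W == pytest.approx(res_cold.W, abs=1e-6)

    def test_summary_mentions_lod(self, structured_world):
        model = VarianceComponentModel(structured_world["y"],
                                       structured_world["psi"],
                                       structured_world["phi"])
        text = model.lod_test().summary()
        assert "LOD" in text and "p-value" in text
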