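import numpy as np
import pytest
import scipy.linalg as la
from scipy.optimize import minimize

import polyblup as pb
from polyblup.reml import (DiagGroups, FA2Inner, FixedKnown, Iid, Kron,
                           RandomTerm, RankOneInner, ScaledKnown,
                           UnstructuredInner, _neg_ll, fa2_rotate, reml_fit)


def _oneway(g=25, r=4, s2g=3.0, s2e=1.0, seed=1):
    rng = np.random.default_rng(seed)
    y = np.repeat(rng.normal(0, np.sqrt(s2g), g), r) + rng.normal(0, np.sqrt(s2e), g * r)
    Z = np.kron(np.eye(g), np.ones((r, 1)))
    X = np.ones((g * r, 1))
    return y, X, Z, g, r


class TestRemlCore:
    def test_balanced_oneway_matches_anova(self):
        y, X, Z, g, r = _oneway()
        fit = reml_fit(y, X, [RandomTerm("g", Iid(g), Z),
                              RandomTerm("e", Iid(g * r))])
        yg = y.reshape(g, r).mean(1)
        msb = r * np.sum((yg - y.mean()) ** 2) / (g - 1)
        mse = np.sum((y.reshape(g, r) - yg[:, None]) ** 2) / (g * (r - 1))
        assert fit.components["e"]["variance"] == pytest.approx(mse, rel=1e-5)
        assert fit.components["g"]["variance"] == pytest.approx((msb - mse) / r,
                                                               rel=1e-4)

    def test_scale_equivariance(self):
        y, X, Z, g, r = _oneway()
        f1 = reml_fit(y, X, [RandomTerm("g", Iid(g), Z), RandomTerm("e", Iid(g * r))])
        c = 2.5
        f2 = reml_fit(c * y, X, [RandomTerm("g", Iid(g), Z), RandomTerm("e", Iid(g * r))])
        assert f2.components["g"]["variance"] == pytest.approx(
            c ** 2 * f1.components["g"]["variance"], rel=1e-4)
        # l_R shifts by the Jacobian of the scaling only
        assert f2.loglik == pytest.approx(f1.loglik - (len(y) - 1) * np.log(c),
                                          rel=1e-6)

    def test_translation_invariance_of_loglik(self):
        # l_R depends on y only through error contrasts: y + X b is equivalent
        y, X, Z, g, r = _oneway()
        t1 = [RandomTerm("g", Iid(g), Z), RandomTerm("e", Iid(g * r))]
        f1 = reml_fit(y, X, t1)
        f2 = reml_fit(y + X @ np.array([17.3]), X,
                      [RandomTerm("g", Iid(g), Z), RandomTerm("e", Iid(g * r))])
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)

    def test_optimum_matches_neldermead_grid(self):
        # 2-parameter problem: gradient optimum equals derivative-free optimum
        y, X, Z, g, r = _oneway(g=15, r=3, seed=5)
        terms = [RandomTerm("g", Iid(g), Z), RandomTerm("e", Iid(g * r))]
        fit = reml_fit(y, X, terms)
        nm = minimize(_neg_ll, np.zeros(2), args=(y, X, terms, len(y), 1, False),
                      method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        got = np.array([fit.params["g"][0], fit.params["e"][0]])
        assert np.abs(np.exp(got) - np.exp(nm.x)).max() < 1e-4

    def test_monotone_improvement_over_start(self):
        y, X, Z, g, r = _oneway(seed=8)
        terms = [RandomTerm("g", Iid(g), Z), RandomTerm("e", Iid(g * r))]
        fit = reml_fit(y, X, terms)
        nv = 2
        vy = np.var(y - X @ np.linalg.lstsq(X, y, rcond=None)[0], ddof=1)
        theta0 = np.concatenate([t.struct.init_params(vy / (2 * nv)) for t in terms])
        ll0 = -_neg_ll(theta0, y, X, terms, len(y), 1, False)
        assert fit.loglik >= ll0 - 1e-9

    def test_fixed_known_recovery(self):
        # heterogeneous known error blocks: sigma2_g, sigma2_gE recovered
        rng = np.random.default_rng(12)
        n, s = 150, 4
        G = np.eye(n)
        u = rng.normal(0, 1.0, n)
        means = []
        reps = 10
        for rep in range(reps):
            errs = np.concatenate([rng.uniform(0.5, 2.0, n) for _ in range(s)])
            y = (np.tile(u, s) + rng.normal(0, np.sqrt(0.5), n * s)
                 + rng.normal(0, np.sqrt(errs)))
            X = np.kron(np.eye(s), np.ones((n, 1)))
            Z = np.tile(np.eye(n), (s, 1))
            fit = reml_fit(y, X, [
                RandomTerm("g", ScaledKnown(G), Z),
                RandomTerm("ge", Iid(n * s)),
                RandomTerm("s1", FixedKnown(np.diag(errs))),
            ])
            means.append([fit.components["g"]["variance"],
                          fit.components["ge"]["variance"]])
            u = rng.normal(0, 1.0, n)
        m = np.mean(means, axis=0)
        se = np.std(means, axis=0, ddof=1) / np.sqrt(reps)
        assert abs(m[0] - 1.0) < 3 * max(se[0], 0.02)
        assert abs(m[1] - 0.5) < 3 * max(se[1], 0.02)

    def test_non_psd_fixed_rejected(self):
        with pytest.raises(ValueError, match="PSD"):
            FixedKnown(np.array([[1.0, 2.0], [2.0, 1.0]]), "bad")

    def test_rank_deficient_X_rejected(self):
        y = np.arange(6.0)
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            reml_fit(y, X, [RandomTerm("e", Iid(6))])


class TestStructures:
    def test_diag_groups_recovers_heterogeneous_variances(self):
        rng = np.random.default_rng(4)
        codes = np.repeat([0, 1], 400)
        y = rng.normal(0, np.sqrt(np.where(codes == 0, 1.0, 4.0)))
        X = np.ones((800, 1))
        fit = reml_fit(y, X, [RandomTerm("e", DiagGroups(codes, 2))])
        v = fit.components["e"]["variances"]
        assert v[0] == pytest.approx(np.var(y[codes == 0]), rel=0.05)
        assert v[1] == pytest.approx(np.var(y[codes == 1]), rel=0.05)

    def test_unstructured_gradients_match_numeric(self):
        rng = np.random.default_rng(6)
        inner = UnstructuredInner(3)
        th = rng.normal(0, 0.3, inner.n_params)
        grads = inner.grads(th)
        for k in range(inner.n_params):
            e = np.zeros_like(th)
            e[k] = 1e-6
            num = (inner.cov(th + e) - inner.cov(th - e)) / 2e-6
            np.testing.assert_allclose(grads[k], num, atol=1e-5)

    @pytest.mark.parametrize("inner_cls,dim", [(FA2Inner, 4), (RankOneInner, 3)])
    def test_inner_gradients_match_numeric(self, inner_cls, dim):
        rng = np.random.default_rng(7)
        inner = inner_cls(dim)
        th = inner.init_params(1.3) + rng.normal(0, 0.1, inner.n_params)
        grads = inner.grads(th)
        for k in range(inner.n_params):
            e = np.zeros_like(th)
            e[k] = 1e-6
            num = (inner.cov(th + e) - inner.cov(th - e)) / 2e-6
            np.testing.assert_allclose(grads[k], num, atol=1e-5)

    def test_rank_one_correlation_is_one(self):
        inner = RankOneInner(3)
        G = inner.cov(np.array([0.1, -0.4, 0.7]))
        d = np.sqrt(np.diag(G))
        np.testing.assert_allclose(G / np.outer(d, d), np.ones((3, 3)), atol=1e-12)


class TestFA2:
    def test_reconstruction_of_fa2_truth(self):
        rng = np.random.default_rng(21)
        s, n = 6, 300
        lam = rng.normal(0.7, 0.4, (s, 2))
        psi = rng.uniform(0.05, 0.3, s)
        Gam = lam @ lam.T + np.diag(psi)
        u = rng.standard_normal((n, s)) @ np.linalg.cholesky(Gam).T
        y = u.ravel() + rng.normal(0, 0.2, n * s)
        X = np.kron(np.ones((n, 1)), np.eye(s))
        fit = reml_fit(y, X, [RandomTerm("gL", Kron(np.eye(n), FA2Inner(s))),
                              RandomTerm("e", Iid(n * s))])
        Gh = fit.components["gL"]["gamma"]
        # FA2 should track the realized covariance of u within sampling noise
        emp = np.cov(u, rowvar=False)
        assert np.abs(Gh - emp).max() < 5 * np.abs(emp).max() / np.sqrt(n)
        rot = fa2_rotate(fit.components["gL"]["loadings"],
                         fit.components["gL"]["psi"])
        assert np.all(rot["squared_radius"] <= 1 + 1e-8)

    def test_rotation_limit_cases(self):
        lam = np.array([[1.0, 0.0], [0.6, 0.8], [0.0, 1.0]])
        rot = fa2_rotate(lam, np.zeros(3))
        np.testing.assert_allclose(rot["squared_radius"], 1.0, atol=1e-10)
        rot0 = fa2_rotate(np.zeros((3, 2)), np.ones(3))
        np.testing.assert_allclose(rot0["squared_radius"], 0.0, atol=1e-12)

    def test_fa2_requires_three_levels(self):
        with pytest.raises(ValueError):
            FA2Inner(2)


class TestAic:
    def test_identical_fits_zero(self):
        y, X, Z, g, r = _oneway()
        terms = lambda: [RandomTerm("g", Iid(g), Z), RandomTerm("e", Iid(g * r))]
        f1 = reml_fit(y, X, terms())
        f2 = reml_fit(y, X, terms())
        assert pb.compare_aic(f1, f2) == pytest.approx(0.0, abs=1e-6)

    def test_fixed_known_adds_no_parameters(self):
        y, X, Z, g, r = _oneway()
        f1 = reml_fit(y, X, [RandomTerm("g", Iid(g), Z), RandomTerm("e", Iid(g * r))])
        f2 = reml_fit(y, X, [RandomTerm("g", Iid(g), Z), RandomTerm("e", Iid(g * r)),
                             RandomTerm("s1", FixedKnown(np.zeros((g * r, g * r))))])
        assert f1.n_free_params == f2.n_free_params == 2
        # all-zero fixed block reproduces the base fit exactly
        assert pb.compare_aic(f2, f1) == pytest.approx(0.0, abs=1e-5)

    def test_different_response_rejected(self):
        y, X, Z, g, r = _oneway()
        f1 = reml_fit(y, X, [RandomTerm("e", Iid(g * r))])
        f2 = reml_fit(y + 1e-3, X, [RandomTerm("e", Iid(g * r))])
        with pytest.raises(ValueError):
            pb.compare_aic(f1, f2)

    def test_heterogeneous_errors_favor_s_term(self):
        # synthetic analog of the with/without Stage-1-error comparison
        rng = np.random.default_rng(31)
        n, s = 120, 4
        u = rng.normal(0, 1.0, n)
        errs = np.concatenate([np.full(n, v) for v in [0.2, 0.6, 1.4, 2.8]])
        y = np.tile(u, s) + rng.normal(0, np.sqrt(0.4), n * s) + rng.normal(0, np.sqrt(errs))
        X = np.kron(np.eye(s), np.ones((n, 1)))
        Z = np.tile(np.eye(n), (s, 1))
        base = [RandomTerm("g", Iid(n), Z), RandomTerm("ge", Iid(n * s))]
        f_without = reml_fit(y, X, list(base))
        f_with = reml_fit(y, X, list(base) + [RandomTerm("s1", FixedKnown(np.diag(errs)))])
        assert pb.compare_aic(f_with, f_without) < 0
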