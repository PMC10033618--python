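import numpy as np
import pandas as pd
import pytest

import polyblup as pb
from polyblup.stage2 import legarra_variance


class TestLegarraVariance:
    def test_iid_four_observations(self):
        s2 = 1.7
        assert legarra_variance(K=s2 * np.eye(4)) == pytest.approx(0.75 * s2)

    def test_constant_mean_zero_K(self):
        assert legarra_variance(K=np.zeros((5, 5)), mu=np.full(5, 3.0)) == 0.0

    def test_two_genotype_gamma_offdiagonal(self):
        # balanced 2-loc, G = I (2 genotypes): E[V_g] = 0.5 * gamma_12
        g12 = 0.37
        G = np.eye(2)
        off = g12  # mean off-diagonal of Gamma
        vg = legarra_variance(K=G, weights=np.full(2, 2.0), t=4.0) * off
        assert vg == pytest.approx(0.5 * g12)

    def test_weighted_matches_expanded(self):
        # weights = replication: the weighted form equals Z-expansion
        rng = np.random.default_rng(1)
        K = rng.standard_normal((4, 6))
        K = K @ K.T
        mu = rng.standard_normal(4)
        w = np.array([1, 3, 2, 2])
        Z = np.zeros((8, 4))
        r = 0
        for i, wi in enumerate(w):
            for _ in range(wi):
                Z[r, i] = 1
                r += 1
        direct = legarra_variance(K=Z @ K @ Z.T, mu=Z @ mu)
        weighted = legarra_variance(K=K, mu=mu, weights=w)
        assert weighted == pytest.approx(direct, rel=1e-12)


class TestSingleTrait:
    def test_null_dominance_pve_near_zero(self):
        ms = pb.sim_population(150, 500, 4, seed=41)
        truth = pb.sim_genetic_values(ms, 1.0, 0.0, 0.0, 0.5, seed=42)
        _, s1 = pb.sim_phenotypes(ms, truth, 3, seed=43)
        fit = pb.fit_stage2(s1, pb.Stage2Spec(model="additive-dominance"), geno=ms)
        assert fit.pve.loc["dominance", "PVE"] < 0.05

    def test_s_term_lowers_aic_with_heterogeneous_errors(self):
        # strongly heterogeneous Stage-1 error variances: the fully efficient
        # model (known error covariance) wins the AIC comparison
        ms = pb.sim_population(150, 400, 4, seed=56)
        truth = pb.sim_genetic_values(ms, 1.0, 0.2, 0.0, 0.4, seed=57)
        _, s1 = pb.sim_phenotypes(ms, truth, 4, error_scales=(0.2, 3.0), seed=58)
        f1 = pb.fit_stage2(s1, pb.Stage2Spec(model="additive-dominance"),
                           geno=ms, include_s_term=True)
        f0 = pb.fit_stage2(s1, pb.Stage2Spec(model="additive-dominance"),
                           geno=ms, include_s_term=False)
        assert f1.aic < f0.aic

    def test_zero_vcov_s_term_matches_no_s_term(self):
        ms = pb.sim_population(60, 200, 4, seed=44)
        truth = pb.sim_genetic_values(ms, 1.0, 0.2, 0.0, 0.4, seed=45)
        _, s1 = pb.sim_phenotypes(ms, truth, 3, seed=46)
        for e in s1.envs:
            s1.vcov[e] = np.zeros_like(s1.vcov[e])
        f1 = pb.fit_stage2(s1, pb.Stage2Spec(), geno=ms, include_s_term=True)
        f0 = pb.fit_stage2(s1, pb.Stage2Spec(), geno=ms, include_s_term=False)
        assert f1.loglik == pytest.approx(f0.loglik, abs=1e-5)
        assert f1.aic == pytest.approx(f0.aic, abs=1e-4)

    def test_pve_rows_sum_to_one_and_scale_invariance(self, dom_fit):
        ms, truth, s1, fit = dom_fit
        assert fit.pve["PVE"].sum() == pytest.approx(1.0)
        # rescale all responses: additive PVE (genomic heritability) unchanged
        import copy
        s1b = copy.deepcopy(s1)
        c = 3.0
        for e in s1b.envs:
            s1b.blue[e] = s1b.blue[e] * c
            s1b.vcov[e] = s1b.vcov[e] * c ** 2
        fb = pb.fit_stage2(s1b, pb.Stage2Spec(model="additive-dominance"), geno=ms)
        assert fb.pve.loc["additive", "PVE"] == pytest.approx(
            fit.pve.loc["additive", "PVE"], abs=0.01)

    def test_single_env_rejected(self):
        ms = pb.sim_population(20, 50, 2, seed=47)
        truth = pb.sim_genetic_values(ms, 1.0, 0.0, 0.0, 0.3, seed=48)
        _, s1 = pb.sim_phenotypes(ms, truth, 2, seed=49)
        s1.envs = s1.envs[:1]
        with pytest.raises(ValueError, match="2 env"):
            pb.fit_stage2(s1, pb.Stage2Spec(model="no-markers"))

    def test_dominance_without_markers_rejected(self):
        ms = pb.sim_population(20, 50, 2, seed=50)
        truth = pb.sim_genetic_values(ms, 1.0, 0.0, 0.0, 0.3, seed=51)
        _, s1 = pb.sim_phenotypes(ms, truth, 2, seed=52)
        with pytest.raises(ValueError, match="marker"):
            pb.fit_stage2(s1, pb.Stage2Spec(model="additive-dominance"))

    def test_fixed_marker_covariate(self):
        # a large-effect QTL entered as a fixed covariate is recovered
        rng = np.random.default_rng(53)
        ms = pb.sim_population(150, 300, 4, seed=53)
        truth = pb.sim_genetic_values(ms, 0.5, 0.0, 0.0, 0.3, seed=54)
        qtl = ms.marker_ids[10]
        effect = 1.5
        truth.additive = truth.additive + effect * ms.W[:, 10]
        _, s1 = pb.sim_phenotypes(ms, truth, 3, seed=55)
        fit = pb.fit_stage2(
            s1, pb.Stage2Spec(model="additive-residual", fixed_markers=(qtl,)),
            geno=ms)
        est = fit.marker_effects.query("marker == @qtl")["effect"].iloc[0]
        se = fit.marker_effects.query("marker == @qtl")["se"].iloc[0]
        assert abs(est - effect) < 4 * se
        assert "fixed markers" in fit.pve.index


@pytest.fixture(scope="module")
def two_trait():
        rng = np.random.default_rng(61)
        ms = pb.sim_population(120, 400, 4, seed=61)
        G = pb.compute_G(ms).values
        gcor = 0.6
        Ga = np.array([[1.0, gcor], [gcor, 1.0]])
        L = np.linalg.cholesky(Ga)
        # additive values with genetic correlation 0.6 via shared markers
        denom = 4 * np.sum(ms.p * (1 - ms.p))
        a_eff = rng.standard_normal((ms.m, 2)) @ L.T / np.sqrt(denom)
        A = ms.W @ a_eff
        envs = [f"e{j}" for j in range(3)]
        ids_d, blue_d, vcov_d = {}, {}, {}
        for j, e in enumerate(envs):
            ge = rng.normal(0, np.sqrt(0.3), (ms.n, 2))
            v = 0.4 + 0.3 * j
            s = rng.normal(0, np.sqrt(v), (ms.n, 2))
            ids_d[e] = list(ms.ids)
            blue_d[e] = A + ge + s
            vcov_d[e] = np.eye(ms.n * 2) * v
        s1 = pb.Stage1Fit(["t1", "t2"], envs, ids_d, blue_d, vcov_d)
        fit = pb.fit_stage2(s1, pb.Stage2Spec(model="additive-residual",
                                              multi="trait"), geno=ms)
        return ms, s1, fit, gcor


class TestMultiTrait:
    def test_additive_correlation_recovered(self, two_trait):
        ms, s1, fit, gcor = two_trait
        corr = fit.additive_correlation()
        assert corr.iloc[0, 1] == pytest.approx(gcor, abs=0.2)

    def test_pve_per_trait_sums_to_one(self, two_trait):
        ms, s1, fit, _ = two_trait
        np.testing.assert_allclose(fit.pve.sum(axis=0), 1.0, atol=1e-8)

    def test_single_trait_reduction_matches(self):
        # multi-trait machinery with one trait reproduces the single-trait fit
        ms = pb.sim_population(60, 200, 4, seed=63)
        truth = pb.sim_genetic_values(ms, 1.0, 0.0, 0.0, 0.4, seed=64)
        _, s1 = pb.sim_phenotypes(ms, truth, 3, seed=65)
        f1 = pb.fit_stage2(s1, pb.Stage2Spec(model="additive-residual"), geno=ms)
        f2 = pb.fit_stage2(s1, pb.Stage2Spec(model="additive-residual",
                                             multi="trait"), geno=ms)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-4)


@pytest.fixture(scope="module")
def loc_fit():
        rng = np.random.default_rng(71)
        ms = pb.sim_population(100, 300, 4, seed=71)
        denom = 4 * np.sum(ms.p * (1 - ms.p))
        s = 3  # locations
        Gam = np.array([[1.0, 0.8, 0.5], [0.8, 1.0, 0.6], [0.5, 0.6, 1.0]])
        L = np.linalg.cholesky(Gam)
        a_eff = rng.standard_normal((ms.m, s)) @ L.T / np.sqrt(denom)
        A = ms.W @ a_eff  # n x s additive values per location
        envs, ids_d, blue_d, vcov_d = [], {}, {}, {}
        locmap = {}
        for k in range(s):
            for j in range(2):  # two envs per location
                e = f"loc{k}_y{j}"
                envs.append(e)
                locmap[e] = f"loc{k}"
                v = 0.3 + 0.2 * j
                ids_d[e] = list(ms.ids)
                blue_d[e] = (A[:, k] + rng.normal(0, np.sqrt(0.3), ms.n)
                             + rng.normal(0, np.sqrt(v), ms.n))[:, None]
                vcov_d[e] = np.eye(ms.n) * v
        s1 = pb.Stage1Fit(["y"], envs, ids_d, blue_d, vcov_d, loc=locmap)
        fit = pb.fit_stage2(s1, pb.Stage2Spec(model="additive-residual",
                                              multi="loc"), geno=ms)
        return ms, s1, fit, Gam


class TestMultiLoc:
    def test_fa2_loadings_radii_bounded(self, loc_fit):
        ms, s1, fit, Gam = loc_fit
        assert fit.loadings is not None
        r2 = fit.loadings["squared_radius"]
        assert np.all(r2 <= 1 + 1e-8)

    def test_gamma_tracks_truth(self, loc_fit):
        ms, s1, fit, Gam = loc_fit
        assert np.abs(fit.gamma_A - Gam).max() < 0.45
        d = np.sqrt(np.diag(fit.gamma_A))
        corr = fit.gamma_A / np.outer(d, d)
        assert corr[0, 1] > corr[0, 2] - 0.3  # ordering roughly preserved

    def test_pve_has_loc_split(self, loc_fit):
        _, _, fit, _ = loc_fit
        assert "g x loc" in fit.pve.index
        assert fit.pve["PVE"].sum() == pytest.approx(1.0)


class TestBlend:
    def test_identical_matrices_flat_aic(self):
        ms = pb.sim_population(60, 200, 4, seed=81)
        truth = pb.sim_genetic_values(ms, 1.0, 0.0, 0.0, 0.4, seed=82)
        _, s1 = pb.sim_phenotypes(ms, truth, 3, seed=83)
        G = pb.compute_G(ms)
        A = pb.RelMatrix(list(G.ids), G.values.copy(), "A")
        w, tab = pb.optimize_blend(s1, pb.Stage2Spec(model="additive-residual"),
                                   geno=ms, A=A, omega_grid=[0.0, 0.5, 1.0])
        assert tab["AIC"].max() - tab["AIC"].min() < 0.5

    def test_blend_recovery(self):
        # data generated under K = 0.7 G + 0.3 A: omega* near 0.3
        rng = np.random.default_rng(85)
        ms = pb.sim_population(150, 400, 4, seed=85)
        G = pb.compute_G(ms)
        M = rng.standard_normal((ms.n, 40))
        A = pb.RelMatrix(list(ms.ids), M @ M.T / 40 + 0.05 * np.eye(ms.n), "A")
        K = 0.7 * G.values + 0.3 * A.values
        L = np.linalg.cholesky(K + 1e-8 * np.eye(ms.n))
        u = L @ rng.standard_normal(ms.n)
        envs = [f"e{j}" for j in range(3)]
        ids_d, blue_d, vcov_d = {}, {}, {}
        for e in envs:
            ids_d[e] = list(ms.ids)
            blue_d[e] = (u + rng.normal(0, np.sqrt(0.3), ms.n)
                         + rng.normal(0, np.sqrt(0.2), ms.n))[:, None]
            vcov_d[e] = np.eye(ms.n) * 0.2
        s1 = pb.Stage1Fit(["y"], envs, ids_d, blue_d, vcov_d)
        w, tab = pb.optimize_blend(
            s1, pb.Stage2Spec(model="additive-residual"), geno=ms, A=A,
            omega_grid=np.arange(0, 1.01, 0.1))
        assert abs(w - 0.3) <= 0.2

    def test_grid_bounds_checked(self):
        ms = pb.sim_population(20, 60, 2, seed=86)
        truth = pb.sim_genetic_values(ms, 1.0, 0.0, 0.0, 0.3, seed=87)
        _, s1 = pb.sim_phenotypes(ms, truth, 2, seed=88)
        G = pb.compute_G(ms)
        with pytest.raises(ValueError):
            pb.optimize_blend(s1, pb.Stage2Spec(), geno=ms, A=G,
                              omega_grid=[-0.1, 0.5])
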