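"""SEM structure, model-implied moments, likelihood and ML fitting."""

import numpy as np
import pytest
import scipy.stats

from conftest import families_from, residual_scale_config
from pedsem.pedigree import kinship_matrix
from pedsem.sem import (FamilyData, ParamTransform, SemModel, SemParams,
                        _CompleteStack, ar_params, assemble_families,
                        family_loglik, fit_ml, lg_params, model_moments,
                        total_loglik)
from pedsem.simulate import SimulationConfig, simulate_dataset, pivot_wide


def ar_moments_by_recursion(params, T):
    """Independent AR oracle: propagate the latent recursion
    eta_1 = mu + zeta_1, eta_t = beta*eta_{t-1} + zeta_t term by term,
    splitting each disturbance into its genetic and environmental part,
    then map latents to the 2T observed traits by (1, lambda) loadings.
    Never touches the package's matrix reduced form.
    """
    b, lam = params.beta_ar, params.lambda_dbp
    a1, ar = params.sigma2_a
    z1, zr = params.sigma2_z
    # latent covariance, one component at a time
    cov = {}
    for comp, (v1, vr) in (("A", (a1, ar)), ("E", (z1, zr))):
        v = np.zeros(T)                      # Var of eta_t (this component)
        v[0] = v1
        for t in range(1, T):
            v[t] = b * b * v[t - 1] + vr
        C = np.zeros((T, T))
        for t in range(T):
            for u in range(T):
                lo = min(t, u)
                C[t, u] = b ** abs(t - u) * v[lo]
        cov[comp] = C
    mean_lat = np.array([params.mu[0] * b ** t for t in range(T)])
    snp_lat = np.array([b ** t for t in range(T)])  # SNP hits eta_1
    # observed: y_{2t} = eta_t + e, y_{2t+1} = lam*eta_t + e
    load = np.zeros((2 * T, T))
    for t in range(T):
        load[2 * t, t] = 1.0
        load[2 * t + 1, t] = lam
    return (load @ mean_lat, load @ snp_lat,
            load @ cov["A"] @ load.T,
            load @ cov["E"] @ load.T + np.diag(np.tile(params.theta, T)))


def lg_moments_by_formula(params, T):
    """Independent LG oracle: eta_t = I + l_t*S + v_t with loadings
    l_t = t-1, written out as explicit scalar covariances."""
    lam = params.lambda_dbp
    loads = np.arange(T, dtype=float)
    Sa = np.asarray(params.sigma2_a)
    Se = np.asarray(params.sigma2_z)
    CA = np.zeros((T, T))
    CE = np.zeros((T, T))
    for t in range(T):
        for u in range(T):
            lt, lu = loads[t], loads[u]
            CA[t, u] = (Sa[0, 0] + lt * Sa[1, 0] + lu * Sa[0, 1]
                        + lt * lu * Sa[1, 1])
            CE[t, u] = (Se[0, 0] + lt * Se[1, 0] + lu * Se[0, 1]
                        + lt * lu * Se[1, 1])
            if t == u:
                CE[t, u] += params.sigma2_v
    mean_lat = params.mu[0] + loads * params.mu[1]
    snp_lat = np.ones(T)  # SNP on the intercept factor
    load = np.zeros((2 * T, T))
    for t in range(T):
        load[2 * t, t] = 1.0
        load[2 * t + 1, t] = lam
    return (load @ mean_lat, load @ snp_lat,
            load @ CA @ load.T,
            load @ CE @ load.T + np.diag(np.tile(params.theta, T)))


def random_families(rng, n_fam=4, n_visits=3, with_g=False):
    """Random pedigree structures with *arbitrary* phenotypes (not drawn
    from either SEM), for likelihood-identity checks."""
    cfg = SimulationConfig(n_families=n_fam, n_visits=n_visits, n_snps=1,
                           n_children_range=(2, 3),
                           n_grandchildren_range=(1, 2),
                           seed=int(rng.integers(1 << 30)))
    from pedsem.simulate import simulate_pedigrees
    peds = simulate_pedigrees(cfg)
    fams = []
    for ped in peds:
        kin = kinship_matrix(ped)
        n = len(ped)
        y = rng.normal(0, 8, (n, 2 * n_visits))
        g = rng.integers(0, 3, n).astype(float) if with_g else None
        fams.append(FamilyData(family_id=ped.family_id, ids=list(kin.ids),
                               kin2=kin.additive, y=y, g=g))
    return fams


def dense_mvn_loglik(moments, fam):
    """scipy-based oracle for one family's log density."""
    n = fam.n
    mean = np.tile(moments.mean, (n, 1))
    if fam.g is not None:
        mean += np.outer(fam.g, moments.mean_per_allele)
    V = (np.kron(fam.kin2, moments.sigma_A)
         + np.kron(np.eye(n), moments.sigma_E))
    yv = fam.y.ravel()
    mask = ~np.isnan(yv)
    return scipy.stats.multivariate_normal.logpdf(
        yv[mask], mean.ravel()[mask], V[np.ix_(mask, mask)])


class TestStructure:
    def test_ar_shapes_and_pattern(self):
        model = SemModel("ar", 3)
        p = ar_params()
        Lam, B, G, PA, PE, th = model.matrices(p)
        assert Lam.shape == (6, 3) and B.shape == (3, 3)
        assert np.count_nonzero(B) == 2          # two lag-1 paths
        assert B[1, 0] == B[2, 1] == p.beta_ar
        assert G.tolist() == [1.0, 0.0, 0.0]     # SNP on first latent
        assert np.count_nonzero(Lam) == 6        # (1, lambda) per visit
        assert th.tolist() == [40, 20, 40, 20, 40, 20]

    def test_lg_shapes_and_pattern(self):
        model = SemModel("lg", 3)
        Lam, B, G, PA, PE, th = model.matrices(lg_params())
        assert Lam.shape == (6, 5) and B.shape == (5, 5)
        # each visit latent regressed on (I, S) with loadings (1, t-1)
        assert B[2:, 0].tolist() == [1.0, 1.0, 1.0]
        assert B[2:, 1].tolist() == [0.0, 1.0, 2.0]
        assert G.tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]
        assert PA[:2, :2].tolist() == [[30, 2], [2, 2]]
        assert np.allclose(np.diag(PE)[2:], 10.0)

    def test_param_counts(self):
        assert ParamTransform(SemModel("ar", 3)).n_params == 9
        assert ParamTransform(SemModel("lg", 3)).n_params == 12
        assert ParamTransform(SemModel("ar", 3), free_gamma=True).n_params == 10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            SemModel("cross-lag", 3)
        with pytest.raises(ValueError, match="visits"):
            SemModel("ar", 0)
        with pytest.raises(ValueError, match="beta_ar"):
            ar_params(beta_ar=1.5).validate()
        with pytest.raises(ValueError, match="PSD"):
            lg_params(sigma2_a=((1.0, 9.0), (9.0, 1.0))).validate()


class TestMoments:
    def test_ar_against_path_recursion(self):
        p = ar_params(mu1=2.5, lambda_dbp=0.8, beta_ar=0.55,
                      sigma2_a=(35.0, 18.0), sigma2_z=(50.0, 27.0),
                      theta=(38.0, 19.0), gamma_snp=1.7)
        for T in (1, 2, 3, 5):
            m = model_moments(SemModel("ar", T), p)
            mean, snp, SA, SE = ar_moments_by_recursion(p, T)
            assert np.allclose(m.mean, mean, atol=1e-12)
            assert np.allclose(m.snp_direction, snp, atol=1e-12)
            assert np.allclose(m.mean_per_allele, 1.7 * snp, atol=1e-12)
            assert np.allclose(m.sigma_A, SA, atol=1e-12)
            assert np.allclose(m.sigma_E, SE, atol=1e-12)

    def test_lg_against_scalar_formula(self):
        p = lg_params(mu_i=118.0, mu_s=1.3, lambda_dbp=0.65,
                      sigma2_a=((28.0, 3.0), (3.0, 2.5)),
                      sigma2_z=((42.0, 2.0), (2.0, 3.5)),
                      sigma2_v=9.0, theta=(41.0, 21.0))
        for T in (2, 3, 4):
            m = model_moments(SemModel("lg", T), p)
            mean, snp, SA, SE = lg_moments_by_formula(p, T)
            assert np.allclose(m.mean, mean, atol=1e-12)
            assert np.allclose(m.snp_direction, snp, atol=1e-12)
            assert np.allclose(m.sigma_A, SA, atol=1e-12)
            assert np.allclose(m.sigma_E, SE, atol=1e-12)

    def test_ar_stationary_variance_closed_form(self):
        # first-visit variances at the stationary values: the latent
        # variance stays flat, so at T = 50 the observed SBP variance is
        # (sigma2_a + sigma2_z) / (1 - beta^2) + theta_sbp exactly
        b, ar_, zr = 0.6, 20.0, 30.0
        stat = (ar_ + zr) / (1 - b * b)
        p = ar_params(beta_ar=b, sigma2_a=(stat * 0.4, ar_),
                      sigma2_z=(stat * 0.6, zr), theta=(40.0, 20.0))
        m = model_moments(SemModel("ar", 50), p)
        var_sbp = np.diag(m.sigma_A + m.sigma_E)[::2]
        assert np.allclose(var_sbp, stat + 40.0, rtol=1e-12)

    def test_lambda_scales_dbp_block(self):
        p1, p2 = ar_params(lambda_dbp=0.5), ar_params(lambda_dbp=1.0)
        m1 = model_moments(SemModel("ar", 3), p1)
        m2 = model_moments(SemModel("ar", 3), p2)
        # DBP-DBP latent covariance scales with lambda^2
        d1 = m1.sigma_A[1::2, 1::2]
        d2 = m2.sigma_A[1::2, 1::2]
        assert np.allclose(d1, 0.25 * d2, atol=1e-12)


class TestLoglik:
    def test_single_person_single_visit_closed_form(self):
        p = ar_params(mu1=120.0, lambda_dbp=0.7, beta_ar=0.3,
                      sigma2_a=(30.0, 30.0), sigma2_z=(50.0, 50.0),
                      theta=(40.0, 20.0))
        m = model_moments(SemModel("ar", 1), p)
        kin2 = np.array([[1.0]])
        y = np.array([[128.0, np.nan]])  # keep only the SBP coordinate
        got = family_loglik(m, kin2, y)
        var = 30.0 + 50.0 + 40.0
        want = scipy.stats.norm.logpdf(128.0, 120.0, np.sqrt(var))
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("kind", ["ar", "lg"])
    def test_dense_oracle_random_families(self, kind):
        rng = np.random.default_rng(17)
        p = ar_params(mu1=1.0, gamma_snp=2.0) if kind == "ar" else \
            lg_params(mu_i=1.0, gamma_snp=2.0)
        m = model_moments(SemModel(kind, 3), p)
        for fam in random_families(rng, n_fam=4, with_g=True):
            got = family_loglik(m, fam.kin2, fam.y, fam.g)
            assert got == pytest.approx(dense_mvn_loglik(m, fam), abs=1e-8)

    @pytest.mark.parametrize("kind", ["ar", "lg"])
    def test_fast_path_matches_dense(self, kind):
        rng = np.random.default_rng(23)
        p = ar_params() if kind == "ar" else lg_params()
        m = model_moments(SemModel(kind, 3), p)
        fams = random_families(rng, n_fam=5, with_g=True)
        slow = sum(family_loglik(m, f.kin2, f.y, f.g) for f in fams)
        fast = total_loglik(SemModel(kind, 3), p, fams)
        assert fast == pytest.approx(slow, rel=1e-12)
        stacked = _CompleteStack(fams).loglik(m)
        assert stacked == pytest.approx(slow, rel=1e-12)

    def test_missing_entries_marginalize(self):
        rng = np.random.default_rng(31)
        (fam,) = random_families(rng, n_fam=1)
        m = model_moments(SemModel("ar", 3), ar_params())
        full = family_loglik(m, fam.kin2, fam.y)
        y2 = fam.y.copy()
        y2[0, 1] = np.nan
        y2[2, :] = np.nan
        fam2 = FamilyData(fam.family_id, fam.ids, fam.kin2, y2)
        got = family_loglik(m, fam2.kin2, fam2.y)
        assert got == pytest.approx(dense_mvn_loglik(m, fam2), abs=1e-8)
        assert got != pytest.approx(full, abs=1e-3)  # genuinely different

    def test_assemble_drops_all_missing_individuals(self):
        cfg = residual_scale_config(n_families=4, n_snps=1, seed=44,
                                    missing_visit_rate=0.9)
        peds, *_, phenos, _ = simulate_dataset(cfg)
        kins = {p.family_id: kinship_matrix(p) for p in peds}
        fams = assemble_families(kins, pivot_wide(phenos), 3)
        for fam in fams:
            assert not np.isnan(fam.y).all(axis=1).any()
            assert fam.kin2.shape == (fam.n, fam.n)


class TestTransform:
    @pytest.mark.parametrize("free_gamma", [False, True])
    def test_ar_roundtrip(self, free_gamma):
        p = ar_params(mu1=-3.0, lambda_dbp=1.2, beta_ar=-0.4,
                      sigma2_a=(12.0, 7.0), sigma2_z=(22.0, 9.0),
                      theta=(33.0, 11.0), gamma_snp=0.8 if free_gamma else 0.0)
        tr = ParamTransform(SemModel("ar", 3), free_gamma=free_gamma)
        q = tr.unpack(tr.pack(p))
        assert np.allclose(tr.natural_vector(q), tr.natural_vector(p),
                           atol=1e-10)

    def test_lg_roundtrip_and_psd(self):
        p = lg_params(sigma2_a=((9.0, -2.0), (-2.0, 4.0)))
        tr = ParamTransform(SemModel("lg", 3))
        q = tr.unpack(tr.pack(p))
        assert np.allclose(q.sigma2_a, p.sigma2_a, atol=1e-6)
        # arbitrary transformed vectors always decode to valid params
        rng = np.random.default_rng(2)
        for _ in range(20):
            r = tr.unpack(rng.normal(0, 2, tr.n_params))
            r.validate()

    def test_ar_decode_always_valid(self):
        tr = ParamTransform(SemModel("ar", 3))
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = tr.unpack(rng.normal(0, 3, tr.n_params))
            p.validate()
            assert abs(p.beta_ar) < 1


class TestFit:
    def test_ar_fit_beats_truth_and_lands_near_it(self, small_ar_dataset):
        d = small_ar_dataset
        model = SemModel("ar", 3)
        fit = fit_ml(model, d["families"], seed=0, n_starts=2,
                     compute_se=True)
        truth_ll = total_loglik(model, d["truth"].params, d["families"])
        assert fit.loglik >= truth_ll - 1e-6
        assert abs(fit.params.beta_ar - d["truth"].params.beta_ar) < 0.2
        assert abs(fit.params.lambda_dbp - d["truth"].params.lambda_dbp) < 0.2
        assert fit.se is not None and np.all(np.isfinite(fit.se))
        names = fit.param_names
        assert names[names.index("beta_ar")] == "beta_ar"
        s = fit.summary()
        assert set(s["estimates"]) == set(names)

    def test_refit_from_optimum_is_stationary(self, small_ar_dataset):
        d = small_ar_dataset
        model = SemModel("ar", 3)
        fit = fit_ml(model, d["families"], seed=0, n_starts=1,
                     compute_se=False)
        refit = fit_ml(model, d["families"], start=fit.params, seed=1,
                       n_starts=1, compute_se=False)
        assert refit.loglik - fit.loglik < 1e-4

    def test_lg_fit_on_lg_data(self):
        cfg = residual_scale_config(n_families=15, n_snps=1, model="lg",
                                    true_params=lg_params(), seed=57,
                                    n_children_range=(2, 4),
                                    n_grandchildren_range=(1, 3))
        peds, *_, phenos, truth = simulate_dataset(cfg)
        fams = families_from(phenos, peds)
        model = SemModel("lg", 3)
        fit = fit_ml(model, fams, seed=0, n_starts=2, compute_se=False)
        assert fit.loglik >= total_loglik(model, truth.params, fams) - 1e-6
        assert abs(fit.params.mu[1] - truth.params.mu[1]) < 0.6

    def test_no_families_rejected(self):
        with pytest.raises(ValueError, match="families"):
            fit_ml(SemModel("ar", 3), [])
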