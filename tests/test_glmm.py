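"""Fitter-level tests: recovery of known truth, AIC semantics, and an
independent lme4 cross-check through Rscript."""

import subprocess

import numpy as np
import pytest

from fishcards.glmm import GlmmError, fit_glmm_raw


def simulate_logit(seed=7, n_p=25, n_r=80, beta=(0.5, -1.2, 0.02),
                   sig_p=0.5, sig_r=0.2):
    rng = np.random.default_rng(seed)
    P = np.repeat(np.arange(n_p), n_r)
    R = np.tile(np.arange(n_r), n_p)
    n = len(P)
    u = rng.normal(0, sig_p, n_p)
    v = rng.normal(0, sig_r, n_r)
    x1 = (rng.random(n) < 0.5).astype(float)
    x2 = rng.uniform(0, 100, n)
    X = np.column_stack([np.ones(n), x1, x2])
    eta = X @ np.asarray(beta) + u[P] + v[R]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y, P, R


class TestBinomial:
    def test_recovers_known_coefficients(self):
        X, y, P, R = simulate_logit()
        res = fit_glmm_raw(X, y, P, R, family="binomial", link="logit")
        assert res.converged
        assert res.coefficients[1] == pytest.approx(-1.2, abs=3 * res.std_errors[1])
        assert res.coefficients[2] == pytest.approx(0.02, abs=3 * res.std_errors[2])
        assert 0.2 < res.sigma_participant < 0.9
        assert (res.p_values <= 1).all() and (res.p_values >= 0).all()

    def test_probit_link_fits_and_scales_down_coefficients(self):
        X, y, P, R = simulate_logit()
        logit = fit_glmm_raw(X, y, P, R, family="binomial", link="logit")
        probit = fit_glmm_raw(X, y, P, R, family="binomial", link="probit")
        assert probit.converged
        # probit coefficients are roughly logit / 1.6-1.8
        ratio = logit.coefficients[1] / probit.coefficients[1]
        assert 1.4 < ratio < 2.1

    def test_duplication_sanity_and_glm_limit(self):
        # duplicating every row is NOT an exact invariance for a mixed model
        # (copied outcomes raise apparent within-cell clustering, which
        # legitimately re-weights shrinkage), but estimates must stay close;
        # and with no real heterogeneity the fitter must reduce to the GLM,
        # which is exactly duplication-invariant
        import statsmodels.api as sm
        X, y, P, R = simulate_logit(n_p=10, n_r=40, sig_p=0.02, sig_r=0.02)
        res1 = fit_glmm_raw(X, y, P, R, family="binomial", link="logit")
        X2 = np.vstack([X, X])
        res2 = fit_glmm_raw(X2, np.concatenate([y, y]),
                            np.concatenate([P, P]), np.concatenate([R, R]),
                            family="binomial", link="logit")
        np.testing.assert_allclose(res1.coefficients, res2.coefficients,
                                   atol=0.15)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(res1.coefficients, glm.params, atol=0.02)

    def test_aic_invariant_to_row_order(self):
        X, y, P, R = simulate_logit(n_p=10, n_r=40)
        res1 = fit_glmm_raw(X, y, P, R, family="binomial", link="logit")
        perm = np.random.default_rng(0).permutation(len(y))
        res2 = fit_glmm_raw(X[perm], y[perm], P[perm], R[perm],
                            family="binomial", link="logit")
        assert res1.aic == pytest.approx(res2.aic, abs=0.05)


@pytest.fixture(scope="module")
def gamma_data():
    rng = np.random.default_rng(13)
    n_p, n_r = 25, 80
    P = np.repeat(np.arange(n_p), n_r)
    R = np.tile(np.arange(n_r), n_p)
    n = len(P)
    u = rng.normal(0, 0.03, n_p)
    v = rng.normal(0, 0.01, n_r)
    x1 = (rng.random(n) < 0.5).astype(float)
    eta = 0.25 - 0.05 * x1 + u[P] + v[R]       # inverse-link scale
    mu = 1.0 / eta
    y = rng.gamma(4.0, mu / 4.0)
    return np.column_stack([np.ones(n), x1]), y, P, R


class TestGamma:
    def test_inverse_link_recovers_effect_and_shape(self, gamma_data):
        X, y, P, R = gamma_data
        res = fit_glmm_raw(X, y, P, R, family="gamma", link="inverse")
        assert res.converged
        assert res.coefficients[1] == pytest.approx(-0.05, abs=0.01)
        assert res.shape == pytest.approx(4.0, rel=0.15)

    def test_identity_link_fits_the_same_data(self, gamma_data):
        X, y, P, R = gamma_data
        res = fit_glmm_raw(X, y, P, R, family="gamma", link="identity")
        # identity on inverse-generated data: converged or honestly reported
        if res.converged:
            assert res.coefficients[1] > 0      # means: 1/0.25 vs 1/0.30
            assert np.isfinite(res.aic)
        else:
            assert not np.isfinite(res.aic) or np.isnan(res.aic)

    def test_rejects_nonpositive_outcome(self, gamma_data):
        X, y, P, R = gamma_data
        y2 = y.copy()
        y2[0] = 0.0
        with pytest.raises(GlmmError):
            fit_glmm_raw(X, y2, P, R, family="gamma", link="inverse")


class TestValidation:
    def test_constant_predictor_rejected(self):
        X, y, P, R = simulate_logit(n_p=5, n_r=10)
        X = X.copy()
        X[:, 1] = 1.0
        with pytest.raises(GlmmError):
            fit_glmm_raw(X, y, P, R, family="binomial", link="logit")

    def test_unknown_family_or_link_rejected(self):
        X, y, P, R = simulate_logit(n_p=5, n_r=10)
        with pytest.raises(GlmmError):
            fit_glmm_raw(X, y, P, R, family="poisson", link="log")
        with pytest.raises(GlmmError):
            fit_glmm_raw(X, y, P, R, family="binomial", link="cloglog")


def test_matches_lme4_glmer_point_estimates(tmp_path):
    """Independent oracle: lme4::glmer on the same data, via Rscript."""
    X, y, P, R = simulate_logit(seed=11, n_p=20, n_r=60, beta=(0.4, -1.2, 0.0))
    X = X[:, :2]
    res = fit_glmm_raw(X, y, P, R, family="binomial", link="logit")
    csv = tmp_path / "d.csv"
    np.savetxt(csv, np.column_stack([y, X[:, 1], P, R]), delimiter=",",
               header="y,x1,p,r", comments="")
    rscript = (
        "suppressMessages(library(lme4));"
        f"d <- read.csv('{csv}');"
        "m <- glmer(y ~ x1 + (1|p) + (1|r), data=d, family=binomial);"
        "cat(fixef(m), AIC(m), as.data.frame(VarCorr(m))$sdcor, sep=',')"
    )
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    vals = [float(v) for v in out.stdout.strip().split(",")]
    r_int, r_x1, r_aic, r_sd1, r_sd2 = vals[:5]
    assert res.coefficients[0] == pytest.approx(r_int, abs=0.05)
    assert res.coefficients[1] == pytest.approx(r_x1, abs=0.05)
    assert res.aic == pytest.approx(r_aic, abs=2.0)
    assert sorted([res.sigma_participant, res.sigma_response_index]) == pytest.approx(
        sorted([r_sd1, r_sd2]), abs=0.08)
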