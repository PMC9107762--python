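import numpy as np
import pandas as pd
import pytest

from sca3prog import (
    CohortConfig,
    FitError,
    ModelTruth,
    NonNestedError,
    blup_random_effects,
    default_truth,
    fit_lmm,
    generate_cohort,
    information_criteria,
    lrt,
)
from sca3prog.design import build_design, registry_spec
from sca3prog.published import PUBLISHED_COLUMNS

from conftest import noiseless_config


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "loglik,k,aic",
        [(-2003.735, 6, 4019.470),   # single-slope linear model column
         (-1962.952, 10, 3945.904),  # base piece-wise column
         (-1950.225, 14, 3928.450)], # best-fitting piece-wise column
    )
    def test_published_aic_values(self, loglik, k, aic):
        got_aic, _ = information_criteria(loglik, k, 634)
        assert got_aic == pytest.approx(aic, abs=1e-3)

    def test_degenerate(self):
        assert information_criteria(0.0, 0, 1) == (0.0, 0.0)


class TestFit:
    def test_noiseless_equals_ols(self):
        """With no random effects and vanishing noise, ML = OLS exactly."""
        cohort = generate_cohort(noiseless_config("LM1", seed=1))
        d = build_design(cohort, registry_spec("LM1"))
        fit = fit_lmm(d)
        ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    def test_aic_bic_identities(self, pm1_fit):
        aic, bic = information_criteria(pm1_fit.loglik, pm1_fit.k,
                                        pm1_fit.n_obs)
        assert pm1_fit.aic == pytest.approx(aic, abs=1e-9)
        assert pm1_fit.bic == pytest.approx(bic, abs=1e-9)
        assert pm1_fit.k == 10

    def test_r2_ordering(self, pm1_fit):
        assert 0.0 <= pm1_fit.r2_marginal <= pm1_fit.r2_conditional <= 1.0

    def test_sigma_psd_and_sigma2_positive(self, pm1_fit):
        assert pm1_fit.sigma2 > 0
        np.testing.assert_allclose(pm1_fit.Sigma, pm1_fit.Sigma.T)
        assert np.linalg.eigvalsh(pm1_fit.Sigma).min() >= -1e-10

    def test_loglik_invariant_to_relabeling_and_row_order(self, small_cohort):
        d = build_design(small_cohort, registry_spec("PM1", 13.0))
        base = fit_lmm(d).loglik
        rng = np.random.default_rng(0)
        shuffled = small_cohort.sample(frac=1.0, random_state=1)
        relabel = {s: f"X{i}" for i, s in
                   enumerate(shuffled.subject_id.unique())}
        shuffled = shuffled.assign(subject_id=shuffled.subject_id.map(relabel))
        other = fit_lmm(build_design(shuffled, registry_spec("PM1", 13.0)))
        assert other.loglik == pytest.approx(base, abs=1e-6)

    def test_rank_deficient_named(self, small_cohort):
        cohort = small_cohort.assign(cag_exp=67)  # constant -> collinear
        with pytest.raises(FitError, match="CAGexp"):
            fit_lmm(build_design(cohort, registry_spec("LM2")))

    def test_monotone_nesting(self, small_cohort):
        """Larger nested models never fit worse at ML."""
        ll = {}
        for name in ("LM1", "LM2", "LM4", "PM1", "PM2c", "PM4c"):
            spec = registry_spec(name, 13.0)
            ll[name] = fit_lmm(build_design(small_cohort, spec)).loglik
        assert ll["LM1"] <= ll["LM2"] + 1e-6
        assert ll["LM2"] <= ll["LM4"] + 1e-6
        assert ll["PM1"] <= ll["PM2c"] + 1e-6
        assert ll["PM2c"] <= ll["PM4c"] + 1e-6


class TestNakagawaR2:
    def test_known_variance_partition(self):
        """sigma2_f : sigma2_r : sigma2 = 1 : 1 : 2 gives R2 = (0.25, 0.50)."""
        rng = np.random.default_rng(42)
        m, v = 2000, 4
        dt = np.tile(np.arange(v, dtype=float), m)
        subj = np.repeat([f"S{i}" for i in range(m)], v)
        slope = 1.0 / np.std(np.arange(v))        # var of fixed part = 1
        b0 = rng.normal(0.0, 1.0, m)              # z'Sigma z = 1 for all rows
        y = slope * dt + np.repeat(b0, v) + rng.normal(0, np.sqrt(2), m * v)
        cohort = pd.DataFrame({
            "subject_id": subj, "duration": dt + 1.0, "icars": y,
            "cag_exp": 67, "aoga": 40.0, "gender": "male",
        })
        # shift dt back so the fixed variance stays exactly 1
        cohort["duration"] = dt
        fit = fit_lmm(build_design(cohort, registry_spec("LM1")))
        assert fit.r2_marginal == pytest.approx(0.25, abs=0.02)
        assert fit.r2_conditional == pytest.approx(0.50, abs=0.02)

    def test_zero_random_covariance_collapses(self):
        cohort = generate_cohort(noiseless_config("LM1", seed=3,
                                                  resid_sd=2.0))
        fit = fit_lmm(build_design(cohort, registry_spec("LM1")))
        # generating Sigma = 0: marginal and conditional nearly coincide
        assert fit.r2_conditional - fit.r2_marginal < 0.05


class TestLRT:
    def _stub_pair(self, small_cohort, ll_null, ll_full):
        null = fit_lmm(build_design(small_cohort, registry_spec("LM1")))
        full = fit_lmm(build_design(small_cohort, registry_spec("PM1", 13.0)))
        null.loglik, full.loglik = ll_null, ll_full
        return null, full

    def test_published_logliks_reject_single_slope(self, small_cohort):
        """2(ll_PM1 - ll_LM1) = 81.566 on 4 df is overwhelming evidence."""
        null, full = self._stub_pair(small_cohort, -2003.735, -1962.952)
        res = lrt(null, full)
        assert res.stat == pytest.approx(81.566, abs=1e-3)
        assert res.df == 4
        assert res.p < 0.001

    def test_identical_fits(self, pm1_fit, small_cohort):
        null, full = self._stub_pair(small_cohort, -1000.0, -1000.0)
        res = lrt(null, full)
        assert res.stat == 0.0 and res.p == 1.0

    def test_non_nested_rejected(self, small_cohort):
        qm1 = fit_lmm(build_design(small_cohort, registry_spec("QM1")))
        pm1 = fit_lmm(build_design(small_cohort, registry_spec("PM1", 13.0)))
        with pytest.raises(NonNestedError):
            lrt(qm1, pm1)

    def test_null_calibration(self):
        """Adding a covariate with zero true effect: the LRT rejects at
        roughly the nominal 5% rate."""
        n_reps, rejections = 150, 0
        for r in range(n_reps):
            cohort = generate_cohort(CohortConfig(n_subjects=25, seed=3000 + r,
                                                  truth=default_truth("LM1")))
            lm1 = fit_lmm(build_design(cohort, registry_spec("LM1")))
            lm2 = fit_lmm(build_design(cohort, registry_spec("LM2")))
            if lrt(lm1, lm2).p < 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert 0.005 <= rate <= 0.12


class TestBlup:
    def test_zero_covariance_gives_zero_blups(self):
        cohort = generate_cohort(noiseless_config("PM1", seed=5, resid_sd=2.0))
        fit = fit_lmm(build_design(cohort, registry_spec("PM1", 13.0)))
        fit.Sigma = np.zeros_like(fit.Sigma)  # at Sigma = 0 shrinkage is total
        b = blup_random_effects(fit)
        np.testing.assert_allclose(b.to_numpy(), 0.0, atol=1e-12)

    def test_blups_match_reference_implementation(self, pm1_cohort, pm1_fit):
        """Empirical-Bayes random effects agree with statsmodels MixedLM."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        d = pm1_fit.design
        ref = MixedLM(d.y, d.X, groups=d.groups, exog_re=d.Z).fit(
            reml=False, method="lbfgs", maxiter=2000, disp=False)
        b = blup_random_effects(pm1_fit)
        b_ref = np.vstack([ref.random_effects[s].to_numpy() for s in b.index])
        assert np.max(np.abs(b.to_numpy() - b_ref)) < 2e-3

    def test_shrinkage_improves_subject_prediction(self, pm1_cohort, pm1_fit):
        """Subject-level predictions beat the population fixed part."""
        d = pm1_fit.design
        b = blup_random_effects(pm1_fit)
        codes = pd.factorize(d.groups)[0]
        fixed = d.X @ pm1_fit.beta
        subj = fixed + np.einsum("nq,nq->n", d.Z, b.to_numpy()[codes])
        rmse_fixed = np.sqrt(np.mean((fixed - d.y) ** 2))
        rmse_subj = np.sqrt(np.mean((subj - d.y) ** 2))
        assert rmse_subj < rmse_fixed


@pytest.mark.parametrize("model_name,n_reps", [
    ("LM2", 30), ("QM1", 30), ("PM2c", 30), ("PM4c", 30),
])
def test_parameter_recovery_published_truths(model_name, n_reps):
    """Fixed effects are recovered without systematic bias when data are
    simulated from the model's own published-column truth (scaled-down
    Monte-Carlo; the full-size experiments live in the acceptance suite)."""
    truth = default_truth(model_name)
    rows = []
    for r in range(n_reps):
        cohort = generate_cohort(CohortConfig(seed=4000 + r, truth=truth))
        spec = registry_spec(model_name, truth.knot)
        rows.append(fit_lmm(build_design(cohort, spec)).beta_dict())
    est = pd.DataFrame(rows)
    for term, true_val in truth.beta.items():
        mc_se = est[term].std(ddof=1) / np.sqrt(n_reps)
        assert est[term].mean() == pytest.approx(true_val, abs=4 * mc_se), term


def test_wald_interval_coverage():
    """Pooled coverage of beta +/- 1.96 SE across replicates is near nominal
    (scaled-down check; ML SEs ignore variance-parameter uncertainty, so mild
    undercoverage is tolerated)."""
    truth = default_truth("PM1")
    spec = registry_spec("PM1", 13.0)
    hits, total = 0, 0
    for r in range(40):
        cohort = generate_cohort(CohortConfig(seed=6000 + r, truth=truth))
        fit = fit_lmm(build_design(cohort, spec))
        for term, true_val in truth.beta.items():
            i = fit.fixed_names.index(term)
            hits += abs(fit.beta[i] - true_val) <= 1.96 * fit.se[i]
            total += 1
    assert 0.85 <= hits / total <= 1.0


@pytest.mark.parametrize("model_name,beta", [
    ("PM5", {"intercept": 30.0, "d1": 2.4, "d2": 3.5, "gender": 2.0,
             "d1*gender": 0.4, "d2*gender": -0.3}),
    ("PM6c", {"intercept": -60.0, "d1": -7.5, "d2": -6.5, "CAGexp": 1.4,
              "dt*CAGexp": 0.15, "RAO": 0.5, "dt*RAO": -0.03}),
])
def test_parameter_recovery_gender_and_rao_models(model_name, beta):
    """The gender and residual-onset-age model structures also recover their
    generating coefficients (no published columns exist for these; plausible
    synthetic truths are used)."""
    truth = ModelTruth(model_name=model_name, knot=13.0, beta=beta,
                       re_cov=np.diag([144.0, 1.0, 1.0]), resid_sd=3.0)
    n_reps, rows = 25, []
    for r in range(n_reps):
        cohort = generate_cohort(CohortConfig(seed=5000 + r, truth=truth))
        spec = registry_spec(model_name, 13.0)
        rows.append(fit_lmm(build_design(cohort, spec)).beta_dict())
    est = pd.DataFrame(rows)
    for term, true_val in beta.items():
        mc_se = est[term].std(ddof=1) / np.sqrt(n_reps)
        assert est[term].mean() == pytest.approx(true_val, abs=4 * mc_se), term
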