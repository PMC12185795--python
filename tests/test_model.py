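"""Poisson RR model: design, IRLS fit, sandwich variance, log-posterior, oracle."""

import math

import numpy as np
import pytest

import bayesrr as br
from bayesrr.cohort import TwoByTwoTable
from bayesrr.errors import DegenerateDesignError, OracleInapplicableError
from bayesrr.model import Design, adjusted_spec, unadjusted_spec
from bayesrr.priors import PriorSpec

from conftest import SEED, random_cohort


class TestBuildDesign:
    def test_unadjusted_structure(self, rng):
        cohort = random_cohort(rng, n=4)
        design = br.build_design(cohort, unadjusted_spec())
        assert design.X.shape == (4, 2)
        assert design.names == ["intercept", "nonagenarian"]
        assert set(design.X[:, 1]) == {0.0, 1.0}

    def test_categorical_reference_is_most_frequent(self, rng):
        cohort = random_cohort(rng, n=60)
        spec = adjusted_spec(("admission_dx",))
        design = br.build_design(cohort, spec)
        dx_cols = [n for n in design.names if n.startswith("admission_dx[")]
        levels = cohort.df["admission_dx"].value_counts()
        assert len(dx_cols) == len(levels) - 1
        assert f"admission_dx[{levels.index[0]}]" not in dx_cols

    def test_column_count_formula(self, rng):
        cohort = random_cohort(rng, n=100)
        spec = adjusted_spec()
        design = br.build_design(cohort, spec)
        n_levels_dx = cohort.df["admission_dx"].nunique()
        # 2 (intercept+exposure) + 2 continuous + 5 binary + (sex-1) + (dx-1)
        assert design.X.shape[1] == 2 + 2 + 5 + 1 + (n_levels_dx - 1)

    def test_missing_covariates_dropped_and_counted(self, rng):
        cohort = random_cohort(rng, n=30)
        df = cohort.df.copy()
        df.loc[:2, "sofa"] = None
        from bayesrr.cohort import SCHEMA, cohort_from_frame

        cohort = cohort_from_frame(df[list(SCHEMA)])
        design = br.build_design(cohort, adjusted_spec(("sofa",)))
        assert design.n_dropped_missing == 3
        assert design.X.shape[0] == 27

    def test_constant_exposure_rejected(self, rng):
        cohort = random_cohort(rng)
        from bayesrr.cohort import SCHEMA, cohort_from_frame

        octo = cohort.df[cohort.df["age_group"] == "octogenarian"]
        sub = cohort_from_frame(octo[list(SCHEMA)])
        with pytest.raises(DegenerateDesignError):
            br.build_design(sub, unadjusted_spec())


class TestPoissonMle:
    def test_two_group_closed_form(self, fixture_table):
        design = br.design_from_two_by_two(fixture_table)
        fit = br.poisson_mle(design)
        b1 = math.log((365 / 807) / (3219 / 7601))
        assert fit.beta[1] == pytest.approx(b1, abs=1e-8)
        assert fit.beta[0] == pytest.approx(math.log(3219 / 7601), abs=1e-8)
        assert fit.se_model()[1] == pytest.approx(math.sqrt(1 / 365 + 1 / 3219), rel=1e-6)

    def test_intercept_only_closed_form(self):
        design = Design(
            X=np.ones((2, 1)),
            y=np.array([1.0, 0.0]),
            names=["intercept"],
            weights=np.array([30.0, 70.0]),
        )
        fit = br.poisson_mle(design)
        assert fit.beta[0] == pytest.approx(math.log(0.3), abs=1e-8)

    def test_matches_statsmodels_glm(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        cohort = random_cohort(rng, n=200)
        design = br.build_design(cohort, adjusted_spec(("sex", "sofa", "mech_vent")))
        fit = br.poisson_mle(design)
        ref = sm.GLM(design.y, design.X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-7)
        np.testing.assert_allclose(fit.se_model(), ref.bse, rtol=1e-5)

    def test_aggregation_equivalence(self, fixture_table):
        # the Poisson likelihood depends only on the group sufficient statistics
        agg = br.design_from_two_by_two(fixture_table)
        expanded = br.build_design(br.expand_two_by_two(fixture_table), unadjusted_spec())
        beta = np.array([-0.9, 0.1])
        from bayesrr.model import poisson_loglik

        assert poisson_loglik(beta, agg) == pytest.approx(
            poisson_loglik(beta, expanded), rel=1e-12
        )
        fit_a = br.poisson_mle(agg)
        fit_e = br.poisson_mle(expanded)
        np.testing.assert_allclose(fit_a.beta, fit_e.beta, atol=1e-9)


class TestSandwichCov:
    def test_two_group_closed_form(self, fixture_table):
        design = br.design_from_two_by_two(fixture_table)
        fit = br.poisson_mle(design)
        expected = math.sqrt(1 / 365 - 1 / 807 + 1 / 3219 - 1 / 7601)
        assert fit.se_robust()[1] == pytest.approx(expected, rel=1e-6)

    def test_robust_below_model_based_for_binary_outcome(self, fixture_table):
        fit = br.poisson_mle(br.design_from_two_by_two(fixture_table))
        assert fit.se_robust()[1] < fit.se_model()[1]

    def test_matches_statsmodels_hc0(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        cohort = random_cohort(rng, n=200)
        design = br.build_design(cohort, adjusted_spec(("sofa", "rrt")))
        fit = br.poisson_mle(design)
        ref = sm.GLM(design.y, design.X, family=sm.families.Poisson()).fit(cov_type="HC0")
        np.testing.assert_allclose(fit.se_robust(), ref.bse, rtol=1e-5)

    def test_zero_residual_meat_vanishes(self):
        # saturated fit: mu equals y exactly, so B = sum (y-mu)^2 xx' = 0
        design = Design(
            X=np.ones((1, 1)),
            y=np.array([1.0]),
            names=["intercept"],
            weights=np.array([5.0]),
        )
        fit = br.poisson_mle(design)
        assert br.sandwich_cov(fit, design)[0, 0] == pytest.approx(0.0, abs=1e-12)


class TestLogPosterior:
    def test_additivity_in_exposure_coefficient(self, fixture_table):
        design = br.design_from_two_by_two(fixture_table)
        prior = br.standard_priors()["non_informative"]
        from bayesrr.model import poisson_loglik
        from scipy.stats import norm

        b_a = np.array([-0.9, 0.05])
        b_b = np.array([-0.9, 0.15])
        got = br.log_posterior(b_b, design, prior) - br.log_posterior(b_a, design, prior)
        want = (
            poisson_loglik(b_b, design)
            - poisson_loglik(b_a, design)
            + norm.logpdf(0.15, 0, 10)
            - norm.logpdf(0.05, 0, 10)
        )
        assert got == pytest.approx(want, rel=1e-10)

    def test_term_by_term_hand_sum(self):
        design = Design(
            X=np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 0.0]]),
            y=np.array([1.0, 0.0, 1.0]),
            names=["intercept", "nonagenarian"],
            weights=np.ones(3),
        )
        prior = PriorSpec("custom", 0.1, 0.5)
        beta = np.array([-0.3, 0.2])
        from scipy.stats import norm

        by_hand = sum(
            y * (beta @ x) - math.exp(beta @ x)
            for x, y in zip(design.X, design.y)
        )
        by_hand += norm.logpdf(beta[1], 0.1, 0.5) + norm.logpdf(beta[0], 0, 10)
        assert br.log_posterior(beta, design, prior) == pytest.approx(by_hand, rel=1e-12)

    def test_mle_maximises_flat_prior_posterior_on_grid(self, fixture_table):
        design = br.design_from_two_by_two(fixture_table)
        prior = br.standard_priors()["non_informative"]
        fit = br.poisson_mle(design)
        at_mle = br.log_posterior(fit.beta, design, prior)
        grid = np.linspace(-0.3, 0.3, 31)
        for db0 in grid[::6]:
            for db1 in grid:
                cand = fit.beta + np.array([db0, db1])
                # prior curvature is ~1/200 of likelihood curvature here
                assert br.log_posterior(cand, design, prior) <= at_mle + 1e-4

    def test_overflow_returns_neg_inf(self, fixture_table):
        design = br.design_from_two_by_two(fixture_table)
        prior = br.standard_priors()["non_informative"]
        assert br.log_posterior(np.array([800.0, 0.0]), design, prior) == -math.inf
        assert br.log_posterior(np.array([math.nan, 0.0]), design, prior) == -math.inf


class TestConjugateOracle:
    def test_non_informative_matches_likelihood(self, fixture_table):
        post = br.conjugate_two_group_posterior(
            fixture_table, br.standard_priors()["non_informative"]
        )
        assert post.mean_log_rr == pytest.approx(0.0658, abs=5e-4)
        assert post.sd_log_rr == pytest.approx(0.0552, abs=5e-4)
        assert post.p_rr_greater(1.0) == pytest.approx(0.883, abs=2e-3)

    def test_skeptical_precision_weighting(self, fixture_table):
        post = br.conjugate_two_group_posterior(
            fixture_table, br.standard_priors()["skeptical"]
        )
        assert post.mean_log_rr == pytest.approx(0.0345, abs=5e-4)
        assert post.sd_log_rr == pytest.approx(0.0400, abs=5e-4)

    def test_infinite_precision_prior_dominates(self, fixture_table):
        prior = PriorSpec("custom", 0.3, 1e-6)
        post = br.conjugate_two_group_posterior(fixture_table, prior)
        assert post.mean_log_rr == pytest.approx(0.3, abs=1e-4)

    def test_zero_deaths_inapplicable(self):
        prior = br.standard_priors()["skeptical"]
        with pytest.raises(OracleInapplicableError):
            br.conjugate_two_group_posterior(TwoByTwoTable(0, 10, 5, 10), prior)

    def test_crude_rr_identity_on_random_cohorts(self, rng):
        # exposure MLE in the unadjusted model == ln crude RR, any cohort
        for _ in range(5):
            cohort = random_cohort(rng, n=120)
            table = br.aggregate_two_by_two(cohort)
            if table.d1 == 0 or table.d0 == 0:
                continue
            fit = br.poisson_mle(br.design_from_two_by_two(table))
            crude = math.log((table.d1 / table.n1) / (table.d0 / table.n0))
            assert fit.beta[1] == pytest.approx(crude, abs=1e-8)
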