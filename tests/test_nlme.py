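"""Mixed-effects machinery: elementary transforms, diagnostics, the joint
objective against an independent Gaussian-density oracle, MAP limits, and
the Laplace objective against the closed-form marginal likelihood of a
linear-Gaussian toy model."""

import math

import numpy as np
import pytest
from scipy import stats

from maintpkpd import nlme
from maintpkpd.params import PopulationParameters, ResidualErrorSpec


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

class TestIndividualParams:
    def test_zero_eta_is_identity(self):
        theta = {"keff_6mp": 0.041, "kmm_6mp": 0.016}
        assert nlme.individual_params_from_eta(theta, {}) == theta

    def test_lognormal_scaling(self):
        out = nlme.individual_params_from_eta(
            {"keff_6mp": 0.041}, {"keff_6mp": math.log(2.0)}
        )
        assert out["keff_6mp"] == pytest.approx(0.082)

    def test_no_iiv_parameter_passes_through(self):
        out = nlme.individual_params_from_eta(
            {"kmm_6mp": 0.016, "vmm_6mp": 0.096}, {"vmm_6mp": 0.5}
        )
        assert out["kmm_6mp"] == 0.016


class TestCvShrinkagePvalue:
    @pytest.mark.parametrize(
        "omega2, cv",
        [(0.0, 0.0), (math.log(1 + 0.34 ** 2), 34.0), (1.0, 131.083)],
    )
    def test_cv_from_omega(self, omega2, cv):
        assert nlme.cv_from_omega(omega2) == pytest.approx(cv, abs=0.05)

    def test_cv_confidence_interval_maps_through(self):
        cv, ci = nlme.cv_from_omega(0.1, ci=(0.05, 0.2))
        assert ci[0] < cv < ci[1]

    def test_shrinkage_limits(self):
        omega2 = 0.25
        spread = np.array([-0.5, 0.5]) / math.sqrt(2.0)  # SD(ddof=1) = omega
        assert nlme.eta_shrinkage(spread, omega2) == pytest.approx(0.0, abs=1e-9)
        assert nlme.eta_shrinkage([0.0, 0.0, 0.0], omega2) == pytest.approx(100.0)
        assert nlme.eta_shrinkage(0.7 * spread, omega2) == pytest.approx(30.0)

    def test_shrinkage_rejects_zero_omega(self):
        with pytest.raises(ValueError):
            nlme.eta_shrinkage([0.1, 0.2], 0.0)

    def test_ttest_symmetric_sample_and_textbook_value(self):
        assert nlme.eta_ttest([-0.3, 0.3]) == pytest.approx(1.0)
        # t = 2*sqrt(3), df=2
        assert nlme.eta_ttest([1.0, 2.0, 3.0]) == pytest.approx(0.07418, abs=1e-4)

    def test_ttest_null_calibration(self, rng):
        pvals = [nlme.eta_ttest(rng.normal(0, 1, 40)) for _ in range(300)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPredictionErrors:
    def test_perfect_predictions_give_zero(self):
        m = nlme.prediction_errors(
            ["a"], {"ANC": np.zeros(3, int)},
            {"ANC": np.array([1.0, 2.0, 3.0])}, {"ANC": np.array([1.0, 2.0, 3.0])},
        )
        assert (m.per_patient[["rmse", "mae"]].to_numpy() == 0).all()

    def test_hand_computed_values(self):
        m = nlme.prediction_errors(
            ["a"], {"ANC": np.zeros(2, int)},
            {"ANC": np.array([0.0, 2.0])}, {"ANC": np.array([1.0, 1.0])},
        )
        row = m.per_patient.iloc[0]
        assert row.rmse == pytest.approx(1.0)
        assert row.mae == pytest.approx(1.0)

    def test_rmse_dominates_mae(self, rng):
        for _ in range(100):
            n = rng.integers(2, 20)
            m = nlme.prediction_errors(
                ["a"], {"ANC": np.zeros(n, int)},
                {"ANC": rng.normal(2, 1, n)}, {"ANC": rng.normal(2, 1, n)},
            )
            row = m.per_patient.iloc[0]
            assert row.rmse >= row.mae >= 0


# ---------------------------------------------------------------------------
# linear-Gaussian toy problem
# ---------------------------------------------------------------------------

class LinearToy(nlme.NLMEProblem):
    """f_ij = a_j + b_j * eta_i with additive error; Laplace is exact."""

    def __init__(self, a, b, y):
        self.a = np.asarray(a, dtype=float)
        self.b = np.asarray(b, dtype=float)
        self.y_mat = np.asarray(y, dtype=float)  # (n, m)
        self.n, self.m = self.y_mat.shape
        self.iiv_names = ("toy",)
        self.channels = ("Y",)
        self.obs_pat = {"Y": np.repeat(np.arange(self.n), self.m)}
        self.obs_y = {"Y": self.y_mat.ravel()}

    def predict(self, theta, eta):
        f = self.a[None, :] + self.b[None, :] * eta[:, [0]]
        return {"Y": f.ravel()}


def _toy_setup(rng, n=7, m=5, sigma2=0.3, omega2=0.7):
    a = rng.normal(1.0, 1.0, m)
    b = rng.normal(0.5, 0.3, m)
    eta = rng.normal(0, math.sqrt(omega2), n)
    y = a[None, :] + b[None, :] * eta[:, None] + rng.normal(0, math.sqrt(sigma2), (n, m))
    problem = LinearToy(a, b, y)
    sigma = {"Y": ResidualErrorSpec("additive", add_var=sigma2)}
    return problem, sigma, omega2


def _toy_closed_form_neg2ll(problem, sigma2, omega2):
    cov = sigma2 * np.eye(problem.m) + omega2 * np.outer(problem.b, problem.b)
    total = 0.0
    for i in range(problem.n):
        r = problem.y_mat[i] - problem.a
        total += -2.0 * stats.multivariate_normal.logpdf(r, cov=cov)
    return total


class TestLaplace:
    def test_matches_closed_form_marginal_likelihood(self, rng):
        problem, sigma, omega2 = _toy_setup(rng)
        closed = _toy_closed_form_neg2ll(problem, 0.3, omega2)
        laplace = nlme.laplace_neg2ll(problem, {}, np.array([omega2]), sigma)
        assert laplace == pytest.approx(closed, abs=1e-8)

    def test_joint_neg2ll_against_gaussian_density_oracle(self, rng):
        for _ in range(20):
            problem, sigma, omega2 = _toy_setup(rng, n=3, m=4)
            eta = rng.normal(0, 1, (3, 1))
            ours = nlme.individual_joint_neg2ll(
                problem, {}, eta, np.array([omega2]), sigma
            )
            f = problem.predict({}, eta)["Y"].reshape(3, 4)
            for i in range(3):
                expected = -2.0 * (
                    stats.norm.logpdf(problem.y_mat[i], f[i], math.sqrt(0.3)).sum()
                    + stats.norm.logpdf(eta[i, 0], 0.0, math.sqrt(omega2))
                )
                assert ours[i] == pytest.approx(expected, abs=1e-10)


class TestMapEstimate:
    def test_prior_mode_without_observations(self):
        problem = LinearToy(np.zeros(0), np.zeros(0), np.zeros((3, 0)))
        sigma = {"Y": ResidualErrorSpec("additive", add_var=1.0)}
        eta, conv = nlme.map_estimate(problem, {}, np.array([0.5]), sigma)
        assert np.allclose(eta, 0.0)

    def test_likelihood_dominated_limit_recovers_truth(self, rng):
        a = np.zeros(30)
        b = np.ones(30)
        eta_star = 0.8
        y = (a + b * eta_star)[None, :].repeat(2, axis=0)
        problem = LinearToy(a, b, y)
        sigma = {"Y": ResidualErrorSpec("additive", add_var=1e-6)}
        eta, _ = nlme.map_estimate(problem, {}, np.array([1e4]), sigma)
        assert np.allclose(eta, eta_star, atol=1e-3)

    def test_prior_dominated_limit_shrinks_to_zero(self, rng):
        problem, sigma, _ = _toy_setup(rng)
        eta, _ = nlme.map_estimate(problem, {}, np.array([1e-8]), sigma)
        assert np.max(np.abs(eta)) < 1e-4


class TestPopulationFitToy:
    def test_monotone_trace_and_variance_recovery(self, rng):
        problem, sigma, omega2 = _toy_setup(rng, n=60, m=8)
        start = PopulationParameters(
            {"toy": 1.0}, {"toy": 0.2},
            {"Y": ResidualErrorSpec("additive", add_var=1.0)},
        )
        fit = nlme.population_fit(problem, start, estimate=(), max_iter=30)
        tr = fit.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(tr, tr[1:]))
        assert fit.params.omega2["toy"] == pytest.approx(omega2, rel=0.5)
        assert fit.params.sigma["Y"].add_var == pytest.approx(0.3, rel=0.3)
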