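"""Generator matrix, transition probabilities, likelihood and design
encoding of the three-state Gompertz model, checked against scipy's matrix
exponential and the analytic illness-death solution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.linalg import expm

from conftest import closed_form_P
from cogspan.markov import (GompertzMultistateModel, TransitionParams,
                            build_design, design_columns, intensity_matrix,
                            log_likelihood, prepare_panel,
                            transition_probability, PanelDataError)


def constant_params(q12=0.1, q13=0.1, q21=0.1, q23=0.1):
    return TransitionParams(alpha=np.log([q12, q13, q21, q23]),
                            xi=np.zeros(4), beta=np.zeros((4, 0)))


class TestIntensityMatrix:
    def test_constant_parameter_identity(self):
        Q = intensity_matrix(80.0, None, constant_params())
        expected = np.array([[-0.2, 0.1, 0.1], [0.1, -0.2, 0.1], [0, 0, 0]])
        np.testing.assert_allclose(Q, expected, atol=1e-14)

    def test_gompertz_age_scaling(self):
        params = TransitionParams(
            alpha=[np.log(0.05), np.log(0.1), np.log(0.1), np.log(0.1)],
            xi=[0.07, 0, 0, 0], beta=np.zeros((4, 0)))
        Q = intensity_matrix(75.0, None, params)
        assert Q[0, 1] == pytest.approx(0.05 * np.exp(0.7), rel=1e-12)

    @given(st.floats(0.001, 0.5), st.floats(0.001, 0.5),
           st.floats(0.001, 0.5), st.floats(0.001, 0.5),
           st.floats(-0.1, 0.15), st.floats(65, 105))
    @settings(max_examples=50, deadline=None)
    def test_generator_properties(self, q12, q13, q21, q23, xi, age):
        params = TransitionParams(alpha=np.log([q12, q13, q21, q23]),
                                  xi=np.full(4, xi), beta=np.zeros((4, 0)))
        Q = intensity_matrix(age, None, params)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(Q[2], 0.0)
        assert (Q[np.triu_indices(3, 1)] >= 0).all()

    def test_dimension_error(self):
        with pytest.raises(ValueError, match="length"):
            intensity_matrix(70, np.ones(3), constant_params())


class TestTransitionProbability:
    def test_identity_at_zero_length(self):
        P = transition_probability(constant_params(), None, 70, 70)
        np.testing.assert_allclose(P, np.eye(3), atol=1e-14)

    def test_matches_scipy_expm_homogeneous(self):
        params = constant_params(0.08, 0.05, 0.2, 0.15)
        Q = intensity_matrix(0, None, params)
        for t in (0.5, 2.0, 10.0):
            P = transition_probability(params, None, 70, 70 + t)
            np.testing.assert_allclose(P, expm(Q * t), atol=1e-12)

    def test_matches_scipy_expm_product_gompertz(self):
        params = TransitionParams(
            alpha=np.log([0.012, 0.018, 0.25, 0.045]),
            xi=[0.08, 0.085, -0.02, 0.08], beta=np.zeros((4, 0)))
        step = 0.5
        a1, a2 = 65.0, 85.0
        m = int(np.ceil((a2 - a1) / step))
        dt = (a2 - a1) / m
        P_oracle = np.eye(3)
        for k in range(m):
            Q = intensity_matrix(a1 + (k + 0.5) * dt, None, params)
            P_oracle = P_oracle @ expm(Q * dt)
        P = transition_probability(params, None, a1, a2, step=step)
        np.testing.assert_allclose(P, P_oracle, atol=1e-12)

    def test_closed_form_no_recovery(self):
        """Homogeneous illness-death model without recovery has an analytic
        solution; the kernel must reproduce it essentially exactly."""
        q12, q13, q23 = 0.08, 0.04, 0.15
        params = constant_params(q12, q13, 1e-300, q23)
        params.alpha[2] = -690.0  # recovery intensity ~ 0
        for t in np.linspace(0.25, 20, 12):
            P = transition_probability(params, None, 65, 65 + t, step=1.0)
            np.testing.assert_allclose(P, closed_form_P(q12, q13, q23, t),
                                       atol=1e-10)

    @given(st.floats(0.01, 0.4), st.floats(0.01, 0.4), st.floats(0.01, 0.4),
           st.floats(0.01, 0.4), st.floats(0, 8))
    @settings(max_examples=40, deadline=None)
    def test_stochastic_matrix_property(self, q12, q13, q21, q23, t):
        P = transition_probability(constant_params(q12, q13, q21, q23),
                                   None, 70, 70 + t)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert (P >= 0).all()

    def test_death_column_monotone(self, truth):
        z = np.zeros(truth.n_covariates)
        deaths = [transition_probability(truth, z, 65, 65 + t)[0, 2]
                  for t in np.linspace(0, 30, 31)]
        assert np.all(np.diff(deaths) >= -1e-12)

    def test_chapman_kolmogorov(self, truth):
        z = np.zeros(truth.n_covariates)
        # matched grids: both factors and the direct product use step 0.5
        P13 = transition_probability(truth, z, 65, 81, step=0.5)
        P12 = transition_probability(truth, z, 65, 73, step=0.5)
        P23 = transition_probability(truth, z, 73, 81, step=0.5)
        np.testing.assert_allclose(P13, P12 @ P23, atol=1e-8)

    @pytest.mark.parametrize("xi", [-0.15, -0.05, 0.05, 0.15])
    def test_grid_convergence_on_halving(self, xi):
        # steepest slopes at the intensity magnitudes this model runs at
        # (midpoint error grows with q * xi^2, so the bound is tied to
        # epidemiologically plausible rates)
        params = TransitionParams(
            alpha=np.log([0.02, 0.025, 0.03, 0.03]),
            xi=np.full(4, xi), beta=np.zeros((4, 0)))
        P1 = transition_probability(params, None, 65, 67, step=1.0)
        P2 = transition_probability(params, None, 65, 67, step=0.5)
        assert np.abs(P1 - P2).max() < 1e-4

    def test_grid_convergence_default_truth(self, truth):
        z = np.zeros(truth.n_covariates)
        P1 = transition_probability(truth, z, 70, 72, step=1.0)
        P2 = transition_probability(truth, z, 70, 72, step=0.5)
        assert np.abs(P1 - P2).max() < 1e-4

    def test_argument_errors(self):
        with pytest.raises(ValueError, match="step"):
            transition_probability(constant_params(), None, 65, 70, step=0)
        with pytest.raises(ValueError, match="a2"):
            transition_probability(constant_params(), None, 70, 65)


class TestLogLikelihood:
    def test_empty_dataset_is_zero(self):
        empty = pd.DataFrame(columns=["subject_id", "age", "state"])
        assert log_likelihood(empty, constant_params()) == 0.0

    def test_two_observation_subject_equals_log_P_entry(self):
        q12, q13, q23 = 0.06, 0.05, 0.12
        params = constant_params(q12, q13, 1e-300, q23)
        params.alpha[2] = -690.0
        panel = pd.DataFrame({"subject_id": ["a", "a"], "age": [65.0, 67.0],
                              "state": ["CH", "CH"]})
        expected = np.log(closed_form_P(q12, q13, q23, 2.0)[0, 0])
        assert log_likelihood(panel, params) == pytest.approx(expected,
                                                              abs=1e-10)

    def test_exact_death_contribution_against_quadrature(self):
        """An exactly observed death contributes the sub-density
        f(t) = P11(t) q13 + P12(t) q23; the same function must integrate to
        the cumulative death probability."""
        q12, q13, q23 = 0.06, 0.05, 0.12
        params = constant_params(q12, q13, 1e-300, q23)
        params.alpha[2] = -690.0
        panel = pd.DataFrame({"subject_id": ["a", "a"], "age": [65.0, 66.0],
                              "state": ["CH", "DEAD"]})
        Pc = closed_form_P(q12, q13, q23, 1.0)
        expected = np.log(Pc[0, 0] * q13 + Pc[0, 1] * q23)
        assert log_likelihood(panel, params) == pytest.approx(expected,
                                                              abs=1e-10)
        density = lambda t: (closed_form_P(q12, q13, q23, t)[0, 0] * q13 +
                             closed_form_P(q12, q13, q23, t)[0, 1] * q23)
        integral, _ = quad(density, 0, 5)
        assert integral == pytest.approx(closed_form_P(q12, q13, q23, 5)[0, 2],
                                         abs=1e-8)

    def test_analytic_gradient_matches_finite_differences(self):
        from scipy.optimize import approx_fprime
        from cogspan._kernels import panel_loglik, panel_loglik_grad
        rng = np.random.default_rng(3)
        p = 2
        n = 40
        a1 = rng.uniform(65, 95, n)
        a2 = a1 + rng.uniform(0.5, 4, n)
        sf = rng.integers(1, 3, n).astype(np.int64)
        st_ = np.where(rng.random(n) < 0.3, 3,
                       rng.integers(1, 3, n)).astype(np.int64)
        Z = rng.normal(0, 1, (n, p))
        theta = np.concatenate([np.log([0.02, 0.03, 0.2, 0.05]),
                                [0.08, 0.09, -0.02, 0.07],
                                rng.normal(0, 0.3, 4 * p)])
        ll, g = panel_loglik_grad(theta, p, a1, a2, sf, st_, Z, 1.0, 65.0)
        assert ll == pytest.approx(
            panel_loglik(theta, p, a1, a2, sf, st_, Z, 1.0, 65.0), abs=1e-10)
        fd = approx_fprime(
            theta, lambda th: panel_loglik(th, p, a1, a2, sf, st_, Z, 1.0,
                                           65.0), 1e-7)
        np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-5)


class TestPanelValidation:
    def test_ordering_violation_names_subject(self):
        panel = pd.DataFrame({"subject_id": ["x", "x"], "age": [70.0, 70.0],
                              "state": ["CH", "CI"]})
        with pytest.raises(PanelDataError, match="x"):
            prepare_panel(panel)

    def test_death_must_be_last_and_unique(self):
        panel = pd.DataFrame({"subject_id": ["x"] * 3,
                              "age": [70.0, 71.0, 72.0],
                              "state": ["CH", "DEAD", "CH"]})
        with pytest.raises(PanelDataError, match="DEAD"):
            prepare_panel(panel)

    def test_drop_counts(self):
        panel = pd.DataFrame({
            "subject_id": ["a", "a", "solo", "gone"],
            "age": [70.0, 72.0, 70.0, 70.0],
            "state": ["CH", "CI", "CH", "DEAD"]})
        clean, excl = prepare_panel(panel)
        assert excl == {"single_record": 1, "dead_first": 1}
        assert clean["subject_id"].unique().tolist() == ["a"]


class TestDesign:
    def test_reference_profile_is_zero_vector(self):
        z = build_design({"apoe": "e3e3", "lifestyle": "g01", "sex": "woman"},
                         covariates=("apoe", "lifestyle", "sex"))
        assert z.to_numpy().sum() == 0

    def test_interaction_columns_are_products(self):
        cov = ("apoe", "lifestyle")
        inter = (("apoe", "lifestyle"),)
        z = build_design({"apoe": "e4", "lifestyle": "g45"}, cov, inter)
        assert z["apoe_e4"].iloc[0] == 1
        assert z["lifestyle_g45"].iloc[0] == 1
        assert z["apoe_e4:lifestyle_g45"].iloc[0] == 1
        assert z["apoe_e2:lifestyle_g23"].iloc[0] == 0

    def test_sex_interaction(self):
        cov = ("apoe", "lifestyle", "sex")
        inter = (("apoe", "sex"),)
        z = build_design({"apoe": "e2", "lifestyle": "g23", "sex": "man"},
                         cov, inter)
        for col in ("apoe_e2", "lifestyle_g23", "sex_man", "apoe_e2:sex_man"):
            assert z[col].iloc[0] == 1

    def test_unknown_variable_and_level(self):
        with pytest.raises(KeyError, match="unknown design variable"):
            build_design({"apoe": "e4"}, covariates=("apoe", "ghost"))
        with pytest.raises(ValueError, match="unknown level"):
            build_design({"apoe": "e5"}, covariates=("apoe",))

    def test_column_order_is_deterministic(self):
        cols = design_columns(("apoe", "sex"), (("apoe", "sex"),))
        assert cols == ["apoe_e2", "apoe_e4", "sex_man",
                        "apoe_e2:sex_man", "apoe_e4:sex_man"]


class TestHazardRatioArithmetic:
    def _toy_fitted(self, beta, se):
        """Directly constructed fitted state to test the delta-method
        arithmetic in isolation."""
        model = GompertzMultistateModel(covariates=("sex",))
        p = 1
        theta = np.zeros(8 + 4 * p)
        theta[8:] = beta
        model._theta_ = theta
        model.design_columns_ = ("sex_man",)
        cov = np.zeros((12, 12))
        for t in range(4):
            cov[8 + t, 8 + t] = se ** 2
        model.covariance_ = cov
        model.params_ = TransitionParams.from_vector(theta, p)
        return model

    def test_zero_coefficient_gives_unit_hr(self):
        tab = self._toy_fitted(0.0, 0.1).hazard_ratios("sex_man")
        assert (tab["hr"] == 1.0).all()

    def test_published_style_row(self):
        tab = self._toy_fitted(0.239, 0.115).hazard_ratios("sex_man")
        row = tab.loc["CH->CI"]
        assert f"{row.hr:.2f} ({row.lo:.2f} to {row.hi:.2f})" == \
            "1.27 (1.01 to 1.59)"

    def test_unknown_contrast_lists_columns(self):
        with pytest.raises(KeyError, match="sex_man"):
            self._toy_fitted(0.0, 0.1).hazard_ratios("nope")
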