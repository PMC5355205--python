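"""Step-selection estimator: steps, controls, likelihood, fit, classification."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from tallgrass.movement import MovementParams, Trajectory, simulate_trajectory
from tallgrass.ssf import (
    PARAM_NAMES,
    FitResult,
    StepData,
    build_steps,
    classify_strategy,
    extract_covariates,
    fit_step_selection,
    negative_log_likelihood,
    prepare_step_data,
    sample_controls,
)


def _traj(hours, start="2011-06-01 00:00"):
    t0 = pd.Timestamp(start)
    ts = [t0 + pd.Timedelta(hours=h) for h in hours]
    rng = np.random.default_rng(1)
    xy = rng.uniform(100, 500, size=(len(ts), 2))
    return Trajectory("B1", pd.DataFrame({"timestamp": ts, "x": xy[:, 0], "y": xy[:, 1]}))


class TestBuildSteps:
    def test_consecutive_fixes_give_n_minus_one_steps(self):
        steps = build_steps(_traj([0, 4, 8, 12, 16, 20, 24]))
        assert len(steps) == 6

    def test_gaps_break_the_chain(self):
        # two 8-h gaps among 7 fixes leave 4 valid consecutive pairs
        steps = build_steps(_traj([0, 4, 12, 16, 24, 28, 32]))
        assert len(steps) == 4

    def test_all_gaps_too_long_gives_no_steps(self):
        steps = build_steps(_traj([0, 8, 16, 24]))
        assert len(steps) == 0

    def test_empty_trajectory_warns(self):
        traj = Trajectory("B1", pd.DataFrame({"timestamp": [pd.Timestamp("2011-06-01")], "x": [0.0], "y": [0.0]}))
        with pytest.warns(UserWarning):
            steps = build_steps(traj)
        assert len(steps) == 0


class TestSampleControls:
    def test_exactly_n_controls(self, small_stack):
        cs = sample_controls((300, 300), 0, small_stack, n=100, radius=200, seed=3)
        assert cs.n == 100
        assert cs.covariates.shape == (100, 6)

    def test_full_acceptance_when_disk_inside_mask(self, small_stack):
        cs = sample_controls((300, 300), 0, small_stack, n=50, radius=100, seed=3)
        assert cs.acceptance_rate == 1.0
        # effective area is the cell-discretized disk area
        assert cs.effective_area == pytest.approx(np.pi * 100**2, rel=0.02)

    def test_fixed_seed_reproducible(self, small_stack):
        a = sample_controls((300, 300), 0, small_stack, n=40, radius=150, seed=9)
        b = sample_controls((300, 300), 0, small_stack, n=40, radius=150, seed=9)
        assert np.array_equal(a.points, b.points)

    def test_degenerate_mask_rejected(self, small_stack):
        with pytest.raises(RuntimeError, match="acceptance"):
            sample_controls((300, 300), 0, small_stack, n=50, radius=1e6, seed=1,
                            max_attempt_factor=120)


class TestExtractCovariates:
    def test_cell_center_returns_exact_value(self, small_stack):
        x, y = 305.0, 125.0  # cell centers on the 10 m grid
        cov = extract_covariates(np.array([[x, y]]), small_stack, pd.Timestamp("2011-04-05"))
        r, c = small_stack.elevation.index_of(x, y)
        assert cov[0, 0] == small_stack.elevation.data[int(r), int(c)]
        assert cov[0, 3] == small_stack.protein[0].data[int(r), int(c)]

    def test_interaction_is_product_of_parts(self, small_stack):
        cov = extract_covariates(np.array([[305.0, 125.0]]), small_stack, pd.Timestamp("2011-05-10"))
        assert cov[0, 5] == pytest.approx(cov[0, 3] * cov[0, 4], rel=1e-12)

    def test_timestamp_selects_biweekly_layer(self, small_stack):
        early = extract_covariates(np.array([[305.0, 125.0]]), small_stack, pd.Timestamp("2011-04-02"))
        later = extract_covariates(np.array([[305.0, 125.0]]), small_stack, pd.Timestamp("2011-04-20"))
        # protein declines between periods as the burn flush fades
        assert early[0, 3] != later[0, 3]


def _single_step_data(theta_ref=100.0, d_case=100.0, d_ctrl=200.0, radius=300.0):
    return StepData(
        d2_case=np.array([d_case**2]),
        x_case=np.zeros((1, 6)),
        d2_ctrl=np.array([[d_ctrl**2]]),
        x_ctrl=np.zeros((1, 1, 6)),
        log_q=np.full((1, 1), -math.log(math.pi * radius**2)),
        log_accept=np.zeros(1),
        radius=radius,
        seed=0,
        sampler="disk",
    )


class TestNegativeLogLikelihood:
    def test_single_term_hand_arithmetic(self):
        """One step, one control, θ=100 m, β=0: NLL equals the closed form
        −[log φ(100) − log(πR² φ(200))] computed by hand."""
        theta, R = 100.0, 300.0
        data = _single_step_data()

        def phi(d):
            return math.exp(-(d**2) / (2 * theta**2)) / (2 * math.pi * theta**2)

        expected = -(math.log(phi(100.0)) - math.log(math.pi * R**2 * phi(200.0)))
        got = negative_log_likelihood(math.log(theta), np.zeros(6), data)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_covariates_cancel_when_beta_zero(self, rng):
        data = _single_step_data()
        alt = _single_step_data()
        alt.x_case = rng.normal(size=(1, 6))
        alt.x_ctrl = rng.normal(size=(1, 1, 6))
        b0 = np.zeros(6)
        assert negative_log_likelihood(4.0, b0, data) == pytest.approx(
            negative_log_likelihood(4.0, b0, alt), rel=1e-12
        )

    def test_constant_covariate_shift_cancels(self, rng):
        """Adding k to one covariate at cases and controls leaves NLL unchanged."""
        n, m = 20, 15
        data = StepData(
            d2_case=rng.uniform(0, 1e4, n),
            x_case=rng.normal(size=(n, 6)),
            d2_ctrl=rng.uniform(0, 1e5, (n, m)),
            x_ctrl=rng.normal(size=(n, m, 6)),
            log_q=np.full((n, m), -10.0),
            log_accept=np.zeros(n),
            radius=500.0,
            seed=0,
        )
        beta = rng.normal(size=6) * 0.3
        base = negative_log_likelihood(5.0, beta, data)
        shifted = StepData(
            d2_case=data.d2_case,
            x_case=data.x_case + np.array([0, 0, 7.5, 0, 0, 0]),
            d2_ctrl=data.d2_ctrl,
            x_ctrl=data.x_ctrl + np.array([0, 0, 7.5, 0, 0, 0]),
            log_q=data.log_q,
            log_accept=data.log_accept,
            radius=data.radius,
            seed=0,
        )
        assert negative_log_likelihood(5.0, beta, shifted) == pytest.approx(base, rel=1e-9)

    def test_invariant_to_control_ordering(self, rng):
        n, m = 10, 8
        data = StepData(
            d2_case=rng.uniform(0, 1e4, n),
            x_case=rng.normal(size=(n, 6)),
            d2_ctrl=rng.uniform(0, 1e5, (n, m)),
            x_ctrl=rng.normal(size=(n, m, 6)),
            log_q=rng.normal(-10, 0.3, size=(n, m)),
            log_accept=np.zeros(n),
            radius=500.0,
            seed=0,
        )
        beta = rng.normal(size=6) * 0.2
        base = negative_log_likelihood(5.0, beta, data)
        perm = rng.permutation(m)
        permuted = StepData(
            d2_case=data.d2_case,
            x_case=data.x_case,
            d2_ctrl=data.d2_ctrl[:, perm],
            x_ctrl=data.x_ctrl[:, perm],
            log_q=data.log_q[:, perm],
            log_accept=data.log_accept,
            radius=data.radius,
            seed=0,
        )
        assert negative_log_likelihood(5.0, beta, permuted) == pytest.approx(base, rel=1e-12)


class TestMonteCarloDenominatorOracle:
    def test_matches_exact_cell_summation(self, small_stack):
        """Uniform-disk MC denominator with 5,000 controls agrees with the
        exact summation over all cells within 1% relative error.

        Run at moderate selection strength so Monte-Carlo noise stays well
        below the tolerance; the weights/normalization being checked do not
        depend on the parameter values."""
        theta = 546.0
        beta = np.array([0.01, -0.05, -0.1, 0.05, -0.001, 0.0])
        a = (310.0, 290.0)
        period = 2
        cs = sample_controls(a, period, small_stack, n=5000, radius=1200.0, seed=19)
        d2 = ((cs.points - np.array(a)) ** 2).sum(axis=1)
        phi = np.exp(-d2 / (2 * theta**2)) / (2 * np.pi * theta**2)
        omega = np.exp(cs.covariates @ beta)
        mc = cs.effective_area / cs.n * (phi * omega).sum()

        g = small_stack.elevation
        xs, ys = g.x_centers(), g.y_centers()
        X, Y = np.meshgrid(xs, ys)
        valid = small_stack.valid_mask(period)
        cov = small_stack.covariates_at(X[valid], Y[valid], period)
        d2e = (X[valid] - a[0]) ** 2 + (Y[valid] - a[1]) ** 2
        phie = np.exp(-d2e / (2 * theta**2)) / (2 * np.pi * theta**2)
        exact = (phie * np.exp(cov @ beta)).sum() * g.cell_size**2
        assert abs(mc - exact) / exact < 0.01


class TestFit:
    @pytest.fixture(scope="class")
    def fitted(self, small_stack):
        params = MovementParams(theta=120.0, beta=np.array([0.05, -0.1, -0.2, 0.4, -0.005, 0.0]))
        traj = simulate_trajectory((300, 300), params, small_stack, 200, seed=33)
        steps = build_steps(traj)
        data = prepare_step_data(steps, small_stack, n_controls=100, seed=34)
        return data, fit_step_selection(data, label="t")

    def test_converges_and_improves_on_init(self, fitted):
        from tallgrass.ssf import choice_set_negative_log_likelihood

        data, fit = fitted
        assert fit.converged
        theta0 = data.mean_step_length() / np.sqrt(np.pi / 2)
        init_nll = choice_set_negative_log_likelihood(np.log(theta0), np.zeros(6), data)
        assert fit.nll <= init_nll + 1e-9

    def test_ci_halfwidth_is_1p96_se(self, fitted):
        _, fit = fitted
        ratio_hi = (fit.ci_high - fit.estimates) / fit.se
        ratio_lo = (fit.estimates - fit.ci_low) / fit.se
        assert np.allclose(ratio_hi, 1.96, atol=1e-12)
        assert np.allclose(ratio_lo, 1.96, atol=1e-12)

    def test_covariance_symmetric_positive_definite(self, fitted):
        _, fit = fitted
        assert np.allclose(fit.covariance, fit.covariance.T)
        assert np.all(np.linalg.eigvalsh(fit.covariance) > 0)

    def test_estimates_in_plausible_range(self, fitted):
        _, fit = fitted
        assert 60 < fit.theta_hat < 250
        assert abs(fit.beta_hat[3] - 0.4) < 4 * fit.se[4]

    def test_few_steps_warns(self, small_stack):
        params = MovementParams(theta=120.0, beta=np.zeros(6))
        traj = simulate_trajectory((300, 300), params, small_stack, 20, seed=35)
        data = prepare_step_data(build_steps(traj), small_stack, n_controls=20, seed=36)
        with pytest.warns(UserWarning, match="steps"):
            fit_step_selection(data)


def _fake_fit(protein, biomass, interaction):
    """FitResult with prescribed (low, high) CIs for the three forage terms."""
    ci = {
        "theta": (500, 600),
        "elevation": (-1, 1),
        "slope": (-1, 1),
        "cos_aspect": (-1, 1),
        "protein": protein,
        "biomass": biomass,
        "protein_x_biomass": interaction,
    }
    lo = np.array([ci[n][0] for n in PARAM_NAMES], dtype=float)
    hi = np.array([ci[n][1] for n in PARAM_NAMES], dtype=float)
    est = (lo + hi) / 2
    se = (hi - est) / 1.96
    return FitResult(
        theta_hat=est[0], beta_hat=est[1:], se=se, ci_low=lo, ci_high=hi,
        covariance=np.eye(7), converged=True, nll=0.0, n_steps=100,
    )


class TestClassifyStrategy:
    def test_protein_with_biomass_avoidance_is_form2(self):
        fit = _fake_fit((0.2, 0.6), (-0.01, -0.001), (-0.001, 0.001))
        assert classify_strategy(fit) == "form2"

    def test_protein_with_indifferent_biomass_is_form3(self):
        fit = _fake_fit((0.1, 0.3), (-0.002, 0.004), (-0.001, 0.001))
        assert classify_strategy(fit) == "form3"

    def test_positive_interaction_is_form1(self):
        fit = _fake_fit((0.1, 0.3), (-0.002, 0.004), (0.0005, 0.002))
        assert classify_strategy(fit) == "form1"

    def test_positive_biomass_is_form1(self):
        fit = _fake_fit((0.1, 0.3), (0.001, 0.004), (-0.001, 0.001))
        assert classify_strategy(fit) == "form1"

    def test_no_protein_selection_is_none(self):
        fit = _fake_fit((-0.1, 0.3), (-0.002, 0.004), (-0.001, 0.001))
        assert classify_strategy(fit) == "none"

    def test_unconverged_fit_refused(self):
        fit = _fake_fit((0.1, 0.3), (-0.002, 0.004), (-0.001, 0.001))
        fit.converged = False
        with pytest.raises(ValueError):
            classify_strategy(fit)
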