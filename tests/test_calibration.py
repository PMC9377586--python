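"""Slope-ratio calibration: fits, crop-and-align, the update rule, the
full loop, and the Brent baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuecal import (
    IndentationCurve,
    calibrate,
    calibrate_brent,
    crop_align,
    fit_slope_zero_intercept,
    percent_difference,
    update_c1,
)
from tissuecal.calibration import slope_sequence_forward
from tissuecal.errors import (
    CalibrationError,
    CurveError,
    InsufficientSimulatedDisplacementError,
)
from tissuecal.reference_data import UPPER_ARM_EXAMPLE
from tissuecal.synthetic import surrogate_forward, synth_experiment


class TestSlopeFit:
    def test_exact_line_through_origin(self):
        c = IndentationCurve([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert fit_slope_zero_intercept(c) == pytest.approx(2.0)

    def test_hand_computed_two_points(self):
        # sum(dF)/sum(d^2) = (0*1 + 1*1) / (0 + 1) = 1
        c = IndentationCurve([0.0, 1.0], [1.0, 1.0])
        assert fit_slope_zero_intercept(c) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scaling_force_scales_slope(self, s):
        d = np.array([0.5, 1.0, 2.0, 3.5])
        f = np.array([0.2, 0.9, 1.7, 3.1])
        base = fit_slope_zero_intercept(IndentationCurve(d, f))
        scaled = fit_slope_zero_intercept(IndentationCurve(d, s * f))
        assert scaled == pytest.approx(s * base, rel=1e-12)

    def test_degenerate_all_zero_displacement(self):
        with pytest.raises(CurveError):
            fit_slope_zero_intercept(IndentationCurve([0.0, 0.0], [1.0, 2.0]))


class TestCropAlign:
    def test_zero_preload_equal_ranges_is_identity(self):
        sim = IndentationCurve([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        exp = IndentationCurve([0.0, 2.0], [0.0, 2.0], meta="experimental")
        out = crop_align(sim, exp)
        assert np.array_equal(out.displacement, sim.displacement)
        assert np.array_equal(out.force, sim.force)

    def test_preload_crop_and_rezero(self):
        sim = IndentationCurve([0.0, 1.0, 2.0, 3.0], [0.1, 0.2, 0.5, 1.0])
        exp = IndentationCurve([0.0, 1.0], [0.4, 1.4], meta="experimental")
        out = crop_align(sim, exp)
        assert np.allclose(out.displacement, [0.0, 1.0])
        assert np.allclose(out.force, [0.5, 1.0])

    def test_span_rule_drops_far_samples(self):
        sim = IndentationCurve([0.0, 1.0, 2.0, 3.0, 4.0], [0.5, 1.0, 1.5, 2.0, 2.5])
        exp = IndentationCurve([0.0, 2.0], [0.4, 1.4], meta="experimental")
        out = crop_align(sim, exp)
        assert out.displacement.max() <= 2.0 + 1e-12
        assert len(out) == 3

    def test_unreachable_preload_is_an_error(self):
        sim = IndentationCurve([0.0, 1.0], [0.0, 0.2])
        exp = IndentationCurve([0.0, 1.0], [0.5, 1.0], meta="experimental")
        with pytest.raises(InsufficientSimulatedDisplacementError):
            crop_align(sim, exp)


class TestUpdateRule:
    @pytest.mark.parametrize(
        "c1, s_sim, s_exp, expected",
        [
            (0.01, 3.0807, 1.5265, 0.004955),
            (0.004955, 1.9580, 1.5265, 0.003863),
            (0.02, 2.0, 2.0, 0.02),
        ],
    )
    def test_known_updates(self, c1, s_sim, s_exp, expected):
        assert update_c1(c1, s_sim, s_exp) == pytest.approx(expected, abs=5e-7)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_consistency(self, s):
        base = update_c1(0.01, 3.0, 1.5)
        assert update_c1(0.01, 3.0 * s, 1.5 * s) == pytest.approx(base, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(CalibrationError):
            update_c1(0.01, -1.0, 1.5)


class TestPercentDifference:
    def test_reproduces_method_comparison_value(self):
        assert percent_difference(0.00779, 0.00808) == pytest.approx(3.65, abs=0.005)

    def test_equal_values_zero(self):
        assert percent_difference(0.3, 0.3) == 0.0

    def test_difference_equal_to_mean(self):
        assert percent_difference(1.0, 3.0) == pytest.approx(100.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, -1.0)


class TestCalibrate:
    def test_linear_forward_converges_after_one_update(self):
        """Exactly linear forward with zero preload: one ratio update lands
        on the solution from any positive initial guess."""
        exp, _ = synth_experiment(
            0.005,
            forward=lambda c: surrogate_forward(c, stiffening=0.0),
            preload_force=0.0,
        )
        for c1_init in (0.0005, 0.01, 0.2):
            state = calibrate(
                lambda c: surrogate_forward(c, stiffening=0.0), exp, c1_init=c1_init
            )
            assert state.converged
            assert state.n_forward_evals == 2  # one update + confirming run
            assert state.final.c1 == pytest.approx(0.005, rel=1e-9)

    def test_replayed_iteration_record(self):
        """Replaying the published female-upper-arm slope sequence through
        the loop reproduces its C1 trace and 4-iteration convergence."""
        ex = UPPER_ARM_EXAMPLE
        exp = IndentationCurve(
            [0.0, 10.0], [0.0, 10.0 * ex["experimental_slope"]], meta="experimental"
        )
        forward = slope_sequence_forward(ex["simulation_slopes"])
        state = calibrate(forward, exp, c1_init=ex["c1_init"])
        assert state.converged
        assert [r.iteration for r in state.iterations] == [1, 2, 3, 4]
        assert [round(c, 6) for c in state.c1_trace] == [
            0.01,
            0.004955,
            0.003863,
            0.003584,
        ]
        assert state.iterations[0].ratio == pytest.approx(2.0181, abs=5e-5)
        assert all(r.k == pytest.approx(1000.0 * r.c1) for r in state.iterations)

    def test_parameter_recovery_with_preload_and_noise(self):
        """Across true C1 values with preload and 1%-of-peak force noise the
        loop converges within 6 iterations to <2.5% slope mismatch."""
        rng_truths = np.linspace(0.001, 0.02, 20)
        for i, true_c1 in enumerate(rng_truths):
            peak = surrogate_forward(true_c1).peak_force
            exp, _ = synth_experiment(
                true_c1, preload_force=0.14, noise_sd=0.01 * peak, seed=100 + i
            )
            state = calibrate(surrogate_forward, exp, c1_init=0.01)
            assert state.converged, f"case {i} did not converge"
            assert state.n_forward_evals <= 6
            assert abs(state.final.ratio - 1.0) < 0.025
            assert state.final.c1 == pytest.approx(true_c1, rel=0.1)

    def test_contraction_for_monotone_nonlinear_forward(self):
        """For s_sim(c1) ~ c1^0.8 (local elasticity in (0, 2)) the iteration
        contracts to the fixed point."""

        def forward(c1):
            d = np.linspace(0.0, 6.0, 50)
            return IndentationCurve(d, 300.0 * c1**0.8 * d)

        exp_curve = forward(0.005).with_meta("experimental")
        state = calibrate(forward, exp_curve, c1_init=0.05, tol=1e-3)
        assert state.converged
        assert state.final.c1 == pytest.approx(0.005, rel=1e-2)
        mismatches = [abs(r.ratio - 1.0) for r in state.iterations]
        assert all(b < a for a, b in zip(mismatches, mismatches[1:]))

    def test_max_iter_exhaustion_is_not_an_exception(self):
        # a forward model pinned at the wrong slope can never converge
        def forward(_c1):
            d = np.linspace(0.0, 5.0, 20)
            return IndentationCurve(d, 10.0 * d)

        exp = IndentationCurve([0.0, 5.0], [0.0, 5.0], meta="experimental")
        state = calibrate(forward, exp, c1_init=0.01, max_iter=4)
        assert not state.converged
        assert state.n_forward_evals == 4


class TestBrentBaseline:
    def test_same_solution_as_ratio_method(self):
        exp, _ = synth_experiment(0.005, preload_force=0.14, noise_sd=0.0, seed=5)
        ratio_state = calibrate(surrogate_forward, exp, c1_init=0.01)
        brent_state = calibrate_brent(surrogate_forward, exp, bracket=(5e-4, 0.2))
        assert brent_state.converged
        assert brent_state.final.c1 == pytest.approx(ratio_state.final.c1, rel=0.025)

    def test_ratio_method_needs_no_more_evaluations(self):
        for seed in (11, 12, 13):
            exp, _ = synth_experiment(
                0.004 + 0.002 * seed % 3, preload_force=0.14, noise_sd=0.0, seed=seed
            )
            ratio_state = calibrate(surrogate_forward, exp, c1_init=0.01)
            brent_state = calibrate_brent(surrogate_forward, exp, bracket=(5e-4, 0.2))
            assert ratio_state.n_forward_evals <= brent_state.n_forward_evals

    def test_invalid_bracket_rejected(self):
        exp, _ = synth_experiment(0.005, preload_force=0.0, noise_sd=0.0, seed=2)
        with pytest.raises(CalibrationError):
            calibrate_brent(surrogate_forward, exp, bracket=(0.05, 0.2))
        with pytest.raises(CalibrationError):
            calibrate_brent(surrogate_forward, exp, bracket=(-1.0, 0.2))
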