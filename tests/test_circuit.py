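"""Unit and property tests for the steering-circuit building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fbsteer import CircuitParams, StimulusSchedule, build_w_hdc, build_w_ii
from fbsteer import circuit as cm
from fbsteer.circuit import (
    CircuitState, StimulusFrame, heading_input, hdc_input, hdc_output,
    integrate, integrate_batch, local_output, mutual_inhibition_step,
    ou_noise_step, pfl_step, phase_shift_180, sigmoid, speed_step, turn_step,
    wind_input_allocentric, wind_input_frontal, wrap_angle,
)

from reference_step import reference_step


# --------------------------------------------------------------------------
# sigmoid
# --------------------------------------------------------------------------

class TestSigmoid:
    def test_midpoint_is_half(self):
        assert sigmoid(0.7, 0.7, 0.1) == pytest.approx(0.5)
        assert sigmoid(-0.15, -0.15, 0.2) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert sigmoid(1e3, 0.7, 0.1) == pytest.approx(1.0)
        assert sigmoid(-1e3, 0.7, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_inversion(self):
        # S(theta + k ln 3) = 3/4 for the logistic
        assert sigmoid(0.7 + 0.1 * np.log(3.0), 0.7, 0.1) == pytest.approx(0.75)

    def test_rejects_bad_input(self):
        with pytest.raises(FloatingPointError):
            sigmoid(np.nan, 0.7, 0.1)
        with pytest.raises(ValueError):
            sigmoid(0.0, 0.7, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted((a, b))
        if hi - lo > 1e-9:
            assert sigmoid(hi, 0.0, 0.1) > sigmoid(lo, 0.0, 0.1)


# --------------------------------------------------------------------------
# sinusoidal inputs
# --------------------------------------------------------------------------

class TestHeadingInput:
    def test_peak_opposite_fb_when_heading_zero(self, params):
        fb = np.linspace(0, 359, 360)
        v = heading_input(0.0, 0.0, fb)
        assert fb[np.argmax(v)] == pytest.approx(180.0)
        assert v.max() == pytest.approx(2.0)
        assert v.min() == pytest.approx(0.0, abs=1e-9)

    def test_heading_and_shift_cancel(self, params):
        fb = params.column_centers
        np.testing.assert_allclose(heading_input(90.0, 90.0, fb),
                                   heading_input(0.0, 0.0, fb), atol=1e-12)

    def test_mean_over_uniform_cycle_is_one(self, params):
        fb = params.column_centers
        for h in (0.0, 37.0, 311.5):
            assert heading_input(h, -90.0, fb).mean() == pytest.approx(1.0)

    def test_batched_headings_broadcast(self, params):
        fb = params.column_centers
        out = heading_input(np.array([0.0, 90.0]), 0.0, fb)
        assert out.shape == (2, 8)
        np.testing.assert_allclose(out[0], heading_input(0.0, 0.0, fb))


class TestWindInput:
    def test_allocentric_matches_heading_bump_at_zero_shift(self, params):
        fb = params.neuron_centers
        np.testing.assert_allclose(wind_input_allocentric(0.0, fb),
                                   heading_input(0.0, 0.0, fb), atol=1e-12)

    def test_allocentric_peak_tracks_wind(self):
        fb = np.linspace(0, 359.5, 720)
        for wind in (0.0, 90.0, 180.0, 275.0):
            v = wind_input_allocentric(wind, fb)
            assert fb[np.argmax(v)] == pytest.approx((180.0 - wind) % 360.0,
                                                     abs=0.5)

    def test_allocentric_independent_of_heading(self, params):
        # same bump whatever the fly's heading: only the wind matters
        fb = params.neuron_centers
        v = wind_input_allocentric(135.0, fb)
        assert v.shape == (20,)
        assert v.max() <= 2.0 and v.min() >= 0.0

    def test_frontal_scale_maximal_at_preferred_wind(self, params):
        # egocentric wind at the left-PFN peak makes the left scale sin(90)=1:
        # the bump then equals the left heading sinusoid exactly plus the
        # right term scaled by sin(90 + peak_l - peak_r) = 0
        fb = params.neuron_centers
        h = 30.0
        wind = h + params.peak_left  # ego = peak_left
        v = wind_input_frontal(h, wind, params)
        left = np.cos(np.deg2rad(fb - (180.0 - h + params.phase_shift_left_pfn)))
        np.testing.assert_allclose(v, left, atol=1e-12)

    def test_frontal_wind_sums_to_unit_amplitude_heading_bump(self, params):
        # frontal wind (ego = 0): scales are sqrt(2)/2 each and the +/-45 deg
        # shifted sinusoids sum to cos(fb - (180 - heading))
        fb = params.neuron_centers
        h = 57.0
        v = wind_input_frontal(h, h, params)
        expect = np.cos(np.deg2rad(fb - (180.0 - h)))
        np.testing.assert_allclose(v, expect, atol=1e-12)

    def test_rear_wind_inverts_bump(self, params):
        h = 0.0
        front = wind_input_frontal(h, h, params)
        rear = wind_input_frontal(h, h + 180.0, params)
        np.testing.assert_allclose(rear, -front, atol=1e-12)


# --------------------------------------------------------------------------
# hDeltaC layer
# --------------------------------------------------------------------------

class TestHdc:
    def test_input_gated_by_odor(self, params):
        bump = wind_input_allocentric(0.0, params.neuron_centers)
        zero = np.zeros(20)
        np.testing.assert_array_equal(hdc_input(bump, False, zero), zero)
        np.testing.assert_array_equal(hdc_input(bump, True, zero), bump)

    def test_broad_opto_without_odor(self, params):
        bump = wind_input_allocentric(0.0, params.neuron_centers)
        opto = np.full(20, params.opto_power_high)
        np.testing.assert_array_equal(hdc_input(bump, False, opto), opto)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            hdc_input(np.zeros(20), True, np.zeros(8))

    def test_w_hdc_rows_normalized(self):
        w = build_w_hdc(20, 8)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_w_hdc_constant_preserved(self):
        w = build_w_hdc(20, 8)
        np.testing.assert_allclose(w @ np.full(20, 1.7), 1.7, atol=1e-12)

    def test_w_hdc_impulse_footprint_is_local(self):
        # one column-wide footprint can overlap at most 3 adjacent columns
        w = build_w_hdc(20, 8)
        for j in range(20):
            cols = np.nonzero(w[:, j])[0]
            assert 1 <= len(cols) <= 3
            # adjacency on the ring
            if len(cols) > 1:
                d = np.diff(sorted(cols))
                assert set(d) <= {1, 7} or np.all(d == 1)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.sampled_from([(8, 8), (16, 8), (20, 8), (24, 12)]))
    def test_w_hdc_rows_normalized_generic(self, shape):
        n, c = shape
        w = build_w_hdc(n, c)
        assert w.shape == (c, n)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_output_at_rest_is_sigmoid_of_zero(self, params):
        w = build_w_hdc(20, 8)
        out = hdc_output(np.zeros(20), w, np.zeros(8), params)
        assert out == pytest.approx(sigmoid(0.0, 0.7, 0.1), rel=1e-9)
        assert out[0] == pytest.approx(9.11e-4, rel=1e-2)

    def test_output_bump_shifted_half_ring(self, params):
        # wind from -22.5 deg puts the input bump exactly at column 4's
        # center (202.5 deg); the 180 deg output shift moves it to column 0
        w = build_w_hdc(20, 8)
        act = wind_input_allocentric(-22.5, params.neuron_centers)
        out = hdc_output(act, w, np.zeros(8), params)
        assert np.argmax(out) == 0
        assert np.argmin(out) == 4

    def test_output_bounded(self, params, rng):
        w = build_w_hdc(20, 8)
        for _ in range(10):
            act = rng.uniform(0, 3, 20)
            n = rng.normal(0, params.sigma_n, 8)
            out = hdc_output(act, w, n, params)
            assert np.all(out > 0 + n.min() - 1e-12)
            assert np.all(out < 1 + n.max() + 1e-12)


# --------------------------------------------------------------------------
# noise, mutual inhibition, PFL, motor readouts
# --------------------------------------------------------------------------

class TestOuNoise:
    def test_deterministic_decay_without_noise(self, rng):
        p = CircuitParams(sigma_n=0.0)
        n = np.full(8, 0.5)
        for _ in range(3):
            n = ou_noise_step(n, p, rng)
        expect = 0.5 * np.exp(-3 * p.dt / p.tau_n)
        np.testing.assert_allclose(n, expect, rtol=1e-12)

    def test_long_run_mean_zero_and_std_sigma(self, params, rng):
        n = np.zeros(8)
        samples = np.empty((4000, 8))
        for i in range(4000):
            n = ou_noise_step(n, params, rng)
            samples[i] = n
        assert abs(samples.mean()) < 3e-3
        assert samples.std() == pytest.approx(params.sigma_n, rel=0.05)


class TestMutualInhibition:
    def test_decoupled_limit_relaxes_to_sigmoid(self):
        p = CircuitParams(w_ii=0.0, g_adapt=0.0)
        u = np.zeros(8)
        a = np.zeros(8)
        drive = np.linspace(-0.5, 0.5, 8)
        for _ in range(200):
            u, a = mutual_inhibition_step(u, a, drive, p)
        # with adaptation off, u settles near S_mi(drive) (a still tracks u
        # but is not fed back)
        np.testing.assert_allclose(u, sigmoid(drive, p.theta_mi, p.k_mi),
                                   atol=1e-6)

    def test_activity_bounded_in_unit_interval(self, params, rng):
        u = rng.uniform(0, 1, 8)
        a = rng.uniform(0, 1, 8)
        for _ in range(500):
            u, a = mutual_inhibition_step(u, a, rng.uniform(0, 1.2, 8), params)
            assert np.all(u > 0) and np.all(u < 1)

    def test_strong_uniform_input_oscillates(self, params):
        # rivalry dynamics: winners switch under sustained uniform drive;
        # u is nonconstant over time after the initial transient
        w = build_w_ii(params)
        u = np.zeros(8)
        a = np.zeros(8)
        drive = np.full(8, 0.6) + 1e-3 * np.sin(np.arange(8))  # tiny asymmetry
        trace = []
        for step in range(12000):  # 12 s at dt_inner
            u, a = mutual_inhibition_step(u, a, drive, params, w_ii=w)
            if step >= 4000 and step % 50 == 0:
                trace.append(u.copy())
        trace = np.array(trace)
        assert trace.std(axis=0).max() > 0.05

    def test_zero_input_fixed_point_is_quiescent(self, params):
        u = np.zeros(8)
        a = np.zeros(8)
        for _ in range(5000):
            u, a = mutual_inhibition_step(u, a, np.zeros(8), params)
        assert np.all(u < 0.15)  # subthreshold rest


class TestLocalAndPfl:
    def test_phi180_is_involution(self):
        v = np.arange(8.0)
        np.testing.assert_array_equal(phase_shift_180(phase_shift_180(v)), v)
        v20 = np.arange(20.0)
        np.testing.assert_array_equal(phase_shift_180(phase_shift_180(v20)), v20)
        with pytest.raises(ValueError):
            phase_shift_180(np.arange(7.0))

    def test_local_output_identity_when_no_inhibition(self, rng):
        h = rng.uniform(0, 1, 8)
        np.testing.assert_array_equal(local_output(h, np.zeros(8)), h)

    def test_local_output_trough_opposite_inhibition_peak(self):
        u = np.zeros(8)
        u[2] = 0.8
        out = local_output(np.zeros(8), u)
        assert np.argmin(out) == (2 + 4) % 8
        assert out.min() == pytest.approx(-0.8)

    def test_constant_inhibition_subtracts_constant(self, rng):
        h = rng.uniform(0, 1, 8)
        np.testing.assert_allclose(local_output(h, np.full(8, 0.3)), h - 0.3)

    def test_pfl_steady_state_is_sigmoid_of_heading_bump(self, params):
        pfl = np.zeros(8)
        for _ in range(200):
            pfl = pfl_step(pfl, 0.0, 180.0, np.zeros(8), params)
        expect = sigmoid(heading_input(0.0, 180.0, params.column_centers),
                         params.theta_pfl, params.k_pfl)
        np.testing.assert_allclose(pfl, expect, atol=1e-9)
        assert np.all(pfl > 0) and np.all(pfl < 1)

    def test_aligned_bumps_sum_constructively(self, params):
        # goal bump aligned with the shifted heading bump drives more total
        # PFL activity than an anti-aligned goal
        cols = params.column_centers
        goal_aligned = heading_input(0.0, 180.0, cols) - 1.0
        goal_anti = -goal_aligned
        pa = pb = np.zeros(8)
        for _ in range(200):
            pa = pfl_step(pa, 0.0, 180.0, goal_aligned, params)
            pb = pfl_step(pb, 0.0, 180.0, goal_anti, params)
        assert pa.sum() > pb.sum()


class TestMotor:
    def test_symmetric_activity_gives_zero_turn(self, params, rng):
        p = params.replace(lambda_turn=0.0)
        pfl = rng.uniform(0, 1, 8)
        assert turn_step(pfl, pfl, p, rng) == pytest.approx(0.0)

    def test_no_events_means_deterministic_steering(self, params, rng):
        p = params.replace(lambda_turn=0.0)
        left = np.full(8, 0.2)
        right = np.full(8, 0.3)
        expect = p.m1 * p.rate_reference_hz * p.dt * (right - left).sum()
        for _ in range(5):
            assert turn_step(left, right, p, rng) == pytest.approx(expect)

    def test_pure_noise_turning_is_unbiased(self, params, rng):
        zero = np.zeros(8)
        turns = np.array([turn_step(zero, zero, params, rng)
                          for _ in range(4000)])
        events = turns != 0.0
        # event rate matches lambda at the reference rate and kicks are
        # zero-mean
        assert events.mean() == pytest.approx(params.p_turn, abs=0.03)
        assert abs(turns.mean()) < 3 * params.sigma_turn / np.sqrt(len(turns))

    def test_speed_baseline_and_linearity(self, params):
        assert speed_step(np.zeros(8), params) == pytest.approx(6.0)
        assert speed_step(np.ones(8), params) == pytest.approx(8.0)
        assert (speed_step(np.full(8, 0.6), params)
                > speed_step(np.full(8, 0.4), params))


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

class TestIntegrate:
    def test_straight_line_when_steering_silent(self, params):
        # hDeltaC clamped and no turn events: left/right PFL3 stay mirror
        # symmetric, heading never changes, motion is a straight line
        p = params.replace(lambda_turn=0.0, sigma_n=0.0)
        sched = StimulusSchedule.pulse(2.0, p.dt, hdc_clamped=True)
        res = integrate_batch(p, sched, np.array([0.0]), np.random.default_rng(0))
        np.testing.assert_allclose(res["heading"][0], 0.0, atol=1e-9)
        np.testing.assert_allclose(res["x"][0], 0.0, atol=1e-9)
        dy = np.diff(res["y"][0])
        np.testing.assert_allclose(dy, p.dt * res["speed"][0][:-1], atol=1e-9)

    def test_heading_90_moves_along_x(self, params):
        p = params.replace(lambda_turn=0.0, sigma_n=0.0)
        sched = StimulusSchedule.pulse(2.0, p.dt, hdc_clamped=True)
        res = integrate_batch(p, sched, np.array([90.0]), np.random.default_rng(0))
        np.testing.assert_allclose(res["y"][0], 0.0, atol=1e-9)
        assert res["x"][0][-1] > 10.0

    def test_single_step_matches_independent_reference(self, params, rng):
        """One engine step reproduces a straight-line scalar re-evaluation
        of the full input -> hDeltaC -> inhibition -> PFL -> motor chain."""
        opto = np.zeros(20)
        opto[3] = params.opto_power_high
        sched = StimulusSchedule.pulse(params.dt, params.dt,
                                       wind_direction=135.0,
                                       odor_window=(0.0, params.dt),
                                       light_window=(0.0, params.dt),
                                       opto_pattern=opto)
        eng = integrate_batch(params, sched, np.array([211.0]),
                              np.random.default_rng(777))
        state = {k: [0.0] * 8 for k in ("u", "a", "n", "pfl3_left",
                                        "pfl3_right", "pfl2")}
        h, x, y, v, state = reference_step(
            params, 211.0, 0.0, 0.0, params.v_base, state, 135.0, True, opto,
            np.random.default_rng(777))
        assert eng["heading"][0][-1] == pytest.approx(h, rel=1e-12, abs=1e-12)
        assert eng["x"][0][-1] == pytest.approx(x, rel=1e-12, abs=1e-12)
        assert eng["y"][0][-1] == pytest.approx(y, rel=1e-12, abs=1e-12)
        assert eng["speed"][0][-1] == pytest.approx(v, rel=1e-12)
        s = eng["state"]
        for key, arr in (("u", s.u), ("a", s.a), ("n", s.n),
                         ("pfl3_left", s.pfl3_left),
                         ("pfl3_right", s.pfl3_right), ("pfl2", s.pfl2)):
            np.testing.assert_allclose(arr[0], state[key], rtol=1e-12,
                                       atol=1e-14)

    def test_multi_step_frontal_matches_reference(self, params):
        sched = StimulusSchedule.pulse(3 * params.dt, params.dt,
                                       wind_direction=40.0,
                                       odor_window=(0.0, 1.0),
                                       representation="frontal")
        eng = integrate_batch(params, sched, np.array([10.0]),
                              np.random.default_rng(5))
        ref_rng = np.random.default_rng(5)
        state = {k: [0.0] * 8 for k in ("u", "a", "n", "pfl3_left",
                                        "pfl3_right", "pfl2")}
        h, x, y, v = 10.0, 0.0, 0.0, params.v_base
        for _ in range(3):
            h, x, y, v, state = reference_step(
                params, h, x, y, v, state, 40.0, True, [0.0] * 20, ref_rng,
                representation="frontal")
        assert eng["heading"][0][-1] == pytest.approx(h, rel=1e-10)
        assert eng["y"][0][-1] == pytest.approx(y, rel=1e-10)

    def test_rotational_equivariance_of_wind_navigation(self, params):
        """Rotating wind and initial heading by 90 deg rotates the
        trajectory headings by 90 deg (deterministic limit)."""
        p = params.replace(sigma_n=0.0, lambda_turn=0.0)
        out = {}
        for delta in (0.0, 90.0):
            sched = StimulusSchedule.pulse(8.0, p.dt,
                                           wind_direction=180.0 + delta,
                                           odor_window=(0.0, 8.0))
            res = integrate_batch(p, sched, np.array([45.0 + delta]),
                                  np.random.default_rng(0))
            out[delta] = res["heading"][0]
        diff = wrap_angle(out[90.0] - out[0.0] - 90.0)
        np.testing.assert_allclose(diff, 0.0, atol=1e-6)

    def test_activities_stay_finite_and_bounded(self, params):
        opto = np.full(20, params.opto_power_high)
        sched = StimulusSchedule.pulse(5.0, params.dt, light_window=(1.0, 5.0),
                                       opto_pattern=opto)
        res = integrate_batch(params, sched, np.array([0.0, 120.0]),
                              np.random.default_rng(3), record_activity=True)
        for snap in res["activity"]:
            for key in ("u", "pfl3_left", "pfl3_right", "pfl2"):
                assert np.all(np.isfinite(snap[key]))
                assert np.all(snap[key] >= 0.0) and np.all(snap[key] <= 1.0)

    def test_integrate_wraps_frames_and_offsets_position(self, params):
        frames = [StimulusFrame(wind_direction_allo=0.0, odor_on=True)
                  for _ in range(10)]
        state = CircuitState.initial(params, heading=20.0)
        state.x = np.asarray(3.0)
        state.y = np.asarray(-2.0)
        traj = integrate(state, frames, params, np.random.default_rng(1))
        assert len(traj) == 11
        assert traj.x[0] == pytest.approx(3.0)
        assert traj.y[0] == pytest.approx(-2.0)
        assert traj.dt == pytest.approx(params.dt)

    def test_upwind_convergence_smoke(self, params):
        # wind from 270 deg, start anti-aligned: the model fly reorients
        # upwind within a few seconds
        sched = StimulusSchedule.pulse(15.0, params.dt, wind_direction=270.0,
                                       odor_window=(1.0, 15.0))
        res = integrate_batch(params, sched, np.array([90.0]),
                              np.random.default_rng(11))
        final = res["heading"][0][-100:]
        err = np.abs(wrap_angle(final - 270.0))
        assert np.median(err) < 30.0


class TestValidation:
    def test_params_invariants(self):
        with pytest.raises(ValueError):
            CircuitParams(dt=0.0)
        with pytest.raises(ValueError):
            CircuitParams(sparse_prob=1.5)
        with pytest.raises(ValueError):
            CircuitParams(n_columns=7)

    def test_w_ii_structure(self, params):
        w = build_w_ii(params)
        np.testing.assert_array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        idx = np.arange(8)
        assert np.all(w[idx, (idx + 4) % 8] == params.w_ii)
        assert w.sum() == pytest.approx(8 * params.w_ii)

    def test_state_validation_catches_nan(self, params):
        state = CircuitState.initial(params)
        state.u = np.array([np.nan] * 8)
        with pytest.raises(FloatingPointError):
            state.validate()

    def test_opto_pattern_validation(self):
        frame = StimulusFrame(opto_pattern=np.full(20, -1.0))
        with pytest.raises(ValueError):
            frame.pattern(20)
        with pytest.raises(ValueError):
            StimulusFrame(opto_pattern=np.zeros(5)).pattern(20)
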