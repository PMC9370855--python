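import numpy as np
import pytest

from gaitpredict import (
    CompensationParams,
    GaitEvents,
    StateSequence,
    Trajectory,
    blend_orientation,
    build_realtime_states,
    calibrate_K,
    detect_contacts,
    estimate_offline_states,
    estimate_raw_states,
    fit_baseline,
    hold_velocity,
)
from gaitpredict.gait_compensation import INITIAL_CONTACT

from oracles import half_ptp


def _states_with_speed(t, v, variant="raw"):
    """StateSequence with a prescribed speed channel (positions unused)."""
    z = np.zeros_like(t)
    return StateSequence(t=t, x=z, y=z, phi=z, v=v, a=z, w=z, variant=variant)


def _ic_times(states, events):
    mask = np.array(events.labels) == INITIAL_CONTACT
    return states.t[events.indices[mask]]


class TestDetectContacts:
    def test_sinusoidal_speed_event_spacing(self):
        # v = 1.2 + 0.15 sin(2*pi*1.8 t): extrema of dv/dt every 1/(2*1.8) s
        t = np.arange(0, 10, 0.01)
        states = _states_with_speed(t, 1.2 + 0.15 * np.sin(2 * np.pi * 1.8 * t))
        events = detect_contacts(states)
        assert abs(len(events) - 35) <= 1
        spacing = np.diff(states.t[events.indices])
        np.testing.assert_allclose(spacing, 1 / 3.6, atol=0.02)
        # the speed at every event sits at the oscillation mean
        np.testing.assert_allclose(states.v[events.indices], 1.2, atol=0.02)

    def test_constant_speed_no_events(self):
        t = np.arange(0, 5, 0.01)
        events = detect_contacts(_states_with_speed(t, np.full_like(t, 1.2)))
        assert len(events) == 0

    def test_simulator_initial_contacts(self, straight_sway_walk):
        # 10 s at 1 stride/s: 20 initial contacts, each within 30 ms of truth
        raw = estimate_raw_states(straight_sway_walk.traj)
        events = detect_contacts(raw)
        ic = _ic_times(raw, events)
        truth = straight_sway_walk.event_times_truth
        assert abs(len(ic) - len(truth)) <= 1
        for t_true in truth[:-1]:
            assert np.min(np.abs(ic - t_true)) < 0.030

    def test_alternating_labels(self, straight_sway_walk):
        raw = estimate_raw_states(straight_sway_walk.traj)
        events = detect_contacts(raw)
        assert all(a != b for a, b in zip(events.labels, events.labels[1:]))

    def test_requires_raw_variant(self, straight_sway_walk):
        raw = estimate_raw_states(straight_sway_walk.traj, variant="offline")
        with pytest.raises(ValueError):
            detect_contacts(raw)

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            GaitEvents(indices=[5, 5], labels=[INITIAL_CONTACT, INITIAL_CONTACT])
        with pytest.raises(ValueError):
            GaitEvents(indices=[5], labels=[])


class TestHoldVelocity:
    def test_sinusoid_held_at_mean(self):
        t = np.arange(0, 10, 0.01)
        states = _states_with_speed(t, 1.2 + 0.15 * np.sin(2 * np.pi * 1.8 * t))
        events = detect_contacts(states)
        v_tilde, _ = hold_velocity(states, events)
        after = v_tilde[events.indices[0] :]
        np.testing.assert_allclose(after, 1.2, atol=0.02)

    def test_empty_events_pass_through(self):
        t = np.arange(0, 5, 0.01)
        states = _states_with_speed(t, np.full_like(t, 1.1))
        v_tilde, a_tilde = hold_velocity(states, GaitEvents(indices=[], labels=[]))
        np.testing.assert_array_equal(v_tilde, states.v)
        np.testing.assert_array_equal(a_tilde, states.a)

    def test_ramp_recovers_mean_acceleration(self):
        # linearly increasing mean speed + ripple: a_tilde tracks the ramp
        t = np.arange(0, 12, 0.01)
        accel = 0.05
        states = _states_with_speed(t, 1.0 + accel * t + 0.1 * np.sin(2 * np.pi * 1.8 * t))
        events = detect_contacts(states)
        _, a_tilde = hold_velocity(states, events)
        mid = slice(events.indices[2], events.indices[-1])
        assert abs(np.mean(a_tilde[mid]) - accel) < 0.1 * accel

    def test_before_first_event_copies_raw(self, straight_sway_walk):
        raw = estimate_raw_states(straight_sway_walk.traj)
        events = detect_contacts(raw)
        v_tilde, _ = hold_velocity(raw, events)
        first = events.indices[0]
        np.testing.assert_array_equal(v_tilde[:first], raw.v[:first])

    def test_stride_mean_speed_preserved(self, straight_sway_walk):
        raw = estimate_raw_states(straight_sway_walk.traj)
        v_tilde, _ = hold_velocity(raw, detect_contacts(raw))
        mid = slice(100, 900)
        true_mean = straight_sway_walk.cfg.mean_speed
        assert abs(np.mean(v_tilde[mid]) - true_mean) < 0.02 * true_mean


class TestBlendOrientation:
    @staticmethod
    def _pair(phi_r_osc=0.1, phi_h_osc=-0.1, base=0.5):
        t = np.arange(0, 10, 0.01)
        theta = 2 * np.pi * t
        z = np.zeros_like(t)
        raw = StateSequence(
            t=t, x=z, y=z, phi=base + phi_r_osc * np.sin(theta), v=z + 1, a=z, w=z,
            variant="raw",
        )
        traj = Trajectory(t=t, x=np.cos(base) * t, y=np.sin(base) * t,
                          phi_pelvis=base + phi_h_osc * np.sin(theta))
        return raw, traj

    def test_k0_identity(self):
        raw, traj = self._pair()
        phi_t, _ = blend_orientation(raw, traj, CompensationParams(K=0.0))
        np.testing.assert_allclose(phi_t, raw.phi, atol=1e-12)

    def test_k1_identity(self):
        raw, traj = self._pair()
        phi_t, _ = blend_orientation(raw, traj, CompensationParams(K=1.0))
        np.testing.assert_allclose(phi_t, traj.phi_pelvis, atol=1e-12)

    def test_counterphase_cancellation_at_half(self):
        raw, traj = self._pair(phi_r_osc=0.1, phi_h_osc=-0.1)
        phi_t, w_t = blend_orientation(raw, traj, CompensationParams(K=0.5))
        np.testing.assert_allclose(phi_t, 0.5, atol=1e-12)
        np.testing.assert_allclose(w_t, 0.0, atol=1e-9)

    def test_missing_pelvis_rejected(self):
        raw, traj = self._pair()
        traj.phi_pelvis[:] = np.nan
        with pytest.raises(ValueError):
            blend_orientation(raw, traj, CompensationParams(K=0.5))


class TestCalibrateK:
    def test_amplitude_ratio_closed_form(self):
        # raw osc +0.1 sin, pelvis osc -0.3 sin: K* = 0.1/(0.1+0.3)
        t = np.arange(0, 10, 0.01)
        theta = 2 * np.pi * t
        z = np.zeros_like(t)
        base = 0.5
        raw = StateSequence(t=t, x=z, y=z, phi=base + 0.1 * np.sin(theta), v=z + 1,
                            a=z, w=z, variant="raw")
        off = StateSequence(t=t, x=z, y=z, phi=np.full_like(t, base), v=z + 1,
                            a=z, w=z, variant="offline")
        traj = Trajectory(t=t, x=t, y=z, phi_pelvis=base - 0.3 * np.sin(theta))
        params = calibrate_K(raw, off, traj)
        assert params.K == pytest.approx(0.25, abs=1e-6)

    def test_pelvis_equals_baseline_gives_k1(self):
        t = np.arange(0, 10, 0.01)
        theta = 2 * np.pi * t
        z = np.zeros_like(t)
        raw = StateSequence(t=t, x=z, y=z, phi=0.5 + 0.1 * np.sin(theta), v=z + 1,
                            a=z, w=z, variant="raw")
        off = StateSequence(t=t, x=z, y=z, phi=np.full_like(t, 0.5), v=z + 1,
                            a=z, w=z, variant="offline")
        traj = Trajectory(t=t, x=t, y=z, phi_pelvis=np.full_like(t, 0.5))
        assert calibrate_K(raw, off, traj).K == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_returns_zero(self):
        t = np.arange(0, 10, 0.01)
        z = np.zeros_like(t)
        phi = 0.5 + 0.1 * np.sin(2 * np.pi * t)
        raw = StateSequence(t=t, x=z, y=z, phi=phi, v=z + 1, a=z, w=z, variant="raw")
        off = StateSequence(t=t, x=z, y=z, phi=np.full_like(t, 0.5), v=z + 1,
                            a=z, w=z, variant="offline")
        traj = Trajectory(t=t, x=t, y=z, phi_pelvis=phi)
        assert calibrate_K(raw, off, traj).K == 0.0

    def test_simulator_recovery(self, straight_sway_walk):
        traj = straight_sway_walk.traj
        raw = estimate_raw_states(traj)
        off = estimate_offline_states(fit_baseline(traj, degree=1))
        params = calibrate_K(raw, off, traj)
        assert abs(params.K - straight_sway_walk.K_truth) < 0.05

    def test_global_minimum_vs_brute_force(self, straight_sway_walk):
        traj = straight_sway_walk.traj
        raw = estimate_raw_states(traj)
        off = estimate_offline_states(fit_baseline(traj, degree=1))
        params = calibrate_K(raw, off, traj)
        phi_r = np.unwrap(raw.phi)
        phi_h = np.unwrap(traj.phi_pelvis) - params.phi_offset
        phi_b = np.unwrap(off.phi)

        def sse(k):
            resid = k * phi_h + (1 - k) * phi_r - phi_b
            return float(np.dot(resid, resid))

        grid = np.arange(0, 1 + 1e-12, 1e-4)
        best = min(sse(k) for k in grid)
        assert sse(params.K) <= best + 1e-9


class TestBuildRealtimeStates:
    def test_unperturbed_walk_equals_raw(self, clean_straight_walk):
        traj = clean_straight_walk.traj
        raw = estimate_raw_states(traj)
        rt = build_realtime_states(traj, CompensationParams(K=0.0))
        assert rt.variant == "realtime"
        np.testing.assert_allclose(rt.v, raw.v, atol=1e-9)
        np.testing.assert_allclose(rt.phi, raw.phi, atol=1e-9)
        np.testing.assert_allclose(rt.a, raw.a, atol=1e-9)

    def test_velocity_oscillation_suppressed(self, straight_sway_walk):
        traj = straight_sway_walk.traj
        raw = estimate_raw_states(traj)
        rt = build_realtime_states(traj, CompensationParams(K=0.0))
        mid = slice(150, 900)
        mean_v = straight_sway_walk.cfg.mean_speed
        assert half_ptp(rt.v[mid] - mean_v) <= 0.25 * half_ptp(raw.v[mid] - mean_v)

    def test_heading_oscillation_suppressed(self, straight_sway_walk):
        traj = straight_sway_walk.traj
        raw = estimate_raw_states(traj)
        off = estimate_offline_states(fit_baseline(traj, degree=1))
        params = calibrate_K(raw, off, traj)
        rt = build_realtime_states(traj, params, raw=raw)
        mid = slice(150, 900)
        assert half_ptp(np.unwrap(rt.phi)[mid]) <= 0.10 * half_ptp(np.unwrap(raw.phi)[mid])

    def test_causality_prefix_recompute(self, straight_sway_walk):
        traj = straight_sway_walk.traj
        params = CompensationParams(K=0.4)
        full = build_realtime_states(traj, params)
        m = 600
        prefix = Trajectory(
            t=traj.t[:m], x=traj.x[:m], y=traj.y[:m], phi_pelvis=traj.phi_pelvis[:m]
        )
        part = build_realtime_states(prefix, params)
        stop = m - 2
        np.testing.assert_allclose(part.v[:stop], full.v[:stop], atol=1e-12)
        np.testing.assert_allclose(part.a[:stop], full.a[:stop], atol=1e-12)
        np.testing.assert_allclose(part.phi[:stop], full.phi[:stop], atol=1e-12)
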