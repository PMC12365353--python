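"""Stimulus evaluation, right-hand sides, Euler integration, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peristalsim import model_core as mc
from peristalsim.dynamics import (
    IntegrationError,
    apply_parameter_noise,
    eval_pep,
    eval_stimulus,
    rhs,
    simulate,
    step,
)
from peristalsim.model_core import State
from peristalsim.phase_analysis import single_point_response


def single_swallow(t0=1.0, **kw):
    return mc.StimulusProgram(events=(mc.SwallowEvent(t0=t0, **kw),))


class TestStimulus:
    def test_silent_before_first_event(self):
        dom = mc.make_domain()
        S = eval_stimulus(single_swallow(t0=1.0), dom, t=0.5)
        np.testing.assert_array_equal(S, np.zeros(dom.n_nodes))

    def test_inhibition_phase_covers_body_and_sphincter(self):
        dom = mc.make_domain()
        ev = mc.SwallowEvent(t0=1.0)
        S = eval_stimulus(mc.StimulusProgram(events=(ev,)), dom, t=1.2)
        assert np.all(S[dom.body_mask] == -ev.i_amp)
        assert np.all(S[dom.les_mask] == -ev.i_amp)
        # the oral kick has not started yet (it is delayed)
        assert S.max() < 0

    def test_kick_phase_is_local_and_positive(self):
        dom = mc.make_domain()
        ev = mc.SwallowEvent(t0=1.0)
        S = eval_stimulus(mc.StimulusProgram(events=(ev,)), dom, ev.t0 + ev.s_delay + 0.1)
        oral = dom.x < ev.oral_extent
        assert np.all(S[oral] == ev.s_amp)
        assert np.all(S[~oral] == 0.0)

    def test_next_swallow_inhibition_masks_previous_kick(self):
        """With onsets spaced by the kick delay, the second swallow's body
        inhibition sums with (and overwhelms) the first swallow's kick."""
        dom = mc.make_domain()
        prog = mc.StimulusProgram(
            events=(mc.SwallowEvent(t0=1.0), mc.SwallowEvent(t0=3.0))
        )
        ev = prog.events[0]
        t = ev.t0 + ev.s_delay + 0.1  # inside kick 1 and inhibition 2
        S = eval_stimulus(prog, dom, t)
        oral = dom.x < ev.oral_extent
        assert np.all(S[oral] == ev.s_amp - ev.i_amp)
        assert S.max() < 0

    def test_point_stimulus_window(self):
        dom = mc.make_domain()
        prog = mc.StimulusProgram(
            point_stimuli=(mc.PointStimulus(x=5.0, t0=2.0, amplitude=3.0, width=1.0),)
        )
        S = eval_stimulus(prog, dom, 2.2)
        hit = np.abs(dom.x - 5.0) <= 0.5
        assert np.all(S[hit] == 3.0)
        assert np.all(S[~hit] == 0.0)


class TestPEP:
    def test_zero_amplitude_is_identity(self):
        dom = mc.make_domain()
        W = eval_pep(mc.PEPSpec(), dom, 1.0)
        np.testing.assert_array_equal(W, np.zeros(dom.n_nodes))

    def test_window_confined_to_body_and_time(self):
        dom = mc.make_domain()
        pep = mc.PEPSpec(amplitude=0.8, t_start=3.0, t_end=8.0)
        inside = eval_pep(pep, dom, 5.0)
        assert np.all(inside[dom.body_mask] == 0.8)
        assert np.all(inside[dom.les_mask] == 0.0)
        np.testing.assert_array_equal(eval_pep(pep, dom, 9.0), np.zeros(dom.n_nodes))


class TestRHS:
    def test_rest_state_with_basal_drive(self):
        spec = mc.default_spec()
        prof = spec.profiles.copy()
        prof.B_SM = np.full(spec.domain.n_nodes, 0.4)
        spec = spec.with_(profiles=prof)
        n = spec.domain.n_nodes
        stt = State(0.0, np.zeros(n), np.zeros(n), np.zeros(n))
        dU, dV, dW = rhs(stt, spec, 0.0)
        np.testing.assert_allclose(dU, 0.0, atol=1e-14)
        np.testing.assert_allclose(dV, 0.0, atol=1e-14)
        np.testing.assert_allclose(dW, 0.4, atol=1e-14)

    def test_suprathreshold_cubic_growth(self):
        """At U = 0.5 (above the 0.3 threshold) the local cubic drives the
        neural field up: dU = -10 * 0.5 * 0.2 * (-1.5) = +1.5."""
        spec = mc.default_spec(s_IN=0.0, i_MN=0.0)
        n = spec.domain.n_nodes
        stt = State(0.0, np.full(n, 0.5), np.zeros(n), np.zeros(n))
        dU, _, _ = rhs(stt, spec, 0.0)
        body = spec.domain.body_mask
        np.testing.assert_allclose(dU[body], 1.5, atol=1e-12)

    def test_nan_state_raises_with_location(self):
        spec = mc.default_spec()
        n = spec.domain.n_nodes
        U = np.zeros(n)
        U[37] = np.nan
        stt = State(0.0, U, np.zeros(n), np.zeros(n))
        with pytest.raises(IntegrationError, match="x=3.7"):
            rhs(stt, spec, 0.0)


class TestStep:
    def test_zero_derivative_leaves_state_unchanged(self):
        spec = mc.default_spec(s_IN=0.0, i_MN=0.0)
        st0 = mc.initial_state(spec)
        st1 = step(st0, spec, 0.0, 0.01)
        np.testing.assert_allclose(st1.U, st0.U, atol=1e-11)
        assert st1.t == pytest.approx(0.01)

    def test_euler_arithmetic_from_rest(self):
        spec = mc.default_spec()
        prof = spec.profiles.copy()
        prof.B_SM = np.full(spec.domain.n_nodes, 0.4)
        spec = spec.with_(profiles=prof)
        n = spec.domain.n_nodes
        st0 = State(0.0, np.zeros(n), np.zeros(n), np.zeros(n))
        st1 = step(st0, spec, 0.0, 0.01)
        np.testing.assert_allclose(st1.W, 0.004, atol=1e-14)

    def test_halving_dt_changes_solution_first_order(self, body_params):
        coarse = single_point_response(body_params, 0.5, t_end=1.0, dt=0.01)
        fine = single_point_response(body_params, 0.5, t_end=1.0, dt=0.005)
        finest = single_point_response(body_params, 0.5, t_end=1.0, dt=0.0025)
        e1 = abs(coarse.U[-1] - finest.U[-1])
        e2 = abs(fine.U[-1] - finest.U[-1])
        assert e2 < e1  # refining dt reduces the error


class TestSimulate:
    def test_zero_stimulus_run_is_stationary(self):
        spec = mc.default_spec(t_end=10.0)
        res = simulate(spec, 0)
        for arr in (res.U, res.V, res.W):
            assert np.max(np.abs(arr[-1] - arr[0])) < 1e-6

    def test_normal_swallow_single_anal_pulse_and_sphincter_cycle(
        self, normal_result, w_threshold
    ):
        from peristalsim import metrics as mx

        res = normal_result
        les = res.domain.les_mask
        les_mean = res.W[:, les].mean(axis=1)
        # sphincter relaxes after the swallow and re-contracts at the end
        assert les_mean[(res.times > 2) & (res.times < 5)].min() < 0.2
        assert les_mean[-1] > 1.0
        moving = [t for t in mx.track_fronts(res, w_threshold) if not t.is_static]
        assert len(moving) == 1
        assert moving[0].direction == "anal"

    def test_recovery_field_stays_nonnegative(self, normal_result):
        assert normal_result.V.min() >= -1e-12

    def test_deterministic_without_noise(self, normal_spec):
        a = simulate(normal_spec, 0)
        b = simulate(normal_spec, 123)
        np.testing.assert_array_equal(a.U, b.U)
        np.testing.assert_array_equal(a.W, b.W)

    def test_instability_guard_names_smaller_dt(self):
        spec = mc.default_spec(dt=0.2, t_end=5.0, program=single_swallow())
        with pytest.raises(IntegrationError, match="smaller dt"):
            simulate(spec, 0)


class TestNoPostInhibitoryRebound:
    @settings(max_examples=20, deadline=None)
    @given(
        st.floats(min_value=0.5, max_value=20.0),
        st.floats(min_value=0.2, max_value=3.0),
    )
    def test_release_from_any_negative_pulse_returns_to_rest(self, amp, dur):
        """A purely inhibitory stimulus never triggers an excitation on
        release: the rectified recovery source leaves no rebound."""
        p = mc.default_body_params()
        g, c = mc.CUBIC_GAIN, mc.RECOVERY_COUPLING
        dt, t_end = 0.01, dur + 10.0
        U = V = 0.0
        peak_after_release = -np.inf
        for k in range(int(round(t_end / dt))):
            t = k * dt
            s = -amp if t < dur else 0.0
            cubic = U * (U - 0.3) * (U - 2.0)
            U, V = U + dt * (-g * (cubic + c * V) + s), V + dt * (max(U, 0.0) - 0.6 * V)
            if t >= dur:
                peak_after_release = max(peak_after_release, U)
        threshold = p.T_ENS * p.A_ENS
        assert peak_after_release < threshold


class TestParameterNoise:
    def test_null_noise_is_identity(self):
        spec = mc.default_spec()
        rng = np.random.default_rng(0)
        prof, s_eff, _ = apply_parameter_noise(
            spec.profiles, mc.NoiseSpec(), rng, spec.domain, spec.s_IN
        )
        np.testing.assert_array_equal(prof.T_ENS, spec.profiles.T_ENS)
        assert s_eff == spec.s_IN

    def test_threshold_shift_spares_the_sphincter(self):
        spec = mc.default_spec()
        noise = mc.NoiseSpec(target="T_ENS", mean_shift=0.1, sd=0.0)
        prof, _, _ = apply_parameter_noise(
            spec.profiles, noise, np.random.default_rng(0), spec.domain, 1.0
        )
        body, les = spec.domain.body_mask, spec.domain.les_mask
        np.testing.assert_allclose(prof.T_ENS[body], 0.4)
        np.testing.assert_allclose(prof.T_ENS[les], 0.3)

    def test_invalid_target_rejected(self):
        with pytest.raises(mc.ConfigurationError):
            mc.NoiseSpec(target="D_SM")

    def test_mean_shift_above_threshold_blocks_the_swallow(self, w_threshold):
        from peristalsim.metrics import transmitted_count

        spec = mc.default_spec(
            t_end=20.0,
            program=single_swallow(),
            noise=mc.NoiseSpec(target="T_ENS", mean_shift=0.3, sd=0.0),
        )
        res = simulate(spec, 0)
        assert transmitted_count(res, w_threshold) == 0

    def test_seeded_draws_reproduce(self):
        spec = mc.default_spec(
            t_end=12.0,
            program=single_swallow(),
            noise=mc.NoiseSpec(target="T_ENS", mean_shift=0.0, sd=0.05),
        )
        a = simulate(spec, 7)
        b = simulate(spec, 7)
        np.testing.assert_array_equal(a.noise_draws, b.noise_draws)
        np.testing.assert_array_equal(a.U, b.U)


class TestGridRobustness:
    def test_halving_dx_and_dt_preserves_pulse_speed(self):
        """Refining the grid changes the measured normal pulse speed by
        well under 5% — the numerics, not the grid, set the speed."""
        from peristalsim.metrics import measure_u_front_speed

        speeds = {}
        for dx, dt in ((0.1, 0.01), (0.05, 0.005)):
            dom = mc.make_domain(dx=dx)
            prof = mc.make_profiles(
                mc.default_body_params(), mc.default_les_params(), dom
            )
            spec = mc.ModelSpec(
                domain=dom,
                profiles=prof,
                dt=dt,
                t_end=20.0,
                save_stride=max(1, int(round(0.1 / dt))),
                program=single_swallow(),
            )
            speeds[dx] = measure_u_front_speed(spec)
        rel = abs(speeds[0.05] - speeds[0.1]) / speeds[0.1]
        assert rel < 0.05
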