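"""Closed-form phase-plane analysis against brute-force oracles."""

import numpy as np
import pytest

from peristalsim import model_core as mc
from peristalsim import phase_analysis as pa
from peristalsim.model_core import CUBIC_GAIN, RECOVERY_COUPLING, LocalParams


def sign_scan_roots(p, lo=-1.0, hi=None, step=1e-4):
    """Independent oracle: roots of the reduced steady-state equation
    h(U) = cubic(U) + c * max(U,0)/D by sign-change scan."""
    if hi is None:
        hi = 3.0 * p.A_ENS
    U = np.arange(lo, hi, step)
    h = (
        U * (U - p.T_ENS * p.A_ENS) * (U - 2.0 * p.A_ENS)
        + RECOVERY_COUPLING * np.maximum(U, 0.0) / p.D_ENS
    )
    sgn = np.sign(h)
    crossings = np.flatnonzero(np.diff(sgn) != 0)
    roots = []
    for i in crossings:
        roots.append(0.5 * (U[i] + U[i + 1]))
    return roots


def lp(D, T=0.3, A=1.0):
    return LocalParams(D_ENS=D, T_ENS=T, A_ENS=A, E_SM=1, D_SM=1, B_SM=0)


class TestLocalEquilibria:
    def test_bistable_sphincter_values(self):
        eqs = pa.local_equilibria(lp(100.0))
        assert [e.branch for e in eqs] == ["rest", "threshold", "upper"]
        assert eqs[1].U == pytest.approx(0.3029, abs=2e-4)
        assert eqs[2].U == pytest.approx(1.9971, abs=2e-4)
        assert [e.stability for e in eqs] == ["stable", "unstable", "stable"]
        for e in eqs:
            assert e.V == pytest.approx(max(e.U, 0.0) / 100.0)

    def test_excitable_body_has_single_rest_state(self):
        eqs = pa.local_equilibria(lp(0.6))
        assert len(eqs) == 1
        assert eqs[0].U == 0.0
        assert eqs[0].stability == "stable"

    def test_amplitude_scaling_preserves_structure(self):
        base = pa.local_equilibria(lp(100.0, A=1.0))
        scaled = pa.local_equilibria(lp(100.0, A=2.0))
        assert len(scaled) == len(base)
        assert scaled[0].U == 0.0
        assert scaled[2].U > base[2].U  # positive roots grow with A

    def test_agrees_with_sign_scan_oracle_on_random_draws(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            p = lp(
                D=float(rng.uniform(0.2, 150.0)),
                T=float(rng.uniform(0.05, 1.5)),
                A=float(rng.uniform(0.3, 2.0)),
            )
            closed = sorted(e.U for e in pa.local_equilibria(p))
            scanned = sign_scan_roots(p)
            # the scan sees a sign change at every simple root incl. 0
            assert len(scanned) == len(closed)
            for u_c, u_s in zip(closed, scanned):
                assert u_c == pytest.approx(u_s, abs=5e-4)

    def test_stability_labels_agree_with_simulation(self):
        p = lp(100.0)
        eqs = pa.local_equilibria(p)
        for eq in eqs:
            if eq.stability != "stable":
                continue
            r = pa.single_point_response(
                p, 0.0, t_end=20.0, U0=eq.U + 0.01, V0=eq.V
            )
            assert r.U[-1] == pytest.approx(eq.U, abs=0.05)
        # the threshold saddle repels: a nudge ends up at rest or upper
        saddle = eqs[1]
        r = pa.single_point_response(p, 0.0, t_end=20.0, U0=saddle.U + 0.01, V0=saddle.V)
        assert abs(r.U[-1] - saddle.U) > 0.5


class TestRegimeClassification:
    def test_printed_regimes(self):
        assert pa.classify_regime(lp(100.0)) == "bistable"
        assert pa.classify_regime(lp(0.6)) == "excitable"

    def test_boundary_is_excitable_by_convention(self):
        p = lp(1.0)
        d_star = pa.bistability_boundary_D(p)
        assert pa.classify_regime(lp(d_star)) == "excitable"
        assert pa.classify_regime(lp(d_star * 1.01)) == "bistable"

    def test_boundary_formula(self):
        assert pa.bistability_boundary_D(lp(1.0)) == pytest.approx(2.0 / 2.89, rel=1e-9)
        assert pa.bistability_boundary_D(lp(1.0, T=1.0)) == pytest.approx(2.0)
        # D* shrinks as the amplitude grows
        assert pa.bistability_boundary_D(lp(1.0, A=2.0)) < pa.bistability_boundary_D(
            lp(1.0, A=1.0)
        )

    def test_boundary_against_root_counting(self):
        p = lp(1.0)
        d_star = pa.bistability_boundary_D(p)
        for D in np.linspace(0.3, 2.0, 25):
            n_roots = len(sign_scan_roots(lp(D)))
            expected = 3 if D > d_star else 1
            if abs(D - d_star) > 0.02:  # away from the degenerate tangency
                assert n_roots == expected, f"D={D}"

    def test_invariant_under_rescaling_preserving_discriminant(self):
        # (A(2 - T))^2 * D fixed => same regime
        base = lp(0.9, T=0.3, A=1.0)
        scaled = lp(0.9 / 4.0, T=0.3, A=2.0)
        assert pa.classify_regime(base) == pa.classify_regime(scaled)


class TestNullclines:
    def test_both_curves_pass_through_origin(self, body_params):
        U = np.linspace(-0.5, 2.5, 301)
        vu, vv = pa.nullclines(body_params, U)
        i0 = np.argmin(np.abs(U))
        assert vu[i0] == pytest.approx(0.0, abs=1e-9)
        assert vv[i0] == pytest.approx(0.0, abs=1e-9)

    def test_u_nullcline_vanishes_at_twice_amplitude(self, body_params):
        vu, _ = pa.nullclines(body_params, np.array([2.0]))
        assert vu[0] == pytest.approx(0.0, abs=1e-12)

    def test_intersections_reproduce_equilibria(self, les_params):
        U = np.linspace(-0.2, 2.5, 270001)
        vu, vv = pa.nullclines(les_params, U)
        diff = vu - vv
        raw = U[np.flatnonzero(np.diff(np.sign(diff)) != 0)]
        crossings = []
        for u in sorted(raw):  # merge duplicates from exact zeros at the kink
            if not crossings or u - crossings[-1] > 1e-3:
                crossings.append(u)
        eqs = sorted(e.U for e in pa.local_equilibria(les_params))
        assert len(crossings) == len(eqs)
        for u_c, u_e in zip(crossings, eqs):
            assert u_c == pytest.approx(u_e, abs=1e-4)


class TestSinglePointResponse:
    def test_suprathreshold_kick_reaches_twice_amplitude(self, body_params):
        r = pa.single_point_response(body_params, 0.5)
        assert r.peak_U == pytest.approx(2.0 * body_params.A_ENS, rel=0.1)

    def test_subthreshold_kick_decays(self, body_params):
        r = pa.single_point_response(body_params, 0.1)
        assert r.peak_U <= 0.1 + 1e-12
        assert abs(r.U[-1]) < 1e-3

    def test_negative_kick_toggles_sphincter_off(self, les_params):
        upper = [e for e in pa.local_equilibria(les_params) if e.branch == "upper"][0]
        r = pa.single_point_response(
            les_params, -1.9, t_end=20.0, U0=upper.U, V0=upper.V
        )
        assert r.U[-1] == pytest.approx(0.0, abs=1e-3)


class TestSpeedPrediction:
    def test_surrogate_tracks_full_model_in_wide_kernel_regime(self):
        """In the regime where the kernel is wide relative to the front
        interface the moment expansion predicts the measured speed closely;
        this is the regime the reaction-diffusion approximation targets."""
        spec = _analysis_spec(s_IN=1.0)
        pred, meas = pa.predict_pulse_speed(spec)
        assert pred == pytest.approx(meas, rel=0.2)

    def test_speeds_increase_with_coupling_strength(self):
        p1, m1 = pa.predict_pulse_speed(_analysis_spec(s_IN=0.7))
        p2, m2 = pa.predict_pulse_speed(_analysis_spec(s_IN=1.0))
        assert p2 > p1 and m2 > m1


def _analysis_spec(s_IN=1.0, r_IN=2.0, d_IN=2.5, length=80.0):
    dom = mc.make_domain(length=length, dx=0.1, x_les=length - 1.0, x_cdp=length - 3.0)
    body = mc.default_body_params()
    prof = mc.make_profiles(body, body, dom)
    return mc.ModelSpec(
        domain=dom,
        profiles=prof,
        t_end=6.0,
        s_IN=s_IN,
        r_IN=r_IN,
        d_IN=d_IN,
        require_bistable_les=False,
        program=mc.StimulusProgram(
            point_stimuli=(mc.PointStimulus(x=2.0, t0=0.2, amplitude=3.0, width=1.0),)
        ),
    )
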