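"""Time integration of the coupled neural–muscle model.

The state is three fields on the grid:

* ``U`` — enteric neural activity, a spatially heterogeneous modified
  FitzHugh–Nagumo variable coupled nonlocally through the interneuron
  kernel;
* ``V`` — neural recovery, fed by the rectified activity ``max(U, 0)`` so a
  purely negative (inhibitory) stimulus leaves no rebound when released;
* ``W`` — smooth-muscle activation, driven locally by ``U`` and nonlocally
  inhibited through the motoneuron kernel (dilatation anal to the pulse).

Right-hand sides (V inhibits U; g = 10, c = 0.5 fixed):

    dU/dt = -g (U (U - T_ENS A_ENS)(U - 2 A_ENS) + c V) + K_IN*U + S_CNS(x,t)
    dV/dt = max(U, 0) - D_ENS V
    dW/dt = E_SM U - D_SM W + B_SM + K_MN*U + W_PEP(x,t)

Integration is plain explicit Euler (dt = 0.01, dx = 0.1 canonically).
``simulate`` first relaxes the analytic initial state for a non-recorded
equilibration interval so the recorded run starts from the true resting
state of the nonlocal system, then integrates the stimulus program,
optionally applying one scalar noise draw per swallow to a body parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coupling
from .model_core import (
    CUBIC_GAIN,
    RECOVERY_COUPLING,
    ConfigurationError,
    ModelSpec,
    NoiseSpec,
    PEPSpec,
    ProfileSet,
    SpatialDomain,
    State,
    StimulusProgram,
    initial_state,
    validate,
)

__all__ = [
    "SimulationResult",
    "eval_stimulus",
    "eval_pep",
    "rhs",
    "step",
    "simulate",
    "apply_parameter_noise",
]

#: instability guard: integration aborts when any |field| exceeds this bound
FIELD_BOUND = 1e3


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimulationResult:
    """Recorded trajectory of one simulation."""

    times: np.ndarray  # (n_frames,)
    U: np.ndarray  # (n_frames, n_nodes)
    V: np.ndarray
    W: np.ndarray
    spec: ModelSpec
    noise_draws: np.ndarray  # per-swallow scalar draws actually applied

    @property
    def domain(self) -> SpatialDomain:
        return self.spec.domain

    def frame_at(self, t: float) -> int:
        """Index of the recorded frame closest to time ``t``."""
        return int(np.argmin(np.abs(self.times - t)))


def eval_stimulus(
    program: StimulusProgram, domain: SpatialDomain, t: float
) -> np.ndarray:
    """The CNS signal S_CNS(x, t): oral kick plus deglutitive inhibition.

    Each swallow contributes ``+s_amp`` on the oral-most ``oral_extent``
    during its kick window, ``-i_amp`` on the body during the body
    inhibition window and ``-i_amp`` on the LES during the LES inhibition
    window.  Overlapping events sum — this is what lets a later swallow's
    inhibition mask the pulse of an earlier one during multiple rapid
    swallows.
    """
    x = domain.x
    S = np.zeros(domain.n_nodes)
    for ev in program.events:
        if t >= ev.t0 and t < ev.t0 + ev.inhib_body_duration:
            S[domain.body_mask] -= ev.i_amp
        if t >= ev.t0 and t < ev.t0 + ev.inhib_les_duration:
            S[domain.les_mask] -= ev.i_amp
        ks, kd = ev.t0 + ev.s_delay, ev.t0 + ev.s_delay + ev.s_duration
        if ks <= t < kd:
            S[x < ev.oral_extent] += ev.s_amp
    for ps in program.point_stimuli:
        if ps.t0 <= t < ps.t0 + ps.duration:
            S[np.abs(x - ps.x) <= ps.width / 2.0] += ps.amplitude
    return S


def eval_pep(pep: PEPSpec, domain: SpatialDomain, t: float) -> np.ndarray:
    """Pan-oesophageal pressurization drive W_PEP(x, t)."""
    W = np.zeros(domain.n_nodes)
    if pep.amplitude == 0.0 or not (pep.t_start <= t < pep.t_end):
        return W
    x_end = domain.x_les if pep.x_end is None else pep.x_end
    window = (domain.x >= pep.x_start) & (domain.x < x_end)
    W[window] = pep.amplitude
    return W


def _check_finite(name: str, arr: np.ndarray, t: float, domain: SpatialDomain):
    bad = ~np.isfinite(arr)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise IntegrationError(
            f"non-finite {name} at x={domain.x[i]:.2f}, t={t:.3f}"
        )


def rhs(
    state: State,
    spec: ModelSpec,
    t: float,
    profiles: ProfileSet | None = None,
    k_in: coupling.DiscreteKernel | None = None,
    k_mn: coupling.DiscreteKernel | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-hand sides (dU, dV, dW) at time ``t``.

    ``profiles`` and prebuilt kernels may be supplied to avoid rebuilding
    them every step (used by :func:`simulate`, and by the noise machinery
    which swaps in perturbed profiles per swallow).
    """
    p = profiles if profiles is not None else spec.profiles
    if k_in is None:
        k_in = coupling.build_interneuron_kernel(
            spec.s_IN, spec.r_IN, spec.d_IN, spec.domain.dx
        )
    if k_mn is None:
        k_mn = coupling.build_motoneuron_kernel(spec.i_MN, spec.r_MN, spec.domain.dx)
    U, V, W = state.U, state.V, state.W
    for name, arr in (("U", U), ("V", V), ("W", W)):
        _check_finite(name, arr, t, spec.domain)
    g, c = CUBIC_GAIN, RECOVERY_COUPLING
    cubic = U * (U - p.T_ENS * p.A_ENS) * (U - 2.0 * p.A_ENS)
    S = eval_stimulus(spec.program, spec.domain, t)
    dU = -g * (cubic + c * V) + coupling.convolve(k_in, U) + S
    dV = np.maximum(U, 0.0) - p.D_ENS * V
    dW = (
        p.E_SM * U
        - p.D_SM * W
        + p.B_SM
        + coupling.convolve(k_mn, U)
        + eval_pep(spec.pep, spec.domain, t)
    )
    return dU, dV, dW


def step(state: State, spec: ModelSpec, t: float, dt: float, **kw) -> State:
    """One forward-Euler update of all three fields."""
    dU, dV, dW = rhs(state, spec, t, **kw)
    return State(
        t=t + dt, U=state.U + dt * dU, V=state.V + dt * dV, W=state.W + dt * dW
    )


def apply_parameter_noise(
    profiles: ProfileSet,
    noise: NoiseSpec,
    rng: np.random.Generator,
    domain: SpatialDomain,
    s_IN: float = 1.0,
) -> tuple[ProfileSet, float, float]:
    """One per-swallow noise application.

    Draws a single standard-normal scalar from ``rng`` (the fluctuation
    models a slow autonomic drift, not per-node channel noise) and shifts
    the body value of the noise target by ``mean_shift + sd * draw``; LES
    values are untouched.  Returns ``(profiles, s_IN_effective, draw)`` —
    for the ``T_ENS`` target a perturbed profile copy, for the ``s_IN``
    target the perturbed kernel amplitude.
    """
    if noise.target not in ("T_ENS", "s_IN"):
        raise ConfigurationError("noise target must be 'T_ENS' or 's_IN'")
    draw = float(rng.standard_normal())
    prof, s_eff = _apply_draw(profiles, noise, draw, domain, s_IN)
    return prof, s_eff, draw


def _apply_draw(
    profiles: ProfileSet,
    noise: NoiseSpec,
    draw: float,
    domain: SpatialDomain,
    s_IN: float,
) -> tuple[ProfileSet, float]:
    delta = noise.mean_shift + noise.sd * draw
    if noise.target == "T_ENS":
        prof = profiles.copy()
        prof.T_ENS = prof.T_ENS + delta * domain.body_mask
        return prof, s_IN
    return profiles, s_IN + delta


def simulate(spec: ModelSpec, seed: int = 0) -> SimulationResult:
    """Integrate the model from its resting state through the stimulus program.

    The analytic initial state is first relaxed for ``equilibration_time``
    (not recorded) so that t = 0 starts from the true nonlocal resting
    state.  One scalar noise draw per swallow event perturbs the configured
    body parameter from that swallow's onset until the next onset (or the
    end of the run).  Deterministic given ``(spec, seed)``.
    """
    rep = validate(spec)
    if not rep.valid:
        raise ConfigurationError("invalid spec: " + "; ".join(rep.violations))
    dom = spec.domain
    dt = spec.dt
    k_in = coupling.build_interneuron_kernel(spec.s_IN, spec.r_IN, spec.d_IN, dom.dx)
    k_mn = coupling.build_motoneuron_kernel(spec.i_MN, spec.r_MN, dom.dx)

    state = initial_state(spec)
    # non-recorded equilibration with no stimulus
    quiet = spec.with_(program=StimulusProgram(), pep=PEPSpec())
    n_eq = int(round(spec.equilibration_time / dt))
    for k in range(n_eq):
        state = step(state, quiet, -spec.equilibration_time + k * dt, dt,
                     k_in=k_in, k_mn=k_mn)
        _guard(state, dom, dt)
    state.t = 0.0

    events = spec.program.events
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal(len(events)) if events else np.zeros(0)

    # per-swallow parameter windows: [t0_i, t0_{i+1})
    def params_for_window(idx: int):
        if spec.noise.is_null or idx < 0:
            return spec.profiles, k_in
        prof, s_in = _apply_draw(
            spec.profiles, spec.noise, draws[idx], dom, spec.s_IN
        )
        if s_in != spec.s_IN:
            kern = coupling.build_interneuron_kernel(
                max(s_in, 0.0), spec.r_IN, spec.d_IN, dom.dx
            )
            return prof, kern
        return prof, k_in

    n_steps = int(round(spec.t_end / dt))
    frames = range(0, n_steps + 1, spec.save_stride)
    n_frames = len(frames)
    times = np.empty(n_frames)
    Uo = np.empty((n_frames, dom.n_nodes))
    Vo = np.empty_like(Uo)
    Wo = np.empty_like(Uo)

    fi = 0
    cached_window = None
    prof, kern = spec.profiles, k_in
    for k in range(n_steps + 1):
        t = k * dt
        if k % spec.save_stride == 0:
            times[fi] = t
            Uo[fi], Vo[fi], Wo[fi] = state.U, state.V, state.W
            fi += 1
        if k == n_steps:
            break
        if not spec.noise.is_null and events:
            # recompute the active-parameter window only at swallow onsets
            widx = sum(1 for ev in events if t >= ev.t0) - 1
            if widx != cached_window:
                prof, kern = params_for_window(widx)
                cached_window = widx
        state = step(state, spec, t, dt, profiles=prof, k_in=kern, k_mn=k_mn)
        _guard(state, dom, dt)
    return SimulationResult(
        times=times, U=Uo, V=Vo, W=Wo, spec=spec, noise_draws=draws
    )


def _guard(state: State, dom: SpatialDomain, dt: float) -> None:
    for name, arr in (("U", state.U), ("V", state.V), ("W", state.W)):
        m = np.abs(arr).max()
        if not np.isfinite(m) or m > FIELD_BOUND:
            i = int(np.argmax(np.abs(arr)))
            raise IntegrationError(
                f"|{name}| = {m:.3g} exceeded the stability bound at "
                f"x={dom.x[i]:.2f}, t={state.t:.3f}; try a smaller dt"
            )
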