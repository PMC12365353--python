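"""Space-clamped phase-plane analysis of the neural layer.

At a single node (kernel contributions excluded) the neural dynamics reduce
to the planar system

    dU/dt = -g * ( U (U - T A) (U - 2A) + c V )
    dV/dt = max(U, 0) - D V

with cubic gain ``g = 10``, recovery coupling ``c = 0.5``, threshold
fraction ``T = T_ENS``, amplitude ``A = A_ENS`` and recovery decay
``D = D_ENS``.  V inhibits U, so the system is a standard excitable /
bistable FitzHugh–Nagumo variant with a rectified recovery source (the
rectifier removes post-inhibitory rebound).

Equilibria are closed-form: ``U* = 0`` always, and positive equilibria are
the roots of the quadratic ``(U - T A)(U - 2A) = -c/D``.  The system is

* **excitable** (single stable rest state) when the quadratic has no two
  distinct positive roots — the oesophageal body (``D = 0.6``);
* **bistable** (rest + tonically active state separated by a threshold
  saddle) otherwise — the LES (``D = 100``).

The bistability boundary in ``D`` is ``D* = 4c / (A(2 - T))²``
(``= 2 / (A(2 - T))²`` with ``c = 0.5``); see
:func:`bistability_boundary_D`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import CUBIC_GAIN, RECOVERY_COUPLING, LocalParams

__all__ = [
    "Equilibrium",
    "local_equilibria",
    "classify_regime",
    "bistability_boundary_D",
    "nullclines",
    "single_point_response",
    "predict_pulse_speed",
]


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the space-clamped (U, V) system."""

    U: float
    V: float
    stability: str  # "stable" | "unstable"
    branch: str  # "rest" | "threshold" | "upper"


def _cubic(U, T, A):
    return U * (U - T * A) * (U - 2.0 * A)


def _cubic_deriv(U, T, A):
    a, b = T * A, 2.0 * A
    return 3.0 * U**2 - 2.0 * (a + b) * U + a * b


def _stability(U: float, p: LocalParams) -> str:
    """Linear stability from the 2x2 Jacobian.

    The rectifier's right-hand derivative is used at U = 0 (r'(0) = 1 by
    convention).
    """
    g, c = CUBIC_GAIN, RECOVERY_COUPLING
    j11 = -g * _cubic_deriv(U, p.T_ENS, p.A_ENS)
    j12 = -g * c
    j21 = 1.0 if U >= 0 else 0.0
    j22 = -p.D_ENS
    tr = j11 + j22
    det = j11 * j22 - j12 * j21
    return "stable" if (det > 0 and tr < 0) else "unstable"


def local_equilibria(p: LocalParams) -> list[Equilibrium]:
    """All steady states of the space-clamped system, closed form.

    ``U* = 0`` always; positive equilibria solve
    ``(U - T A)(U - 2A) = -c/D`` i.e.
    ``U² - A(T + 2) U + (2 T A² + c/D) = 0``, kept only when real, distinct
    and positive.  ``V* = max(U*, 0)/D``.
    """
    T, A, D = p.T_ENS, p.A_ENS, p.D_ENS
    c = RECOVERY_COUPLING
    out = [Equilibrium(0.0, 0.0, _stability(0.0, p), "rest")]
    bq = -A * (T + 2.0)
    cq = 2.0 * T * A**2 + c / D
    disc = bq * bq - 4.0 * cq
    if disc > 0:
        sq = np.sqrt(disc)
        roots = sorted(((-bq - sq) / 2.0, (-bq + sq) / 2.0))
        if all(r > 0 for r in roots) and roots[0] != roots[1]:
            out.append(
                Equilibrium(roots[0], roots[0] / D, _stability(roots[0], p), "threshold")
            )
            out.append(
                Equilibrium(roots[1], roots[1] / D, _stability(roots[1], p), "upper")
            )
    return out


def classify_regime(p: LocalParams) -> str:
    """``"bistable"`` iff two distinct positive equilibria exist (strict
    inequality at the boundary), else ``"excitable"``."""
    return "bistable" if len(local_equilibria(p)) == 3 else "excitable"


def bistability_boundary_D(p: LocalParams) -> float:
    """Critical recovery decay ``D*`` above which the node is bistable.

    Two distinct positive roots of ``(U - TA)(U - 2A) = -c/D`` exist iff
    ``-c/D`` exceeds the parabola minimum ``-(A(2 - T))²/4``, i.e.
    ``D > D* = 4c / (2A - TA)²`` (``= 2/(2A - TA)²`` with ``c = 0.5``).
    """
    return 4.0 * RECOVERY_COUPLING / (2.0 * p.A_ENS - p.T_ENS * p.A_ENS) ** 2


def nullclines(p: LocalParams, U_range: np.ndarray):
    """Sampled nullclines on ``U_range``.

    U-nullcline: ``V = -cubic(U)/c`` (where dU/dt = 0);
    V-nullcline: ``V = max(U, 0)/D``.
    Returns ``(V_u, V_v)`` arrays aligned with ``U_range``.
    """
    U = np.asarray(U_range, dtype=float)
    V_u = -_cubic(U, p.T_ENS, p.A_ENS) / RECOVERY_COUPLING
    V_v = np.maximum(U, 0.0) / p.D_ENS
    return V_u, V_v


@dataclass
class PointResponse:
    t: np.ndarray
    U: np.ndarray
    V: np.ndarray

    @property
    def peak_U(self) -> float:
        return float(self.U.max())


def single_point_response(
    p: LocalParams,
    kick_amplitude: float,
    t_end: float = 10.0,
    dt: float = 0.01,
    U0: float | None = None,
    V0: float = 0.0,
) -> PointResponse:
    """Space-clamped Euler trajectory from an initial kick.

    By default integrates from ``(kick_amplitude, 0)``.  Supplying ``U0``
    instead starts from ``(U0 + kick_amplitude, V0)`` — useful for kicking
    the bistable node out of its upper state.  A supra-threshold kick in the
    excitable regime produces an excursion whose peak U is close to
    ``2 A_ENS``.
    """
    g, c = CUBIC_GAIN, RECOVERY_COUPLING
    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    U = np.empty(n + 1)
    V = np.empty(n + 1)
    U[0] = kick_amplitude if U0 is None else U0 + kick_amplitude
    V[0] = V0
    for k in range(n):
        du = -g * (_cubic(U[k], p.T_ENS, p.A_ENS) + c * V[k])
        dv = max(U[k], 0.0) - p.D_ENS * V[k]
        U[k + 1] = U[k] + dt * du
        V[k + 1] = V[k] + dt * dv
    return PointResponse(t=t, U=U, V=V)


# ---------------------------------------------------------------------------
# surrogate-PDE pulse-speed prediction


def _surrogate_front_speed(
    p: LocalParams,
    coeffs,
    length: float = 30.0,
    dx: float = 0.1,
    dt: float | None = None,
    t_end: float = 4.0,
    threshold: float = 1.0,
) -> float:
    """Front speed of the advection–diffusion surrogate PDE.

    Integrates ``U_t = -g(cubic + cV) + M0 U - M1 U_x + (M2/2) U_xx``,
    ``V_t = r(U) - D V`` from a localized seed at the oral end and fits the
    leading-edge position of ``U > threshold`` against time.  Central
    differences for U_x, standard 3-point Laplacian, zero-padded boundaries.
    ``dt`` defaults to a value safely below the explicit diffusive and
    advective stability limits of the kernel at hand.
    """
    g, c = CUBIC_GAIN, RECOVERY_COUPLING
    if dt is None:
        dt = 2e-4
        if coeffs.diffusion > 0:
            dt = min(dt, 0.1 * dx**2 / (2.0 * coeffs.diffusion))
        if coeffs.advection > 0:
            dt = min(dt, 0.1 * dx / coeffs.advection)
    n = int(round(length / dx)) + 1
    x = np.arange(n) * dx
    U = np.where(x < 1.0, 2.0 * p.A_ENS, 0.0)
    V = np.zeros(n)
    M0, M1, D2 = coeffs.linear_gain, coeffs.advection, coeffs.diffusion
    steps = int(round(t_end / dt))
    record_every = max(1, int(round(0.05 / dt)))
    ts, edges = [], []
    Upad = np.zeros(n + 2)
    for k in range(steps):
        Upad[1:-1] = U
        ux = (Upad[2:] - Upad[:-2]) / (2.0 * dx)
        uxx = (Upad[2:] - 2.0 * Upad[1:-1] + Upad[:-2]) / dx**2
        du = (
            -g * (_cubic(U, p.T_ENS, p.A_ENS) + c * V)
            + M0 * U
            - M1 * ux
            + D2 * uxx
        )
        dv = np.maximum(U, 0.0) - p.D_ENS * V
        U = U + dt * du
        V = V + dt * dv
        if k % record_every == 0:
            above = np.flatnonzero(U > threshold)
            if above.size:
                ts.append(k * dt)
                edges.append(x[above[-1]])
    ts, edges = np.asarray(ts), np.asarray(edges)
    # drop frames once the front nears the far boundary
    keep = edges < length - 3.0
    ts, edges = ts[keep], edges[keep]
    if ts.size < 5 or edges[-1] - edges[0] < 2.0:
        raise RuntimeError("no travelling front detected in the surrogate PDE")
    slope = np.polyfit(ts, edges, 1)[0]
    return float(slope)


def predict_pulse_speed(spec) -> tuple[float, float]:
    """(predicted, measured) body pulse speed for a model specification.

    The prediction integrates the moment-expansion surrogate PDE of the
    interneuron coupling; the measurement runs the full nonlocal model with
    the spec's swallow program (or a default single swallow) and fits the
    leading edge of the neural pulse.  Both are leading-edge speeds of U in
    the body, oral of the deceleration point.
    """
    from . import coupling, dynamics, metrics

    kern = coupling.build_interneuron_kernel(
        spec.s_IN, spec.r_IN, spec.d_IN, spec.domain.dx
    )
    coeffs = coupling.advection_diffusion_surrogate(kern)
    body = spec.profiles.local(0)
    # rough speed scale fixes the surrogate domain length so fast fronts
    # have room to reach their asymptotic speed
    v_rough = coeffs.advection + np.sqrt(
        4.0 * CUBIC_GAIN * max(coeffs.diffusion, 0.0)
    )
    length = max(30.0, 10.0 + 4.0 * v_rough * 4.0)
    predicted = _surrogate_front_speed(body, coeffs, length=length)
    measured = metrics.measure_u_front_speed(spec)
    return predicted, measured
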