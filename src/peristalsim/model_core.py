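"""Model geometry, parameter profiles and simulation specification.

The oesophagus is a 1-D segment of (dimensionless) length ``length`` with
``x`` increasing oral → anal.  The distal window ``x >= x_les`` is the lower
oesophageal sphincter (LES); everything oral of it is the oesophageal body.
``x_cdp`` marks the contractile deceleration point, used only by the display
transform.

Each node carries local parameters for the neural layer (excitation threshold
fraction ``T_ENS``, amplitude ``A_ENS``, recovery decay ``D_ENS``) and the
muscle layer (neuromuscular efficacy ``E_SM``, decay ``D_SM``, basal drive
``B_SM``).  A :class:`ProfileSet` holds one array per parameter, built from a
body value and an LES value with an optional linear ramp across ``x_les``.
The body is parameterised in the excitable regime (single resting state), the
LES in the bistable regime (rest and tonically contracted states coexist),
which is what lets the sphincter behave as a toggle switch.

All quantities are in nondimensional model units; no physical calibration is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "SpatialDomain",
    "LocalParams",
    "ProfileSet",
    "ModelConstants",
    "SwallowEvent",
    "StimulusProgram",
    "PointStimulus",
    "PEPSpec",
    "NoiseSpec",
    "ModelSpec",
    "State",
    "ValidationReport",
    "make_domain",
    "make_profiles",
    "initial_state",
    "validate",
    "default_body_params",
    "default_les_params",
    "default_spec",
]

# Fixed coefficients of the neural cubic (see ModelConstants).
CUBIC_GAIN = 10.0
RECOVERY_COUPLING = 0.5
#: Sign convention of the recovery term in dU/dt: -1 means V inhibits U
#: (dU contains -CUBIC_GAIN*RECOVERY_COUPLING*V).  Kept as a switchable
#: constant for auditability of the sign convention.
RECOVERY_SIGN = -1.0


class ConfigurationError(ValueError):
    """Raised for inconsistent model configuration."""


@dataclass(frozen=True)
class SpatialDomain:
    """Simulation geometry.  ``x`` increases oral → anal."""

    length: float = 10.0
    dx: float = 0.1
    x_les: float = 9.0
    x_cdp: float = 7.0

    def __post_init__(self) -> None:
        if not (0 < self.dx < self.length):
            raise ConfigurationError("require 0 < dx < length")
        if not (0 < self.x_cdp < self.x_les < self.length):
            raise ConfigurationError("require 0 < x_cdp < x_les < length")

    @property
    def n_nodes(self) -> int:
        return int(round(self.length / self.dx)) + 1

    @property
    def x(self) -> np.ndarray:
        """Grid coordinates x_i = i*dx."""
        return np.arange(self.n_nodes) * self.dx

    @property
    def les_mask(self) -> np.ndarray:
        """Boolean mask of LES nodes (x >= x_les)."""
        return self.x >= self.x_les - 1e-12

    @property
    def body_mask(self) -> np.ndarray:
        return ~self.les_mask

    def index_of(self, x: float) -> int:
        """Nearest grid index of a physical coordinate."""
        return int(round(x / self.dx))


def make_domain(
    length: float = 10.0, dx: float = 0.1, x_les: float = 9.0, x_cdp: float = 7.0
) -> SpatialDomain:
    """Construct a validated :class:`SpatialDomain`."""
    return SpatialDomain(length=length, dx=dx, x_les=x_les, x_cdp=x_cdp)


@dataclass(frozen=True)
class LocalParams:
    """Node-local parameters of the neural and muscle layers.

    ``T_ENS`` is a dimensionless fraction: the cubic in the neural equation
    has roots at 0, ``T_ENS*A_ENS`` and ``2*A_ENS``, so ``T_ENS*A_ENS`` is
    the absolute excitation threshold and ``2*A_ENS`` the excursion
    amplitude.
    """

    D_ENS: float
    T_ENS: float
    A_ENS: float
    E_SM: float
    D_SM: float
    B_SM: float

    def __post_init__(self) -> None:
        if self.A_ENS <= 0:
            raise ConfigurationError("A_ENS must be > 0")
        if self.D_ENS <= 0:
            raise ConfigurationError("D_ENS must be > 0")
        if self.D_SM <= 0:
            raise ConfigurationError("D_SM must be > 0")
        if not (0 < self.T_ENS < 2):
            raise ConfigurationError("T_ENS must lie in (0, 2)")


def default_body_params() -> LocalParams:
    """Calibrated canonical body (excitable-regime) parameters."""
    return LocalParams(D_ENS=0.6, T_ENS=0.3, A_ENS=1.0, E_SM=1.0, D_SM=1.0, B_SM=0.0)


def default_les_params() -> LocalParams:
    """Calibrated canonical LES (bistable-regime) parameters.

    LES tone emerges from the neural on-state (B_SM stays 0): the bistable
    neural layer holds U at its upper equilibrium, which drives W through
    the muscle equation.
    """
    return LocalParams(D_ENS=100.0, T_ENS=0.3, A_ENS=1.0, E_SM=1.0, D_SM=1.0, B_SM=0.0)


_PROFILE_FIELDS = ("D_ENS", "T_ENS", "A_ENS", "E_SM", "D_SM", "B_SM")


@dataclass
class ProfileSet:
    """Per-node arrays for each :class:`LocalParams` field."""

    D_ENS: np.ndarray
    T_ENS: np.ndarray
    A_ENS: np.ndarray
    E_SM: np.ndarray
    D_SM: np.ndarray
    B_SM: np.ndarray

    def copy(self) -> "ProfileSet":
        return ProfileSet(**{f: getattr(self, f).copy() for f in _PROFILE_FIELDS})

    def local(self, i: int) -> LocalParams:
        """The local parameter set at node ``i``."""
        return LocalParams(**{f: float(getattr(self, f)[i]) for f in _PROFILE_FIELDS})

    def arrays(self) -> dict:
        return {f: getattr(self, f) for f in _PROFILE_FIELDS}


def make_profiles(
    body: LocalParams,
    les: LocalParams,
    domain: SpatialDomain,
    smoothing_width: float = 0.0,
) -> ProfileSet:
    """Build piecewise-constant profiles switching from body to LES values.

    With ``smoothing_width = 0`` the profiles jump at ``x_les`` (LES value at
    ``x >= x_les``).  A positive width inserts a linear ramp of that width
    centred on ``x_les``.
    """
    if smoothing_width < 0:
        raise ConfigurationError("smoothing_width must be >= 0")
    if smoothing_width >= domain.length - domain.x_les:
        raise ConfigurationError("smoothing_width must be smaller than the LES length")
    x = domain.x
    out = {}
    for f in _PROFILE_FIELDS:
        b, l = getattr(body, f), getattr(les, f)
        if smoothing_width == 0.0:
            arr = np.where(domain.les_mask, l, b).astype(float)
        else:
            lo = domain.x_les - smoothing_width / 2.0
            frac = np.clip((x - lo) / smoothing_width, 0.0, 1.0)
            arr = b + (l - b) * frac
        out[f] = arr
    return ProfileSet(**out)


@dataclass(frozen=True)
class ModelConstants:
    """Fixed coefficients of the neural cubic: immutable by contract."""

    cubic_gain: float = CUBIC_GAIN
    recovery_coupling: float = RECOVERY_COUPLING


@dataclass(frozen=True)
class SwallowEvent:
    """One swallow: oral kick plus deglutitive inhibition.

    From onset ``t0`` the central command applies the negative stimulus
    ``-i_amp`` to the whole body (for ``inhib_body_duration``) and to the LES
    (for ``inhib_les_duration``); the positive stimulus ``+s_amp`` acts on
    the oral-most ``oral_extent`` of the domain during
    ``(t0+s_delay, t0+s_delay+s_duration)``.  Overlapping events sum, and
    with the default timing (``s_delay`` equal to the canonical 2-unit
    rapid-swallow interval) the next swallow's body inhibition exactly
    covers the previous swallow's kick window, masking it — the mechanism
    behind the multiple-rapid-swallows behaviour.
    """

    t0: float
    s_amp: float = 1.5
    i_amp: float = 10.5
    oral_extent: float = 0.5
    s_delay: float = 2.0
    s_duration: float = 0.5
    inhib_body_duration: float = 1.0
    inhib_les_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.s_amp < 0 or self.i_amp < 0:
            raise ConfigurationError("stimulus amplitudes must be >= 0")
        if min(
            self.inhib_body_duration, self.inhib_les_duration, self.s_duration
        ) < 0:
            raise ConfigurationError("durations must be >= 0")


@dataclass(frozen=True)
class PointStimulus:
    """Extra localized stimulus (secondary-peristalsis experiments)."""

    x: float
    t0: float
    amplitude: float
    width: float = 0.5
    duration: float = 0.5


@dataclass(frozen=True)
class StimulusProgram:
    """Ordered swallow events plus optional point stimuli."""

    events: tuple = ()
    point_stimuli: tuple = ()

    def __post_init__(self) -> None:
        ev = tuple(sorted(self.events, key=lambda e: e.t0))
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "point_stimuli", tuple(self.point_stimuli))


@dataclass(frozen=True)
class PEPSpec:
    """Pan-oesophageal pressurization: a rectangular space-time window of
    constant positive drive added directly to dW/dt.  ``amplitude = 0``
    reproduces the no-PEP model exactly."""

    amplitude: float = 0.0
    t_start: float = 0.0
    t_end: float = 0.0
    x_start: float = 0.0
    x_end: Optional[float] = None  # None => up to x_les (whole body)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("PEP amplitude must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Per-swallow stochastic fluctuation of one body parameter.

    One scalar standard-normal draw per swallow event (autonomic, not
    per-node) shifts the body value of ``target`` by ``mean_shift + sd*z``
    for the duration of that swallow cycle; LES values are untouched.
    """

    target: str = "T_ENS"
    mean_shift: float = 0.0
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in ("T_ENS", "s_IN"):
            raise ConfigurationError("noise target must be 'T_ENS' or 's_IN'")
        if self.sd < 0:
            raise ConfigurationError("sd must be >= 0")

    @property
    def is_null(self) -> bool:
        return self.sd == 0.0 and self.mean_shift == 0.0


@dataclass
class ModelSpec:
    """Everything needed to run one simulation."""

    domain: SpatialDomain
    profiles: ProfileSet
    s_IN: float = 1.0
    r_IN: float = 0.5
    d_IN: float = 0.5
    i_MN: float = -0.3
    r_MN: float = 3.0
    constants: ModelConstants = field(default_factory=ModelConstants)
    program: StimulusProgram = field(default_factory=StimulusProgram)
    pep: PEPSpec = field(default_factory=PEPSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    dt: float = 0.01
    t_end: float = 20.0
    save_stride: int = 10
    equilibration_time: float = 40.0
    #: set False for experiments that deliberately run without a bistable
    #: sphincter (e.g. the uniform-domain unidirectionality sweep)
    require_bistable_les: bool = True

    def with_(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


def default_spec(**overrides) -> ModelSpec:
    """The calibrated canonical model (no stimulus program)."""
    domain = make_domain()
    profiles = make_profiles(default_body_params(), default_les_params(), domain)
    spec = ModelSpec(domain=domain, profiles=profiles)
    return spec.with_(**overrides) if overrides else spec


@dataclass
class State:
    """Instantaneous fields on the grid: neural activity ``U``, recovery
    ``V`` and muscle activation ``W``."""

    t: float
    U: np.ndarray
    V: np.ndarray
    W: np.ndarray

    def copy(self) -> "State":
        return State(self.t, self.U.copy(), self.V.copy(), self.W.copy())


def initial_state(spec: ModelSpec) -> State:
    """Analytic pre-swallow state, ignoring kernel contributions.

    Body nodes start at rest (``U = V = 0``, ``W = B_SM / D_SM``); LES nodes
    at the upper stable equilibrium of the local system (``U*`` from the
    closed-form analysis, ``V* = U*/D_ENS``,
    ``W* = (E_SM U* + B_SM)/D_SM``).  Raises if the LES profile is not
    bistable, since the tonically contracted sphincter presupposes it.
    """
    from . import phase_analysis  # deferred: avoids import cycle

    dom = spec.domain
    n = dom.n_nodes
    U = np.zeros(n)
    V = np.zeros(n)
    W = spec.profiles.B_SM / spec.profiles.D_SM
    for i in np.flatnonzero(dom.les_mask):
        p = spec.profiles.local(i)
        eqs = phase_analysis.local_equilibria(p)
        uppers = [e for e in eqs if e.branch == "upper" and e.stability == "stable"]
        if not uppers:
            if not spec.require_bistable_les:
                continue  # monostable sphincter: start at rest like the body
            raise ConfigurationError(
                f"LES node at x={dom.x[i]:.2f} is not bistable under the given "
                "profiles; check the regime with phase_analysis.classify_regime"
            )
        u = uppers[0].U
        U[i] = u
        V[i] = u / p.D_ENS
        W[i] = (p.E_SM * u + p.B_SM) / p.D_SM
    return State(t=0.0, U=U, V=V, W=W)


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


def validate(spec: ModelSpec) -> ValidationReport:
    """Check a :class:`ModelSpec` for consistency and regime sanity.

    The normal behaviours presuppose an excitable body and a bistable LES;
    deviations are reported as warnings, structural problems as violations.
    """
    from . import phase_analysis

    rep = ValidationReport()
    dom = spec.domain
    n = dom.n_nodes
    for name, arr in spec.profiles.arrays().items():
        if arr.shape != (n,):
            rep.violations.append(
                f"profile {name} has length {arr.shape}, expected ({n},)"
            )
    if spec.dt <= 0:
        rep.violations.append(f"dt={spec.dt} must be > 0")
    if spec.t_end <= 0:
        rep.violations.append(f"t_end={spec.t_end} must be > 0")
    if spec.r_IN <= 0 or spec.r_MN <= 0:
        rep.violations.append("kernel radii r_IN and r_MN must be > 0")
    if spec.save_stride < 1:
        rep.violations.append("save_stride must be >= 1")
    if spec.dt >= 0.1:
        rep.warnings.append(
            f"dt={spec.dt} is coarse for the explicit Euler scheme; "
            "the canonical value is 0.01"
        )
    if rep.violations:
        return rep
    body_i = int(np.flatnonzero(dom.body_mask)[0])
    les_i = int(np.flatnonzero(dom.les_mask)[-1])
    body_regime = phase_analysis.classify_regime(spec.profiles.local(body_i))
    les_regime = phase_analysis.classify_regime(spec.profiles.local(les_i))
    if body_regime != "excitable":
        rep.warnings.append(f"body regime {body_regime}, expected excitable")
    if les_regime != "bistable":
        rep.warnings.append(f"LES regime {les_regime}, expected bistable")
    for ev in spec.program.events:
        if ev.t0 + ev.s_delay + ev.s_duration > spec.t_end:
            rep.warnings.append(
                f"swallow at t0={ev.t0} extends past t_end={spec.t_end}"
            )
    return rep
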