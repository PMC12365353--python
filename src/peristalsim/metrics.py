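"""Pulse detection and the Chicago-style outcome classifier.

Contraction pulses are tracked on the muscle field ``W``: each recorded
frame is thresholded (default half the normal-preset peak), split into
connected supra-threshold segments, and segments are linked across frames by
interval overlap (merges inherit the track with the largest overlap).  A
track whose edges never travel is the tonically contracted sphincter and is
flagged static.

From the tracks the module measures the clinical analogues used to label a
run: pulse speed (least-squares leading-edge slope oral of the deceleration
point), directional pulse counts after a point stimulus, the IRP analogue
(minimum windowed LES mean of ``W`` after a swallow), transmitted-swallow
counts, peak contraction amplitude and duration, and a pan-oesophageal
pressurization indicator.  ``classify_outcome`` maps a bundle of these
metrics to one Chicago-classification label via a fixed decision list;
inefficient oesophageal motility is a cohort-level label (fraction of failed
swallows over repeated seeded runs) assigned by the scenario runner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SimulationResult, simulate
from .model_core import ModelSpec, PointStimulus, StimulusProgram

__all__ = [
    "FrontTrack",
    "MetricsBundle",
    "track_fronts",
    "front_speed",
    "count_directional_pulses",
    "les_relaxation_metric",
    "transmitted_count",
    "sweep_d_threshold",
    "classify_outcome",
    "compute_metrics",
    "NormalReference",
]

#: default W threshold as a fraction of the normal-preset peak
THRESHOLD_FRACTION = 0.5
#: minimum edge excursion (length units) for a track to count as travelling
MIN_TRAVEL = 1.5
#: IRP analogue window (time units), mirroring the 4-s clinical window
IRP_HORIZON = 4.0
#: relaxed iff the IRP analogue is below this fraction of resting LES tone
RELAX_BAND = 0.25


class UndefinedSpeedError(RuntimeError):
    pass


@dataclass
class FrontTrack:
    """One linked supra-threshold component through time."""

    event_id: int
    times: list = field(default_factory=list)
    lo: list = field(default_factory=list)  # oral edge per frame
    hi: list = field(default_factory=list)  # anal edge per frame

    @property
    def birth_time(self) -> float:
        return self.times[0]

    @property
    def death_time(self) -> float:
        return self.times[-1]

    def _excursions(self) -> tuple[float, float]:
        """(max anal advance of the anal edge, max oral advance of the oral
        edge), both relative to the birth frame."""
        hi = np.asarray(self.hi)
        lo = np.asarray(self.lo)
        return float(hi.max() - hi[0]), float(lo[0] - lo.min())

    @property
    def direction(self) -> str:
        """'anal', 'oral', 'both' (expanding) or 'static'."""
        anal, oral = self._excursions()
        a, o = anal >= MIN_TRAVEL, oral >= MIN_TRAVEL
        if a and o:
            return "both"
        if a:
            return "anal"
        if o:
            return "oral"
        return "static"

    @property
    def is_static(self) -> bool:
        return self.direction == "static"

    def leading_edge(self) -> np.ndarray:
        """Leading-edge positions: the anal edge for analward motion, the
        oral edge for oralward motion (anal edge for static/both)."""
        return np.asarray(self.lo if self.direction == "oral" else self.hi)


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Connected runs of True as (start, stop) index pairs (stop inclusive)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], splits + 1))
    stops = np.concatenate((splits, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]


def track_fronts(result: SimulationResult, threshold: float) -> list[FrontTrack]:
    """Link supra-threshold components of ``W`` across frames by overlap.

    Returns every track, including the static sphincter component; callers
    filter on :attr:`FrontTrack.is_static` to get travelling pulses.
    """
    x = result.domain.x
    tracks: list[FrontTrack] = []
    active: list[tuple[tuple[int, int], FrontTrack]] = []
    next_id = 0
    for fi, t in enumerate(result.times):
        segs = _segments(result.W[fi] > threshold)
        # one-to-one greedy matching by descending overlap, so a splitting
        # component passes its identity to the larger child
        pairs = []
        for si, (a, b) in enumerate(segs):
            for (pa, pb), tr in active:
                ov = min(b, pb) - max(a, pa) + 1
                if ov > 0:
                    pairs.append((ov, si, tr))
        pairs.sort(key=lambda p: -p[0])
        assigned: dict[int, FrontTrack] = {}
        taken: set[int] = set()
        for ov, si, tr in pairs:
            if si in assigned or id(tr) in taken:
                continue
            assigned[si] = tr
            taken.add(id(tr))
        new_active = []
        for si, (a, b) in enumerate(segs):
            tr = assigned.get(si)
            if tr is None:
                tr = FrontTrack(event_id=next_id)
                next_id += 1
                tracks.append(tr)
            tr.times.append(float(t))
            tr.lo.append(float(x[a]))
            tr.hi.append(float(x[b]))
            new_active.append(((a, b), tr))
        active = new_active
    return tracks


def front_speed(
    track: FrontTrack, x_window: tuple[float, float] = (2.0, 7.0)
) -> float:
    """Least-squares slope of the leading-edge position against time,
    restricted to frames whose leading edge lies inside ``x_window``
    (default: the body oral of the deceleration point, excluding the
    launch transient near the stimulated patch).
    """
    pos = track.leading_edge()
    t = np.asarray(track.times)
    m = (pos >= x_window[0]) & (pos <= x_window[1])
    if m.sum() < 3:
        raise UndefinedSpeedError(
            f"track {track.event_id}: only {int(m.sum())} frames in window "
            f"{x_window}; need >= 3"
        )
    return float(np.polyfit(t[m], pos[m], 1)[0])


def count_directional_pulses(
    result: SimulationResult, origin_x: float, threshold: float
) -> tuple[int, int]:
    """(n_forward, n_backward) travelling pulses born near ``origin_x``.

    A track expanding both ways (a point stimulus with a symmetric kernel
    spreads as one component before splitting) counts in both directions.
    """
    n_f = n_b = 0
    for tr in track_fronts(result, threshold):
        if tr.is_static:
            continue
        born_near = tr.lo[0] - 2.0 <= origin_x <= tr.hi[0] + 2.0
        if not born_near:
            continue
        d = tr.direction
        if d in ("anal", "both"):
            n_f += 1
        if d in ("oral", "both"):
            n_b += 1
    return n_f, n_b


def les_relaxation_metric(
    result: SimulationResult, swallow_t0: float, horizon: float = IRP_HORIZON
) -> tuple[float, bool]:
    """IRP analogue: minimum over ``(t0, t0+horizon)`` of the spatial mean
    of ``W`` over the LES window.

    Returns ``(value, relaxed)`` where ``relaxed`` means the value dropped
    below ``RELAX_BAND`` times the pre-swallow resting LES tone.
    """
    les = result.domain.les_mask
    les_mean = result.W[:, les].mean(axis=1)
    resting = float(les_mean[result.frame_at(swallow_t0)])
    m = (result.times > swallow_t0) & (result.times <= swallow_t0 + horizon)
    if not m.any():
        return resting, False
    value = float(les_mean[m].min())
    return value, value < RELAX_BAND * resting


def transmitted_count(
    result: SimulationResult, threshold: float, oral_limit: float = 1.0
) -> int:
    """Number of contraction tracks that traverse the body.

    A traversing track moves analward, is born in the oral half, touches
    ``x <= oral_limit`` and reaches ``x >= x_les - 1``.  The birth and
    direction requirements keep a simultaneous whole-body pressurization
    (which spans the body without travelling) from counting as peristalsis.
    """
    x_goal = result.domain.x_les - 1.0
    mid = result.domain.length / 2.0
    n = 0
    for tr in track_fronts(result, threshold):
        if tr.direction != "anal":
            continue
        if tr.hi[0] > mid:
            continue
        if min(tr.lo) <= oral_limit and max(tr.hi) >= x_goal:
            n += 1
    return n


def _central_stimulus_spec(
    spec: ModelSpec, d: float, length: float = 20.0
) -> ModelSpec:
    """Spec variant for the unidirectionality experiment: a uniform
    excitable domain (LES off), no swallow program, one supra-threshold
    point stimulus at the domain centre.  A longer domain than the
    anatomical default gives each direction enough runway for a clean
    directionality verdict."""
    from .model_core import make_domain, make_profiles

    dom = make_domain(
        length=length, dx=spec.domain.dx, x_les=length - 1.0, x_cdp=length - 3.0
    )
    body = spec.profiles.local(0)
    profiles = make_profiles(body, body, dom)
    centre = length / 2.0
    # amplitude high enough to ignite without any kernel self-drive: the
    # stimulated patch must cross threshold even when d_IN >= r_IN leaves
    # it without recurrent excitation
    prog = StimulusProgram(
        point_stimuli=(PointStimulus(x=centre, t0=1.0, amplitude=3.0, width=1.0),)
    )
    return spec.with_(domain=dom, profiles=profiles, d_IN=d, program=prog,
                      t_end=10.0, require_bistable_les=False)


def measure_u_front_speed(
    spec: ModelSpec,
    threshold: float = 1.0,
    x_window: tuple[float, float] | None = None,
) -> float:
    """Leading-edge speed of the neural pulse U in the body.

    Runs the spec's program (or a default single swallow when it is empty)
    and fits the anal-most position of ``U > threshold`` against time,
    restricted to ``x_window`` (default: the body oral of the deceleration
    point, excluding the launch region).
    """
    from .model_core import SwallowEvent

    if not spec.program.events and not spec.program.point_stimuli:
        spec = spec.with_(
            program=StimulusProgram(events=(SwallowEvent(t0=1.0),)), t_end=20.0
        )
    if x_window is None:
        x_window = (2.0, spec.domain.x_cdp - 0.5)
    res = simulate(spec, 0)
    x = spec.domain.x
    ts, edges = [], []
    for fi, t in enumerate(res.times):
        above = np.flatnonzero((res.U[fi] > threshold) & (x < spec.domain.x_les))
        if above.size:
            ts.append(t)
            edges.append(x[above[-1]])
    ts, edges = np.asarray(ts), np.asarray(edges)
    m = (edges > x_window[0]) & (edges < x_window[1])
    if m.sum() < 3:
        raise UndefinedSpeedError("no travelling neural front in the body window")
    return float(np.polyfit(ts[m], edges[m], 1)[0])


def directional_excitation(
    result: SimulationResult,
    origin_x: float,
    margin: float = 2.0,
    level: float = 1.0,
) -> tuple[bool, bool]:
    """(forward, backward) neural-pulse propagation flags.

    A direction counts as propagated when the neural field ``U`` exceeds
    ``level`` (well above the excitation threshold) beyond ``margin`` on
    that side of the stimulated point — far enough that neither the direct
    stimulus nor a single kernel jump can reach it, so supra-threshold
    activity there implies a self-sustained travelling pulse.  Unlike the
    muscle-band tracks this verdict stays well defined for arbitrarily fast
    pulses, and it inherits the one-sided-kernel invariant exactly: with
    ``d_IN >= r_IN`` no excitation can ever appear oral of the source.
    """
    x = result.domain.x
    excited = result.U > level
    forward = bool(excited[:, x >= origin_x + margin].any())
    backward = bool(excited[:, x <= origin_x - margin].any())
    return forward, backward


def sweep_d_threshold(spec: ModelSpec, d_values) -> float:
    """Smallest ``d_IN`` from which no backward pulse forms.

    For each ``d`` in ascending order, runs a central point-stimulus
    simulation on a uniform excitable domain and checks for oral-direction
    neural propagation (:func:`directional_excitation`); returns the
    smallest ``d`` at which the backward pulse is absent and stays absent
    for all larger sampled values.  Raises when a backward pulse is still
    present at the largest ``d``.
    """
    import warnings

    d_values = sorted(float(d) for d in d_values)
    backward = []
    any_forward = False
    for d in d_values:
        cs = _central_stimulus_spec(spec, d)
        res = simulate(cs, 0)
        fwd, bwd = directional_excitation(res, cs.domain.length / 2.0)
        backward.append(bwd)
        any_forward = any_forward or fwd
    if backward[-1]:
        raise RuntimeError(
            f"backward pulse still present at d_IN={d_values[-1]}; "
            "extend the sweep range"
        )
    if not any_forward:
        warnings.warn("no forward pulse at any sampled d_IN", stacklevel=2)
    # smallest d after the last backward-pulse occurrence
    thr = d_values[0]
    for d, nb in zip(d_values, backward):
        if nb:
            thr = None
        elif thr is None:
            thr = d
    return float(thr)


# ---------------------------------------------------------------------------
# metric bundles and classification


@dataclass
class NormalReference:
    """Normal-preset reference values used to normalize disorder metrics."""

    peak_W: float
    speed: float
    duration: float

    @property
    def threshold(self) -> float:
        return THRESHOLD_FRACTION * self.peak_W


@dataclass
class MetricsBundle:
    """Flat record of the per-run metrics feeding the classifier."""

    tracks: list
    speed: float | None
    n_forward: int
    n_backward: int
    les_relax: float
    relaxed: bool
    peak_W: float
    supra_duration: float
    pep_fraction: float
    transmitted: int

    def as_record(self) -> dict:
        """Delimited-text-friendly flat mapping (tracks omitted)."""
        return {
            "speed": self.speed if self.speed is not None else float("nan"),
            "n_forward": self.n_forward,
            "n_backward": self.n_backward,
            "les_relax": self.les_relax,
            "relaxed": int(self.relaxed),
            "peak_W": self.peak_W,
            "supra_duration": self.supra_duration,
            "pep_fraction": self.pep_fraction,
            "transmitted": self.transmitted,
        }


def default_threshold(spec: ModelSpec) -> float:
    """W threshold = THRESHOLD_FRACTION x the calibrated normal peak."""
    return THRESHOLD_FRACTION * normal_reference().peak_W


_NORMAL_REF_CACHE: dict = {}


def normal_reference() -> NormalReference:
    """Metrics of the canonical normal single-swallow run (cached)."""
    if "ref" not in _NORMAL_REF_CACHE:
        from .model_core import SwallowEvent, default_spec

        spec = default_spec(
            t_end=20.0, program=StimulusProgram(events=(SwallowEvent(t0=1.0),))
        )
        res = simulate(spec, 0)
        body = spec.domain.body_mask
        # peak W in the body away from the stimulated oral patch
        interior = body & (spec.domain.x >= 1.0)
        peak = float(res.W[:, interior].max())
        thr = THRESHOLD_FRACTION * peak
        moving = [t for t in track_fronts(res, thr) if not t.is_static]
        speed = max(front_speed(t) for t in moving)
        duration = _supra_duration(res, thr)
        _NORMAL_REF_CACHE["ref"] = NormalReference(
            peak_W=peak, speed=speed, duration=duration
        )
    return _NORMAL_REF_CACHE["ref"]


def _supra_duration(res: SimulationResult, threshold: float) -> float:
    """Longest contiguous supra-threshold time of W at any body node
    (oral of the deceleration point, anal of the stimulated patch)."""
    x = res.domain.x
    cols = np.flatnonzero((x >= 1.0) & (x <= res.domain.x_cdp))
    if res.times.size < 2:
        return 0.0
    frame_dt = float(res.times[1] - res.times[0])
    best = 0
    for c in cols:
        above = res.W[:, c] > threshold
        run = longest = 0
        for a in above:
            run = run + 1 if a else 0
            longest = max(longest, run)
        best = max(best, longest)
    return best * frame_dt


def _pep_fraction(res: SimulationResult, threshold: float) -> float:
    """Largest simultaneous supra-threshold fraction of the body."""
    body = res.domain.body_mask
    frac = (res.W[:, body] > threshold).mean(axis=1)
    return float(frac.max())


def compute_metrics(
    result: SimulationResult,
    swallow_t0: float | None = None,
    threshold: float | None = None,
) -> MetricsBundle:
    """Measure every classifier input on one simulation result."""
    spec = result.spec
    if threshold is None:
        threshold = default_threshold(spec)
    if swallow_t0 is None:
        evs = spec.program.events
        swallow_t0 = evs[0].t0 if evs else 0.0
    tracks = track_fronts(result, threshold)
    moving = [t for t in tracks if not t.is_static]
    speed = None
    if moving:
        speeds = []
        for t in moving:
            try:
                speeds.append(front_speed(t))
            except UndefinedSpeedError:
                pass
        if speeds:
            speed = max(speeds)
    n_f, n_b = 0, 0
    for tr in moving:
        if tr.direction in ("anal", "both"):
            n_f += 1
        if tr.direction in ("oral", "both"):
            n_b += 1
    les_val, relaxed = les_relaxation_metric(result, swallow_t0)
    interior = result.domain.body_mask & (result.domain.x >= 1.0)
    peak = float(result.W[:, interior].max())
    return MetricsBundle(
        tracks=tracks,
        speed=speed,
        n_forward=n_f,
        n_backward=n_b,
        les_relax=les_val,
        relaxed=relaxed,
        peak_W=peak,
        supra_duration=_supra_duration(result, threshold),
        pep_fraction=_pep_fraction(result, threshold),
        transmitted=transmitted_count(result, threshold),
    )


#: PEP flag: this fraction of the body simultaneously pressurized
PEP_FRACTION_MIN = 0.6
#: premature iff speed exceeds this multiple of the normal speed
PREMATURE_FACTOR = 1.5
#: hypercontractile iff peak W exceeds this multiple of normal
HYPER_AMP_FACTOR = 1.5
#: ... or supra-threshold duration exceeds this multiple of normal
HYPER_DUR_FACTOR = 2.0


def classify_outcome(bundle: MetricsBundle, ref: NormalReference | None = None) -> str:
    """Map one run's metrics to a Chicago-style label (first match wins).

    impaired relaxation + transmitted + premature  -> achalasia III
    impaired + not transmitted + PEP               -> achalasia II
    impaired + not transmitted                     -> achalasia I
    impaired + transmitted                         -> EGJOO
    relaxed + premature                            -> DES
    relaxed + not transmitted                      -> absent contractility
    relaxed + hypercontractile                     -> jackhammer
    otherwise                                      -> normal

    Premature and hypercontractile are normalized to the normal-preset
    reference (model units are dimensionless, so clinical absolute cutoffs
    do not apply).  The cohort-level IEM label (>70% failed swallows over
    seeded repetitions) is assigned by the scenario runner, not here.
    """
    if ref is None:
        ref = normal_reference()
    transmitted = bundle.transmitted >= 1
    premature = bundle.speed is not None and bundle.speed > PREMATURE_FACTOR * ref.speed
    hyper = (
        bundle.peak_W > HYPER_AMP_FACTOR * ref.peak_W
        or bundle.supra_duration > HYPER_DUR_FACTOR * ref.duration
    )
    pep = bundle.pep_fraction >= PEP_FRACTION_MIN
    impaired = not bundle.relaxed
    if impaired and transmitted and premature:
        return "achalasia III"
    if impaired and not transmitted and pep:
        return "achalasia II"
    if impaired and not transmitted:
        return "achalasia I"
    if impaired and transmitted:
        return "EGJOO"
    if premature:
        return "DES"
    if not transmitted:
        return "absent contractility"
    if hyper:
        return "jackhammer"
    return "normal"
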