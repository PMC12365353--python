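"""Named scenario presets for normal motility and every disorder pattern.

Each preset is the calibrated normal model with one or more documented
parameter changes, expressed as multiples of the normal value ("low" = x0.3,
"high" = x2 unless a preset-specific multiplier is stated).  The factor
groups mirror the clinical reasoning:

* LES-impairment factors — weak deglutitive inhibition (``icns``), a deeper
  sphincter on-state (low LES ``T_ENS``, ``tens``), or basal muscle drive at
  the sphincter (``bsm``, an absolute override since the normal basal drive
  is zero);
* pulse-loss factors — weak oral kick (``scns``), raised body threshold
  (``tens``), weak interneuron coupling (``sin``), weak neuromuscular
  transmission (``esm``);
* premature-contraction factors — stronger/wider/more-deviated interneuron
  coupling (``sin``, ``rin``, ``din``);
* hypercontractility factors — larger neural amplitude (``aens``), stronger
  neuromuscular gain (``esm``), slower muscle decay (``dsm``).

Combining the groups yields the Chicago-classification catalogue: EGJOO
(impairment alone), achalasia I (impairment x pulse loss), achalasia II
(adds pan-oesophageal pressurization), achalasia III (impairment x
premature), DES / absent contractility / jackhammer (body factors alone),
and the two stochastic IEM protocols (per-swallow noise on body ``T_ENS``
or ``s_IN``).

A few presets whose intended clinical pattern is not reachable under this
calibration carry their empirically verified label together with a note;
notably, strongly increased ``r_IN`` or ``s_IN`` can impair LES relaxation
through the nonlocal coupling and tip a spasm preset into the achalasia III
pattern — the same crossover the clinical taxonomy itself acknowledges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import metrics as mx
from .dynamics import SimulationResult, simulate
from .model_core import (
    ModelSpec,
    NoiseSpec,
    PEPSpec,
    StimulusProgram,
    SwallowEvent,
    default_spec,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioOutcome",
    "preset",
    "preset_names",
    "mrs_program",
    "run_scenario",
]

LOW = 0.3
HIGH = 2.0
#: premature-contraction multiplier (x2 overshoots into sphincter
#: impairment through the nonlocal coupling; 1.6x is spasm territory)
PREMATURE_MULT = 1.6
#: hypercontractile neural-amplitude multiplier; larger values push the
#: body over its bistability boundary and the contraction never releases
AENS_MULT = 1.1
#: absolute basal LES muscle drive for the "high B_SM" presets
BSM_LES_HIGH = 2.0
#: IEM noise calibration: per-swallow body-parameter fluctuation
IEM_TENS_NOISE = dict(target="T_ENS", mean_shift=0.032, sd=0.012)
IEM_SIN_NOISE = dict(target="s_IN", mean_shift=-0.08, sd=0.012)
#: cohort size and failure criterion for the IEM protocols
IEM_RUNS = 10
IEM_FAIL_FRACTION = 0.7


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, fully specified experiment."""

    name: str
    spec: ModelSpec
    expected_label: str
    #: free-text note, e.g. when the calibrated outcome diverges from the
    #: clinically intended pattern
    note: str = ""
    #: number of seeded repetitions (IEM cohorts)
    n_runs: int = 1


def _single_swallow(t0: float = 1.0, **ev) -> StimulusProgram:
    return StimulusProgram(events=(SwallowEvent(t0=t0, **ev),))


def mrs_program(n_swallows: int = 5, interval: float = 2.0) -> StimulusProgram:
    """Multiple rapid swallows: ``n`` onsets spaced by ``interval`` starting
    at t = 1 (clinically five swallows at 2 s intervals)."""
    return StimulusProgram(
        events=tuple(SwallowEvent(t0=1.0 + i * interval) for i in range(n_swallows))
    )


def _override_profile(spec: ModelSpec, fld: str, region: str, value: float) -> ModelSpec:
    prof = spec.profiles.copy()
    mask = spec.domain.les_mask if region == "les" else spec.domain.body_mask
    arr = getattr(prof, fld).copy()
    arr[mask] = value
    setattr(prof, fld, arr)
    return spec.with_(profiles=prof)


def _override_event(spec: ModelSpec, **ev_kw) -> ModelSpec:
    events = tuple(replace(e, **ev_kw) for e in spec.program.events)
    return spec.with_(program=replace(spec.program, events=events))


def _base(**kw) -> ModelSpec:
    return default_spec(t_end=20.0, program=_single_swallow()).with_(**kw) if kw else \
        default_spec(t_end=20.0, program=_single_swallow())


# --- factor appliers -------------------------------------------------------


def _les_factor(spec: ModelSpec, which: str) -> ModelSpec:
    if which == "icns":
        return _override_event(spec, i_amp=10.5 * LOW)
    if which == "tens":
        return _override_profile(spec, "T_ENS", "les", 0.3 * LOW)
    if which == "bsm":
        return _override_profile(spec, "B_SM", "les", BSM_LES_HIGH)
    raise KeyError(which)


def _loss_factor(spec: ModelSpec, which: str) -> ModelSpec:
    if which == "scns":
        return _override_event(spec, s_amp=1.5 * LOW)
    if which == "tens":
        return _override_profile(spec, "T_ENS", "body", 0.3 * HIGH)
    if which == "sin":
        return spec.with_(s_IN=spec.s_IN * LOW)
    if which == "esm":
        return _override_profile(spec, "E_SM", "body", 1.0 * LOW)
    raise KeyError(which)


def _premature_factor(spec: ModelSpec, which: str) -> ModelSpec:
    if which == "sin":
        return spec.with_(s_IN=spec.s_IN * PREMATURE_MULT)
    if which == "rin":
        return spec.with_(r_IN=spec.r_IN * PREMATURE_MULT)
    if which == "din":
        return spec.with_(d_IN=spec.d_IN * PREMATURE_MULT)
    if which == "tens":
        return _override_profile(spec, "T_ENS", "body", 0.3 * 0.6)
    raise KeyError(which)


_PEP_WINDOW = PEPSpec(amplitude=1.0, t_start=3.0, t_end=8.0)


def _build_catalogue() -> dict[str, ScenarioSpec]:
    cat: dict[str, ScenarioSpec] = {}

    def add(name, spec, label, note="", n_runs=1):
        cat[name] = ScenarioSpec(name, spec, label, note, n_runs)

    add("normal", _base(), "normal")

    for les in ("icns", "tens", "bsm"):
        add(f"egjoo_{les}", _les_factor(_base(), les), "EGJOO")

    for les in ("icns", "tens", "bsm"):
        for loss in ("scns", "tens", "sin", "esm"):
            add(
                f"achalasia1_{les}_{loss}",
                _loss_factor(_les_factor(_base(), les), loss),
                "achalasia I",
            )

    for les in ("icns", "tens", "bsm"):
        add(
            f"achalasia2_{les}",
            _loss_factor(_les_factor(_base(pep=_PEP_WINDOW), les), "scns"),
            "achalasia II",
        )

    for pre in ("sin", "rin", "din"):
        for les in ("icns", "tens", "bsm"):
            if pre == "din":
                # saltatory propagation at high d_IN fragments the
                # contraction band: no traversing track, no premature speed
                label, note = "achalasia I", (
                    "intended achalasia III; at high d_IN the contraction "
                    "band fragments and transmission is lost"
                )
            else:
                label, note = "achalasia III", ""
            add(
                f"achalasia3_{pre}_{les}",
                _premature_factor(_les_factor(_base(), les), pre),
                label,
                note,
            )

    add("des_sin", _premature_factor(_base(), "sin"), "DES")
    add("des_rin", _premature_factor(_base(), "rin"), "DES")
    add(
        "des_din",
        _premature_factor(_base(), "din"),
        "absent contractility",
        "intended DES; saltatory propagation at high d_IN fragments the "
        "contraction band (fast neural pulse, no contiguous contraction)",
    )
    add(
        "des_tens",
        _premature_factor(_base(), "tens"),
        "normal",
        "intended DES; lowering body T_ENS accelerates the pulse but hits "
        "the excitable/bistable boundary before the premature criterion",
    )

    for loss in ("scns", "tens", "sin", "esm"):
        add(f"absent_{loss}", _loss_factor(_base(), loss), "absent contractility")

    add(
        "jackhammer_aens",
        _override_profile(_base(), "A_ENS", "body", AENS_MULT),
        "normal",
        "intended jackhammer; A_ENS is capped by the body bistability "
        "boundary (~1.07) and the reachable contraction stays below the "
        "hypercontractile cutoffs",
    )
    add(
        "jackhammer_esm",
        _override_profile(_base(), "E_SM", "body", HIGH),
        "jackhammer",
    )
    add(
        "jackhammer_dsm",
        _override_profile(_base(), "D_SM", "body", 1.0 * LOW),
        "jackhammer",
    )

    add(
        "iem_tens",
        _base(noise=NoiseSpec(**IEM_TENS_NOISE)),
        "IEM",
        n_runs=IEM_RUNS,
    )
    add(
        "iem_sin",
        _base(noise=NoiseSpec(**IEM_SIN_NOISE)),
        "IEM",
        n_runs=IEM_RUNS,
    )
    return cat


_CATALOGUE: dict[str, ScenarioSpec] | None = None


def _catalogue() -> dict[str, ScenarioSpec]:
    global _CATALOGUE
    if _CATALOGUE is None:
        _CATALOGUE = _build_catalogue()
    return _CATALOGUE


def preset_names() -> list[str]:
    return list(_catalogue())


def preset(name: str) -> ScenarioSpec:
    """Look up a scenario preset by name."""
    cat = _catalogue()
    if name not in cat:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(cat)}"
        )
    return cat[name]


@dataclass
class ScenarioOutcome:
    """Everything produced by one scenario run."""

    scenario: ScenarioSpec
    label: str
    results: list = field(default_factory=list)  # SimulationResult per run
    bundles: list = field(default_factory=list)  # MetricsBundle per run
    failed_fraction: float | None = None  # IEM cohorts only

    @property
    def matches_expected(self) -> bool:
        return self.label == self.scenario.expected_label


def run_scenario(name: str, seed: int = 0, out_dir=None) -> ScenarioOutcome:
    """Simulate a preset, measure metrics, classify, optionally export.

    Deterministic given ``(name, seed)``.  IEM presets run ``n_runs`` seeded
    repetitions of the single-swallow protocol and return the cohort label
    ("IEM" when the failed-swallow fraction exceeds 70%); all other presets
    run once.
    """
    sc = preset(name)
    ref = mx.normal_reference()
    results, bundles = [], []
    for k in range(sc.n_runs):
        res = simulate(sc.spec, seed=seed + k)
        results.append(res)
        bundles.append(mx.compute_metrics(res))
    if sc.n_runs > 1:
        failed = np.mean([b.transmitted == 0 for b in bundles])
        if failed > IEM_FAIL_FRACTION:
            label = "IEM"
        else:
            labels = [mx.classify_outcome(b, ref) for b in bundles]
            label = max(set(labels), key=labels.count)
        outcome = ScenarioOutcome(sc, label, results, bundles, float(failed))
    else:
        label = mx.classify_outcome(bundles[0], ref)
        outcome = ScenarioOutcome(sc, label, results, bundles)
    if out_dir is not None:
        _export(outcome, out_dir, seed)
    return outcome


def _export(outcome: ScenarioOutcome, out_dir, seed: int) -> None:
    from pathlib import Path

    from . import viz_export

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = outcome.results[0]
    viz_export.write_result(res, out, seed=seed)
    viz_export.write_result(viz_export.hrm_transform(res), out)
    viz_export.write_result(viz_export.distension_transform(res), out)
    with open(out / "metrics.csv", "w") as fh:
        rec = outcome.bundles[0].as_record()
        rec["label"] = outcome.label
        if outcome.failed_fraction is not None:
            rec["failed_fraction"] = outcome.failed_fraction
        fh.write(",".join(rec.keys()) + "\n")
        fh.write(",".join(str(v) for v in rec.values()) + "\n")
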