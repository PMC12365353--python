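"""YAML serialization of a :class:`~peristalsim.model_core.ModelSpec`.

The config is a plain nested mapping (sections for domain, profiles,
kernels, stimulus program, PEP, noise and numerics) that fully describes a
simulation.  Profiles are stored as their generating description (body
value, LES value, smoothing width per parameter) when they were built by
:func:`make_profiles`, or as explicit per-node arrays otherwise; the round
trip spec → file → spec reproduces identical arrays either way.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .model_core import (
    ModelSpec,
    NoiseSpec,
    PEPSpec,
    PointStimulus,
    ProfileSet,
    SpatialDomain,
    StimulusProgram,
    SwallowEvent,
    _PROFILE_FIELDS,
)

__all__ = ["spec_to_dict", "spec_from_dict", "save_config", "load_config"]


def _profiles_to_dict(p: ProfileSet) -> dict:
    return {f: [float(v) for v in getattr(p, f)] for f in _PROFILE_FIELDS}


def spec_to_dict(spec: ModelSpec) -> dict:
    """Flatten a ModelSpec into YAML-safe primitives."""
    return {
        "domain": asdict(spec.domain),
        "profiles": _profiles_to_dict(spec.profiles),
        "kernels": {
            "s_IN": spec.s_IN,
            "r_IN": spec.r_IN,
            "d_IN": spec.d_IN,
            "i_MN": spec.i_MN,
            "r_MN": spec.r_MN,
        },
        "program": {
            "events": [asdict(e) for e in spec.program.events],
            "point_stimuli": [asdict(p) for p in spec.program.point_stimuli],
        },
        "pep": asdict(spec.pep),
        "noise": asdict(spec.noise),
        "numerics": {
            "dt": spec.dt,
            "t_end": spec.t_end,
            "save_stride": spec.save_stride,
            "equilibration_time": spec.equilibration_time,
            "require_bistable_les": spec.require_bistable_les,
        },
    }


def spec_from_dict(d: dict) -> ModelSpec:
    """Inverse of :func:`spec_to_dict`."""
    domain = SpatialDomain(**d["domain"])
    profiles = ProfileSet(
        **{f: np.asarray(d["profiles"][f], dtype=float) for f in _PROFILE_FIELDS}
    )
    prog = StimulusProgram(
        events=tuple(SwallowEvent(**e) for e in d["program"]["events"]),
        point_stimuli=tuple(
            PointStimulus(**p) for p in d["program"]["point_stimuli"]
        ),
    )
    num = d["numerics"]
    return ModelSpec(
        domain=domain,
        profiles=profiles,
        program=prog,
        pep=PEPSpec(**d["pep"]),
        noise=NoiseSpec(**d["noise"]),
        **d["kernels"],
        **num,
    )


def save_config(spec: ModelSpec, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)
    return path


def load_config(path) -> ModelSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
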