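"""Display transforms and file export.

High-resolution manometry (HRM) only registers positive intraluminal
pressure, and real pressure topography shows the pulse slowing visibly at
the contractile deceleration point (CDP).  The HRM transform therefore
(a) rectifies the muscle field ``W`` and (b) remaps coordinates distal to
``x_cdp`` so that a pulse travelling at constant model speed is displayed at
``factor`` times that speed past the CDP (default 0.5).  Display position
``x`` past the CDP shows the model value at ``x_cdp + (x - x_cdp)/factor``;
model coordinates past the anal end are clamped to the domain end, so the
sphincter band remains visible as the distal-most display band.

The distension plot is the complementary view: dilatation (``W < 0``) is an
increase of tube radius above ``r_base``, contraction is shown only as
colour (the rectified HRM value at the same display coordinate).

Arrays are written either as delimited text matrices (header row/column of
coordinates) or as a compressed binary container (bit-exact round trip),
with a YAML sidecar recording the full model specification and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dynamics import SimulationResult

__all__ = [
    "HRMMap",
    "DistensionMap",
    "hrm_transform",
    "distension_transform",
    "write_result",
    "read_result",
]


@dataclass
class HRMMap:
    """Rectified pressure topography on display coordinates."""

    times: np.ndarray
    x_display: np.ndarray
    values: np.ndarray  # (n_times, n_x), all >= 0
    x_cdp: float
    factor: float


@dataclass
class DistensionMap:
    """Tube-radius / colour view of the same run."""

    times: np.ndarray
    x_display: np.ndarray
    R: np.ndarray  # radius, >= r_base
    C: np.ndarray  # colour = rectified pressure, >= 0
    r_base: float


def _display_to_model(x: np.ndarray, x_cdp: float, factor: float, x_max: float):
    """Monotone display→model coordinate map implementing the CDP slowdown.

    Identity proximal to the CDP; distal display coordinates advance
    ``1/factor`` model units per display unit (so displayed speed = factor
    × model speed), clamped at the anal end of the domain.
    """
    m = np.where(x < x_cdp, x, x_cdp + (x - x_cdp) / factor)
    return np.minimum(m, x_max)


def hrm_transform(
    result: SimulationResult, x_cdp: float | None = None, factor: float = 0.5
) -> HRMMap:
    """HRM pressure topography of a simulation result.

    ``factor`` is the displayed-to-model speed ratio distal to the CDP;
    ``factor = 1`` is the identity mapping (rectification only).  Values at
    remapped coordinates are linearly interpolated from the model grid.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    dom = result.domain
    if x_cdp is None:
        x_cdp = dom.x_cdp
    if not (0 < x_cdp < dom.length):
        raise ValueError("x_cdp must lie inside the domain")
    x = dom.x
    model_x = _display_to_model(x, x_cdp, factor, dom.length)
    vals = np.empty_like(result.W)
    for fi in range(result.W.shape[0]):
        vals[fi] = np.interp(model_x, x, result.W[fi])
    return HRMMap(
        times=result.times.copy(),
        x_display=x.copy(),
        values=np.maximum(vals, 0.0),
        x_cdp=float(x_cdp),
        factor=float(factor),
    )


def distension_transform(result: SimulationResult, r_base: float = 1.0) -> DistensionMap:
    """Distension–contraction plot: ``R = max(-W, 0) + r_base`` on model
    coordinates, colour = the HRM-transformed value at the same display
    coordinate."""
    hrm = hrm_transform(result)
    R = np.maximum(-result.W, 0.0) + r_base
    return DistensionMap(
        times=result.times.copy(),
        x_display=hrm.x_display,
        R=R,
        C=hrm.values,
        r_base=float(r_base),
    )


# ---------------------------------------------------------------------------
# file output


def _spec_to_metadata(result: SimulationResult, seed: int | None) -> dict:
    from .config_io import spec_to_dict

    meta = {"spec": spec_to_dict(result.spec)}
    if seed is not None:
        meta["seed"] = int(seed)
    return meta


def _write_matrix_csv(path: Path, times, xs, M) -> None:
    """Delimited text: header row of coordinates, first column of times."""
    with open(path, "w") as fh:
        fh.write("t\\x," + ",".join(f"{v:.6g}" for v in xs) + "\n")
        for t, row in zip(times, M):
            fh.write(f"{t:.6g}," + ",".join(f"{v:.9g}" for v in row) + "\n")


def write_result(
    obj,
    out_dir,
    fmt: str = "both",
    seed: int | None = None,
) -> list[Path]:
    """Write a :class:`SimulationResult`, :class:`HRMMap` or
    :class:`DistensionMap` under ``out_dir``.

    ``fmt``: ``"csv"`` (delimited text, one file per field), ``"npz"``
    (binary container, bit-exact round trip) or ``"both"``.  A YAML sidecar
    ``metadata.yaml`` records the model specification and seed for
    simulation results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(obj, SimulationResult):
        fields = {"U": obj.U, "V": obj.V, "W": obj.W}
        times, xs = obj.times, obj.domain.x
        base = "result"
    elif isinstance(obj, HRMMap):
        fields = {"HRM": obj.values}
        times, xs = obj.times, obj.x_display
        base = "hrm"
    elif isinstance(obj, DistensionMap):
        fields = {"R": obj.R, "C": obj.C}
        times, xs = obj.times, obj.x_display
        base = "distension"
    else:
        raise TypeError(f"cannot export object of type {type(obj).__name__}")

    if fmt in ("csv", "both"):
        for name, M in fields.items():
            p = out / f"{base}_{name}.csv"
            _write_matrix_csv(p, times, xs, M)
            written.append(p)
    if fmt in ("npz", "both"):
        p = out / f"{base}.npz"
        np.savez_compressed(p, times=times, x=xs, **fields)
        written.append(p)
    if fmt not in ("csv", "npz", "both"):
        raise ValueError("fmt must be 'csv', 'npz' or 'both'")

    if isinstance(obj, SimulationResult):
        import yaml

        meta = out / "metadata.yaml"
        with open(meta, "w") as fh:
            yaml.safe_dump(_spec_to_metadata(obj, seed), fh, sort_keys=False)
        written.append(meta)
    return written


def read_result(npz_path) -> dict:
    """Load a binary container back into a dict of arrays."""
    with np.load(npz_path) as z:
        return {k: z[k].copy() for k in z.files}
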