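"""Trephine (stoma incision) morphometry on the deformed wall.

A stoma trephine is a circular through-hole; under intraabdominal
pressure the wall bulges and the hole dilates into an ellipse-like
shape.  This module measures the hole boundary loop — by convention the
one at the innermost wall surface — in the reference and deformed
configurations and reports perimeter, enclosed area, the axial and
sagittal diameters and the percent enlargement of perimeter and area,
the quantities used to grade parastomal-hernia risk.

Measurement conventions:

* the deformed loop is generally non-planar; its area is the magnitude
  of the Newell vector area ``0.5 * || sum r_i x r_{i+1} ||``, which is
  orientation-robust and reduces to the ordinary enclosed area for a
  planar loop;
* diameters are loop extents along two configurable global axes
  (defaults: x, the horizontal body axis, and z, the antero-posterior
  protrusion direction);
* absolute quantities are reported in cm / cm^2 (the mesh is in mm);
  percent increases are ``100 * (deformed - reference) / reference`` and
  are kept at full precision — rounding happens only in formatted
  tables.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh_core import MM_PER_CM, MeshError, TetMesh
from .elastic_fem import DisplacementField

AXIAL_AXIS = np.array([1.0, 0.0, 0.0])
SAGITTAL_AXIS = np.array([0.0, 0.0, 1.0])

#: group labels of the position scheme: the through-strip stoma alone,
#: then one group per lateral column
GROUP_OF = {"s0": "s0", "s1": "i=1", "s2": "i=2", "s3": "i=3"}


@dataclass
class TrephineMeasurement:
    """Absolute loop dimensions and (optionally) percent enlargements."""
    perimeter_cm: float
    area_cm2: float
    axial_diameter_cm: float
    sagittal_diameter_cm: float
    pct_perimeter_increase: float | None = None
    pct_area_increase: float | None = None


def extract_trephine_loop(mesh: TetMesh, loop_name: str,
                          u: DisplacementField | None = None) -> np.ndarray:
    """Closed 3-D polyline (L, 3) of a named loop, optionally deformed.

    Returns reference coordinates, or reference plus the solved
    displacement of each loop node when ``u`` is given.  Orientation is
    normalized counter-clockwise about the loop's mean normal (taken
    with a non-negative component along the sagittal axis).
    """
    if loop_name not in mesh.loops:
        raise MeshError(f"unknown loop '{loop_name}' "
                        f"(available: {sorted(mesh.loops)})")
    idx = mesh.loops[loop_name]
    pts = mesh.nodes[idx].copy()
    if u is not None:
        pts += u.u[idx]
    nvec = _newell_vector(pts)
    ref = SAGITTAL_AXIS if abs(nvec @ SAGITTAL_AXIS) > 1e-12 else AXIAL_AXIS
    if nvec @ ref < 0:
        pts = pts[::-1]
    return pts


def _newell_vector(pts: np.ndarray) -> np.ndarray:
    nxt = np.roll(pts, -1, axis=0)
    return 0.5 * np.cross(pts, nxt).sum(axis=0)


def measure_loop(loop: np.ndarray,
                 axial_axis: np.ndarray = AXIAL_AXIS,
                 sagittal_axis: np.ndarray = SAGITTAL_AXIS) -> TrephineMeasurement:
    """Perimeter, Newell area and axis extents of a closed polyline (mm in,
    cm out).  The loop must have at least 8 vertices and nonzero area."""
    pts = np.asarray(loop, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 8:
        raise MeshError("loop must be an (L>=8, 3) polyline")
    seg = np.roll(pts, -1, axis=0) - pts
    perimeter = float(np.linalg.norm(seg, axis=1).sum())
    area = float(np.linalg.norm(_newell_vector(pts)))
    if area <= 0.0 or perimeter <= 0.0:
        raise MeshError("degenerate (zero-area) loop")
    ax = pts @ (axial_axis / np.linalg.norm(axial_axis))
    sg = pts @ (sagittal_axis / np.linalg.norm(sagittal_axis))
    return TrephineMeasurement(
        perimeter_cm=perimeter / MM_PER_CM,
        area_cm2=area / MM_PER_CM ** 2,
        axial_diameter_cm=float(ax.max() - ax.min()) / MM_PER_CM,
        sagittal_diameter_cm=float(sg.max() - sg.min()) / MM_PER_CM,
    )


def enlargement(reference: TrephineMeasurement,
                deformed: TrephineMeasurement) -> TrephineMeasurement:
    """Percent increase of the deformed loop over the reference loop."""
    if reference.area_cm2 <= 0 or reference.perimeter_cm <= 0:
        raise MeshError("reference measurement must have positive dimensions")
    return replace(
        deformed,
        pct_perimeter_increase=100.0 * (deformed.perimeter_cm
                                        - reference.perimeter_cm)
        / reference.perimeter_cm,
        pct_area_increase=100.0 * (deformed.area_cm2 - reference.area_cm2)
        / reference.area_cm2,
    )


def position_group(label: str) -> str:
    """Column group of a position label: 's0' or 'i=1'/'i=2'/'i=3'."""
    key = label if label == "s0" else label[:2]
    if label != "s0" and (len(label) != 3 or key not in GROUP_OF
                          or not label[2].isdigit()):
        raise MeshError(f"unknown position label '{label}'")
    if key not in GROUP_OF:
        raise MeshError(f"unknown position label '{label}'")
    return GROUP_OF[key]


def summarize_by_position(
        measurements: dict[str, TrephineMeasurement]) -> dict[str, dict[str, float]]:
    """Mean percent enlargement per column group.

    The through-strip position ``s0`` is reported alone; lateral columns
    are averaged per ``i`` group.  Empty groups are omitted.  Input
    measurements must carry percent fields (see :func:`enlargement`).
    """
    acc: dict[str, list[TrephineMeasurement]] = {}
    for label, m in measurements.items():
        if m.pct_area_increase is None or m.pct_perimeter_increase is None:
            raise MeshError(f"measurement for '{label}' lacks percent fields; "
                            "run enlargement() first")
        acc.setdefault(position_group(label), []).append(m)
    out = {}
    for group in ("s0", "i=1", "i=2", "i=3"):
        if group not in acc:
            continue
        ms = acc[group]
        out[group] = {
            "mean_pct_area_increase": float(np.mean([m.pct_area_increase
                                                     for m in ms])),
            "mean_pct_perimeter_increase": float(np.mean(
                [m.pct_perimeter_increase for m in ms])),
            "n": len(ms),
        }
    return out
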