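"""Reference-frame transforms: lab / plate frames to the model global frame.

Musculoskeletal modeling software expects a fixed global frame (X anterior,
Y up, Z to the subject's right). Motion labs orient their capture volume
differently, so the acquisition configuration declares, per lab (with an
optional per-plate override), how each model axis maps onto a signed lab
axis. The induced matrix must be a proper rotation (a signed permutation
with determinant +1).

Plate pose is derived from the C3D CORNERS quadrilateral: the plate centre
is the corner mean, local x runs along the corner 1 -> 2 edge, the normal z
follows the right-hand rule around the corner winding, and y = z x x.

Forces and torques transform as vectors; the CoP transforms as a point (the
plate-centre translation applies exactly once). Output is in model-frame SI
units: N, N*m, metres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forceplate import GRFSeries

_AXES = {"x": 0, "y": 1, "z": 2}


class FrameError(ValueError):
    """Invalid axes specification or degenerate plate geometry."""


@dataclass(frozen=True)
class AxesSpec:
    """Maps each model axis to a signed source axis, e.g. x='+y', y='+z', z='+x'."""

    x: str = "+x"
    y: str = "+y"
    z: str = "+z"

    def items(self):
        return (("x", self.x), ("y", self.y), ("z", self.z))


def rotation_from_spec(spec: AxesSpec) -> np.ndarray:
    """Signed-permutation rotation R with model_vec = R @ source_vec."""
    R = np.zeros((3, 3))
    used: set[int] = set()
    for target, source in spec.items():
        source = source.strip().lower().replace(" ", "")
        sign = 1.0
        if source and source[0] in "+-":
            sign = -1.0 if source[0] == "-" else 1.0
            source = source[1:]
        if source not in _AXES:
            raise FrameError(f"axis spec {target}<-{spec!r}: unknown source axis {source!r}")
        j = _AXES[source]
        if j in used:
            raise FrameError(f"source axis {source!r} mapped twice in {spec!r}")
        used.add(j)
        R[_AXES[target], j] = sign
    if not np.isclose(np.linalg.det(R), 1.0):
        raise FrameError(
            f"axes spec {spec!r} is left-handed (determinant {np.linalg.det(R):+.0f}); "
            "a proper rotation is required")
    return R


def spec_from_rotation(R: np.ndarray) -> AxesSpec:
    """Inverse of :func:`rotation_from_spec` (valid on signed permutations)."""
    names = "xyz"
    kw = {}
    for i in range(3):
        j = int(np.argmax(np.abs(R[i])))
        kw[names[i]] = ("+" if R[i, j] > 0 else "-") + names[j]
    return AxesSpec(**kw)


def plate_pose(corners_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plate centre (m, lab frame) and plate->lab rotation from the corners."""
    c = np.asarray(corners_mm, dtype=np.float64)
    if c.shape != (4, 3):
        raise FrameError("plate corners must be a 4x3 array")
    center_m = c.mean(axis=0) * 0.001
    u = c[1] - c[0]
    v = c[2] - c[1]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise FrameError("degenerate plate corners (coincident points)")
    x = u / nu
    z = np.cross(u, v)
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise FrameError("degenerate plate corners (collinear points)")
    z = z / nz
    y = np.cross(z, x)
    return center_m, np.column_stack([x, y, z])


def rotate_markers(positions: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate marker positions (frames x 3) into the model frame."""
    return positions @ R.T


def grf_to_global(grf: GRFSeries, corners_mm: np.ndarray, lab_rotation: np.ndarray,
                  reaction: bool = True) -> GRFSeries:
    """Express a plate-local GRF series in the model global frame.

    Force and torque rotate as vectors (plate -> lab -> model); the CoP is a
    point: plate-local CoP (m) -> plate pose -> lab coordinates -> model
    frame. With ``reaction=True`` (the default) the exported wrench is the
    reaction acting on the subject, i.e. the negated plate measurement.
    """
    if grf.frame != "plate-local":
        raise FrameError(f"expected a plate-local series, got frame {grf.frame!r}")
    center_m, R_plate = plate_pose(corners_mm)
    R = np.asarray(lab_rotation, dtype=np.float64)
    sign = -1.0 if reaction else 1.0
    F = sign * (grf.F @ R_plate.T) @ R.T
    torque = sign * (grf.torque @ R_plate.T) @ R.T
    cop = (grf.cop @ R_plate.T + center_m) @ R.T
    return GRFSeries(F=F, cop=cop, torque=torque, contact=grf.contact.copy(),
                     frame="global", plate_index=grf.plate_index,
                     threshold=grf.threshold)
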