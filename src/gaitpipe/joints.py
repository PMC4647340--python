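"""Subject-specific joint centers from static standing trials.

Model scaling benefits from subject-specific joint centers. The hip joint
center is estimated with the Harrington pelvic regression: pelvic width PW
(ASIS-to-ASIS distance) and pelvic depth PD (mid-ASIS to mid-PSIS distance)
predict the HJC offset in a pelvis-fixed frame. All other supported joints
(knee, ankle, elbow, shoulder, wrist) are the midpoint of two user-chosen
anatomical landmarks, e.g. the femoral epicondyles for the knee.

The pelvis frame is pinned as: origin at the mid-ASIS point, z toward the
right ASIS, x anterior (mid-PSIS toward mid-ASIS, orthogonalized against z),
y = z x x (pointing up for a standing subject). All constructions commute
with rigid transforms of the input pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionData

#: Harrington pelvic regression coefficients, millimetres.
#: offset = scale * predictor + intercept, expressed in the pelvis frame;
#: x anterior, y up, z right. The z offset is mirrored for the left side.
#: Source: Harrington et al.'s combined regression (adults and children),
#: J Biomech 40(3):595-602, 2007.
HARRINGTON_COEFFS = {
    "x": {"scale": -0.24, "predictor": "PD", "intercept": -9.9},
    "y": {"scale": -0.30, "predictor": "PW", "intercept": -10.9},
    "z": {"scale": 0.33, "predictor": "PW", "intercept": 7.3},
}

#: Default pelvis landmark names (a common C3D marker dialect).
PELVIS_LANDMARKS = ("LASI", "RASI", "LPSI", "RPSI")

MIN_VALID_FRAMES = 10


class JointCenterError(ValueError):
    """Missing landmarks or degenerate geometry."""


@dataclass
class StaticPose:
    """Mean marker positions (mm, acquisition frame) over a static trial."""

    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.positions[label]
        except KeyError:
            raise JointCenterError(
                f"landmark {label!r} is not present in the static pose "
                f"(available: {sorted(self.positions)})") from None

    def __contains__(self, label: str) -> bool:
        return label in self.positions


@dataclass(frozen=True)
class JointCenterResult:
    joint: str
    side: str               # left | right | ""
    position: np.ndarray    # (3,) mm, acquisition frame
    method: str             # harrington | midpoint

    @property
    def label(self) -> str:
        suffix = {"left": "_L", "right": "_R"}.get(self.side, "")
        return f"{self.joint.upper()}{suffix}"


def mean_pose(acq: AcquisitionData, min_valid: int = MIN_VALID_FRAMES) -> StaticPose:
    """Average each marker over its valid frames only.

    A landmark with fewer than ``min_valid`` valid frames is rejected: a
    static mean built on a handful of samples is not trustworthy.
    """
    pose = StaticPose()
    for m in acq.markers:
        ok = ~m.mask
        if int(ok.sum()) < min_valid:
            raise JointCenterError(
                f"marker {m.label!r} has only {int(ok.sum())} valid frame(s) "
                f"in the static trial; at least {min_valid} are required")
        pose.positions[m.label] = m.positions[ok].mean(axis=0)
    return pose


def pelvis_frame(lasis: np.ndarray, rasis: np.ndarray,
                 lpsis: np.ndarray, rpsis: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pelvis origin (mid-ASIS) and orthonormal axes as columns (x, y, z)."""
    lasis, rasis = np.asarray(lasis, float), np.asarray(rasis, float)
    lpsis, rpsis = np.asarray(lpsis, float), np.asarray(rpsis, float)
    origin = 0.5 * (lasis + rasis)
    mid_psis = 0.5 * (lpsis + rpsis)
    z = rasis - lasis
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise JointCenterError("ASIS landmarks coincide; pelvis frame undefined")
    z = z / nz
    x = origin - mid_psis
    x = x - (x @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise JointCenterError("pelvis landmarks are collinear; frame undefined")
    x = x / nx
    y = np.cross(z, x)
    return origin, np.column_stack([x, y, z])


def harrington_local_offsets(pw: float, pd: float, side: str) -> np.ndarray:
    """HJC offset (mm) in the pelvis frame for pelvic width/depth in mm."""
    values = {"PW": pw, "PD": pd}
    off = np.array([c["scale"] * values[c["predictor"]] + c["intercept"]
                    for c in HARRINGTON_COEFFS.values()])
    if side == "left":
        off[2] = -off[2]
    elif side != "right":
        raise JointCenterError(f"side must be 'left' or 'right', got {side!r}")
    return off


def harrington_hjc(pose: StaticPose, side: str,
                   landmarks: tuple[str, str, str, str] = PELVIS_LANDMARKS,
                   ) -> JointCenterResult:
    """Hip joint center via the Harrington pelvic regression."""
    lasi, rasi, lpsi, rpsi = (pose[name] for name in landmarks)
    origin, axes = pelvis_frame(lasi, rasi, lpsi, rpsi)
    pw = float(np.linalg.norm(lasi - rasi))
    pd = float(np.linalg.norm(origin - 0.5 * (lpsi + rpsi)))
    local = harrington_local_offsets(pw, pd, side)
    return JointCenterResult(joint="hjc", side=side,
                             position=origin + axes @ local,
                             method="harrington")


def midpoint_center(pose: StaticPose, joint: str, landmark_a: str, landmark_b: str,
                    side: str = "") -> JointCenterResult:
    """Joint center as the arithmetic midpoint of two landmarks."""
    p = 0.5 * (pose[landmark_a] + pose[landmark_b])
    return JointCenterResult(joint=joint, side=side, position=p, method="midpoint")


def compute_centers(pose: StaticPose, static_cfg) -> list[JointCenterResult]:
    """All joint centers requested by the static configuration."""
    out: list[JointCenterResult] = []
    for req in static_cfg.joints:
        if req.method == "harrington":
            for side in req.sides:
                out.append(harrington_hjc(pose, side))
        else:
            out.append(midpoint_center(pose, req.name, req.landmark_a,
                                       req.landmark_b, side=req.side))
    return out
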