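"""Force-plate wrench assembly (types 1-4) and CoP / free-torque computation.

The C3D convention classifies plates by their output: type 1 reports forces
plus the centre of pressure directly; type 2 reports forces and moments from
six channels; type 3 is the 8-channel piezoelectric layout whose four
vertical and four shear transducer signals must be combined; type 4 is a
type-2 plate whose raw channels must first be premultiplied by a 6x6
calibration matrix.

All moments are interpreted about the transducer origin, located by the
plate's ORIGIN vector (from the surface centre to the transducer origin,
plate axes). With the applied force F acting at surface point p (local z=0)
and a free torque Tz about the surface normal,

    M = (p - o) x F + Tz * ez

which inverts, on frames where \\|Fz\\| clears the contact threshold, to

    CoPx = ox + (-My - oz*Fx) / Fz
    CoPy = oy + ( Mx - oz*Fy) / Fz
    Tz   = Mz - (CoPx - ox)*Fy + (CoPy - oy)*Fx

Off-contact frames carry placeholder values (CoP at the plate surface
centre, zero torque) because downstream dynamics tools reject NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import ForcePlateSpec

#: Default vertical-force contact threshold (N). The plate signals are
#: thresholded before CoP computation; 20 N rejects unloaded-plate noise
#: while keeping all of stance.
DEFAULT_FZ_THRESHOLD = 20.0


class PlateConfigError(ValueError):
    """Channel count, type, or calibration data inconsistent with the plate type."""


@dataclass
class PlateWrench:
    """Per-frame force (N) and moment (N*m) in plate-local axes.

    ``cop_direct``/``tz_direct`` retain device-reported CoP (m) and free
    torque for type-1 plates; for those plates the moments are synthesised
    from the reported CoP so that one uniform wrench path serves all types.
    """

    F: np.ndarray                      # (n, 3) N
    M: np.ndarray                      # (n, 3) N*m about the transducer origin
    valid: np.ndarray = None           # (n,) bool
    cop_direct: np.ndarray | None = None
    tz_direct: np.ndarray | None = None

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=np.float64)
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.F.shape != self.M.shape:
            raise ValueError("force and moment arrays must have the same shape")
        if self.valid is None:
            self.valid = np.ones(self.F.shape[0], dtype=bool)


@dataclass
class GRFSeries:
    """Ground-reaction series of one plate: force, CoP point, torque vector.

    In the plate-local frame the torque is the free torque (0, 0, Tz) and the
    CoP lies on the surface plane (z = 0). ``frame`` tags the frame of
    reference: ``plate-local``, ``lab`` or ``global``.
    """

    F: np.ndarray                      # (n, 3) N
    cop: np.ndarray                    # (n, 3) m
    torque: np.ndarray                 # (n, 3) N*m
    contact: np.ndarray                # (n,) bool
    frame: str = "plate-local"
    plate_index: int = 0
    threshold: float = DEFAULT_FZ_THRESHOLD

    @property
    def tz(self) -> np.ndarray:
        return self.torque[:, 2]

    def copy(self) -> "GRFSeries":
        return GRFSeries(self.F.copy(), self.cop.copy(), self.torque.copy(),
                         self.contact.copy(), self.frame, self.plate_index,
                         self.threshold)


def _moments_from_cop(F: np.ndarray, cop_m: np.ndarray, tz: np.ndarray,
                      origin_m: np.ndarray) -> np.ndarray:
    """Forward model: moments about the transducer origin from CoP and Tz."""
    d = cop_m - origin_m[None, :]
    M = np.cross(d, F)
    M[:, 2] += tz
    return M


def assemble_wrench(channels: np.ndarray, spec: ForcePlateSpec,
                    length_unit_mm: bool = True) -> PlateWrench:
    """Build the plate-local wrench from raw analog channels.

    ``channels`` has shape (nsamples, n_channels) ordered per the plate's
    canonical channel order:

    * type 1: (Fx, Fy, Fz, CoPx, CoPy, Tz) — CoP in the acquisition length
      unit relative to the plate surface centre, Tz in N*m;
    * type 2: (Fx, Fy, Fz, Mx, My, Mz) — moments in N*m;
    * type 3: (fx12, fx34, fy14, fy23, fz1, fz2, fz3, fz4) with transducer
      numbering 1 = +x+y, 2 = -x+y, 3 = -x-y, 4 = +x-y and sensor offsets
      a (x, m) and b (y, m);
    * type 4: type-2 channel vector premultiplied per frame by the 6x6
      calibration matrix.
    """
    channels = np.asarray(channels, dtype=np.float64)
    if channels.ndim != 2 or channels.shape[1] != spec.n_channels:
        raise PlateConfigError(
            f"plate {spec.index} (type {spec.type}) expects {spec.n_channels} "
            f"channels, got {channels.shape[1] if channels.ndim == 2 else channels.ndim}")
    scale = 0.001 if length_unit_mm else 1.0

    if spec.type == 1:
        F = channels[:, 0:3]
        cop = np.zeros_like(F)
        cop[:, 0] = channels[:, 3] * scale
        cop[:, 1] = channels[:, 4] * scale
        tz = channels[:, 5]
        origin_m = np.asarray(spec.origin, dtype=float) * 0.001
        M = _moments_from_cop(F, cop, tz, origin_m)
        return PlateWrench(F=F, M=M, cop_direct=cop, tz_direct=tz)

    if spec.type == 2:
        return PlateWrench(F=channels[:, 0:3].copy(), M=channels[:, 3:6].copy())

    if spec.type == 3:
        if spec.sensor_offsets is None:
            raise PlateConfigError(
                f"plate {spec.index} is type 3 but has no sensor offsets (a, b)")
        a, b = spec.sensor_offsets
        fx12, fx34, fy14, fy23 = channels[:, 0], channels[:, 1], channels[:, 2], channels[:, 3]
        fz1, fz2, fz3, fz4 = channels[:, 4], channels[:, 5], channels[:, 6], channels[:, 7]
        F = np.column_stack([fx12 + fx34, fy14 + fy23, fz1 + fz2 + fz3 + fz4])
        M = np.column_stack([
            b * (fz1 + fz2 - fz3 - fz4),
            a * (-fz1 + fz2 + fz3 - fz4),
            b * (-fx12 + fx34) + a * (fy14 - fy23),
        ])
        return PlateWrench(F=F, M=M)

    if spec.type == 4:
        if spec.cal_matrix is None:
            raise PlateConfigError(
                f"plate {spec.index} is type 4 but carries no calibration matrix")
        cal = np.asarray(spec.cal_matrix, dtype=np.float64)
        if cal.shape != (6, 6):
            raise PlateConfigError("calibration matrix must be 6x6")
        w = channels @ cal.T
        return PlateWrench(F=w[:, 0:3], M=w[:, 3:6])

    raise PlateConfigError(f"unsupported force-plate type {spec.type}")


def compute_cop_and_torque(w: PlateWrench, origin_m: np.ndarray,
                           fz_threshold: float = DEFAULT_FZ_THRESHOLD,
                           plate_index: int = 0) -> GRFSeries:
    """Invert the plate wrench to CoP and free torque on contact frames.

    ``origin_m`` is the surface-centre -> transducer-origin vector in metres.
    Frames with \\|Fz\\| below ``fz_threshold`` get the off-contact
    placeholder (CoP at the surface centre, zero torque); the force is passed
    through unchanged. The division is guarded by the contact mask, so no
    frame ever divides by a small Fz.
    """
    origin_m = np.asarray(origin_m, dtype=np.float64).reshape(3)
    F, M = w.F, w.M
    n = F.shape[0]
    contact = (np.abs(F[:, 2]) >= fz_threshold) & w.valid
    cop = np.zeros((n, 3))
    torque = np.zeros((n, 3))
    if np.any(contact):
        Fx, Fy, Fz = F[contact, 0], F[contact, 1], F[contact, 2]
        Mx, My, Mz = M[contact, 0], M[contact, 1], M[contact, 2]
        ox, oy, oz = origin_m
        cx = ox + (-My - oz * Fx) / Fz
        cy = oy + (Mx - oz * Fy) / Fz
        cop[contact, 0] = cx
        cop[contact, 1] = cy
        torque[contact, 2] = Mz - (cx - ox) * Fy + (cy - oy) * Fx
    return GRFSeries(F=F.copy(), cop=cop, torque=torque, contact=contact,
                     frame="plate-local", plate_index=plate_index,
                     threshold=fz_threshold)


def zero_off_contact(grf: GRFSeries) -> GRFSeries:
    """Exported-series policy: zero force and torque outside contact."""
    out = grf.copy()
    out.F[~out.contact] = 0.0
    out.torque[~out.contact] = 0.0
    return out
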