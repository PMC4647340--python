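"""Synthetic gait sessions with known ground truth.

Every pipeline stage is testable without external recordings: this module
fabricates a complete session — one static standing trial plus dynamic
walking trials — writes it through the same C3D layer the pipeline reads,
and returns the generating truth (applied wrenches, contact intervals,
pre-occlusion marker curves, EMG modulation, joint-center geometry).

Modelled structure (not physiological realism):

* vertical GRF is a double-hump (two Gaussian bumps) confined exactly to the
  true contact interval, with a sharp onset (the curve is >= ~50 N at the
  interval edges and identically zero outside), so threshold crossings are
  sample-exact for any threshold below the in-contact minimum;
* the CoP progresses heel to toe along the plate; shear forces are small
  fractions of the vertical force; a small free torque oscillates about the
  surface normal;
* per-plate raw analog channels are produced by the exact forward model of
  the plate type (type-3 transducer signals constructed so the documented
  combination recovers the truth; type-4 channels premultiplied by the
  inverse calibration matrix; type-1 channels carry CoP directly);
* markers follow smooth walking curves with sinusoidal gait oscillation;
  occlusion gaps are injected at recorded frames;
* EMG is a constant-amplitude band-limited noise carrier (randomized phase,
  amplitude flattened via the analytic signal) gated by stance-locked
  Gaussian bursts, so the expected rectified-mean envelope is exactly
  (2/pi) * amplitude * burst(t).

All randomness flows from one seed through a single generator; with a fixed
seed the session is byte-identical across runs. Noise enters as fixed
standard-normal draws multiplied by the configured levels, so recovery
error is monotone in each noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from . import _c3d
from .acquisition import AcquisitionData, ForcePlateSpec, load_acquisition

LAB_AXES = {"x": "+x", "y": "+z", "z": "-y"}  # lab X fwd / Y left / Z up -> model


@dataclass(frozen=True)
class NoiseLevels:
    """Additive gaussian noise, in the native unit of each channel."""

    marker_mm: float = 0.2
    force_n: float = 0.5
    emg_rel: float = 0.02   # relative to each muscle's burst amplitude

    @classmethod
    def zero(cls) -> "NoiseLevels":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SessionParams:
    n_trials: int = 3
    video_rate: float = 100.0
    analog_rate: float = 1000.0
    duration: float = 2.4           # s per dynamic trial
    static_frames: int = 120
    plate_types: tuple[int, ...] = (2, 3)
    noise: NoiseLevels = field(default_factory=NoiseLevels)
    walking_speed: float = 1200.0   # mm/s
    subject: str = "subject01"
    session: str = "session1"

    @property
    def ratio(self) -> int:
        r = self.analog_rate / self.video_rate
        if abs(r - round(r)) > 1e-9:
            raise ValueError("analog rate must be an integer multiple of the video rate")
        return int(round(r))


# plate geometry (mm, lab frame, surfaces at z = 0)
_PLATE_SIZE = np.array([600.0, 400.0])
_PLATE_CENTERS = [np.array([300.0, 0.0, 0.0]), np.array([900.0, 0.0, 0.0])]
_PLATE_ORIGINS = [np.array([0.0, 0.0, -40.0]), np.array([0.0, 0.0, -45.0])]
_SENSOR_OFFSETS = (0.25, 0.15)      # a (x), b (y), metres, type-3 plates
_EMG_MUSCLES = [                    # (name, amplitude V, plate gating the burst, center s)
    ("rectus_femoris_r", 0.8e-3, 1, 0.30),
    ("gastrocnemius_r", 1.2e-3, 1, 0.70),
    ("rectus_femoris_l", 0.9e-3, 2, 0.30),
    ("tibialis_anterior_l", 1.0e-3, 2, 0.65),
]
_GAPS = [("RKNE", 60, 5), ("LANK", 120, 8), ("RTOE", 0, 4), ("LHEE", 150, 25)]


def plate_corners(center: np.ndarray) -> np.ndarray:
    hx, hy = _PLATE_SIZE / 2.0
    return center + np.array([[-hx, -hy, 0.0], [hx, -hy, 0.0],
                              [hx, hy, 0.0], [-hx, hy, 0.0]])


def default_cal_matrix() -> np.ndarray:
    """Well-conditioned 6x6 calibration matrix for type-4 plates."""
    c = np.eye(6)
    for i in range(6):
        c[i, (i + 1) % 6] = 0.04
        c[i, (i + 2) % 6] = -0.02
    return c


def make_plate_specs(plate_types: tuple[int, ...]) -> list[ForcePlateSpec]:
    specs = []
    ch0 = 0
    for i, ptype in enumerate(plate_types):
        nch = 8 if ptype == 3 else 6
        specs.append(ForcePlateSpec(
            index=i + 1, type=ptype,
            corners=plate_corners(_PLATE_CENTERS[i % len(_PLATE_CENTERS)]),
            origin=_PLATE_ORIGINS[i % len(_PLATE_ORIGINS)].copy(),
            channel_indices=list(range(ch0 + 1, ch0 + 1 + nch)),
            cal_matrix=default_cal_matrix() if ptype == 4 else None,
            sensor_offsets=_SENSOR_OFFSETS if ptype == 3 else None))
        ch0 += nch
    return specs


# ---------------------------------------------------------------------------
# ground-truth wrench and its channel-level forward models
# ---------------------------------------------------------------------------

def stance_wrench(t: np.ndarray, t_on: float, t_off: float,
                  peak_n: float = 550.0):
    """Truth (F, cop_local_m, tz) on the analog time grid.

    Zero outside [t_on, t_off); inside, a double-hump vertical force with
    heel-to-toe CoP progression, anterior-posterior shear, and a small free
    torque.
    """
    n = t.shape[0]
    F = np.zeros((n, 3))
    cop = np.zeros((n, 3))
    tz = np.zeros(n)
    inside = (t >= t_on) & (t < t_off)
    s = (t[inside] - t_on) / (t_off - t_on)
    fz = peak_n * (np.exp(-0.5 * ((s - 0.28) / 0.13) ** 2)
                   + np.exp(-0.5 * ((s - 0.72) / 0.13) ** 2))
    F[inside, 0] = -0.15 * fz * np.sin(2.0 * np.pi * s)
    F[inside, 1] = 0.05 * fz * np.sin(np.pi * s)
    F[inside, 2] = fz
    cop[inside, 0] = -0.12 + 0.27 * s
    cop[inside, 1] = 0.02 * np.sin(np.pi * s)
    tz[inside] = 1.2 * np.sin(2.0 * np.pi * s)
    return F, cop, tz


def moments_about_origin(F: np.ndarray, cop_m: np.ndarray, tz: np.ndarray,
                         origin_mm: np.ndarray) -> np.ndarray:
    """Forward model M = (p - o) x F + Tz * ez, transducer-origin moments."""
    o = np.asarray(origin_mm, dtype=float) * 0.001
    d = cop_m - o[None, :]
    M = np.cross(d, F)
    M[:, 2] += tz
    return M


def channels_from_wrench(spec: ForcePlateSpec, F: np.ndarray, M: np.ndarray,
                         cop_m: np.ndarray | None = None,
                         tz: np.ndarray | None = None) -> np.ndarray:
    """Raw analog channels that the plate type would report for this wrench.

    Exact inverse of the assembly path: feeding the result to
    ``assemble_wrench`` reproduces (F, M) (types 2-4) or the reported CoP
    (type 1, which requires ``cop_m`` and ``tz``).
    """
    if spec.type == 1:
        if cop_m is None or tz is None:
            raise ValueError("type-1 channels require the CoP and free torque")
        return np.column_stack([F, cop_m[:, 0] * 1000.0, cop_m[:, 1] * 1000.0, tz])
    if spec.type == 2:
        return np.column_stack([F, M])
    if spec.type == 3:
        a, b = spec.sensor_offsets
        qu = M[:, 0] / (4.0 * b)        # vertical-quadrant Mx share
        qv = M[:, 1] / (4.0 * a)        # vertical-quadrant My share
        dx = -M[:, 2] / (4.0 * b)       # shear split carrying half of Mz
        dy = M[:, 2] / (4.0 * a)
        fz4 = F[:, 2] / 4.0
        return np.column_stack([
            F[:, 0] / 2.0 + dx, F[:, 0] / 2.0 - dx,
            F[:, 1] / 2.0 + dy, F[:, 1] / 2.0 - dy,
            fz4 + qu - qv, fz4 + qu + qv, fz4 - qu + qv, fz4 - qu - qv])
    if spec.type == 4:
        w = np.column_stack([F, M])
        return np.linalg.solve(np.asarray(spec.cal_matrix, dtype=float),
                               w.T).T
    raise ValueError(f"unsupported plate type {spec.type}")


# ---------------------------------------------------------------------------
# session truth containers
# ---------------------------------------------------------------------------

@dataclass
class PlateTruth:
    plate_index: int
    type: int
    contact: tuple[float, float]        # (t_on, t_off) s
    F: np.ndarray                       # (n, 3) N, plate-local
    cop: np.ndarray                     # (n, 3) m, plate-local
    tz: np.ndarray                      # (n,) N*m
    channels: np.ndarray                # (n, nch) noiseless


@dataclass
class TrialTruth:
    name: str
    plates: list[PlateTruth]
    markers: dict[str, np.ndarray]      # pre-occlusion, pre-noise (nframes, 3) mm
    gaps: list[tuple[str, int, int]]    # (label, start frame 0-based, length)
    emg_envelope: dict[str, np.ndarray] # expected rectified-mean envelope (V)
    emg_amplitude: dict[str, float]


@dataclass
class GaitSessionTruth:
    seed: int
    params: SessionParams
    trials: dict[str, TrialTruth] = field(default_factory=dict)
    static_markers: dict[str, np.ndarray] = field(default_factory=dict)  # mm
    joint_centers: dict[str, np.ndarray] = field(default_factory=dict)   # mm
    static_occlusion: tuple[str, int, int] = ("RASI", 10, 5)


# ---------------------------------------------------------------------------
# marker curves
# ---------------------------------------------------------------------------

_MARKER_OFFSETS = {     # mm, relative to the pelvis centre path
    "LASI": (80, 120, 0), "RASI": (80, -120, 0),
    "LPSI": (-80, 60, 20), "RPSI": (-80, -60, 20),
    "RKNE": (60, -110, -470), "LKNE": (60, 110, -470),
    "RANK": (40, -130, -870), "LANK": (40, 130, -870),
    "RHEE": (-40, -120, -910), "LHEE": (-40, 120, -910),
    "RTOE": (180, -120, -920), "LTOE": (180, 120, -920),
}
MARKER_PROTOCOL = list(_MARKER_OFFSETS)


def _marker_curves(params: SessionParams, rng: np.random.Generator,
                   ) -> dict[str, np.ndarray]:
    nframes = int(round(params.duration * params.video_rate))
    t = np.arange(nframes) / params.video_rate
    pelvis = np.column_stack([
        params.walking_speed * t,
        10.0 * np.sin(2.0 * np.pi * 1.0 * t),
        950.0 + 15.0 * np.sin(2.0 * np.pi * 2.0 * t),
    ])
    out: dict[str, np.ndarray] = {}
    for label, off in _MARKER_OFFSETS.items():
        phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
        wobble = 5.0 * np.sin(2.0 * np.pi * 1.0 * t[:, None] + phase[None, :])
        out[label] = pelvis + np.asarray(off, dtype=float)[None, :] + wobble
    return out


_STATIC_LANDMARKS = {   # mm, lab frame, standing at x = 500
    "LASI": (580, 120, 950), "RASI": (580, -120, 950),
    "LPSI": (420, 60, 970), "RPSI": (420, -60, 970),
    "RKNE": (560, -125, 480), "LKNE": (560, 125, 480),
    "RLEP": (560, -170, 480), "RMEP": (560, -80, 480),
    "LLEP": (560, 170, 480), "LMEP": (560, 80, 480),
    "RLMA": (540, -150, 80), "RMMA": (540, -90, 80),
    "LLMA": (540, 150, 80), "LMMA": (540, 90, 80),
    "RANK": (540, -120, 80), "LANK": (540, 120, 80),
    "RHEE": (460, -120, 30), "LHEE": (460, 120, 30),
    "RTOE": (680, -120, 20), "LTOE": (680, 120, 20),
}


def _static_truth_centers() -> dict[str, np.ndarray]:
    lm = {k: np.asarray(v, dtype=float) for k, v in _STATIC_LANDMARKS.items()}
    centers = {
        "KJC_R": 0.5 * (lm["RLEP"] + lm["RMEP"]),
        "KJC_L": 0.5 * (lm["LLEP"] + lm["LMEP"]),
        "AJC_R": 0.5 * (lm["RLMA"] + lm["RMMA"]),
        "AJC_L": 0.5 * (lm["LLMA"] + lm["LMMA"]),
    }
    # Harrington regression evaluated inline on the noiseless landmarks
    mid_asis = 0.5 * (lm["LASI"] + lm["RASI"])
    mid_psis = 0.5 * (lm["LPSI"] + lm["RPSI"])
    pw = float(np.linalg.norm(lm["LASI"] - lm["RASI"]))
    pd = float(np.linalg.norm(mid_asis - mid_psis))
    z = (lm["RASI"] - lm["LASI"]) / pw
    x = mid_asis - mid_psis
    x = x - (x @ z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    lx, ly, lz = -0.24 * pd - 9.9, -0.30 * pw - 10.9, 0.33 * pw + 7.3
    centers["HJC_R"] = mid_asis + lx * x + ly * y + lz * z
    centers["HJC_L"] = mid_asis + lx * x + ly * y - lz * z
    return centers


# ---------------------------------------------------------------------------
# EMG carrier
# ---------------------------------------------------------------------------

def constant_amplitude_carrier(n: int, rate: float, rng: np.random.Generator,
                               band: tuple[float, float] = (50.0, 350.0),
                               ) -> np.ndarray:
    """Band-limited noise with unit instantaneous amplitude.

    White noise is band-passed in the frequency domain, then divided by its
    analytic-signal amplitude, leaving only phase randomness. Rectifying and
    low-passing the result yields 2/pi on average.
    """
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spectrum[(freqs < band[0]) | (freqs > band[1])] = 0.0
    carrier = np.fft.irfft(spectrum, n)
    amp = np.abs(hilbert(carrier))
    return carrier / np.maximum(amp, 1e-12 * np.max(amp))


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _dynamic_trial(name: str, params: SessionParams, specs: list[ForcePlateSpec],
                   rng: np.random.Generator, shift_s: float):
    """Build one dynamic trial; returns (TrialTruth, c3d write kwargs)."""
    nframes = int(round(params.duration * params.video_rate))
    nsamples = nframes * params.ratio
    t = np.arange(nsamples) / params.analog_rate
    contacts = [(0.5 + shift_s, 1.1 + shift_s), (1.0 + shift_s, 1.6 + shift_s)]

    plates: list[PlateTruth] = []
    analog_cols: list[np.ndarray] = []
    analog_labels: list[str] = []
    analog_units: list[str] = []
    for i, spec in enumerate(specs):
        t_on, t_off = contacts[i % len(contacts)]
        F, cop, tz = stance_wrench(t, t_on, t_off)
        M = moments_about_origin(F, cop, tz, spec.origin)
        channels = channels_from_wrench(spec, F, M, cop_m=cop, tz=tz)
        plates.append(PlateTruth(spec.index, spec.type, (t_on, t_off),
                                 F, cop, tz, channels))
        noisy = channels + params.noise.force_n * rng.standard_normal(channels.shape)
        for k in range(channels.shape[1]):
            analog_cols.append(noisy[:, k])
            analog_labels.append(f"FP{spec.index}_{k + 1}")
            analog_units.append("N")

    emg_envelope: dict[str, np.ndarray] = {}
    emg_amplitude: dict[str, float] = {}
    for muscle, amp, plate_no, center_s in _EMG_MUSCLES:
        t_on, t_off = contacts[(plate_no - 1) % len(contacts)]
        center = t_on + center_s * (t_off - t_on)
        burst = np.exp(-0.5 * ((t - center) / 0.09) ** 2)
        carrier = constant_amplitude_carrier(nsamples, params.analog_rate, rng)
        raw = amp * burst * carrier \
            + params.noise.emg_rel * amp * rng.standard_normal(nsamples)
        analog_cols.append(raw)
        analog_labels.append(muscle)
        analog_units.append("V")
        emg_envelope[muscle] = (2.0 / np.pi) * amp * burst
        emg_amplitude[muscle] = amp

    markers = _marker_curves(params, rng)
    residuals = {lb: np.zeros(nframes) for lb in markers}
    noisy_markers = {
        lb: pos + params.noise.marker_mm * rng.standard_normal(pos.shape)
        for lb, pos in markers.items()}
    gaps = [(lb, s, ln) for (lb, s, ln) in _GAPS if lb in markers]
    for lb, start, length in gaps:
        residuals[lb][start:start + length] = -1.0

    events = []
    for i, (t_on, t_off) in enumerate(contacts[:len(specs)]):
        side = "Right" if i == 0 else "Left"
        events.append(("Foot Strike", side, t_on))
        events.append(("Foot Off", side, t_off))

    truth = TrialTruth(name=name, plates=plates, markers=markers, gaps=gaps,
                       emg_envelope=emg_envelope, emg_amplitude=emg_amplitude)
    labels = list(markers)
    kwargs = dict(
        points=np.stack([noisy_markers[lb] for lb in labels], axis=1),
        residuals=np.stack([residuals[lb] for lb in labels], axis=1),
        point_labels=labels,
        video_rate=params.video_rate,
        analog=np.column_stack(analog_cols),
        analog_labels=analog_labels,
        analog_rate=params.analog_rate,
        analog_units=analog_units,
        force_platforms=[dict(type=s.type, corners=s.corners, origin=s.origin,
                              channels=s.channel_indices,
                              cal_matrix=s.cal_matrix) for s in specs],
        events=sorted(events, key=lambda e: e[2]),
    )
    return truth, kwargs


def _static_trial(params: SessionParams, rng: np.random.Generator,
                  truth: GaitSessionTruth):
    nframes = params.static_frames
    labels = list(_STATIC_LANDMARKS)
    base = np.stack([np.asarray(_STATIC_LANDMARKS[lb], dtype=float)
                     for lb in labels], axis=0)           # (npts, 3)
    points = np.tile(base[None, :, :], (nframes, 1, 1))
    points = points + params.noise.marker_mm * rng.standard_normal(points.shape)
    residuals = np.zeros((nframes, len(labels)))
    occ_label, occ_start, occ_len = truth.static_occlusion
    j = labels.index(occ_label)
    residuals[occ_start:occ_start + occ_len, j] = -1.0
    truth.static_markers = {lb: base[i].copy() for i, lb in enumerate(labels)}
    truth.joint_centers = _static_truth_centers()
    return dict(points=points, residuals=residuals, point_labels=labels,
                video_rate=params.video_rate)


def _write_configs(session_dir: Path, params: SessionParams,
                   specs: list[ForcePlateSpec], trial_names: list[str]) -> None:
    plates_xml = []
    for s in specs:
        extra = ""
        if s.type == 3:
            a, b = s.sensor_offsets
            extra = f'\n        <sensorOffsets a="{a}" b="{b}"/>'
        plates_xml.append(
            f'      <platform index="{s.index}" type="{s.type}">\n'
            f'        <channels>{" ".join(str(c) for c in s.channel_indices)}</channels>'
            f'{extra}\n      </platform>')
    emg_ch0 = sum(len(s.channel_indices) for s in specs)
    emg_xml = "\n".join(
        f'      <emg channel="{emg_ch0 + i + 1}" muscle="{m}"/>'
        for i, (m, _, _, _) in enumerate(_EMG_MUSCLES))
    markers_xml = "\n".join(f"      <marker>{m}</marker>" for m in MARKER_PROTOCOL)
    (session_dir / "acquisition.xml").write_text(f"""<?xml version="1.0"?>
<acquisition>
  <lab name="synthetic-lab">
    <units>mm</units>
    <axes><x>{LAB_AXES['x']}</x><y>{LAB_AXES['y']}</y><z>{LAB_AXES['z']}</z></axes>
    <forcePlatforms reaction="true">
{chr(10).join(plates_xml)}
    </forcePlatforms>
    <markerProtocol>
{markers_xml}
    </markerProtocol>
    <emgProtocol>
{emg_xml}
    </emgProtocol>
  </lab>
</acquisition>
""")
    trials_xml = "\n".join(f"    <trial>{t}</trial>" for t in trial_names)
    plate_list = " ".join(str(s.index) for s in specs)
    (session_dir / "elaboration.xml").write_text(f"""<?xml version="1.0"?>
<elaboration id="run1">
  <trials>
{trials_xml}
  </trials>
  <filters markerCutoff="8" grfCutoff="40" maxGap="10"/>
  <emg hpCutoff="30" lpCutoff="6"/>
  <window method="grf-threshold" threshold="20" minContact="0.05" plates="{plate_list}"/>
  <maxEmgTrials>
{trials_xml}
  </maxEmgTrials>
</elaboration>
""")
    (session_dir / "static.xml").write_text("""<?xml version="1.0"?>
<static>
  <joints>
    <joint name="hjc" method="harrington" side="both"/>
    <joint name="kjc" method="midpoint" side="right" a="RLEP" b="RMEP"/>
    <joint name="kjc" method="midpoint" side="left" a="LLEP" b="LMEP"/>
    <joint name="ajc" method="midpoint" side="right" a="RLMA" b="RMMA"/>
    <joint name="ajc" method="midpoint" side="left" a="LLMA" b="LMMA"/>
  </joints>
</static>
""")


def generate_session(root: Path | str | None, params: SessionParams | None = None,
                     seed: int = 42, write: bool = True,
                     ) -> tuple[GaitSessionTruth, dict[str, AcquisitionData]]:
    """Generate a full session; returns (truth, in-memory acquisitions).

    With ``write=True`` the session is also written as C3D files plus the
    three configuration XMLs under ``root/InputData/<subject>/<session>/``.
    The in-memory acquisitions bypass the file layer for fast unit tests but
    carry the identical (noisy) data.
    """
    params = params or SessionParams()
    rng = np.random.default_rng(seed)
    specs = make_plate_specs(params.plate_types)
    truth = GaitSessionTruth(seed=seed, params=params)
    trial_names = [f"trial{i + 1}" for i in range(params.n_trials)]

    session_dir = None
    if write:
        if root is None:
            raise ValueError("a root directory is required when write=True")
        session_dir = Path(root) / "InputData" / params.subject / params.session
        session_dir.mkdir(parents=True, exist_ok=True)

    acqs: dict[str, AcquisitionData] = {}
    for i, name in enumerate(trial_names):
        trial_truth, kwargs = _dynamic_trial(name, params, specs, rng,
                                             shift_s=0.05 * i)
        truth.trials[name] = trial_truth
        acqs[name] = _acquisition_from_kwargs(name, params, specs, kwargs)
        if write:
            _c3d.write_c3d(session_dir / f"{name}.c3d", **kwargs)

    static_kwargs = _static_trial(params, rng, truth)
    acqs["static"] = _acquisition_from_kwargs("static", params, [], static_kwargs)
    if write:
        _c3d.write_c3d(session_dir / "static.c3d", **static_kwargs)
        _write_configs(session_dir, params, specs, trial_names)
    return truth, acqs


def _acquisition_from_kwargs(name: str, params: SessionParams,
                             specs: list[ForcePlateSpec], kwargs) -> AcquisitionData:
    """Build AcquisitionData directly from generator arrays (no file I/O)."""
    from .acquisition import AnalogChannel, EventList, MarkerTrajectory

    points = kwargs["points"]
    residuals = kwargs["residuals"]
    labels = kwargs["point_labels"]
    markers = []
    for j, lb in enumerate(labels):
        mask = residuals[:, j] < 0
        pos = points[:, j, :].astype(float).copy()
        pos[mask] = np.nan
        markers.append(MarkerTrajectory(lb, pos, mask))
    analog = []
    if "analog" in kwargs and kwargs["analog"] is not None:
        arr = kwargs["analog"]
        for j, lb in enumerate(kwargs["analog_labels"]):
            analog.append(AnalogChannel(lb, arr[:, j].astype(float).copy(),
                                        kwargs["analog_rate"]))
    plates = [replace(s, corners=s.corners.copy(), origin=s.origin.copy())
              for s in specs]
    return AcquisitionData(
        markers=markers, analog=analog, plates=plates,
        events=EventList(sorted(kwargs.get("events") or [], key=lambda e: e[2])),
        video_rate=params.video_rate, units="mm", name=name)


def load_written_session(root: Path | str, params: SessionParams | None = None,
                         ) -> dict[str, AcquisitionData]:
    """Read back every trial of a written session through the C3D layer."""
    params = params or SessionParams()
    session_dir = Path(root) / "InputData" / params.subject / params.session
    out = {}
    for path in sorted(session_dir.glob("*.c3d")):
        out[path.stem] = load_acquisition(path, name=path.stem)
    return out
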