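"""Acquisition ingestion: parse C3D trials into the internal data model.

One acquisition (trial) carries five data categories: marker trajectories,
force-plate characteristics, raw analog channels (plate transducers, EMG),
events, and sampling rates. All scale factors and analog offsets are applied
on load, so downstream code always sees physical units — marker positions in
the file's length unit (normally mm), analog samples in volts or newtons.

A point sample is considered occluded when the file flags it invalid
(negative residual) or when all three coordinates are exactly zero; both
dialects occur in exported C3D files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _c3d
from ._c3d import C3DError


@dataclass
class MarkerTrajectory:
    """One labelled 3D trajectory; ``mask`` is True where the sample is missing."""

    label: str
    positions: np.ndarray   # (nframes, 3) in acquisition length units
    mask: np.ndarray        # (nframes,) bool, True = occluded

    @property
    def nframes(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "MarkerTrajectory":
        return MarkerTrajectory(self.label, self.positions.copy(), self.mask.copy())


@dataclass
class AnalogChannel:
    label: str
    samples: np.ndarray     # (nsamples,) physical units
    rate: float             # Hz


@dataclass
class ForcePlateSpec:
    """One force plate as described by the C3D FORCE_PLATFORM group.

    ``origin`` is the vector from the plate surface center to the transducer
    origin (mm, plate axes). ``channel_indices`` are 1-based analog channel
    numbers in the plate's canonical order. ``sensor_offsets`` (a, b) in
    metres apply to 8-channel piezoelectric plates (type 3) and come from the
    lab configuration, not from the file.
    """

    index: int
    type: int
    corners: np.ndarray           # (4, 3) mm, lab frame
    origin: np.ndarray            # (3,) mm
    channel_indices: list[int]
    cal_matrix: np.ndarray | None = None       # (6, 6), type 4 only
    sensor_offsets: tuple[float, float] | None = None  # (a, b) m, type 3 only

    @property
    def n_channels(self) -> int:
        return 8 if self.type == 3 else 6


@dataclass
class EventList:
    events: list[tuple[str, str, float]] = field(default_factory=list)  # (label, side, time s)

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    def times(self, label: str, side: str | None = None) -> list[float]:
        return [t for (lab, ctx, t) in self.events
                if lab == label and (side is None or ctx.lower() == side.lower())]

    def labels(self) -> list[str]:
        return sorted({lab for (lab, _, _) in self.events})


@dataclass
class AcquisitionData:
    """In-memory twin of one C3D trial."""

    markers: list[MarkerTrajectory]
    analog: list[AnalogChannel]
    plates: list[ForcePlateSpec]
    events: EventList
    video_rate: float
    units: str = "mm"
    name: str = ""

    @property
    def nframes(self) -> int:
        return self.markers[0].nframes if self.markers else 0

    @property
    def analog_rate(self) -> float:
        return self.analog[0].rate if self.analog else self.video_rate

    @property
    def rate_ratio(self) -> int:
        return int(round(self.analog_rate / self.video_rate))

    def marker(self, label: str) -> MarkerTrajectory:
        for m in self.markers:
            if m.label == label:
                return m
        raise KeyError(f"marker {label!r} not present in trial {self.name!r}")

    def channel(self, index_1based: int) -> AnalogChannel:
        return self.analog[index_1based - 1]

    def plate_channels(self, plate: ForcePlateSpec) -> np.ndarray:
        """Raw samples of a plate's channels, shape (nsamples, n_channels)."""
        cols = [self.channel(i).samples for i in plate.channel_indices]
        return np.column_stack(cols)


class ConfigurationMismatch(Exception):
    """Acquisition content contradicts what the lab configuration declares."""


def load_acquisition(path, name: str | None = None) -> AcquisitionData:
    """Load one C3D trial, applying all scale factors and analog offsets.

    Raises :class:`gaitpipe._c3d.C3DError` when the file cannot be parsed.
    """
    c = _c3d.read_c3d(path)
    valid = c.valid
    markers = [
        MarkerTrajectory(label=c.point_labels[i],
                         positions=np.where(valid[:, i:i + 1], c.points[:, i, :], np.nan),
                         mask=~valid[:, i])
        for i in range(len(c.point_labels))
    ]
    analog = [AnalogChannel(label=c.analog_labels[j],
                            samples=c.analog[:, j].copy(),
                            rate=c.analog_rate)
              for j in range(c.analog.shape[1])]

    plates: list[ForcePlateSpec] = []
    fp = c.params.get("FORCE_PLATFORM", {})
    used = int(np.atleast_1d(fp.get("USED", 0))[0]) if fp else 0
    if used:
        types = np.atleast_1d(np.asarray(fp["TYPE"], dtype=int)).ravel()
        corners = np.asarray(fp["CORNERS"], dtype=float).reshape(used, 4, 3)
        origins = np.asarray(fp["ORIGIN"], dtype=float).reshape(used, 3)
        channels = np.atleast_2d(np.asarray(fp["CHANNEL"], dtype=int)).reshape(used, -1)
        cal = fp.get("CAL_MATRIX")
        for i in range(used):
            ptype = int(types[i])
            n_needed = 8 if ptype == 3 else 6
            ch = [int(x) for x in channels[i][:n_needed] if x > 0]
            cal_m = None
            if ptype == 4 and cal is not None:
                cal_m = np.asarray(cal, dtype=float).reshape(used, 6, 6)[i].T
            plates.append(ForcePlateSpec(index=i + 1, type=ptype,
                                         corners=corners[i], origin=origins[i],
                                         channel_indices=ch, cal_matrix=cal_m))

    duration = (markers[0].nframes / c.video_rate) if markers else 0.0
    events = EventList([e for e in c.events if 0.0 <= e[2] <= duration + 1e-9]
                       if markers else list(c.events))
    return AcquisitionData(markers=markers, analog=analog, plates=plates,
                           events=events, video_rate=c.video_rate,
                           units=c.point_units,
                           name=name or str(path))


def validate_against_lab(acq: AcquisitionData, lab) -> list[str]:
    """Report discrepancies between a trial and the lab configuration.

    Returns human-readable reports; an empty list means the trial is
    consistent with the declared protocol. This never raises — callers decide
    whether a report is fatal.
    """
    reports: list[str] = []
    have_markers = {m.label for m in acq.markers}
    for label in lab.marker_protocol:
        if label not in have_markers:
            reports.append(f"protocol marker {label!r} missing from trial {acq.name!r}")
    if lab.n_plates != len(acq.plates):
        reports.append(
            f"lab configuration declares {lab.n_plates} force plate(s), "
            f"trial {acq.name!r} contains {len(acq.plates)}")
    n_analog = len(acq.analog)
    for p in lab.plates:
        for idx in p.channels:
            if idx > n_analog:
                reports.append(
                    f"plate {p.index} channel {idx} exceeds the {n_analog} "
                    f"analog channel(s) of trial {acq.name!r}")
    for ch_idx, muscle in lab.emg_map.items():
        if ch_idx > n_analog:
            reports.append(
                f"EMG channel {ch_idx} ({muscle}) exceeds the {n_analog} "
                f"analog channel(s) of trial {acq.name!r}")
    for i, (cfg_p, acq_p) in enumerate(zip(lab.plates, acq.plates), start=1):
        if cfg_p.type != acq_p.type:
            reports.append(
                f"plate {i}: configuration declares type {cfg_p.type}, "
                f"file declares type {acq_p.type}")
    if lab.units and lab.units != acq.units:
        reports.append(
            f"length units disagree: configuration says {lab.units!r}, "
            f"file says {acq.units!r}")
    return reports


def merge_lab_plate_info(acq: AcquisitionData, lab) -> None:
    """Fill plate fields the C3D file cannot carry (type-3 sensor offsets,
    channel-map overrides) from the lab configuration, in place."""
    for cfg_p, acq_p in zip(lab.plates, acq.plates):
        if cfg_p.sensor_offsets is not None:
            acq_p.sensor_offsets = cfg_p.sensor_offsets
        if cfg_p.channels:
            acq_p.channel_indices = list(cfg_p.channels)
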