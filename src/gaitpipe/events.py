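"""Analysis-window definition and gait-event detection.

A dynamic trial is rarely processed whole: the analysis window selects the
video-frame interval of interest. Three sources are supported — events
already present in the acquisition, a thresholding detector on the vertical
ground-reaction force, and manual start/stop frames from the elaboration
configuration.

Frames are 1-based (the motion-lab convention). An event at time t maps to
frame floor(t*rate) for window starts / heel strikes and ceil(t*rate) for
window stops / toe offs, clamped to the trial; an event at 1.00 s in a
100 Hz trial therefore opens the window at frame 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acquisition import EventList
from .forceplate import GRFSeries

DEFAULT_THRESHOLD_N = 20.0
DEFAULT_MIN_CONTACT_S = 0.05
DEFAULT_START_LABEL = "Foot Strike"
DEFAULT_STOP_LABEL = "Foot Off"


class WindowError(ValueError):
    """The requested analysis window cannot be built."""


def _frame_floor(t: float, rate: float) -> int:
    """floor(t*rate) robust to the float32 precision of stored event times."""
    x = t * rate
    r = round(x)
    return int(r) if abs(x - r) <= 1e-4 * max(1.0, abs(x)) else math.floor(x)


def _frame_ceil(t: float, rate: float) -> int:
    x = t * rate
    r = round(x)
    return int(r) if abs(x - r) <= 1e-4 * max(1.0, abs(x)) else math.ceil(x)


@dataclass(frozen=True)
class AnalysisWindow:
    start: int              # first video frame, 1-based, inclusive
    stop: int               # last video frame, 1-based, inclusive
    source: str             # events | grf-threshold | manual

    def __post_init__(self):
        if not 1 <= self.start <= self.stop:
            raise WindowError(f"invalid window [{self.start}, {self.stop}]")

    @property
    def nframes(self) -> int:
        return self.stop - self.start + 1


@dataclass(frozen=True)
class ContactEvent:
    kind: str               # heel-strike | toe-off
    plate_index: int
    time: float             # s
    frame: int              # video frame, 1-based


def _contact_runs(loaded: np.ndarray, min_samples: int) -> list[tuple[int, int]]:
    """Maximal runs of True lasting >= min_samples, as (first, one-past-last)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], loaded.astype(int), [0]))))
    return [(int(idx[i]), int(idx[i + 1]))
            for i in range(0, len(idx), 2)
            if idx[i + 1] - idx[i] >= min_samples]


def detect_contacts(grf: GRFSeries, analog_rate: float, video_rate: float,
                    threshold: float = DEFAULT_THRESHOLD_N,
                    min_contact: float = DEFAULT_MIN_CONTACT_S) -> list[ContactEvent]:
    """Threshold the vertical GRF into heel-strike / toe-off events.

    A contact is a maximal run of samples with \\|Fz\\| >= threshold lasting
    at least ``min_contact`` seconds (debouncing noise spikes). Heel strike
    is the first sample of the run; toe off the first sample after it. Event
    times are converted to video frames with floor (strike) / ceil (toe-off).
    """
    if threshold <= 0:
        raise WindowError("threshold must be positive")
    fz = np.abs(grf.F[:, 2])
    min_samples = max(1, int(round(min_contact * analog_rate)))
    out: list[ContactEvent] = []
    for first, stop in _contact_runs(fz >= threshold, min_samples):
        t_on = first / analog_rate
        t_off = stop / analog_rate
        out.append(ContactEvent("heel-strike", grf.plate_index, t_on,
                                max(1, _frame_floor(t_on, video_rate))))
        out.append(ContactEvent("toe-off", grf.plate_index, t_off,
                                max(1, _frame_ceil(t_off, video_rate))))
    return out


def window_from_events(events: EventList, video_rate: float, nframes: int,
                       start_label: str = DEFAULT_START_LABEL,
                       stop_label: str = DEFAULT_STOP_LABEL) -> AnalysisWindow:
    """Window from the first start-label event to the next stop-label event."""
    if len(events) == 0:
        raise WindowError(
            "trial carries no events; use the grf-threshold or manual window mode")
    starts = events.times(start_label)
    if not starts:
        raise WindowError(
            f"no {start_label!r} event in trial; available labels: {events.labels()}")
    t0 = min(starts)
    stops = [t for t in events.times(stop_label) if t > t0]
    if not stops:
        raise WindowError(
            f"no {stop_label!r} event after {t0:.3f} s; available labels: "
            f"{events.labels()}")
    t1 = min(stops)
    start = max(1, _frame_floor(t0, video_rate))
    stop = min(nframes, _frame_ceil(t1, video_rate))
    if stop < start:
        raise WindowError(f"stop event at {t1:.3f} s precedes start at {t0:.3f} s")
    return AnalysisWindow(start=start, stop=stop, source="events")


def window_from_contacts(contacts: list[ContactEvent], nframes: int) -> AnalysisWindow:
    """Window spanning the first heel strike to the last toe off."""
    strikes = [c for c in contacts if c.kind == "heel-strike"]
    offs = [c for c in contacts if c.kind == "toe-off"]
    if not strikes or not offs:
        raise WindowError("no qualifying contact found by GRF thresholding")
    start = min(c.frame for c in strikes)
    stop = min(nframes, max(c.frame for c in offs))
    return AnalysisWindow(start=start, stop=stop, source="grf-threshold")


def manual_window(start: int, stop: int, nframes: int) -> AnalysisWindow:
    if start < 1 or stop > nframes:
        raise WindowError(
            f"manual window [{start}, {stop}] outside trial of {nframes} frames")
    return AnalysisWindow(start=start, stop=stop, source="manual")


def crop_frames(arr: np.ndarray, w: AnalysisWindow) -> np.ndarray:
    """Crop a video-rate array (frames on axis 0) to the window."""
    if w.stop > arr.shape[0]:
        raise WindowError(
            f"window [{w.start}, {w.stop}] outside trial of {arr.shape[0]} frames")
    return arr[w.start - 1:w.stop].copy()


def crop_analog(arr: np.ndarray, w: AnalysisWindow, ratio: int) -> np.ndarray:
    """Crop an analog-rate array to samples [(start-1)*ratio+1, stop*ratio]."""
    if w.stop * ratio > arr.shape[0]:
        raise WindowError(
            f"window [{w.start}, {w.stop}] x ratio {ratio} outside the "
            f"{arr.shape[0]}-sample analog record")
    return arr[(w.start - 1) * ratio:w.stop * ratio].copy()


def crop_grf(grf: GRFSeries, w: AnalysisWindow, ratio: int) -> GRFSeries:
    return GRFSeries(
        F=crop_analog(grf.F, w, ratio),
        cop=crop_analog(grf.cop, w, ratio),
        torque=crop_analog(grf.torque, w, ratio),
        contact=crop_analog(grf.contact, w, ratio),
        frame=grf.frame, plate_index=grf.plate_index, threshold=grf.threshold,
    )
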