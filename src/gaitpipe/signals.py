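"""Zero-lag filtering and marker gap interpolation.

Marker trajectories and ground-reaction series are smoothed with a zero-lag
second-order low-pass Butterworth filter: the causal filter is applied
forward and then backward, cancelling its phase delay. The double pass
squares the single-pass magnitude response, so the nominal cutoff is the
-6 dB point of the effective filter (gain 0.5); no cutoff-warping
correction is applied, matching common motion-lab practice.

Occlusion gaps in marker data are restored by shape-preserving piecewise
cubic (PCHIP) interpolation, which cannot overshoot near trajectory
extrema. Only interior gaps no longer than the configured maximum are
interpolated; longer gaps and gaps touching the first or last frame are
left untouched. Every gap is logged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy.interpolate import PchipInterpolator

from .acquisition import MarkerTrajectory


class FilterError(ValueError):
    """Invalid filter parameters or a series too short to filter."""


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass zero-lag Butterworth specification (order fixed at 2)."""

    cutoff: float           # Hz
    order: int = 2


@dataclass
class GapLogEntry:
    marker: str
    start: int              # 0-based first missing frame of the gap
    length: int
    action: str             # interpolated | skipped-too-long | skipped-boundary

    def format(self) -> str:
        return f"{self.marker}\tframes {self.start + 1}-{self.start + self.length}\t{self.action}"


def _design(rate: float, cutoff: float, order: int, btype: str):
    if not 0.0 < cutoff < rate / 2.0:
        raise FilterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={rate / 2.0} Hz)")
    return _sig.butter(order, cutoff / (rate / 2.0), btype=btype)


def zero_lag_butterworth(x: np.ndarray, rate: float, spec: FilterSpec | float,
                         btype: str = "lowpass", label: str = "") -> np.ndarray:
    """Forward-backward Butterworth filter along axis 0.

    Output length equals input length and the phase shift is zero. Edge
    transients are reduced by odd-reflection padding of length 3x the filter
    order. Raises :class:`FilterError` when the cutoff is at or above the
    Nyquist frequency or the series is too short to pad.
    """
    if not isinstance(spec, FilterSpec):
        spec = FilterSpec(cutoff=float(spec))
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise FilterError(f"series {label or '<unnamed>'} contains non-finite samples")
    b, a = _design(rate, spec.cutoff, spec.order, btype)
    padlen = 3 * spec.order
    if x.shape[0] <= padlen:
        raise FilterError(
            f"series {label or '<unnamed>'} has {x.shape[0]} samples; "
            f"at least {padlen + 1} are required for zero-lag filtering")
    return _sig.filtfilt(b, a, x, axis=0, padtype="odd", padlen=padlen)


def _gap_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (start, length) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return [(int(idx[i]), int(idx[i + 1] - idx[i])) for i in range(0, len(idx), 2)]


def fill_gaps(traj: MarkerTrajectory, max_gap: int) -> tuple[MarkerTrajectory, list[GapLogEntry]]:
    """Interpolate interior occlusion gaps of length <= ``max_gap``.

    Valid samples are never modified. ``max_gap = 0`` disables interpolation
    entirely; every gap is then logged as skipped. Gaps touching the first or
    last frame have no bracketing data and are always skipped.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = traj.copy()
    log: list[GapLogEntry] = []
    n = traj.nframes
    runs = _gap_runs(traj.mask)
    if not runs:
        return out, log
    valid = np.flatnonzero(~traj.mask)
    if valid.size == 0:
        return out, [GapLogEntry(traj.label, 0, n, "skipped-boundary")]
    interp = None
    for start, length in runs:
        boundary = start == 0 or start + length == n
        if boundary:
            log.append(GapLogEntry(traj.label, start, length, "skipped-boundary"))
            continue
        if max_gap == 0 or length > max_gap:
            log.append(GapLogEntry(traj.label, start, length, "skipped-too-long"))
            continue
        if interp is None:
            interp = PchipInterpolator(valid, traj.positions[valid], axis=0,
                                       extrapolate=False)
        frames = np.arange(start, start + length)
        out.positions[frames] = interp(frames)
        out.mask[frames] = False
        log.append(GapLogEntry(traj.label, start, length, "interpolated"))
    return out, log


def filter_trajectory(traj: MarkerTrajectory, rate: float,
                      spec: FilterSpec | float) -> tuple[MarkerTrajectory, list[str]]:
    """Low-pass a marker trajectory, skipping across remaining occlusions.

    Filtering runs independently on each maximal run of valid frames; runs
    too short for the filter padding are left unfiltered and reported.
    Missing frames are never invented.
    """
    if not isinstance(spec, FilterSpec):
        spec = FilterSpec(cutoff=float(spec))
    out = traj.copy()
    notes: list[str] = []
    padlen = 3 * spec.order
    for start, length in _gap_runs(~traj.mask):  # runs of VALID frames
        seg = slice(start, start + length)
        if length <= padlen:
            notes.append(f"{traj.label}: segment frames {start + 1}-{start + length} "
                         f"too short to filter ({length} samples)")
            continue
        out.positions[seg] = zero_lag_butterworth(
            traj.positions[seg], rate, spec, label=traj.label)
    return out, notes


def write_gap_log(entries: list[GapLogEntry], notes: list[str], path) -> None:
    """Plain-text gap log: one line per gap, then any filtering notes."""
    with open(path, "w") as fh:
        fh.write("# marker gap log\n")
        for e in entries:
            fh.write(e.format() + "\n")
        for note in notes:
            fh.write(f"# {note}\n")
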