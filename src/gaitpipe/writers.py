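"""Text writers for musculoskeletal-modeling software, with parsers.

Three formats are produced, all tab-delimited text with "." as the decimal
mark regardless of locale and six decimal places, so outputs are bit-stable
across platforms:

* ``.trc`` — marker trajectories (mm by default), the marker-file dialect
  with the PathFileType banner, the DataRate/CameraRate/... header pair and
  per-marker X/Y/Z column triplets; occluded samples become empty fields;
* ``.mot`` — time series with the ``datacolumns``/``datarows``/``range``
  header dialect; used for ground-reaction wrenches (force N, CoP point m,
  torque N*m, nine columns per plate) and, by default, EMG envelopes;
* ``.sto`` — the ``nRows=``/``nColumns=`` storage dialect, same payload.

The bundled parsers accept both time-series dialects and exist so every
writer is round-trip tested.
"""

from __future__ import annotations

import numpy as np

from .forceplate import GRFSeries

PRECISION = 6
_FMT = f"%.{PRECISION}f"


class WriterError(ValueError):
    """Inconsistent data shapes for the requested file."""


def _fmt(x: float) -> str:
    return _FMT % x


def _time_column(n: int, rate: float) -> np.ndarray:
    return np.arange(n) / rate


# ---------------------------------------------------------------------------
# .trc
# ---------------------------------------------------------------------------

def write_trc(markers: dict[str, np.ndarray], rate: float, path,
              units: str = "mm", masks: dict[str, np.ndarray] | None = None,
              start_frame: int = 1, name: str | None = None) -> None:
    """Write marker trajectories to a .trc file.

    ``markers`` maps label -> (nframes, 3); ``masks`` (optional) maps
    label -> boolean occlusion mask — missing samples are written as empty
    fields. Times restart at zero.
    """
    labels = list(markers)
    if not labels:
        raise WriterError("no markers to write")
    arrays = [np.asarray(markers[lb], dtype=float) for lb in labels]
    nframes = arrays[0].shape[0]
    if any(a.shape != (nframes, 3) for a in arrays):
        raise WriterError("all trajectories must share one frame count")
    masks = masks or {}
    t = _time_column(nframes, rate)
    name = name or str(path)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{_fmt(rate)}\t{_fmt(rate)}\t{nframes}\t{len(labels)}\t{units}\t"
                 f"{_fmt(rate)}\t{start_frame}\t{nframes}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(labels) + "\t\t\t\n")
        cols = "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, len(labels) + 1))
        fh.write(f"\t\t{cols}\n")
        for f in range(nframes):
            row = [str(start_frame + f), _fmt(t[f])]
            for lb, arr in zip(labels, arrays):
                missing = bool(np.asarray(masks.get(lb, ()), dtype=bool)[f]) \
                    if lb in masks else False
                if missing or not np.all(np.isfinite(arr[f])):
                    row.extend(["", "", ""])
                else:
                    row.extend(_fmt(v) for v in arr[f])
            fh.write("\t".join(row) + "\n")


def read_trc(path) -> tuple[dict[str, np.ndarray], float, str]:
    """Parse a .trc file -> (markers, rate, units); missing samples are NaN."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_vals = lines[2].split("\t")
    rate = float(header_vals[0])
    nframes = int(header_vals[2])
    nmarkers = int(header_vals[3])
    units = header_vals[4]
    labels = [s for s in lines[3].split("\t")[2:] if s][:nmarkers]
    data = np.full((nframes, nmarkers * 3), np.nan)
    for i, line in enumerate(lines[5:5 + nframes]):
        cells = line.split("\t")[2:2 + nmarkers * 3]
        for j, cell in enumerate(cells):
            if cell.strip():
                data[i, j] = float(cell)
    markers = {lb: data[:, 3 * i:3 * i + 3] for i, lb in enumerate(labels)}
    return markers, rate, units


# ---------------------------------------------------------------------------
# time-series dialects (.mot / .sto / .txt)
# ---------------------------------------------------------------------------

def _write_mot(path, name: str, columns: list[str], table: np.ndarray) -> None:
    nrows, ncols = table.shape
    t0, tf = table[0, 0], table[-1, 0]
    with open(path, "w", newline="\n") as fh:
        fh.write(f"name {name}\n")
        fh.write(f"datacolumns {ncols}\n")
        fh.write(f"datarows {nrows}\n")
        fh.write(f"range {_fmt(t0)} {_fmt(tf)}\n")
        fh.write("endheader\n")
        fh.write("\t".join(columns) + "\n")
        for row in table:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _write_sto(path, name: str, columns: list[str], table: np.ndarray) -> None:
    nrows, ncols = table.shape
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{name}\n")
        fh.write(f"nRows={nrows}\n")
        fh.write(f"nColumns={ncols}\n")
        fh.write("endheader\n")
        fh.write("\t".join(columns) + "\n")
        for row in table:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _write_txt(path, columns: list[str], table: np.ndarray) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in table:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_timeseries(path) -> tuple[list[str], np.ndarray]:
    """Parse either time-series dialect (or bare .txt) -> (columns, table)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip() == "endheader":
            start = i + 1
            break
    else:  # headerless .txt
        start = 0
    columns = lines[start].split("\t")
    data = [[float(c) for c in line.split("\t")]
            for line in lines[start + 1:] if line.strip()]
    return columns, np.asarray(data)


def grf_column_names(plate_indices: list[int]) -> list[str]:
    cols = ["time"]
    for k, idx in enumerate(plate_indices):
        prefix = "" if k == 0 else f"{k}_"
        cols += [f"{prefix}ground_force_vx", f"{prefix}ground_force_vy",
                 f"{prefix}ground_force_vz",
                 f"{prefix}ground_force_px", f"{prefix}ground_force_py",
                 f"{prefix}ground_force_pz",
                 f"{prefix}ground_torque_x", f"{prefix}ground_torque_y",
                 f"{prefix}ground_torque_z"]
    return cols


def write_grf_mot(grfs: list[GRFSeries], rate: float, path,
                  name: str = "ground reaction") -> None:
    """One .mot per trial holding every plate: per plate nine columns
    (force vx/vy/vz N, CoP px/py/pz m, torque x/y/z N*m), global frame."""
    if not grfs:
        raise WriterError("no ground-reaction series to write")
    n = grfs[0].F.shape[0]
    if any(g.F.shape[0] != n for g in grfs):
        raise WriterError("all plates must be cropped to the same window")
    t = _time_column(n, rate)
    blocks = [t[:, None]]
    for g in grfs:
        blocks += [g.F, g.cop, g.torque]
    table = np.hstack(blocks)
    _write_mot(path, name, grf_column_names([g.plate_index for g in grfs]), table)


def write_emg_mot(envelopes: dict[str, np.ndarray], rate: float, path,
                  fmt: str = "mot", name: str = "emg envelopes") -> None:
    """Normalized envelopes: time plus one column per muscle.

    ``fmt`` selects the dialect: ``mot`` (default), ``sto`` or ``txt``.
    """
    if not envelopes:
        raise WriterError("no EMG envelopes to write")
    muscles = list(envelopes)
    n = len(np.asarray(envelopes[muscles[0]]))
    if any(len(np.asarray(envelopes[m])) != n for m in muscles):
        raise WriterError("all envelopes must share a time base")
    t = _time_column(n, rate)
    table = np.column_stack([t] + [np.asarray(envelopes[m], dtype=float)
                                   for m in muscles])
    columns = ["time"] + muscles
    if fmt == "mot":
        _write_mot(path, name, columns, table)
    elif fmt == "sto":
        _write_sto(path, name, columns, table)
    elif fmt == "txt":
        _write_txt(path, columns, table)
    else:
        raise WriterError(f"unknown EMG output format {fmt!r} (mot|sto|txt)")
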