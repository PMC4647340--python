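"""Minimal C3D reader/writer.

C3D is the motion-lab interchange format: one binary file holds synchronized
3D point trajectories, analog samples (force-plate channels, EMG), the
FORCE_PLATFORM parameter group describing each plate, and labelled events.

This codec covers the subset the pipeline needs:

* Intel (little-endian) processor type only;
* floating-point or signed 16-bit integer point/analog data on read,
  floating-point on write;
* POINT, ANALOG, FORCE_PLATFORM and EVENT parameter groups.

Parameter data is stored column-major (first dimension varies fastest), so a
parameter with dimensions ``(3, 4, n)`` is returned as an array of shape
``(n, 4, 3)``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

_BLOCK = 512
_PROC_INTEL = 84

# parameter type codes
_T_CHAR = -1
_T_INT8 = 1
_T_INT16 = 2
_T_FLOAT = 4


class C3DError(Exception):
    """Raised when a file cannot be parsed as C3D."""


@dataclass
class C3DContent:
    """Decoded content of one C3D file (physical units already applied)."""

    points: np.ndarray            # (nframes, npoints, 3) in point_units
    residuals: np.ndarray         # (nframes, npoints) float, <0 = invalid
    point_labels: list[str]
    video_rate: float
    first_frame: int
    analog: np.ndarray            # (nsamples, nchannels) physical units
    analog_labels: list[str]
    analog_rate: float
    point_units: str = "mm"
    analog_units: list[str] = field(default_factory=list)
    events: list[tuple[str, str, float]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def nframes(self) -> int:
        return self.points.shape[0]

    @property
    def valid(self) -> np.ndarray:
        """True where a point sample is usable."""
        all_zero = np.all(self.points == 0.0, axis=2)
        return (self.residuals >= 0) & ~all_zero


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _decode_param(type_code: int, dims: list[int], raw: bytes):
    if type_code == _T_CHAR:
        width = dims[0] if dims else len(raw)
        if len(dims) <= 1:
            return raw.decode("ascii", "replace").rstrip()
        n = int(np.prod(dims[1:]))
        return [raw[i * width:(i + 1) * width].decode("ascii", "replace").rstrip()
                for i in range(n)]
    dtype = {_T_INT8: np.int8, _T_INT16: "<i2", _T_FLOAT: "<f4"}[type_code]
    arr = np.frombuffer(raw, dtype=dtype)
    if dims:
        arr = arr.reshape(tuple(reversed(dims)))
    elif arr.size == 1:
        return arr[0].item()
    return np.array(arr)


def _read_parameters(buf: bytes, start: int) -> dict:
    """Parse the parameter section into {GROUP: {PARAM: value}}."""
    proc = buf[start + 3]
    if proc != _PROC_INTEL:
        raise C3DError(f"unsupported processor type {proc} (only Intel/PC handled)")
    groups_by_id: dict[int, str] = {}
    out: dict[str, dict] = {}
    pending: list[tuple[int, str, object]] = []  # params seen before their group
    pos = start + 4
    while pos < len(buf) - 1:
        nchar = struct.unpack_from("<b", buf, pos)[0]
        gid = struct.unpack_from("<b", buf, pos + 1)[0]
        if nchar == 0 or gid == 0:
            break
        name = buf[pos + 2:pos + 2 + abs(nchar)].decode("ascii", "replace").upper()
        off_pos = pos + 2 + abs(nchar)
        offset = struct.unpack_from("<h", buf, off_pos)[0]
        body = off_pos + 2
        if gid < 0:  # group definition
            groups_by_id[-gid] = name
            out.setdefault(name, {})
        else:  # parameter
            type_code = struct.unpack_from("<b", buf, body)[0]
            ndims = buf[body + 1]
            dims = list(buf[body + 2:body + 2 + ndims])
            nbytes = abs(type_code) * int(np.prod(dims)) if dims else abs(type_code)
            raw = buf[body + 2 + ndims:body + 2 + ndims + nbytes]
            value = _decode_param(type_code, dims, raw)
            gname = groups_by_id.get(gid)
            if gname is None:
                pending.append((gid, name, value))
            else:
                out.setdefault(gname, {})[name] = value
        if offset == 0:
            break
        pos = off_pos + offset
    for gid, name, value in pending:
        gname = groups_by_id.get(gid)
        if gname is not None:
            out.setdefault(gname, {})[name] = value
    return out


def read_c3d(path) -> C3DContent:
    try:
        with open(path, "rb") as fh:
            buf = fh.read()
    except OSError as exc:
        raise C3DError(f"cannot read C3D file {path}: {exc}") from exc
    if len(buf) < _BLOCK or buf[1] != 0x50:
        raise C3DError(f"{path} is not a C3D file (bad magic byte)")

    param_block = buf[0]
    (npoints, analog_per_frame, first_frame, last_frame, _maxgap) = struct.unpack_from(
        "<5H", buf, 2)
    point_scale = struct.unpack_from("<f", buf, 12)[0]
    data_block = struct.unpack_from("<H", buf, 16)[0]
    ratio = struct.unpack_from("<H", buf, 18)[0]
    video_rate = struct.unpack_from("<f", buf, 20)[0]

    params = _read_parameters(buf, (param_block - 1) * _BLOCK)
    point_grp = params.get("POINT", {})
    analog_grp = params.get("ANALOG", {})

    nframes = last_frame - first_frame + 1
    nchan = analog_per_frame // ratio if ratio else 0
    is_float = point_scale < 0
    labels = list(point_grp.get("LABELS", []))[:npoints]
    while len(labels) < npoints:
        labels.append(f"PT{len(labels) + 1}")
    analog_labels = list(analog_grp.get("LABELS", []))[:nchan]
    while len(analog_labels) < nchan:
        analog_labels.append(f"CH{len(analog_labels) + 1}")

    frame_words = npoints * 4 + nchan * ratio
    pos = (data_block - 1) * _BLOCK
    if is_float:
        raw = np.frombuffer(buf, dtype="<f4", count=nframes * frame_words, offset=pos)
    else:
        raw = np.frombuffer(buf, dtype="<i2", count=nframes * frame_words, offset=pos)
    raw = raw.reshape(nframes, frame_words)

    pts = raw[:, :npoints * 4].reshape(nframes, npoints, 4).astype(np.float64)
    coords = pts[..., :3]
    w = pts[..., 3]
    if is_float:
        residuals = np.where(w < 0, -1.0, np.mod(np.abs(w), 65536.0))
    else:
        coords = coords * abs(point_scale)
        residuals = np.where(w < 0, -1.0, (w.astype(np.int64) & 0xFF) * abs(point_scale))

    analog_raw = raw[:, npoints * 4:].reshape(nframes * ratio, nchan) if nchan \
        else np.zeros((0, 0))
    analog = np.asarray(analog_raw, dtype=np.float64)
    if nchan:
        gen_scale = float(np.atleast_1d(analog_grp.get("GEN_SCALE", 1.0))[0])
        scales = np.asarray(analog_grp.get("SCALE", np.ones(nchan)), dtype=float).ravel()[:nchan]
        offsets = np.asarray(analog_grp.get("OFFSET", np.zeros(nchan)), dtype=float).ravel()[:nchan]
        analog = (analog - offsets) * scales * gen_scale

    analog_rate = float(np.atleast_1d(analog_grp.get("RATE", video_rate * ratio))[0]) \
        if nchan else video_rate * max(ratio, 1)

    events: list[tuple[str, str, float]] = []
    ev = params.get("EVENT", {})
    used = int(np.atleast_1d(ev.get("USED", 0))[0]) if ev else 0
    if used:
        times = np.asarray(ev["TIMES"], dtype=float).reshape(used, 2)
        ev_labels = list(ev.get("LABELS", [""] * used))
        contexts = list(ev.get("CONTEXTS", [""] * used))
        for i in range(used):
            t = times[i, 0] * 60.0 + times[i, 1]
            events.append((ev_labels[i], contexts[i], float(t)))
        events.sort(key=lambda e: e[2])

    units = point_grp.get("UNITS", "mm")
    if isinstance(units, list):
        units = units[0] if units else "mm"
    analog_units = analog_grp.get("UNITS", [])
    if isinstance(analog_units, str):
        analog_units = [analog_units]

    return C3DContent(
        points=coords, residuals=residuals, point_labels=labels,
        video_rate=float(video_rate), first_frame=first_frame,
        analog=analog, analog_labels=analog_labels, analog_rate=analog_rate,
        point_units=units or "mm", analog_units=list(analog_units),
        events=events, params=params,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _encode_string_array(strings: list[str], width: int | None = None) -> tuple[bytes, list[int]]:
    width = width or max((len(s) for s in strings), default=1)
    width = max(width, 1)
    data = b"".join(s[:width].ljust(width).encode("ascii") for s in strings)
    return data, [width, len(strings)]


def _param_bytes(name: str, type_code: int, dims: list[int], data: bytes, gid: int) -> bytes:
    body = struct.pack("<bB", type_code, len(dims)) + bytes(dims) + data + b"\x00"
    offset = 2 + len(body)
    return (struct.pack("<bb", len(name), gid) + name.encode("ascii")
            + struct.pack("<h", offset) + body)


def _group_bytes(name: str, gid: int) -> bytes:
    return (struct.pack("<bb", len(name), -gid) + name.encode("ascii")
            + struct.pack("<h", 3) + b"\x00")


def _p_int16(name, values, gid, dims=None):
    arr = np.atleast_1d(np.asarray(values, dtype="<i2"))
    dims = dims if dims is not None else ([len(arr)] if arr.size != 1 else [])
    return _param_bytes(name, _T_INT16, dims, arr.tobytes(), gid)


def _p_float(name, values, gid, dims=None):
    arr = np.atleast_1d(np.asarray(values, dtype="<f4"))
    dims = dims if dims is not None else ([len(arr)] if arr.size != 1 else [])
    return _param_bytes(name, _T_FLOAT, dims, arr.tobytes(), gid)


def _p_strings(name, strings, gid, width=None):
    data, dims = _encode_string_array(list(strings), width)
    return _param_bytes(name, _T_CHAR, dims, data, gid)


def write_c3d(path, *, points: np.ndarray, point_labels: list[str],
              video_rate: float, residuals: np.ndarray | None = None,
              analog: np.ndarray | None = None,
              analog_labels: list[str] | None = None,
              analog_rate: float | None = None,
              analog_units: list[str] | None = None,
              point_units: str = "mm",
              force_platforms: list[dict] | None = None,
              events: list[tuple[str, str, float]] | None = None,
              first_frame: int = 1) -> None:
    """Write a floating-point Intel C3D file.

    ``points``: (nframes, npoints, 3); ``residuals``: (nframes, npoints),
    negative marks an invalid sample. ``analog``: (nsamples, nchannels) in
    physical units (written with unit scale / zero offset). Each entry of
    ``force_platforms`` is a dict with keys ``type``, ``corners`` (4x3 mm,
    lab frame), ``origin`` (3, mm), ``channels`` (1-based analog indices) and
    optionally ``cal_matrix`` (6x6). Events are (label, context, time_s).
    """
    points = np.asarray(points, dtype=np.float64)
    nframes, npoints = points.shape[0], points.shape[1]
    if residuals is None:
        residuals = np.zeros((nframes, npoints))
    analog = np.zeros((0, 0)) if analog is None else np.asarray(analog, dtype=np.float64)
    nchan = analog.shape[1] if analog.ndim == 2 else 0
    if nchan:
        nsamples = analog.shape[0]
        if nsamples % nframes:
            raise C3DError("analog sample count must be a multiple of the frame count")
        ratio = nsamples // nframes
        if analog_rate is None:
            analog_rate = video_rate * ratio
        if abs(analog_rate - video_rate * ratio) > 1e-9:
            raise C3DError("analog rate must be an integer multiple of the video rate")
    else:
        ratio = 1
        analog_rate = video_rate
    analog_labels = analog_labels or [f"CH{i + 1}" for i in range(nchan)]
    analog_units = analog_units or ["V"] * nchan
    events = events or []
    force_platforms = force_platforms or []

    gid_point, gid_analog, gid_fp, gid_event = 1, 2, 3, 4

    def build_params(data_start_block: int) -> bytes:
        parts = [bytes([0x01, 0x50, 0, _PROC_INTEL])]  # nblocks patched later
        parts.append(_group_bytes("POINT", gid_point))
        parts.append(_p_int16("USED", npoints, gid_point))
        parts.append(_p_int16("FRAMES", min(nframes, 32767), gid_point))
        parts.append(_p_float("SCALE", -1.0, gid_point))
        parts.append(_p_float("RATE", video_rate, gid_point))
        parts.append(_p_int16("DATA_START", data_start_block, gid_point))
        parts.append(_p_strings("LABELS", point_labels, gid_point))
        parts.append(_p_strings("UNITS", [point_units], gid_point))
        parts.append(_group_bytes("ANALOG", gid_analog))
        parts.append(_p_int16("USED", nchan, gid_analog))
        parts.append(_p_float("RATE", analog_rate, gid_analog))
        parts.append(_p_float("GEN_SCALE", 1.0, gid_analog))
        if nchan:
            parts.append(_p_strings("LABELS", analog_labels, gid_analog))
            parts.append(_p_float("SCALE", np.ones(nchan), gid_analog))
            parts.append(_p_int16("OFFSET", np.zeros(nchan), gid_analog))
            parts.append(_p_strings("UNITS", analog_units, gid_analog))
        parts.append(_group_bytes("FORCE_PLATFORM", gid_fp))
        nfp = len(force_platforms)
        parts.append(_p_int16("USED", nfp, gid_fp))
        parts.append(_p_int16("ZERO", [0, 0], gid_fp, dims=[2]))
        if nfp:
            types = [fp["type"] for fp in force_platforms]
            parts.append(_p_int16("TYPE", types, gid_fp, dims=[nfp]))
            corners = np.stack([np.asarray(fp["corners"], float) for fp in force_platforms])
            parts.append(_p_float("CORNERS", corners.ravel(), gid_fp, dims=[3, 4, nfp]))
            origins = np.stack([np.asarray(fp["origin"], float) for fp in force_platforms])
            parts.append(_p_float("ORIGIN", origins.ravel(), gid_fp, dims=[3, nfp]))
            maxch = max(len(fp["channels"]) for fp in force_platforms)
            chan = np.zeros((nfp, maxch), dtype=int)
            for i, fp in enumerate(force_platforms):
                chan[i, :len(fp["channels"])] = fp["channels"]
            parts.append(_p_int16("CHANNEL", chan.ravel(), gid_fp, dims=[maxch, nfp]))
            cals = np.stack([
                np.asarray(fp.get("cal_matrix", np.zeros((6, 6))), float).T
                for fp in force_platforms])
            parts.append(_p_float("CAL_MATRIX", cals.ravel(), gid_fp, dims=[6, 6, nfp]))
        parts.append(_group_bytes("EVENT", gid_event))
        parts.append(_p_int16("USED", len(events), gid_event))
        if events:
            times = np.array([[0.0, t] for (_, _, t) in events])
            parts.append(_p_float("TIMES", times.ravel(), gid_event, dims=[2, len(events)]))
            parts.append(_p_strings("LABELS", [e[0] for e in events], gid_event))
            parts.append(_p_strings("CONTEXTS", [e[1] for e in events], gid_event))
        parts.append(b"\x00\x00")  # terminator
        blob = b"".join(parts)
        nblocks = -(-len(blob) // _BLOCK)
        blob = blob[:2] + bytes([nblocks]) + blob[3:]
        return blob + b"\x00" * (nblocks * _BLOCK - len(blob))

    params = build_params(0)
    data_start_block = 2 + len(params) // _BLOCK
    params = build_params(data_start_block)

    header = bytearray(_BLOCK)
    struct.pack_into("<BB", header, 0, 2, 0x50)
    struct.pack_into("<5H", header, 2, npoints, nchan * ratio, first_frame,
                     first_frame + nframes - 1, 10)
    struct.pack_into("<f", header, 12, -1.0)
    struct.pack_into("<H", header, 16, data_start_block)
    struct.pack_into("<H", header, 18, ratio)
    struct.pack_into("<f", header, 20, video_rate)

    frame_words = npoints * 4 + nchan * ratio
    data = np.zeros((nframes, frame_words), dtype="<f4")
    pts = np.zeros((nframes, npoints, 4), dtype="<f4")
    pts[..., :3] = points
    pts[..., 3] = residuals
    data[:, :npoints * 4] = pts.reshape(nframes, npoints * 4)
    if nchan:
        data[:, npoints * 4:] = analog.reshape(nframes, ratio * nchan)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(params)
        payload = data.tobytes()
        fh.write(payload)
        pad = (-len(payload)) % _BLOCK
        fh.write(b"\x00" * pad)
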