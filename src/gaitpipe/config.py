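"""Declarative configuration: three XML files validated against XSD schemas.

One elaboration run is governed by three files, mirroring how a motion lab
separates what rarely changes from what changes per study:

* ``acquisition.xml`` — the laboratory: coordinate-axes mapping to the model
  global frame, force-plate layout (types, analog channel maps, type-3
  sensor offsets, per-plate axes overrides), marker protocol, EMG
  channel-to-muscle map;
* ``elaboration.xml`` — one dynamic elaboration: selected trials, filter
  cutoffs and maximum gap size, analysis-window method and parameters,
  output marker list, EMG max-peak trial set, and the identifier naming the
  output subfolder;
* ``static.xml`` — joint centers of interest and the landmark pair for each
  midpoint joint.

Every file is validated against the packaged XML Schema before parsing;
schema violations are reported with the offending element and line number.
Unknown elements are rejected by the schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .frames import AxesSpec

_SCHEMA_DIR = Path(__file__).parent / "schemas"


class ConfigError(ValueError):
    """A configuration file is malformed or violates its schema."""


@dataclass
class PlateConfig:
    index: int
    type: int
    channels: list[int]
    sensor_offsets: tuple[float, float] | None = None
    axes: AxesSpec | None = None


@dataclass
class LabConfig:
    name: str
    axes: AxesSpec
    plates: list[PlateConfig] = field(default_factory=list)
    marker_protocol: list[str] = field(default_factory=list)
    emg_map: dict[int, str] = field(default_factory=dict)   # channel -> muscle
    reaction: bool = True
    units: str = "mm"

    @property
    def n_plates(self) -> int:
        return len(self.plates)


@dataclass
class WindowConfig:
    method: str
    start_label: str = "Foot Strike"
    stop_label: str = "Foot Off"
    threshold: float = 20.0
    min_contact: float = 0.05
    plates: list[int] = field(default_factory=list)
    start: int | None = None
    stop: int | None = None


@dataclass
class ElabConfig:
    identifier: str
    trials: list[str]
    window: WindowConfig
    marker_cutoff: float | None = None
    grf_cutoff: float | None = None
    max_gap: int = 10
    emg_hp: float = 30.0
    emg_lp: float = 6.0
    emg_format: str = "mot"
    output_markers: list[str] = field(default_factory=list)
    max_emg_trials: list[str] = field(default_factory=list)


@dataclass
class JointRequest:
    name: str
    method: str             # harrington | midpoint
    side: str = ""
    landmark_a: str = ""
    landmark_b: str = ""

    @property
    def sides(self) -> list[str]:
        return ["left", "right"] if self.side in ("", "both") else [self.side]


@dataclass
class StaticConfig:
    joints: list[JointRequest] = field(default_factory=list)


def parse_config(path, schema_name: str) -> etree._Element:
    """Validate an XML file against a packaged schema and return its root.

    Schema violations raise :class:`ConfigError` quoting the offending
    element and its line number.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file {path} does not exist")
    schema_doc = etree.parse(str(_SCHEMA_DIR / schema_name))
    schema = etree.XMLSchema(schema_doc)
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ConfigError(f"{path}: not well-formed XML: {exc}") from exc
    if not schema.validate(doc):
        err = schema.error_log[0]
        raise ConfigError(f"{path}:{err.line}: {err.message}")
    return doc.getroot()


def _axes_from_element(el) -> AxesSpec:
    return AxesSpec(x=el.findtext("x"), y=el.findtext("y"), z=el.findtext("z"))


def load_lab_config(path) -> LabConfig:
    root = parse_config(path, "acquisition.xsd")
    lab_el = root.find("lab")
    fp_el = lab_el.find("forcePlatforms")
    plates = []
    for p_el in fp_el.findall("platform"):
        channels = [int(x) for x in p_el.findtext("channels").split()]
        so_el = p_el.find("sensorOffsets")
        offsets = (float(so_el.get("a")), float(so_el.get("b"))) \
            if so_el is not None else None
        ax_el = p_el.find("axes")
        plates.append(PlateConfig(
            index=int(p_el.get("index")), type=int(p_el.get("type")),
            channels=channels, sensor_offsets=offsets,
            axes=_axes_from_element(ax_el) if ax_el is not None else None))
    ptype_needs = {1: 6, 2: 6, 3: 8, 4: 6}
    for p in plates:
        if len(p.channels) != ptype_needs[p.type]:
            raise ConfigError(
                f"{path}: plate {p.index} is type {p.type} and needs "
                f"{ptype_needs[p.type]} channels, got {len(p.channels)}")
        if p.type == 3 and p.sensor_offsets is None:
            raise ConfigError(
                f"{path}: plate {p.index} is type 3 and requires sensorOffsets")
    emg_map = {}
    emg_el = lab_el.find("emgProtocol")
    if emg_el is not None:
        for e in emg_el.findall("emg"):
            emg_map[int(e.get("channel"))] = e.get("muscle")
    return LabConfig(
        name=lab_el.get("name"),
        axes=_axes_from_element(lab_el.find("axes")),
        plates=plates,
        marker_protocol=[m.text for m in lab_el.find("markerProtocol").findall("marker")],
        emg_map=emg_map,
        reaction=(fp_el.get("reaction", "true").lower() in ("true", "1")),
        units=lab_el.findtext("units", "mm"),
    )


def load_elab_config(path) -> ElabConfig:
    root = parse_config(path, "elaboration.xsd")
    w_el = root.find("window")
    window = WindowConfig(
        method=w_el.get("method"),
        start_label=w_el.get("startLabel", "Foot Strike"),
        stop_label=w_el.get("stopLabel", "Foot Off"),
        threshold=float(w_el.get("threshold", "20")),
        min_contact=float(w_el.get("minContact", "0.05")),
        plates=[int(x) for x in (w_el.get("plates") or "").split()],
        start=int(w_el.get("start")) if w_el.get("start") else None,
        stop=int(w_el.get("stop")) if w_el.get("stop") else None,
    )
    if window.method == "manual" and (window.start is None or window.stop is None):
        raise ConfigError(f"{path}: manual window requires start and stop frames")
    f_el = root.find("filters")
    e_el = root.find("emg")
    cfg = ElabConfig(
        identifier=root.get("id"),
        trials=[t.text for t in root.find("trials").findall("trial")],
        window=window,
        marker_cutoff=float(f_el.get("markerCutoff")) if f_el is not None
        and f_el.get("markerCutoff") else None,
        grf_cutoff=float(f_el.get("grfCutoff")) if f_el is not None
        and f_el.get("grfCutoff") else None,
        max_gap=int(f_el.get("maxGap", "10")) if f_el is not None else 10,
        emg_hp=float(e_el.get("hpCutoff", "30")) if e_el is not None else 30.0,
        emg_lp=float(e_el.get("lpCutoff", "6")) if e_el is not None else 6.0,
        emg_format=root.get("emgFormat", "mot"),
    )
    om_el = root.find("outputMarkers")
    if om_el is not None:
        cfg.output_markers = [m.text for m in om_el.findall("marker")]
    mt_el = root.find("maxEmgTrials")
    if mt_el is not None:
        cfg.max_emg_trials = [t.text for t in mt_el.findall("trial")]
    return cfg


def load_static_config(path) -> StaticConfig:
    root = parse_config(path, "static.xsd")
    joints = []
    for j_el in root.find("joints").findall("joint"):
        req = JointRequest(
            name=j_el.get("name"), method=j_el.get("method"),
            side=j_el.get("side", ""),
            landmark_a=j_el.get("a", ""), landmark_b=j_el.get("b", ""))
        if req.method == "midpoint" and (not req.landmark_a or not req.landmark_b):
            raise ConfigError(
                f"{path}: midpoint joint {req.name!r} requires landmarks a and b")
        joints.append(req)
    return StaticConfig(joints=joints)
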