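"""File I/O, run configuration, and provenance.

Stacks travel as multi-page grayscale TIFF (8/16-bit) with a JSON sidecar
(`<file>.json`) carrying the axis metadata TIFF tags cannot hold. Tables are
UTF-8 CSV with '.' decimals and a header row, preceded by '#'-prefixed
provenance comments (tool version, config hash, seed).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .detect import DetectionParams
from .frames import FrameStack
from .simulate import SimulationConfig
from .track import TrackingParams

__all__ = [
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "parse_molarity",
    "format_molarity",
    "RunConfig",
    "config_hash",
]

logger = logging.getLogger("spiris")

_SI = {"aM": 1e-18, "fM": 1e-15, "pM": 1e-12, "nM": 1e-9,
       "uM": 1e-6, "mM": 1e-3, "M": 1.0}
_MOLARITY_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*([a-zA-Z]+)\s*$")


def parse_molarity(text: str | float) -> float:
    """Parse an SI-suffixed molarity string ('100aM', '1 fM') to molar.

    Suffixes are case-sensitive. Bare numbers pass through as molar.
    """
    if isinstance(text, (int, float)):
        return float(text)
    try:
        return float(text)
    except ValueError:
        pass
    m = _MOLARITY_RE.match(text)
    if not m or m.group(2) not in _SI:
        raise ValueError(f"cannot parse molarity {text!r}")
    return float(m.group(1)) * _SI[m.group(2)]


def format_molarity(c: float) -> str:
    """Human-readable molarity with the largest sub-unity SI suffix."""
    if c == 0:
        return "0M"
    for suffix, scale in [("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9),
                          ("pM", 1e-12), ("fM", 1e-15), ("aM", 1e-18)]:
        if abs(c) >= scale:
            return f"{c / scale:g}{suffix}"
    return f"{c:g}M"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(path, stack: FrameStack, extra_meta: dict | None = None) -> Path:
    """Write a stack as 16-bit multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    data = np.clip(np.rint(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "axis_kind": stack.axis_kind,
        "axis_values": list(map(float, stack.axis_values)),
        "pixel_pitch": stack.pixel_pitch,
        "spiris_version": __version__,
    }
    meta.update(stack.meta)
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_stack(path) -> FrameStack:
    """Read a multi-page grayscale TIFF and its sidecar metadata.

    Fails closed: RGB or mixed-shape pages raise (naming the offending
    page), as do truncated files. A missing sidecar falls back to a time
    axis with a 1 s frame interval, with a logged warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shape0 = None
        for i, page in enumerate(tif.pages):
            if page.ndim != 2:
                raise ValueError(f"page {i} of {path} is not grayscale 2-D")
            if shape0 is None:
                shape0 = page.shape
            elif page.shape != shape0:
                raise ValueError(f"page {i} of {path} has shape {page.shape}, "
                                 f"expected {shape0}")
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"{path} is not a grayscale stack")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        axis_kind = meta.pop("axis_kind")
        axis_values = np.asarray(meta.pop("axis_values"), dtype=float)
        pixel_pitch = float(meta.pop("pixel_pitch", 0.5))
        if len(axis_values) != len(frames):
            raise ValueError(f"sidecar axis length {len(axis_values)} does not "
                             f"match page count {len(frames)}")
    else:
        logger.warning("no sidecar for %s: assuming time axis, 1 s frame interval",
                       path)
        axis_kind = "time"
        axis_values = np.arange(len(frames), dtype=float)
        pixel_pitch = 0.5
        meta = {}
    return FrameStack(frames.astype(float), axis_kind, axis_values, pixel_pitch, meta)


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    """CSV with '#'-prefixed provenance comment lines before the header."""
    path = Path(path)
    lines = [f"# spiris_version={__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    body = df.to_csv(index=False, float_format="%.10g")
    path.write_text("\n".join(lines) + "\n" + body)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclasses.dataclass
class RunConfig:
    """One reproducible run: paths, stage parameters, seed.

    Serializes losslessly to/from JSON; unknown keys are rejected so typos
    fail loudly.
    """

    outdir: str = "spiris_out"
    stack: str | None = None
    kernel: str | None = None
    grid: str | None = None
    mode: str = "kinetic"
    seed: int = 0
    log_level: str = "INFO"
    replicates: int = 3
    blank_replicates: int = 12
    concentrations: list = dataclasses.field(
        default_factory=lambda: ["100aM", "1fM", "10fM"])
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    tracking: TrackingParams = dataclasses.field(default_factory=TrackingParams)

    def __post_init__(self) -> None:
        if self.mode not in ("kinetic", "endpoint"):
            raise ValueError("mode must be 'kinetic' or 'endpoint'")
        if isinstance(self.simulation, dict):
            self.simulation = _from_strict(SimulationConfig, self.simulation)
        if isinstance(self.detection, dict):
            self.detection = _from_strict(DetectionParams, self.detection)
        if isinstance(self.tracking, dict):
            self.tracking = _from_strict(TrackingParams, self.tracking)
        self.concentrations_molar = [parse_molarity(c) for c in self.concentrations]

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        for key in ("simulation", "detection", "tracking"):
            d[key] = dataclasses.asdict(d[key])
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_strict(cls, data)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())


def _from_strict(cls, data: dict):
    """Construct a dataclass, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    fixed = {}
    for k, v in data.items():
        if isinstance(v, list) and k in ("image_shape", "z_range", "area_range",
                                         "ratio_range"):
            v = tuple(v)
        fixed[k] = v
    return cls(**fixed)
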