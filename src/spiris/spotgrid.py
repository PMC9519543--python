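"""Microarray geometry: probe spots, track assignment, replicate aggregation.

Grids are authored in micrometres so they stay instrument-independent;
conversion to pixels uses the stack's pixel pitch. The default layout
matches the spotter pattern used on these chips: 16 replicate spots per
probe at a 200 um pitch.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .track import BACKGROUND, EventLog, Track

__all__ = ["Spot", "SpotGrid", "build_grid", "assign", "per_probe_curves"]


@dataclass(frozen=True)
class Spot:
    spot_id: str
    cx_um: float
    cy_um: float
    radius_um: float
    probe_label: str

    def contains(self, x_um: float, y_um: float) -> bool:
        return (x_um - self.cx_um) ** 2 + (y_um - self.cy_um) ** 2 <= self.radius_um**2


@dataclass
class SpotGrid:
    """Collection of non-overlapping circular probe spots."""

    spots: list[Spot]
    pitch_um: float = 200.0

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ValueError("spot ids must be unique")
        for i, a in enumerate(self.spots):
            for b in self.spots[i + 1:]:
                d = math.hypot(a.cx_um - b.cx_um, a.cy_um - b.cy_um)
                if d < a.radius_um + b.radius_um:
                    raise ValueError(f"spots {a.spot_id} and {b.spot_id} overlap")

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def probe_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.spots:
            if s.probe_label not in seen:
                seen.append(s.probe_label)
        return seen

    def spots_for_probe(self, probe_label: str) -> list[Spot]:
        return [s for s in self.spots if s.probe_label == probe_label]

    def to_json(self) -> str:
        return json.dumps(
            {"pitch_um": self.pitch_um, "spots": [asdict(s) for s in self.spots]},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SpotGrid":
        data = json.loads(text)
        return cls([Spot(**s) for s in data["spots"]], pitch_um=data["pitch_um"])


def build_grid(
    probe_labels: list[str],
    replicates: int = 16,
    pitch_um: float = 200.0,
    diameter_um: float = 90.0,
    origin_um: tuple[float, float] = (0.0, 0.0),
    columns: int | None = None,
) -> SpotGrid:
    """Regular rectangular lattice: one row-major block of replicates per probe.

    Probe blocks are stacked vertically; within a block, replicate spots fill
    rows left to right at the given pitch. Nearest-center distance equals the
    pitch, which must exceed the spot diameter.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if diameter_um <= 0 or pitch_um <= diameter_um:
        raise ValueError("need pitch > spot diameter > 0")
    if columns is None:
        columns = int(math.ceil(math.sqrt(replicates)))
    rows_per_block = int(math.ceil(replicates / columns))
    ox, oy = origin_um
    spots: list[Spot] = []
    radius = diameter_um / 2.0
    row0 = 0
    for probe in probe_labels:
        for rep in range(replicates):
            r, c = divmod(rep, columns)
            spots.append(
                Spot(
                    spot_id=f"{probe}_{rep:02d}",
                    cx_um=ox + c * pitch_um,
                    cy_um=oy + (row0 + r) * pitch_um,
                    radius_um=radius,
                    probe_label=probe,
                )
            )
        row0 += rows_per_block
    return SpotGrid(spots, pitch_um=pitch_um)


def assign(tracks: list[Track], grid: SpotGrid, pixel_pitch: float) -> dict[int, str]:
    """Map each track to the spot whose disc contains it, else background."""
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    centers = np.array([[s.cx_um, s.cy_um] for s in grid.spots])
    radii = np.array([s.radius_um for s in grid.spots])
    out: dict[int, str] = {}
    for t in tracks:
        x_um, y_um = t.x * pixel_pitch, t.y * pixel_pitch
        if len(grid.spots) == 0:
            out[t.track_id] = BACKGROUND
            continue
        d = np.hypot(centers[:, 0] - x_um, centers[:, 1] - y_um)
        i = int(np.argmin(d))
        out[t.track_id] = grid.spots[i].spot_id if d[i] <= radii[i] else BACKGROUND
    return out


def per_probe_curves(event_log: EventLog, grid: SpotGrid,
                     mode: str = "mean") -> pd.DataFrame:
    """Aggregate replicate spots of each probe into one cumulative curve.

    ``mode='mean'`` returns the pointwise mean and SD across replicate spots
    (spots absent from the event log contribute flat-zero curves);
    ``mode='sum'`` pools counts instead. Columns: probe_label, time_s,
    value, sd, n_spots.
    """
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    times = event_log.frame_times
    n = len(times)
    rows = []
    for probe in grid.probe_labels:
        spots = grid.spots_for_probe(probe)
        curves = np.stack(
            [event_log.counts.get(s.spot_id, np.zeros(n, dtype=int)) for s in spots]
        )
        if mode == "mean":
            value = curves.mean(axis=0)
            sd = curves.std(axis=0, ddof=1) if len(spots) > 1 else np.zeros(n)
        else:
            value = curves.sum(axis=0)
            sd = np.zeros(n)
        for i in range(n):
            rows.append(
                {"probe_label": probe, "time_s": times[i],
                 "value": float(value[i]), "sd": float(sd[i]),
                 "n_spots": len(spots)}
            )
    return pd.DataFrame(rows,
                        columns=["probe_label", "time_s", "value", "sd", "n_spots"])
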