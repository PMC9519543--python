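"""Link per-frame detections into binding events.

Bound nanoparticles are immobile, so association is greedy nearest-neighbor
matching within a small radius, frame to frame. Dropouts (false negatives)
are healed by merging co-located tracks across short temporal gaps, and
single-frame positives (false positives) are removed by a minimum-duration
filter. Each surviving track is one binding event; debinding never
decrements the cumulative count (total-binding convention).
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TrackingParams",
    "Track",
    "EventLog",
    "associate",
    "repair_gaps",
    "remove_single_frame",
    "track_detections",
    "cumulative_binding",
]


@dataclass
class TrackingParams:
    """Linking parameters, derived from the dwell-time prior.

    ``max_gap`` is the longest dropout (frames) still attributed to the same
    bound particle; re-appearance after a longer gap is a new binding event.
    ``min_duration`` is the least number of supported frames for a track to
    count as a real event.
    """

    association_radius: float = 2.0
    max_gap: int = 2
    min_duration: int = 2

    def __post_init__(self) -> None:
        if self.association_radius <= 0:
            raise ValueError("association_radius must be positive")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Track:
    """One particle's presence interval after linking."""

    track_id: int
    x: float
    y: float
    first_frame: int
    last_frame: int
    support: tuple[int, ...]
    repaired_gaps: int = 0

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError("first_frame must be <= last_frame")
        if self.support and (min(self.support) < self.first_frame
                             or max(self.support) > self.last_frame):
            raise ValueError("support must lie within [first_frame, last_frame]")

    @property
    def n_support(self) -> int:
        return len(self.support)


def _detections_by_frame(detections: pd.DataFrame):
    det = detections.sort_values("frame_index", kind="stable")
    for frame, grp in det.groupby("frame_index", sort=True):
        yield int(frame), grp[["x", "y"]].to_numpy(float)


def associate(detections: pd.DataFrame, params: TrackingParams) -> list[Track]:
    """Greedy nearest-neighbor linking, frame by frame.

    In each frame, (active track, detection) pairs within
    ``association_radius`` are matched in order of increasing distance (ties
    broken by lowest track id, then detection order). Unmatched detections
    open new tracks; a track unmatched in a frame ends there. Track position
    is the running mean of its supporting detections.
    """
    if detections.empty:
        return []
    # active track state: [sum_x, sum_y, n, last_frame, first_frame, support list]
    state: dict[int, list] = {}
    finished: list[Track] = []
    next_id = 0
    prev_frame: int | None = None

    def _close(tid: int) -> None:
        sx, sy, n, last, first, support = state.pop(tid)
        finished.append(Track(tid, sx / n, sy / n, first, last, tuple(support)))

    for frame, pts in _detections_by_frame(detections):
        if prev_frame is not None:
            # tracks not matched in the immediately preceding frame end
            for tid in [t for t, s in state.items() if s[3] < frame - 1]:
                _close(tid)
        active = sorted(state.items())
        pairs = []
        for tid, s in active:
            tx, ty = s[0] / s[2], s[1] / s[2]
            d = np.hypot(pts[:, 0] - tx, pts[:, 1] - ty)
            for j in np.nonzero(d <= params.association_radius)[0]:
                pairs.append((float(d[j]), tid, int(j)))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, tid, j in pairs:
            if tid in used_t or j in used_d:
                continue
            used_t.add(tid)
            used_d.add(j)
            s = state[tid]
            s[0] += pts[j, 0]
            s[1] += pts[j, 1]
            s[2] += 1
            s[3] = frame
            s[5].append(frame)
        for tid, s in list(state.items()):
            if tid not in used_t and s[3] < frame:
                _close(tid)
        for j in range(len(pts)):
            if j not in used_d:
                state[next_id] = [pts[j, 0], pts[j, 1], 1, frame, frame, [frame]]
                next_id += 1
        prev_frame = frame
    for tid in list(state):
        _close(tid)
    finished.sort(key=lambda t: t.track_id)
    return finished


def _merge(a: Track, b: Track) -> Track:
    """Merge two co-located tracks separated by a repaired gap."""
    na, nb = a.n_support, b.n_support
    gap = b.first_frame - a.last_frame - 1
    return Track(
        track_id=min(a.track_id, b.track_id),
        x=(a.x * na + b.x * nb) / (na + nb),
        y=(a.y * na + b.y * nb) / (na + nb),
        first_frame=a.first_frame,
        last_frame=b.last_frame,
        support=tuple(sorted(set(a.support) | set(b.support))),
        repaired_gaps=a.repaired_gaps + b.repaired_gaps + max(gap, 0),
    )


def repair_gaps(tracks: list[Track], params: TrackingParams) -> list[Track]:
    """Heal dropouts: merge co-located tracks whose temporal gap <= max_gap.

    Two tracks merge when the later one starts at most ``max_gap`` frames
    after the earlier one ends and their representative positions lie within
    ``association_radius``. Applied to convergence, so the operation is
    idempotent.
    """
    tracks = sorted(tracks, key=lambda t: (t.first_frame, t.track_id))
    changed = True
    while changed:
        changed = False
        for i in range(len(tracks)):
            for j in range(len(tracks)):
                if i == j:
                    continue
                a, b = tracks[i], tracks[j]
                gap = b.first_frame - a.last_frame - 1
                if not 0 <= gap <= params.max_gap:
                    continue
                if np.hypot(a.x - b.x, a.y - b.y) > params.association_radius:
                    continue
                merged = _merge(a, b)
                tracks = [t for k, t in enumerate(tracks) if k not in (i, j)]
                tracks.append(merged)
                tracks.sort(key=lambda t: (t.first_frame, t.track_id))
                changed = True
                break
            if changed:
                break
    return tracks


def remove_single_frame(tracks: list[Track], params: TrackingParams) -> list[Track]:
    """Discard tracks supported by fewer than ``min_duration`` frames."""
    return [t for t in tracks if t.n_support >= params.min_duration]


def track_detections(detections: pd.DataFrame, params: TrackingParams) -> list[Track]:
    """Full linking chain: associate -> repair gaps -> duration filter."""
    return remove_single_frame(repair_gaps(associate(detections, params), params),
                               params)


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": t.track_id,
                "x": t.x,
                "y": t.y,
                "first_frame": t.first_frame,
                "last_frame": t.last_frame,
                "n_support": t.n_support,
                "repaired_gaps": t.repaired_gaps,
            }
            for t in tracks
        ],
        columns=["track_id", "x", "y", "first_frame", "last_frame",
                 "n_support", "repaired_gaps"],
    )


class EventLog:
    """Per-spot cumulative binding-event curves plus per-track bind times.

    Each surviving track contributes +1 at the time of its first frame;
    debinding never decrements (total-binding convention), so every curve is
    non-decreasing.
    """

    def __init__(self, frame_times: np.ndarray,
                 counts: dict[str, np.ndarray],
                 tracks: pd.DataFrame):
        self.frame_times = np.asarray(frame_times, dtype=float)
        self.counts = counts
        self.tracks = tracks
        for sid, c in counts.items():
            if np.any(np.diff(c) < 0):
                raise ValueError(f"cumulative count for {sid} decreases")

    @property
    def spot_ids(self) -> list[str]:
        return sorted(self.counts)

    def final_counts(self) -> dict[str, int]:
        return {sid: int(c[-1]) for sid, c in self.counts.items()}

    def curve(self, spot_id: str) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.frame_times,
                             "cumulative_count": self.counts[spot_id]})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.spot_ids:
            for t, c in zip(self.frame_times, self.counts[sid]):
                rows.append({"spot_id": sid, "time_s": t, "cumulative_count": int(c)})
        return pd.DataFrame(rows, columns=["spot_id", "time_s", "cumulative_count"])


BACKGROUND = "background"


def cumulative_binding(
    tracks: list[Track],
    frame_times: np.ndarray,
    spot_assignment: dict[int, str] | None = None,
) -> EventLog:
    """Build per-spot cumulative binding curves from surviving tracks.

    ``spot_assignment`` maps track_id to a spot id (or ``"background"``);
    missing entries default to ``"background"``. A track that ends before
    the last frame is recorded with its debind time, but the cumulative
    count is unchanged by debinding.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    n = len(frame_times)
    if spot_assignment is None:
        spot_assignment = {}
    spot_ids = sorted(set(spot_assignment.values()) | {BACKGROUND})
    counts = {sid: np.zeros(n, dtype=int) for sid in spot_ids}
    rows = []
    for t in tracks:
        sid = spot_assignment.get(t.track_id, BACKGROUND)
        if t.first_frame < 0 or t.first_frame >= n:
            raise ValueError(f"track {t.track_id} first_frame outside frame_times")
        counts[sid][t.first_frame:] += 1
        debind = (frame_times[t.last_frame] if t.last_frame < n - 1 else np.nan)
        rows.append({"track_id": t.track_id, "spot_id": sid,
                     "t_bind": frame_times[t.first_frame], "t_debind": debind})
    table = pd.DataFrame(rows, columns=["track_id", "spot_id", "t_bind", "t_debind"])
    return EventLog(frame_times, counts, table)
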