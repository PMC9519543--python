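"""Brute-force reference for the tracking chain on small instances.

For well-separated immobile particles, the optimal reconstruction is exact:
cluster detections transitively by distance, merge each cluster's frame
support into runs separated by more than ``max_gap`` missing frames, and
keep runs with at least ``min_duration`` supported frames. Each surviving
run is one binding event.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def _clusters(points: np.ndarray, radius: float) -> list[list[int]]:
    """Transitive closure of the 'within radius' relation (union-find)."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def oracle_events(detections: pd.DataFrame, association_radius: float,
                  max_gap: int, min_duration: int) -> list[tuple[int, ...]]:
    """Supports (sorted frame tuples) of every true binding event."""
    if detections.empty:
        return []
    pts = detections[["x", "y"]].to_numpy(float)
    frames = detections["frame_index"].to_numpy(int)
    events: list[tuple[int, ...]] = []
    for idx in _clusters(pts, association_radius):
        support = sorted(set(frames[idx]))
        run = [support[0]]
        for f in support[1:]:
            if f - run[-1] - 1 <= max_gap:
                run.append(f)
            else:
                if len(run) >= min_duration:
                    events.append(tuple(run))
                run = [f]
        if len(run) >= min_duration:
            events.append(tuple(run))
    return sorted(events)


def random_instance(rng: np.random.Generator, n_sites=4, n_frames=12,
                    radius=2.0, jitter=0.4):
    """Random well-separated instance: sites >= 3*radius apart, random frame
    supports, detections jittered within ``jitter`` px of the site."""
    sites = []
    while len(sites) < n_sites:
        p = rng.uniform(0, 60, 2)
        if all(np.hypot(*(p - q)) > 3.0 * radius for q in sites):
            sites.append(p)
    rows = []
    for s in sites:
        k = rng.integers(1, n_frames + 1)
        support = sorted(rng.choice(n_frames, size=k, replace=False))
        for f in support:
            dx, dy = rng.uniform(-jitter, jitter, 2)
            rows.append({"frame_index": int(f), "x": s[0] + dx, "y": s[1] + dy,
                         "score": 1.0, "area": 10.0, "perimeter": 8.0,
                         "ratio": 1.25})
    return pd.DataFrame(rows)
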