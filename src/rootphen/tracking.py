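"""Match lateral-root observations across frames into stable tracks.

Matching is frame-to-frame, greedy nearest-neighbour on the pixel position
where the root meets the main root (its current base pixel), with a distance
gate.  Stable labels are assigned in order of first appearance, so label 1 is
the first-emerged LR — the ordering the decay-curve analysis relies on.
The base pixel drifts a little as the plant settles; matching against the
current base (rather than the first-seen one) tolerates that drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .skeleton import LRObservation, RootSystemFrame


@dataclass
class LRTrack:
    """One lateral root followed through the series."""

    label: int                          # 1 = first emerged
    emergence_time_h: float
    frame_indices: list[int] = field(default_factory=list)
    timestamps_h: list[float] = field(default_factory=list)
    base_pixels: list[tuple[int, int]] = field(default_factory=list)
    base_arcs_mm: list[float] = field(default_factory=list)
    polylines_px: list[np.ndarray] = field(default_factory=list)
    lengths_mm: list[float] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frame_indices)


def match_frames(
    prev: list[LRObservation],
    curr: list[LRObservation],
    radius_px: float = 10.0,
) -> list[int | None]:
    """Map each current observation to a previous one or flag it new.

    Greedy over candidate pairs in ascending base-pixel distance; pairs
    farther than ``radius_px`` stay unmatched and each previous observation
    is used at most once.  Returns, per current observation, the index of
    the matched previous observation or ``None`` (new LR).
    """
    mapping: list[int | None] = [None] * len(curr)
    if not prev or not curr:
        return mapping
    pairs = []
    for ci, c in enumerate(curr):
        for pi, p in enumerate(prev):
            d = math.dist(c.base_pixel, p.base_pixel)
            if d <= radius_px:
                pairs.append((d, ci, pi))
    pairs.sort()
    used_prev: set[int] = set()
    used_curr: set[int] = set()
    for d, ci, pi in pairs:
        if ci in used_curr or pi in used_prev:
            continue
        mapping[ci] = pi
        used_curr.add(ci)
        used_prev.add(pi)
    return mapping


def build_tracks(
    frames: list[RootSystemFrame],
    radius_px: float = 10.0,
    min_track_frames: int = 4,
) -> list[LRTrack]:
    """Chain frame-to-frame matches into labelled tracks.

    Labels are assigned in order of emergence (ties broken by base arc
    position along the MR, apical last); tracks observed in fewer than
    ``min_track_frames`` frames are dropped as spurious.
    """
    times = [f.timestamp_h for f in frames]
    if any(t1 > t2 for t1, t2 in zip(times[:-1], times[1:])):
        raise ValueError("frames must be sorted by timestamp")

    tracks: list[LRTrack] = []
    prev_obs: list[LRObservation] = []
    prev_track_of_obs: list[int] = []   # track index per prev observation
    for fi, frame in enumerate(frames):
        curr = frame.laterals
        mapping = match_frames(prev_obs, curr, radius_px=radius_px)
        curr_track_of_obs: list[int] = []
        for ci, obs in enumerate(curr):
            pi = mapping[ci]
            if pi is None:
                tracks.append(
                    LRTrack(label=0, emergence_time_h=frame.timestamp_h)
                )
                ti = len(tracks) - 1
            else:
                ti = prev_track_of_obs[pi]
            tr = tracks[ti]
            tr.frame_indices.append(fi)
            tr.timestamps_h.append(frame.timestamp_h)
            tr.base_pixels.append(tuple(obs.base_pixel))
            tr.base_arcs_mm.append(obs.base_arc_on_mr_mm)
            tr.polylines_px.append(obs.polyline_px)
            tr.lengths_mm.append(obs.length_mm)
            curr_track_of_obs.append(ti)
        prev_obs = curr
        prev_track_of_obs = curr_track_of_obs

    kept = [t for t in tracks if t.n_frames >= min_track_frames]
    kept.sort(key=lambda t: (t.emergence_time_h, t.base_arcs_mm[0]))
    for i, t in enumerate(kept, start=1):
        t.label = i
    return kept


def tracks_to_dataframe(tracks: list[LRTrack], plant_id: str = "plant") -> pd.DataFrame:
    """Tidy export: one row per track per frame."""
    rows = []
    for t in tracks:
        for k in range(t.n_frames):
            rows.append(
                {
                    "plant_id": plant_id,
                    "lr_label": t.label,
                    "emergence_time_h": t.emergence_time_h,
                    "time_h": t.timestamps_h[k],
                    "base_row": t.base_pixels[k][0],
                    "base_col": t.base_pixels[k][1],
                    "base_arc_on_mr_mm": t.base_arcs_mm[k],
                    "length_mm": t.lengths_mm[k],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["plant_id", "lr_label", "emergence_time_h", "time_h",
                 "base_row", "base_col", "base_arc_on_mr_mm", "length_mm"],
    )
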