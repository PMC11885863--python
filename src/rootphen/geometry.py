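"""Polyline helpers shared across the package.

Coordinate conventions
----------------------
Plates are imaged upright, so image rows increase in the direction of
gravity.  Metric geometry uses ``(x, y)`` in millimetres with gravity along
``+y``; pixel chains use ``(row, col)``.  ``chain_to_mm`` maps between the
two (``x = col * px_mm``, ``y = row * px_mm``).
"""

from __future__ import annotations

import numpy as np


def as_polyline(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"polyline must be (N, 2), got shape {pts.shape}")
    return pts


def polyline_length(points) -> float:
    """Total arc length of a polyline (sum of segment lengths)."""
    pts = as_polyline(points)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def arc_positions(points) -> np.ndarray:
    """Cumulative arc length at every vertex, starting at 0."""
    pts = as_polyline(points)
    if len(pts) == 0:
        return np.zeros(0)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def point_at_arc(points, s: float) -> np.ndarray:
    """Point at arc length ``s`` from the first vertex (linear interpolation
    within the containing segment).

    Raises ``ValueError`` if ``s`` is negative or exceeds the total length.
    """
    pts = as_polyline(points)
    arcs = arc_positions(pts)
    total = arcs[-1] if len(arcs) else 0.0
    if s < 0 or s > total + 1e-12:
        raise ValueError(f"arc length {s} outside [0, {total}]")
    s = min(s, total)
    i = int(np.searchsorted(arcs, s, side="right")) - 1
    i = min(max(i, 0), len(pts) - 2) if len(pts) > 1 else 0
    if len(pts) == 1 or arcs[i + 1] == arcs[i]:
        return pts[i].copy()
    frac = (s - arcs[i]) / (arcs[i + 1] - arcs[i])
    return pts[i] + frac * (pts[i + 1] - pts[i])


def smooth_polyline(points, window: int = 3) -> np.ndarray:
    """Moving-average smoothing of interior vertices; endpoints are kept.

    Reduces rasterisation jitter in pixel chains before angle evaluation.
    ``window`` must be odd; ``window <= 1`` is a no-op.
    """
    pts = as_polyline(points)
    if window <= 1 or len(pts) <= 2:
        return pts.copy()
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    out = pts.copy()
    for i in range(1, len(pts) - 1):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def chain_to_mm(chain_px, px_mm: float) -> np.ndarray:
    """Convert a ``(row, col)`` pixel chain to an ``(x, y)`` polyline in mm."""
    chain = as_polyline(chain_px)
    return np.column_stack([chain[:, 1] * px_mm, chain[:, 0] * px_mm])
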