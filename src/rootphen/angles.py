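"""Gravity-referenced angle features of lateral roots.

Two angles summarise how a lateral root (LR) grows relative to gravity:

* **base-tip angle** — the unsigned angle between the gravity vector and the
  chord from the LR base to its current tip.  As gravitropism bends the LR
  downward this angle declines over time.
* **emergence angle** — the same construction, but the far point is taken a
  fixed arc length (default 2 mm) along the LR skeleton from the base, so the
  value captures the initial growth direction before gravitropic bending
  dominates.  An LR shorter than the traversal distance has no emergence
  angle yet.

Both reduce to the right-triangle ``arctan(|dx| / dy)`` construction when the
far point lies below the base; the ``arccos`` form used here extends it to
tips level with or above the base.  The main-root tip angle (used after 90°
plate-rotation assays) applies the same chord construction to the last
millimetre of the main root.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import arc_positions, as_polyline, point_at_arc

logger = logging.getLogger(__name__)

#: gravity direction in (x, y) mm coordinates — straight down the plate
GRAVITY = np.array([0.0, 1.0])


def gravity_angle(base, p, reference=None, signed: bool = False) -> float:
    """Angle in degrees between the vector ``base -> p`` and gravity.

    Unsigned by default, in ``[0, 180]``.  With ``signed=True`` the sign
    encodes the side of the reference axis (positive towards ``+x``).
    ``reference`` replaces the gravity vector, e.g. with a local main-root
    tangent for a parent-referenced emergence angle.
    """
    v = np.asarray(p, dtype=float) - np.asarray(base, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector: p coincides with base")
    ref = GRAVITY if reference is None else np.asarray(reference, dtype=float)
    rn = np.linalg.norm(ref)
    if rn == 0:
        raise ValueError("zero-length reference vector")
    ref = ref / rn
    cosang = np.clip(np.dot(v, ref) / n, -1.0, 1.0)
    ang = math.degrees(math.acos(cosang))
    if signed:
        cross = v[0] * ref[1] - v[1] * ref[0]
        ang = math.copysign(ang, cross) if cross != 0 else ang
    return ang


def base_tip_angle(polyline, signed: bool = False) -> float:
    """Gravity angle of the base→tip chord of an LR polyline (mm coords).

    Interior vertices are ignored by construction.  A degenerate polyline
    whose tip coincides with its base yields NaN (logged).
    """
    pts = as_polyline(polyline)
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    if np.allclose(pts[0], pts[-1]):
        logger.warning("degenerate LR polyline (tip == base); angle missing")
        return float("nan")
    return gravity_angle(pts[0], pts[-1], signed=signed)


def emergence_angle(
    polyline,
    distance_mm: float = 2.0,
    reference=None,
    signed: bool = False,
) -> float:
    """Gravity angle of the chord from the base to the point ``distance_mm``
    along the LR skeleton; NaN while the LR is shorter than the traversal
    distance.  The distance is a parameter (2 mm by default)."""
    if distance_mm <= 0:
        raise ValueError("traversal distance must be positive")
    pts = as_polyline(polyline)
    if len(pts) < 2:
        return float("nan")
    total = arc_positions(pts)[-1]
    if total + 1e-9 < distance_mm:
        return float("nan")
    target = point_at_arc(pts, min(distance_mm, total))
    if np.allclose(pts[0], target):
        return float("nan")
    return gravity_angle(pts[0], target, reference=reference, signed=signed)


def mr_tip_angle(mr_polyline, window_mm: float = 1.0) -> float:
    """Gravity angle of the main-root tip over its last ``window_mm``.

    Quantifies reorientation after a 90° plate rotation; NaN when the main
    root is shorter than the window.
    """
    if window_mm <= 0:
        raise ValueError("window_mm must be positive")
    pts = as_polyline(mr_polyline)
    arcs = arc_positions(pts)
    if len(pts) < 2 or arcs[-1] < window_mm:
        return float("nan")
    anchor = point_at_arc(pts, arcs[-1] - window_mm)
    if np.allclose(anchor, pts[-1]):
        return float("nan")
    return gravity_angle(anchor, pts[-1])


def first_lr_decay_curve(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Base-tip angle of the first-emerged LR, aligned on its emergence.

    Parameters
    ----------
    records : tidy angle table with columns
        ``plant_id, lr_label, time_h, base_tip_deg`` (label 1 = first LR).

    Returns
    -------
    per_plant : DataFrame ``plant_id, hours_since_emergence, base_tip_deg``
        (hour bins = floor of hours since the LR's first observation).
    cohort : DataFrame ``hours_since_emergence, mean_deg, sd_deg, n``.
    Plants without any LR are excluded with a warning.
    """
    required = {"plant_id", "lr_label", "time_h", "base_tip_deg"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rows = []
    for pid, sub in records.groupby("plant_id"):
        first = sub[sub["lr_label"] == 1]
        if first.empty:
            logger.warning("plant %s has no first LR; excluded from decay curve", pid)
            continue
        t0 = first["time_h"].min()
        hrs = np.floor(first["time_h"] - t0).astype(int)
        grp = (
            first.assign(hours_since_emergence=hrs)
            .groupby("hours_since_emergence")["base_tip_deg"]
            .mean()
            .reset_index()
        )
        grp.insert(0, "plant_id", pid)
        rows.append(grp)
    if not rows:
        per_plant = pd.DataFrame(
            columns=["plant_id", "hours_since_emergence", "base_tip_deg"]
        )
        cohort = pd.DataFrame(
            columns=["hours_since_emergence", "mean_deg", "sd_deg", "n"]
        )
        return per_plant, cohort
    per_plant = pd.concat(rows, ignore_index=True)
    cohort = (
        per_plant.groupby("hours_since_emergence")["base_tip_deg"]
        .agg(mean_deg="mean", sd_deg="std", n="count")
        .reset_index()
    )
    return per_plant, cohort


def exponential_decay(t, theta_e, final_angle, kappa):
    """Gravitropic bending law: angle relaxes exponentially toward an
    asymptote, ``theta(t) = final + (theta_e - final) * exp(-kappa * t)``."""
    return final_angle + (theta_e - final_angle) * np.exp(-kappa * np.asarray(t, float))


def fit_gravitropic_decay(hours, angles_deg) -> dict:
    """Least-squares fit of the exponential bending law to a base-tip series.

    Returns ``{"theta_e", "final_angle", "kappa"}`` in degrees / h^-1.
    """
    t = np.asarray(hours, dtype=float)
    y = np.asarray(angles_deg, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 4:
        raise ValueError("need at least 4 finite points to fit the decay law")
    p0 = (y[0], min(y[-1], y[0]), 0.05)
    popt, _ = curve_fit(
        exponential_decay,
        t,
        y,
        p0=p0,
        bounds=([0.0, 0.0, 0.0], [180.0, 180.0, 10.0]),
        maxfev=20000,
    )
    return {"theta_e": popt[0], "final_angle": popt[1], "kappa": popt[2]}
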