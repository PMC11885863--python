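"""Scalar feature catalogue: lengths, counts, densities, speeds, spectra,
and convex-hull geometry.

Per frame the catalogue holds main-root (MR), lateral-root (LR) and total
(TR = MR + sum LR) lengths in mm, the LR count, LR density (LR length per mm
of MR), discrete LR density (LRs per cm of MR, i.e. 10 x count / MR length
in mm) and the MR/TR ratio.  Frames captured every 15 min are averaged to
one value per clock hour; growth speeds are finite differences of the hourly
lengths; frequency-domain features are the amplitude spectrum of the
detrended, variance-normalised speeds; hull metrics describe the convex hull
of all root pixels at one evaluation hour per day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .skeleton import RootSystemFrame

logger = logging.getLogger(__name__)


def frame_metrics(rsf: RootSystemFrame) -> dict:
    """Length/count/density features of one decomposed frame.

    With a zero-length MR the densities and the MR/TR ratio are undefined
    (NaN) while the lengths are still reported.
    """
    mr = rsf.mr_length_mm
    lr = float(sum(o.length_mm for o in rsf.laterals))
    tr = mr + lr
    n_lr = len(rsf.laterals)
    if mr > 0:
        lr_density = lr / mr                  # mm per mm of MR
        discrete_density = 10.0 * n_lr / mr   # LRs per cm of MR
        mr_over_tr = mr / tr
    else:
        lr_density = discrete_density = mr_over_tr = float("nan")
    return {
        "time_h": rsf.timestamp_h,
        "mr_len_mm": mr,
        "lr_len_mm": lr,
        "tr_len_mm": tr,
        "n_lr": n_lr,
        "lr_density": lr_density,
        "discrete_lr_density": discrete_density,
        "mr_over_tr": mr_over_tr,
    }


def hourly_aggregate(df: pd.DataFrame, time_col: str = "time_h") -> pd.DataFrame:
    """Average 15-min-cadence records to one value per clock hour.

    The hour grid spans the observed range; an hour with no frames stays
    missing (NaN row) — gaps are never interpolated here.
    """
    if df.empty:
        return df.assign(hour=pd.Series(dtype=int)).drop(columns=[time_col])
    hours = np.floor(df[time_col]).astype(int)
    out = df.drop(columns=[time_col]).groupby(hours).mean(numeric_only=True)
    out.index.name = "hour"
    full = range(int(hours.min()), int(hours.max()) + 1)
    return out.reindex(full).reset_index()


def growth_speeds(hourly_lengths, clip_negative: bool = True):
    """Growth speed (mm/h) from hourly lengths by finite differences.

    Central differences on interior points, one-sided at the ends.  Root
    length cannot shrink, so negative speeds (segmentation noise) are
    clipped to 0 by default; the number clipped is logged and the raw
    differences are returned alongside.

    Returns ``(speeds, raw_speeds)``.
    """
    y = np.asarray(hourly_lengths, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 hourly points for speeds")
    raw = np.gradient(y)
    speeds = raw.copy()
    if clip_negative:
        neg = np.sum(raw < 0)
        if neg:
            logger.info("clipped %d negative speed values to 0", neg)
        speeds = np.clip(speeds, 0.0, None)
    return speeds, raw


@dataclass
class Spectrum:
    """Amplitude spectrum of a growth-speed series."""

    frequency_per_h: np.ndarray
    amplitude: np.ndarray

    def peak_frequency(self) -> float:
        """Frequency of the largest non-DC amplitude."""
        if len(self.frequency_per_h) < 2:
            return float("nan")
        i = 1 + int(np.argmax(self.amplitude[1:]))
        return float(self.frequency_per_h[i])


def spectral_features(
    speed_series,
    dt_h: float = 1.0,
    detrend_window_h: float = 24.0,
) -> Spectrum:
    """Detrend, normalise and Fourier-transform a speed series.

    Missing points are linearly interpolated first (count logged), the trend
    is removed by subtracting a centred moving average (default 24 h window,
    to isolate the daily band), the residual is scaled to unit variance, and
    the one-sided DFT amplitude spectrum is returned on the frequency grid
    ``k / (N * dt)``.  An all-constant series yields a zero spectrum.
    """
    y = np.asarray(speed_series, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("series too short for a spectrum")
    missing = ~np.isfinite(y)
    if missing.any():
        logger.info("interpolating %d missing points before DFT", missing.sum())
        idx = np.arange(n)
        y = y.copy()
        y[missing] = np.interp(idx[missing], idx[~missing], y[~missing])
    win = max(3, int(round(detrend_window_h / dt_h)) | 1)  # odd window
    trend = (
        pd.Series(y).rolling(window=win, center=True, min_periods=1).mean().to_numpy()
    )
    resid = y - trend
    sd = resid.std()
    if sd > 0:
        resid = resid / sd
    amp = np.abs(np.fft.rfft(resid)) / n
    freq = np.fft.rfftfreq(n, d=dt_h)
    return Spectrum(frequency_per_h=freq, amplitude=amp)


@dataclass
class HullMetrics:
    """Convex-hull geometry of the root system at one evaluation hour."""

    hull_area_mm2: float
    hull_width_mm: float
    hull_height_mm: float
    aspect_ratio: float               # height / width; NaN when width == 0
    mr_area_density: float            # MR length / hull area (mm/mm^2)
    lr_area_density: float
    tr_area_density: float


def hull_metrics(
    points_mm,
    mr_len_mm: float = float("nan"),
    lr_len_mm: float = float("nan"),
    tr_len_mm: float = float("nan"),
) -> HullMetrics:
    """Convex hull of root pixel coordinates (mm) with derived densities.

    Degenerate inputs (fewer than 3 points, or collinear) get area 0 and
    missing densities; width/height are the bounding-box extents of the
    hull, which for a convex hull equal those of the full point set.
    """
    pts = np.asarray(points_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (N, 2)")
    if len(pts) == 0:
        return HullMetrics(*(float("nan"),) * 7)
    width = float(np.ptp(pts[:, 0]))
    height = float(np.ptp(pts[:, 1]))
    try:
        area = float(ConvexHull(pts).volume)  # "volume" is area in 2-D
    except QhullError:
        area = 0.0
    aspect = height / width if width > 0 else float("nan")
    if area > 0:
        dens = (mr_len_mm / area, lr_len_mm / area, tr_len_mm / area)
    else:
        dens = (float("nan"),) * 3
    return HullMetrics(area, width, height, aspect, *dens)


def feature_table(
    frames: list[RootSystemFrame],
    plant_id: str | None = None,
) -> pd.DataFrame:
    """Per-plant hourly feature table: metrics averaged per hour plus
    MR/LR/TR growth speeds."""
    per_frame = pd.DataFrame([frame_metrics(f) for f in frames])
    hourly = hourly_aggregate(per_frame)
    for channel in ("mr", "lr", "tr"):
        col = f"{channel}_len_mm"
        if hourly[col].notna().sum() >= 2:
            y = hourly[col].to_numpy()
            filled = pd.Series(y).interpolate(limit_direction="both").to_numpy()
            speeds, _ = growth_speeds(filled)
            speeds[~np.isfinite(y)] = np.nan
            hourly[f"{channel}_speed_mm_h"] = speeds
        else:
            hourly[f"{channel}_speed_mm_h"] = np.nan
    if plant_id is None and frames:
        plant_id = frames[0].plant_id
    hourly.insert(0, "plant_id", plant_id)
    return hourly
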