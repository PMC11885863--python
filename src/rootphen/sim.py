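"""Parametric synthetic root-growth simulator and mask renderer.

Generates ground-truthed time series of a vertically grown Arabidopsis-like
root system: one main root (MR) growing downward with a small random heading
wobble, and lateral roots (LRs) emerging at stochastic times and positions
along the mature MR zone.  Each LR starts at an emergence angle drawn from a
configurable normal distribution, holds it through an emergence plateau
(``bend_delay_h``), and its base-tip chord angle then relaxes exponentially
toward a final asymptote — a controllable stand-in for gravitropic bending:

    theta(age) = final_angle + (theta_e - final_angle) * exp(-kappa * (age - bend_delay_h))

for ``age > bend_delay_h`` and ``theta = theta_e`` before.  The tip position
is constructed from the chord (length ``lr_speed * age`` at angle
``theta(age)``), so the true base-tip angle obeys the law exactly and the
proximal segment laid down during the plateau is straight at the emergence
angle.  Angles are unsigned degrees from the gravity vector (plates are vertical, so
gravity is the +y axis of the mm coordinate frame / the +row axis of images).
The rendered binary masks plus the exact ground truth make every downstream
estimator testable against a known answer.

The generative model and all its defaults are choices of this package, tuned
to plausible Arabidopsis plate-assay magnitudes; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .geometry import arc_positions, point_at_arc, polyline_length
from .skeleton import MaskFrame


@dataclass(frozen=True)
class SimParams:
    """Growth-model parameters (rates per hour, lengths in mm, angles in
    degrees from gravity)."""

    duration_h: float = 48.0
    frame_interval_min: int = 15
    mr_speed: float = 0.35            # mm/h, Arabidopsis MR elongation scale
    mr_wobble_sd: float = 1.0         # deg per step, MR heading random walk
    lr_emergence_rate: float = 0.15   # LRs/h along the mature MR zone
    emergence_angle_mean: float = 65.0
    emergence_angle_sd: float = 10.0
    final_angle: float = 25.0         # asymptote of gravitropic bending
    decay_rate_kappa: float = 0.0385  # 1/h (half-life ~18 h)
    lr_speed: float = 0.25            # mm/h
    seed: int = 0
    maturation_lag_h: float = 24.0    # LRs emerge only on MR older than this
    min_base_spacing_mm: float = 1.5  # minimum spacing between LR bases
    bend_delay_h: float = 10.0        # emergence plateau before bending starts
    min_lr_clearance_mm: float = 0.8  # minimum distance between LR trajectories

    def __post_init__(self):
        for name in ("duration_h", "mr_speed", "mr_wobble_sd", "lr_emergence_rate",
                     "lr_speed", "decay_rate_kappa", "maturation_lag_h",
                     "min_base_spacing_mm", "bend_delay_h", "min_lr_clearance_mm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        for name in ("emergence_angle_mean", "emergence_angle_sd", "final_angle"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        for name in ("emergence_angle_mean", "final_angle"):
            v = getattr(self, name)
            if not 0 <= v <= 180:
                raise ValueError(f"{name} must be in [0, 180], got {v}")
        if self.emergence_angle_sd < 0:
            raise ValueError("emergence_angle_sd must be >= 0")
        if self.frame_interval_min <= 0 or 60 % self.frame_interval_min != 0:
            raise ValueError("frame_interval_min must be a positive divisor of 60")


def _min_polyline_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum vertex-to-vertex distance between two polylines."""
    if len(a) == 0 or len(b) == 0:
        return float("inf")
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def theta_law(age_h, theta_e: float, params: "SimParams"):
    """True base-tip chord angle of an LR at a given age.

    The LR holds its emergence angle through an emergence plateau
    (``bend_delay_h``), after which gravitropic bending relaxes the chord
    angle exponentially toward ``final_angle`` at rate ``decay_rate_kappa``.
    """
    age = np.asarray(age_h, dtype=float)
    dt = np.maximum(age - params.bend_delay_h, 0.0)
    theta = params.final_angle + (theta_e - params.final_angle) * np.exp(
        -params.decay_rate_kappa * dt
    )
    return theta if theta.shape else float(theta)


@dataclass
class LRGroundTruth:
    """Ground truth for one lateral root.

    The tip position is constructed directly from the chord: at age ``a`` the
    tip sits at ``base + lr_speed * a * u(theta_law(a))``, so the true
    base-tip angle follows the bending law exactly and, while the plateau
    lasts, the proximal polyline is straight at the emergence angle.
    """

    emergence_time_h: float           # first frame in which the LR is visible
    growth_start_h: float             # one frame interval earlier
    base_arc_on_mr_mm: float
    base_xy_mm: np.ndarray            # (x, y) of the base
    side: int                         # +1 grows toward +x, -1 toward -x
    emergence_angle_deg: float        # theta_e actually drawn (clipped)
    first_frame: int                  # index of the first frame with growth
    points_mm: np.ndarray             # (k, 2) tip trajectory incl. base

    def polyline_at(self, frame_idx: int) -> np.ndarray:
        """LR polyline (base → tip) as of frame ``frame_idx``."""
        n = max(0, frame_idx - self.first_frame + 1)
        return self.points_mm[: n + 1]

    def length_at(self, frame_idx: int) -> float:
        return polyline_length(self.polyline_at(frame_idx))

    def age_at(self, t_h: float) -> float:
        """LR age in hours at absolute time ``t_h`` (growth starts one frame
        interval before the first frame in which the LR is visible)."""
        return t_h - self.growth_start_h

    def true_base_tip_deg(self, frame_idx: int) -> float:
        """Chord angle from the bending law (exact, by construction)."""
        if frame_idx < self.first_frame:
            return float("nan")
        poly = self.polyline_at(frame_idx)
        if len(poly) < 2:
            return float("nan")
        v = poly[-1] - poly[0]
        n = np.linalg.norm(v)
        if n == 0:
            return float("nan")
        return math.degrees(math.acos(np.clip(v[1] / n, -1.0, 1.0)))


@dataclass
class GroundTruthSeries:
    """Exact geometry of one simulated plant across all frames."""

    params: SimParams
    times_h: np.ndarray               # (n_frames,)
    mr_points_mm: np.ndarray          # (n_frames, 2): tip position per frame
    lrs: list[LRGroundTruth] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.times_h)

    def mr_polyline_at(self, frame_idx: int) -> np.ndarray:
        return self.mr_points_mm[: frame_idx + 1]

    def lrs_at(self, frame_idx: int) -> list[LRGroundTruth]:
        """LRs that have started growing by ``frame_idx``."""
        return [lr for lr in self.lrs if lr.first_frame <= frame_idx]

    def to_dataframe(self) -> pd.DataFrame:
        """One row per LR per frame (tidy ground-truth export)."""
        rows = []
        for label, lr in enumerate(self.lrs, start=1):
            for i in range(lr.first_frame, self.n_frames):
                rows.append(
                    {
                        "label": label,
                        "time_h": self.times_h[i],
                        "base_x_mm": lr.base_xy_mm[0],
                        "base_y_mm": lr.base_xy_mm[1],
                        "length_mm": lr.length_at(i),
                        "true_base_tip_deg": lr.true_base_tip_deg(i),
                        "true_emergence_deg": lr.emergence_angle_deg,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["label", "time_h", "base_x_mm", "base_y_mm", "length_mm",
                     "true_base_tip_deg", "true_emergence_deg"],
        )


def simulate_root_system(params: SimParams) -> GroundTruthSeries:
    """Simulate one plant.  Deterministic for a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval_min / 60.0
    n_frames = int(round(params.duration_h / dt)) + 1
    times = np.arange(n_frames) * dt

    # Main root: heading random walk, initial heading straight down.
    headings = np.zeros(n_frames)
    if params.mr_wobble_sd > 0:
        steps = rng.normal(0.0, params.mr_wobble_sd, size=n_frames - 1)
        headings[1:] = np.cumsum(steps)
    mr = np.zeros((n_frames, 2))
    for i in range(1, n_frames):
        h = math.radians(headings[i])
        mr[i] = mr[i - 1] + params.mr_speed * dt * np.array([math.sin(h), math.cos(h)])
    mr_arcs = arc_positions(mr)

    # Lateral roots: Poisson emergence on the mature MR zone.
    lrs: list[LRGroundTruth] = []
    base_arcs: list[float] = []
    for i in range(1, n_frames):
        t = times[i]
        if rng.random() >= params.lr_emergence_rate * dt:
            continue
        # mature zone: MR laid down at least maturation_lag_h before now
        mature_idx = np.searchsorted(times, t - params.maturation_lag_h, side="right")
        if mature_idx < 2:
            continue
        zone_len = mr_arcs[mature_idx - 1]
        if zone_len <= 0:
            continue
        placed = None
        for _ in range(8):  # rejection sampling for base spacing
            cand = rng.uniform(0.0, zone_len)
            if all(abs(cand - a) >= params.min_base_spacing_mm for a in base_arcs):
                placed = cand
                break
        if placed is None:
            continue
        theta_e = float(
            np.clip(
                rng.normal(params.emergence_angle_mean, params.emergence_angle_sd),
                0.0,
                180.0,
            )
        )
        side = 1 if rng.random() < 0.5 else -1
        base = point_at_arc(mr, placed)
        # tip trajectory from the chord construction (growth begins at the
        # start of the emergence interval, one step before frame i)
        t0 = t - dt

        def trajectory(s: int) -> np.ndarray:
            pts = [base.copy()]
            for j in range(i, n_frames):
                age = times[j] - t0
                theta = math.radians(theta_law(age, theta_e, params))
                length = params.lr_speed * age
                pts.append(
                    base + length * np.array([s * math.sin(theta), math.cos(theta)])
                )
            return np.asarray(pts)

        # LRs of one plant rarely cross in projection (similar set-point
        # angles); enforce a clearance against other LRs and the drifting MR
        # so the skeleton decomposition stays well posed.  Try the drawn
        # side, then the other, else skip the emergence event.
        clear = params.min_lr_clearance_mm
        near_base = np.linalg.norm(mr - base, axis=1) <= 1.5 * clear
        mr_far = mr[~near_base]
        pts = None
        for s in (side, -side):
            cand = trajectory(s)
            cand_far = cand[np.linalg.norm(cand - base, axis=1) > 1.5 * clear]
            if _min_polyline_distance(cand_far, mr_far) < clear:
                continue
            if all(
                _min_polyline_distance(cand[1:], other.points_mm[1:]) >= clear
                for other in lrs
            ):
                pts, side = cand, s
                break
        if pts is None:
            continue
        base_arcs.append(placed)
        lrs.append(
            LRGroundTruth(
                emergence_time_h=t,
                growth_start_h=t0,
                base_arc_on_mr_mm=placed,
                base_xy_mm=base,
                side=side,
                emergence_angle_deg=theta_e,
                first_frame=i,
                points_mm=np.asarray(pts),
            )
        )
    lrs.sort(key=lambda lr: lr.emergence_time_h)
    return GroundTruthSeries(params=params, times_h=times, mr_points_mm=mr, lrs=lrs)


@dataclass(frozen=True)
class RenderParams:
    """Rasterisation settings for turning ground truth into binary masks."""

    px_mm: float = 0.1                # mm per pixel
    stroke_width_px: int = 3
    image_shape: tuple[int, int] = (700, 700)   # (rows, cols)
    seed_px: tuple[int, int] | None = None      # MR start; default top-centre

    def __post_init__(self):
        if self.px_mm <= 0:
            raise ValueError("px_mm must be positive")
        if self.stroke_width_px < 1:
            raise ValueError("stroke_width_px must be >= 1")

    @property
    def origin(self) -> tuple[int, int]:
        if self.seed_px is not None:
            return self.seed_px
        return (10, self.image_shape[1] // 2)


def _mm_to_px(points_mm: np.ndarray, rp: RenderParams) -> np.ndarray:
    r0, c0 = rp.origin
    rows = points_mm[:, 1] / rp.px_mm + r0
    cols = points_mm[:, 0] / rp.px_mm + c0
    return np.column_stack([rows, cols])


def _rasterize(polylines_px: list[np.ndarray], rp: RenderParams) -> np.ndarray:
    mask = np.zeros(rp.image_shape, dtype=bool)
    for poly in polylines_px:
        pts = np.rint(poly).astype(int)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            mask[rr, cc] = True
        if len(pts) == 1:
            mask[pts[0, 0], pts[0, 1]] = True
    radius = rp.stroke_width_px // 2
    if radius > 0:
        mask = dilation(mask, disk(radius))
    return mask.astype(np.uint8)


def render_frames(
    gt: GroundTruthSeries, rp: RenderParams, plant_id: str = "sim"
) -> list[MaskFrame]:
    """Rasterise every frame of a ground-truth series to binary masks.

    Thick anti-alias-free line drawing (Bresenham segments + disk dilation)
    keeps the masks strictly binary.  Raises if any geometry falls outside
    the image, naming the offending frame.
    """
    frames = []
    nrows, ncols = rp.image_shape
    margin = rp.stroke_width_px // 2 + 1
    for i in range(gt.n_frames):
        polys = [gt.mr_polyline_at(i)]
        polys += [lr.polyline_at(i) for lr in gt.lrs_at(i)]
        polys_px = [_mm_to_px(p, rp) for p in polys if len(p) > 0]
        for p in polys_px:
            if (
                p[:, 0].min() < margin
                or p[:, 0].max() >= nrows - margin
                or p[:, 1].min() < margin
                or p[:, 1].max() >= ncols - margin
            ):
                raise ValueError(
                    f"frame {i} (t={gt.times_h[i]:.2f} h): geometry outside "
                    f"image of shape {rp.image_shape}"
                )
        frames.append(
            MaskFrame(
                image=_rasterize(polys_px, rp),
                timestamp_h=float(gt.times_h[i]),
                px_mm=rp.px_mm,
                plant_id=plant_id,
                seed_point=rp.origin,
            )
        )
    return frames


def write_mask_series(frames: list[MaskFrame], out_dir) -> list[Path]:
    """Write masks as zero-padded numbered PNGs (0/255)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, f in enumerate(frames):
        p = out / f"frame_{i:05d}.png"
        iio.imwrite(p, (f.image * 255).astype(np.uint8))
        paths.append(p)
    return paths


def write_ground_truth(gt: GroundTruthSeries, out_dir) -> tuple[Path, Path]:
    """Write the per-LR-per-frame ground truth CSV and a SimParams sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "ground_truth.csv"
    gt.to_dataframe().to_csv(csv_path, index=False)
    json_path = out / "sim_params.json"
    json_path.write_text(json.dumps(dataclasses.asdict(gt.params), indent=2))
    return csv_path, json_path
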