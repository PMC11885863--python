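"""End-to-end orchestration: masks in, feature tables / statistics / figures out.

The pipeline runs per plant — skeletonize, decompose, track, measure angles,
aggregate hourly metrics, hull geometry — then across the cohort: group
comparisons, first-LR decay curves, and the superposition map.  A failure in
one plant excludes that plant (and is reported); the run fails only if every
plant fails.  Given the same configuration and inputs the outputs are
byte-identical, and a manifest (effective configuration, seed, warnings)
records the provenance of every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import angles as _angles
from . import metrics as _metrics
from .cohortstats import save_superposition, superposition_map, timeseries_compare
from .geometry import chain_to_mm, smooth_polyline
from .skeleton import MaskFrame, RootSystemFrame, decompose_frame
from .tracking import LRTrack, build_tracks, tracks_to_dataframe

logger = logging.getLogger(__name__)

_NUM_RE = re.compile(r"(\d+)")


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    input_dir: str = "."
    output_dir: str = "out"
    px_mm: float = 0.1
    frame_interval_min: int = 15
    group_map: dict[str, str] = field(default_factory=dict)   # plant_id -> group
    control_group: str = "control"
    seed_points: dict[str, tuple[int, int]] = field(default_factory=dict)
    emergence_distance_mm: float = 2.0
    prune_len_mm: float = 0.3
    min_lr_len_mm: float = 0.5
    seed_attach_radius_px: float = 20.0
    radius_px: float = 10.0
    min_track_frames: int = 4
    alpha: float = 0.05
    min_n: int = 3
    hull_hour: int = 8                 # daily hull evaluation hour (lights-on)
    smooth_window: int = 3             # chain smoothing before angles; 1 = off
    seed: int = 0

    def __post_init__(self):
        if self.px_mm <= 0:
            raise ValueError("px_mm must be positive")
        if self.frame_interval_min <= 0 or 60 % self.frame_interval_min:
            raise ValueError("frame_interval_min must divide 60")
        for name in ("emergence_distance_mm", "prune_len_mm", "min_lr_len_mm",
                     "seed_attach_radius_px", "radius_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.smooth_window >= 1 and self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed_points" in raw:
            raw["seed_points"] = {k: tuple(v) for k, v in raw["seed_points"].items()}
        return cls(**raw)


def load_mask_series(path, config: PipelineConfig, plant_id: str) -> list[MaskFrame]:
    """Load one plant's mask time series.

    ``path`` is either a directory of numbered PNG/TIFF frames or a single
    multi-page TIFF.  Frames are ordered by the integers embedded in their
    filenames (or page order), timestamps are ``index x frame_interval``,
    and unreadable frames are skipped with a warning.  Without a configured
    seed point the topmost foreground pixel of the first non-empty frame is
    used (plates are imaged upright, so the seed sits at the top).
    """
    path = Path(path)
    dt_h = config.frame_interval_min / 60.0
    seed_point = config.seed_points.get(plant_id)
    images: list[np.ndarray] = []
    if path.is_dir():
        files = [p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}]

        def index_of(p: Path):
            m = _NUM_RE.findall(p.stem)
            return (int(m[-1]) if m else 0, p.name)

        for p in sorted(files, key=index_of):
            try:
                images.append(iio.imread(p))
            except Exception:
                logger.warning("%s: unreadable frame %s skipped", plant_id, p.name)
    else:
        try:
            stack = iio.imread(path)
        except Exception as e:
            raise ValueError(f"cannot read {path}: {e}") from e
        if stack.ndim == 2:
            stack = stack[None]
        images = list(stack)
    binaries = []
    for img in images:
        if img.ndim == 3:
            img = img[..., 0]
        binaries.append((np.asarray(img) > 0).astype(np.uint8))
    if not binaries:
        raise ValueError(f"{plant_id}: no readable frames in {path}")
    if seed_point is None:
        for img in binaries:
            rows, cols = np.nonzero(img)
            if len(rows):
                top = rows.min()
                seed_point = (int(top), int(np.median(cols[rows == top])))
                logger.info("%s: inferred seed point %s from topmost foreground",
                            plant_id, seed_point)
                break
        else:
            seed_point = (0, 0)
    return [
        MaskFrame(image=img, timestamp_h=i * dt_h, px_mm=config.px_mm,
                  plant_id=plant_id, seed_point=seed_point)
        for i, img in enumerate(binaries)
    ]


def angle_records(
    tracks: list[LRTrack],
    px_mm: float,
    plant_id: str,
    emergence_distance_mm: float = 2.0,
    smooth_window: int = 3,
) -> pd.DataFrame:
    """Tidy per-LR-per-frame angle table (base-tip and emergence angles)."""
    rows = []
    for t in tracks:
        for k in range(t.n_frames):
            poly = chain_to_mm(t.polylines_px[k], px_mm)
            poly = smooth_polyline(poly, smooth_window)
            bt = _angles.base_tip_angle(poly) if len(poly) >= 2 else float("nan")
            em = _angles.emergence_angle(poly, emergence_distance_mm)
            rows.append({
                "plant_id": plant_id,
                "lr_label": t.label,
                "time_h": t.timestamps_h[k],
                "base_tip_deg": bt,
                "emergence_deg": em,
                "lr_length_mm": t.lengths_mm[k],
            })
    return pd.DataFrame(
        rows, columns=["plant_id", "lr_label", "time_h", "base_tip_deg",
                       "emergence_deg", "lr_length_mm"],
    )


@dataclass
class PlantResult:
    """Everything measured for one plant."""

    plant_id: str
    frames: list[RootSystemFrame]
    tracks: list[LRTrack]
    angle_table: pd.DataFrame
    features: pd.DataFrame


def process_plant(frames: list[MaskFrame], config: PipelineConfig) -> PlantResult:
    """Run the per-plant stages: decompose every frame, track LRs, measure
    angles, build the hourly feature table."""
    plant_id = frames[0].plant_id
    rsfs = [
        decompose_frame(
            f,
            prune_len_mm=config.prune_len_mm,
            min_lr_len_mm=config.min_lr_len_mm,
            seed_attach_radius_px=config.seed_attach_radius_px,
        )
        for f in frames
    ]
    tracks = build_tracks(rsfs, radius_px=config.radius_px,
                          min_track_frames=config.min_track_frames)
    ang = angle_records(tracks, config.px_mm, plant_id,
                        emergence_distance_mm=config.emergence_distance_mm,
                        smooth_window=config.smooth_window)
    feats = _metrics.feature_table(rsfs, plant_id)
    return PlantResult(plant_id, rsfs, tracks, ang, feats)


def _features_long(results: list[PlantResult], group_map: dict[str, str]) -> pd.DataFrame:
    """Stack per-plant hourly features into the tidy long layout the
    comparison step consumes."""
    parts = []
    for r in results:
        melted = r.features.melt(id_vars=["plant_id", "hour"],
                                 var_name="feature", value_name="value")
        parts.append(melted)
    long = pd.concat(parts, ignore_index=True)
    long["group"] = long["plant_id"].map(group_map)
    return long.dropna(subset=["group"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all outputs under
    ``config.output_dir``.  Returns a summary dict (also written as the run
    manifest)."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    plant_dirs = sorted(p for p in in_dir.iterdir() if p.is_dir())
    if not plant_dirs:
        raise ValueError(f"no plant directories under {in_dir}")
    results: list[PlantResult] = []
    for pdir in plant_dirs:
        pid = pdir.name
        try:
            frames = load_mask_series(pdir, config, pid)
            results.append(process_plant(frames, config))
        except Exception as e:
            msg = f"plant {pid} failed and was excluded: {e}"
            logger.error(msg)
            warnings.append(msg)
    if not results:
        raise RuntimeError("all plants failed")

    features = pd.concat([r.features for r in results], ignore_index=True)
    features.to_csv(out_dir / "features.csv", index=False)
    track_parts = [tracks_to_dataframe(r.tracks, r.plant_id) for r in results]
    tracks = pd.concat(
        [t for t in track_parts if not t.empty] or track_parts[:1],
        ignore_index=True,
    )
    tracks.to_csv(out_dir / "tracks.csv", index=False)
    angle_parts = [r.angle_table for r in results]
    angles_df = pd.concat(
        [a for a in angle_parts if not a.empty] or angle_parts[:1],
        ignore_index=True,
    )
    angles_df.to_csv(out_dir / "angles.csv", index=False)

    per_plant, cohort = _angles.first_lr_decay_curve(angles_df)
    per_plant.to_csv(out_dir / "first_lr_decay_per_plant.csv", index=False)
    cohort.to_csv(out_dir / "first_lr_decay_cohort.csv", index=False)

    stats_path = None
    if config.group_map and len(set(config.group_map.values())) >= 2:
        long = _features_long(results, config.group_map)
        comp = timeseries_compare(long, control=config.control_group,
                                  alpha=config.alpha, min_n=config.min_n)
        stats_path = out_dir / "comparisons.csv"
        comp.to_csv(stats_path, index=False)

    plants = []
    for r in results:
        last = r.frames[-1]
        polys = [last.mr_polyline_px] + [o.polyline_px for o in last.laterals]
        mask = np.zeros(
            (
                int(max(p[:, 0].max() for p in polys)) + 3,
                int(max(p[:, 1].max() for p in polys)) + 3,
            ),
            dtype=np.uint8,
        )
        for poly in polys:
            ipoly = np.rint(poly).astype(int)
            mask[ipoly[:, 0], ipoly[:, 1]] = 1
        plants.append(
            (mask, tuple(last.mr_polyline_px[0]), tuple(last.mr_polyline_px[-1]))
        )
    smap = superposition_map(plants)
    save_superposition(smap, out_dir / "superposition")

    manifest = {
        "config": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in dataclasses.asdict(config).items()
        },
        "n_plants": len(results),
        "plants": [r.plant_id for r in results],
        "warnings": warnings,
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.name != "manifest.json"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
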