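"""Cohort-level genotype comparison and superposition maps.

Two-group comparisons use the Mann-Whitney rank-sum test at every feature x
hour point, flagged at P < 0.05 per treatment line, with an additional
"both lines" flag that is set only when every treatment line is individually
significant against the control — the convention used for time-resolved
phenotype plots.  No multiple-testing correction is applied by default
(hourly tests are strongly correlated); Benjamini-Hochberg FDR is available
behind a flag.

A superposition map overlays whole cohorts: each plant's segmentation is
rotated about its MR start so that the start-to-tip chord is vertical,
translated so all MR starts coincide, and the binary masks are summed — the
resulting count image reads directly as "number of plants whose root passes
through this pixel".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

#: combined sample size at or below which the exact null distribution is used
EXACT_N_LIMIT = 12


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U_a, p)``.

    Ranks use midranks for ties.  The p-value is exact (full enumeration of
    the rank permutation null) when the combined sample size is at most
    ``EXACT_N_LIMIT`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_N_LIMIT and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def timeseries_compare(
    table: pd.DataFrame,
    control: str,
    alpha: float = 0.05,
    min_n: int = 3,
    fdr: bool = False,
) -> pd.DataFrame:
    """Test every treatment line against the control at each feature x hour.

    Parameters
    ----------
    table : tidy long table with columns
        ``feature, hour, group, plant_id, value``.
    control : group id of the control line.
    alpha : per-test significance level (default 0.05).
    min_n : hours where either group has fewer plants are skipped (warned).
    fdr : apply Benjamini-Hochberg step-up correction across hours within
        each feature x group before flagging (off by default).

    Returns one row per feature x hour x treatment group with the U
    statistic, p-value, per-line ``significant`` flag and the shared
    ``both_lines`` flag (true iff every treatment line tested at that
    feature x hour is significant).
    """
    needed = {"feature", "hour", "group", "value"}
    if missing := needed - set(table.columns):
        raise ValueError(f"table missing columns: {sorted(missing)}")
    groups = [g for g in table["group"].unique() if g != control]
    if not groups:
        raise ValueError("no treatment group besides the control")
    rows = []
    for (feature, hour), sub in table.groupby(["feature", "hour"], sort=True):
        ctrl = sub.loc[sub["group"] == control, "value"].dropna().to_numpy()
        if len(ctrl) < min_n:
            logger.warning("%s h=%s: control n=%d < %d, skipped",
                           feature, hour, len(ctrl), min_n)
            continue
        for g in groups:
            vals = sub.loc[sub["group"] == g, "value"].dropna().to_numpy()
            if len(vals) < min_n:
                logger.warning("%s h=%s group %s: n=%d < %d, skipped",
                               feature, hour, g, len(vals), min_n)
                continue
            u, p = mann_whitney(vals, ctrl)
            rows.append({
                "feature": feature, "hour": hour, "group": g,
                "n_group": len(vals), "n_control": len(ctrl),
                "U": u, "p": p,
            })
    out = pd.DataFrame(rows, columns=["feature", "hour", "group", "n_group",
                                      "n_control", "U", "p"])
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        out["both_lines"] = pd.Series(dtype=bool)
        return out
    if fdr:
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = np.nan
        for _, idx in out.groupby(["feature", "group"]).groups.items():
            out.loc[idx, "p_adj"] = multipletests(
                out.loc[idx, "p"], method="fdr_bh"
            )[1]
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    n_lines = len(groups)
    both = (
        out.groupby(["feature", "hour"])["significant"]
        .agg(lambda s: bool(s.all()) and len(s) == n_lines)
        .rename("both_lines")
    )
    return out.merge(both, on=["feature", "hour"], how="left")


@dataclass
class SuperpositionMap:
    """Count image of overlaid, MR-aligned root segmentations."""

    counts: np.ndarray                # integer image
    reference_px: tuple[int, int]     # common MR start pixel
    n_plants: int


def _rotate_mask_about_start(
    mask: np.ndarray,
    start: tuple[int, int],
    end: tuple[int, int],
    ref: tuple[int, int],
    out_shape: tuple[int, int],
) -> np.ndarray:
    """Rotate a binary mask about the MR start so the start->end chord points
    straight down, then translate the start onto ``ref``.  Nearest-neighbour
    resampling keeps the result binary."""
    dr = end[0] - start[0]
    dc = end[1] - start[1]
    alpha = math.atan2(dc, dr)  # chord angle from the +row (gravity) axis
    ca, sa = math.cos(alpha), math.sin(alpha)
    # output pixel o maps back to input pixel R(alpha) @ (o - ref) + start
    matrix = np.array([[ca, -sa], [sa, ca]])
    offset = np.asarray(start, float) - matrix @ np.asarray(ref, float)
    rotated = ndimage.affine_transform(
        mask.astype(np.uint8), matrix, offset=offset,
        output_shape=out_shape, order=0, mode="constant", cval=0,
        prefilter=False,
    )
    return (rotated > 0).astype(np.uint32)


def superposition_map(
    plants: list[tuple[np.ndarray, tuple[int, int], tuple[int, int]]],
    out_shape: tuple[int, int] | None = None,
    reference_px: tuple[int, int] | None = None,
) -> SuperpositionMap:
    """Overlay a cohort of final segmentations into one count image.

    ``plants`` holds ``(mask, mr_start_px, mr_end_px)`` triples.  Each mask
    is rotated so its MR chord is vertical (tip down), aligned at the MR
    start, and the binary results are summed; the value at a pixel is the
    number of plants whose root occupies it.  Plants with a degenerate MR
    chord (start == end) are excluded with a warning.
    """
    if not plants:
        raise ValueError("no plants to superpose")
    if out_shape is None:
        rows = max(p[0].shape[0] for p in plants)
        cols = max(p[0].shape[1] for p in plants)
        out_shape = (2 * rows, 2 * cols)
    if reference_px is None:
        reference_px = (out_shape[0] // 8, out_shape[1] // 2)
    counts = np.zeros(out_shape, dtype=np.uint32)
    n_used = 0
    for i, (mask, start, end) in enumerate(plants):
        if tuple(start) == tuple(end):
            logger.warning("plant %d: MR start == end, excluded", i)
            continue
        counts += _rotate_mask_about_start(
            np.asarray(mask), tuple(start), tuple(end), reference_px, out_shape
        )
        n_used += 1
    return SuperpositionMap(counts=counts, reference_px=reference_px, n_plants=n_used)


def save_superposition(smap: SuperpositionMap, out_prefix) -> tuple[str, str]:
    """Write the raw 16-bit count PNG and a colormapped overview PNG."""
    import imageio.v3 as iio
    import matplotlib

    raw_path = f"{out_prefix}_counts.png"
    iio.imwrite(raw_path, smap.counts.astype(np.uint16))
    cmap = matplotlib.colormaps["viridis"]
    top = max(1, int(smap.counts.max()))
    rgb = (cmap(smap.counts / top)[:, :, :3] * 255).astype(np.uint8)
    view_path = f"{out_prefix}_overview.png"
    iio.imwrite(view_path, rgb)
    return raw_path, view_path
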