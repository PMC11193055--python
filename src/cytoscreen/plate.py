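"""Plate-level bookkeeping: layouts, tile mosaics, counts and rates.

A 96-well screening run maps wells to (cell line, treatment, dose,
timepoint, replicate, role).  Wells may be acquired as 12 tiles in
meandering (serpentine) order on a 3x4 grid and are reassembled into one
mosaic before detection, so nuclei straddling tile seams are counted once.
Viable counts follow the live/dead rule: Hoechst-positive minus
PI-positive, clamped at zero.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detect import ChannelImage, DetectionParams, count_image

__all__ = ["PlateLayout", "TileSet", "WellCount", "GrowthSeries", "SurvivalResult",
           "serpentine_position", "split_tiles", "reassemble", "count_well",
           "growth_series", "survival_rate"]

logger = logging.getLogger(__name__)

LAYOUT_COLUMNS = ["well", "cell_line", "treatment", "dose_uM",
                  "timepoint_h", "replicate", "role"]
ROLES = {"sample", "untreated_control", "solvent_control", "medium_control"}
_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


@dataclass(frozen=True)
class PlateLayout:
    """Well → condition mapping for one plate (8x12 grid, wells A1..H12)."""

    plate_id: str
    wells: pd.DataFrame  # columns LAYOUT_COLUMNS

    def __post_init__(self):
        df = self.wells
        missing = set(LAYOUT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"layout missing columns {sorted(missing)}")
        bad = [w for w in df["well"] if not _WELL_RE.match(str(w))]
        if bad:
            raise ValueError(f"invalid well ids for an 8x12 plate: {bad}")
        bad_roles = set(df["role"]) - ROLES
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}")

    @classmethod
    def from_csv(cls, path, plate_id: Optional[str] = None) -> "PlateLayout":
        df = pd.read_csv(path)
        return cls(plate_id=plate_id or Path(path).stem, wells=df)

    def to_csv(self, path) -> None:
        self.wells.to_csv(path, index=False, columns=LAYOUT_COLUMNS)


def serpentine_position(index: int, grid_shape: Tuple[int, int] = (3, 4)) -> Tuple[int, int]:
    """(row, col) of acquisition index ``index`` on a serpentine grid.

    Row 0 runs left→right, row 1 right→left, and so on, starting top-left.
    """
    rows, cols = grid_shape
    if not 0 <= index < rows * cols:
        raise ValueError(f"tile index {index} outside grid {grid_shape}")
    r, k = divmod(index, cols)
    c = k if r % 2 == 0 else cols - 1 - k
    return r, c


@dataclass(frozen=True)
class TileSet:
    """Per-well tiles in acquisition order (default 12 on a 3x4 grid)."""

    well_id: str
    tiles: Tuple[ChannelImage, ...]
    grid_shape: Tuple[int, int] = (3, 4)

    def __post_init__(self):
        rows, cols = self.grid_shape
        if len(self.tiles) != rows * cols:
            raise ValueError(
                f"expected {rows * cols} tiles for grid {self.grid_shape}, "
                f"got {len(self.tiles)}"
            )
        shapes = {t.shape for t in self.tiles}
        if len(shapes) > 1:
            raise ValueError(f"tiles have mismatched shapes: {sorted(shapes)}")


def reassemble(tiles: TileSet) -> ChannelImage:
    """Stitch serpentine-ordered tiles into one mosaic (no blending)."""
    rows, cols = tiles.grid_shape
    th, tw = tiles.tiles[0].shape
    mosaic = np.empty((rows * th, cols * tw))
    for idx, tile in enumerate(tiles.tiles):
        r, c = serpentine_position(idx, tiles.grid_shape)
        mosaic[r * th:(r + 1) * th, c * tw:(c + 1) * tw] = tile.pixels
    first = tiles.tiles[0]
    return ChannelImage(mosaic, channel=first.channel, well_id=tiles.well_id)


def split_tiles(image: ChannelImage, grid_shape: Tuple[int, int] = (3, 4)) -> TileSet:
    """Cut a mosaic into serpentine-ordered tiles (inverse of reassemble)."""
    rows, cols = grid_shape
    h, w = image.shape
    if h % rows or w % cols:
        raise ValueError(f"image {image.shape} not divisible into {grid_shape} tiles")
    th, tw = h // rows, w // cols
    tiles: List[ChannelImage] = []
    for idx in range(rows * cols):
        r, c = serpentine_position(idx, grid_shape)
        tiles.append(ChannelImage(
            image.pixels[r * th:(r + 1) * th, c * tw:(c + 1) * tw],
            channel=image.channel, well_id=image.well_id, tile_index=idx))
    return TileSet(well_id=image.well_id, tiles=tuple(tiles), grid_shape=grid_shape)


@dataclass(frozen=True)
class WellCount:
    """Hoechst total, PI-positive and viable counts for one well."""

    well_id: str
    hoechst_count: int
    pi_count: int
    viable_count: int

    def __post_init__(self):
        if self.hoechst_count < 0 or self.pi_count < 0:
            raise ValueError("counts must be >= 0")
        if self.viable_count != max(0, self.hoechst_count - self.pi_count):
            raise ValueError("viable_count must equal max(0, hoechst - pi)")


def count_well(hoechst: ChannelImage, pi: ChannelImage,
               params: DetectionParams = DetectionParams(),
               well_center_xy: Optional[Tuple[float, float]] = None,
               well_radius_px: Optional[float] = None) -> WellCount:
    """Count nuclei in both channels and apply the live/dead subtraction.

    Both channels are detected with identical parameters on the full
    (reassembled) well image.  PI counts exceeding Hoechst counts — a
    spillover artifact — clamp viable at zero with a logged warning.
    """
    if hoechst.channel != "hoechst" or pi.channel != "pi":
        raise ValueError("count_well expects (hoechst, pi) channel images")
    if hoechst.well_id and pi.well_id and hoechst.well_id != pi.well_id:
        raise ValueError(
            f"channel well mismatch: {hoechst.well_id!r} vs {pi.well_id!r}")
    n_h = count_image(hoechst, params, well_center_xy, well_radius_px)
    n_p = count_image(pi, params, well_center_xy, well_radius_px)
    if n_p > n_h:
        logger.warning("well %s: PI count %d exceeds Hoechst count %d; "
                       "viable clamped to 0", hoechst.well_id or "?", n_p, n_h)
    return WellCount(well_id=hoechst.well_id or pi.well_id,
                     hoechst_count=n_h, pi_count=n_p,
                     viable_count=max(0, n_h - n_p))


CONDITION_KEYS = ["cell_line", "treatment", "dose_uM"]


@dataclass(frozen=True)
class GrowthSeries:
    """Per-condition viable-count time course with fold changes vs 0 h."""

    condition: Tuple
    points: pd.DataFrame  # timepoint_h, mean_viable, sd_viable, n, fold_change


def _counts_frame(counts: Iterable[WellCount], layout: PlateLayout) -> pd.DataFrame:
    df = pd.DataFrame([{"well": c.well_id, "viable": c.viable_count,
                        "hoechst": c.hoechst_count, "pi": c.pi_count}
                       for c in counts])
    merged = df.merge(layout.wells, on="well", how="left", validate="one_to_one")
    unknown = merged[merged["role"].isna()]["well"].tolist()
    if unknown:
        raise ValueError(f"wells missing from layout: {unknown}")
    return merged


def growth_series(counts: Sequence[WellCount], layout: PlateLayout,
                  reference_timepoint_h: float = 0.0) -> List[GrowthSeries]:
    """Aggregate viable counts into growth curves per condition.

    Each condition (cell line, treatment, dose) needs wells at the
    reference timepoint (a 0 h plate); fold change at t is the ratio of
    mean viable counts t vs reference.  Single-replicate points report the
    sd as NaN rather than zero.
    """
    merged = _counts_frame(counts, layout)
    out: List[GrowthSeries] = []
    for condition, grp in merged.groupby(CONDITION_KEYS, sort=True, dropna=False):
        agg = (grp.groupby("timepoint_h")["viable"]
               .agg(mean_viable="mean",
                    sd_viable=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
                    n="count")
               .reset_index()
               .sort_values("timepoint_h", ignore_index=True))
        ref = agg[agg["timepoint_h"] == reference_timepoint_h]
        if ref.empty:
            raise ValueError(
                f"no {reference_timepoint_h} h reference wells for condition "
                f"{dict(zip(CONDITION_KEYS, condition))}")
        ref_mean = float(ref["mean_viable"].iloc[0])
        agg["fold_change"] = agg["mean_viable"] / ref_mean
        out.append(GrowthSeries(condition=tuple(condition), points=agg))
    return out


@dataclass(frozen=True)
class SurvivalResult:
    """Survival of a treated well group relative to its untreated control.

    ``survival`` is the ratio of group means (mean treated viable / mean
    untreated viable) and may exceed 1; ``killing`` is its complement.
    ``survival_mean_of_ratios`` reports the alternative per-well-ratio
    convention for transparency.
    """

    survival: float
    killing: float
    survival_mean_of_ratios: float
    n_treated: int
    n_untreated: int


def survival_rate(treated: Sequence[WellCount],
                  untreated: Sequence[WellCount]) -> SurvivalResult:
    if not treated or not untreated:
        raise ValueError("treated and untreated groups must be non-empty")
    t = np.array([c.viable_count for c in treated], dtype=float)
    u = np.array([c.viable_count for c in untreated], dtype=float)
    u_mean = u.mean()
    if u_mean <= 0:
        raise ValueError("untreated control has zero mean viable count")
    survival = float(t.mean() / u_mean)
    # per-well-ratio convention needs paired wells; NaN otherwise
    if len(t) == len(u) and (u > 0).all():
        mean_of_ratios = float(np.mean(t / u))
    else:
        mean_of_ratios = float("nan")
    return SurvivalResult(survival=survival, killing=1.0 - survival,
                          survival_mean_of_ratios=mean_of_ratios,
                          n_treated=len(t), n_untreated=len(u))
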