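"""Synthetic two-channel well images with known ground truth.

Emulates a Hoechst/PI co-stained well of a 96-well plate: nuclei are
isotropic Gaussian spots scattered inside a circular well on a dark
background.  The Hoechst channel shows every nucleus; the PI channel shows
only the dead ones.  Ground truth (positions, radii, dead flags) is kept
alongside the rendered images so every downstream stage can be scored
without real microscope data.

Spot model: a nucleus of radius r is rendered as a Gaussian of standard
deviation r/sqrt(2), which makes the optimal LoG detection scale exactly r
/ sqrt(2) and gives closed-form oracles for the detector tests.  Default
radii 2.1-5.7 px keep that optimum inside the detector's sigma grid.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import tifffile

from .detect import ChannelImage

__all__ = ["Nucleus", "SyntheticScene", "generate_scene", "render_channels",
           "write_scene", "read_channel_tiff"]

# Random sequential placement of hard disks saturates well below close
# packing; 0.42 of the field area is a safe feasibility bound in practice.
_PACKING_CAPACITY = 0.42


@dataclass(frozen=True)
class Nucleus:
    x: float
    y: float
    radius_px: float
    peak_intensity: float
    dead: bool


@dataclass(frozen=True)
class SyntheticScene:
    """Ground truth for one rendered well: geometry, nuclei, noise model."""

    field_width_px: int
    field_height_px: int
    well_center_xy: Tuple[float, float]
    well_radius_px: float
    nuclei: Tuple[Nucleus, ...]
    background_level: float
    noise_sd: float
    seed: int
    out_of_well_level: float = 0.0

    @property
    def n_dead(self) -> int:
        return sum(n.dead for n in self.nuclei)

    @property
    def n_live(self) -> int:
        return len(self.nuclei) - self.n_dead


def generate_scene(n_cells: int,
                   dead_fraction: float = 0.0,
                   field_size: Tuple[int, int] = (600, 600),
                   well_radius_px: Optional[float] = None,
                   radius_range_px: Tuple[float, float] = (2.1, 5.7),
                   min_separation_px: float = 10.0,
                   peak_range: Tuple[float, float] = (0.3, 0.8),
                   background_level: float = 0.05,
                   noise_sd: float = 0.005,
                   seed: int = 0) -> SyntheticScene:
    """Place ``n_cells`` nuclei uniformly inside the well disk.

    Exactly ``round(n_cells * dead_fraction)`` nuclei are flagged dead.
    When ``min_separation_px`` > 0 all pairwise center distances respect
    it (random sequential placement with bounded retries); an infeasible
    density raises rather than silently under-filling.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not 0 <= dead_fraction <= 1:
        raise ValueError("dead_fraction must be in [0, 1]")
    width, height = int(field_size[0]), int(field_size[1])
    if well_radius_px is None:
        well_radius_px = 0.5 * min(width, height) - 8.0
    if well_radius_px <= 0:
        raise ValueError("well radius must be positive")
    cx, cy = width / 2.0, height / 2.0

    margin = radius_range_px[1]
    place_radius = max(well_radius_px - margin, 1.0)
    if n_cells > 0 and min_separation_px > 0:
        # placement region = well disk (minus margin) clipped to the frame
        region_area = min(math.pi * place_radius ** 2,
                          max(width - 2 * margin, 1) * max(height - 2 * margin, 1))
        per_cell = math.pi * (min_separation_px / 2.0) ** 2
        capacity = int(_PACKING_CAPACITY * region_area / per_cell)
        if n_cells > capacity:
            raise ValueError(
                f"cannot place {n_cells} nuclei with min separation "
                f"{min_separation_px} px in a well of radius "
                f"{well_radius_px:.0f} px (capacity about {capacity})"
            )

    rng = np.random.default_rng(seed)
    xs = np.empty(n_cells)
    ys = np.empty(n_cells)
    placed = 0
    attempts = 0
    max_attempts = 1000 * max(n_cells, 1)
    min_sq = min_separation_px ** 2
    while placed < n_cells:
        if attempts >= max_attempts:
            raise ValueError(
                f"placement stalled after {max_attempts} attempts: "
                f"{placed}/{n_cells} nuclei at min separation "
                f"{min_separation_px} px; reduce density"
            )
        attempts += 1
        # uniform point in the well disk; whole nuclei stay inside the
        # well and the frame, so edge-of-mask detections are never cells
        r = place_radius * math.sqrt(rng.random())
        theta = 2.0 * math.pi * rng.random()
        x = cx + r * math.cos(theta)
        y = cy + r * math.sin(theta)
        if not (margin <= x <= width - margin and margin <= y <= height - margin):
            continue
        if min_separation_px > 0 and placed:
            d2 = (xs[:placed] - x) ** 2 + (ys[:placed] - y) ** 2
            if d2.min() < min_sq:
                continue
        xs[placed], ys[placed] = x, y
        placed += 1

    radii = rng.uniform(*radius_range_px, size=n_cells)
    peaks = rng.uniform(*peak_range, size=n_cells)
    n_dead = int(round(n_cells * dead_fraction))
    dead = np.zeros(n_cells, dtype=bool)
    if n_dead:
        dead[rng.choice(n_cells, size=n_dead, replace=False)] = True

    nuclei = tuple(
        Nucleus(x=float(xs[i]), y=float(ys[i]), radius_px=float(radii[i]),
                peak_intensity=float(peaks[i]), dead=bool(dead[i]))
        for i in range(n_cells)
    )
    return SyntheticScene(field_width_px=width, field_height_px=height,
                          well_center_xy=(cx, cy), well_radius_px=float(well_radius_px),
                          nuclei=nuclei, background_level=background_level,
                          noise_sd=noise_sd, seed=int(seed))


def _add_spot(canvas: np.ndarray, nucleus: Nucleus) -> None:
    """Add one isotropic Gaussian spot (sd = radius/sqrt(2)) in place."""
    sd = nucleus.radius_px / math.sqrt(2.0)
    half = int(math.ceil(4.0 * sd)) + 1
    h, w = canvas.shape
    x0, y0 = nucleus.x, nucleus.y
    xi, yi = int(round(x0)), int(round(y0))
    ylo, yhi = max(0, yi - half), min(h, yi + half + 1)
    xlo, xhi = max(0, xi - half), min(w, xi + half + 1)
    if ylo >= yhi or xlo >= xhi:
        return
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    canvas[ylo:yhi, xlo:xhi] += nucleus.peak_intensity * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sd ** 2)
    )


def render_channels(scene: SyntheticScene,
                    well_id: str = "A1") -> Tuple[ChannelImage, ChannelImage]:
    """Render (hoechst, pi) images for a scene.

    Hoechst receives every nucleus, PI only the dead ones, at the same peak
    intensity (the live/dead rule subtracts counts, not intensities).
    Pixels outside the well disk sit at the out-of-well level; seeded
    Gaussian noise is added everywhere and the result clipped to [0, 1].
    """
    h, w = scene.field_height_px, scene.field_width_px
    cx, cy = scene.well_center_xy
    yy, xx = np.ogrid[:h, :w]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= scene.well_radius_px ** 2

    channels = []
    for k, channel in enumerate(("hoechst", "pi")):
        canvas = np.full((h, w), scene.background_level)
        for nucleus in scene.nuclei:
            if channel == "pi" and not nucleus.dead:
                continue
            _add_spot(canvas, nucleus)
        canvas = np.where(inside, canvas, scene.out_of_well_level)
        if scene.noise_sd > 0:
            noise_rng = np.random.default_rng([scene.seed, k])
            canvas = canvas + noise_rng.normal(0.0, scene.noise_sd, size=(h, w))
        channels.append(ChannelImage(np.clip(canvas, 0.0, 1.0),
                                     channel=channel, well_id=well_id))
    return channels[0], channels[1]


def read_channel_tiff(path, channel: str = "hoechst", well_id: str = "",
                      tile_index: Optional[int] = None) -> ChannelImage:
    """Load a 16-bit grayscale TIFF back into a unit-scaled ChannelImage."""
    from .detect import to_grayscale
    arr = tifffile.imread(str(path))
    return to_grayscale(arr, channel=channel, well_id=well_id, tile_index=tile_index)


def write_scene(scene: SyntheticScene, hoechst: ChannelImage, pi: ChannelImage,
                out_dir, well_id: str = "A1") -> dict:
    """Write the channel TIFFs, ground-truth CSV and a JSON manifest.

    Images are stored as 16-bit grayscale (unit floats x 65535, rounded);
    reading them back reproduces the rendered arrays to within one
    quantization step.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        files = {}
        for img in (hoechst, pi):
            name = f"{well_id}_{img.channel}.tif"
            data = np.round(img.pixels * 65535.0).astype(np.uint16)
            tifffile.imwrite(str(out_dir / name), data)
            files[img.channel] = name

        truth_name = f"{well_id}_truth.csv"
        with open(out_dir / truth_name, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "radius_px", "dead"])
            for n in scene.nuclei:
                writer.writerow([f"{n.x:.4f}", f"{n.y:.4f}",
                                 f"{n.radius_px:.4f}", int(n.dead)])

        manifest = {
            "well_id": well_id,
            "seed": scene.seed,
            "n_cells": len(scene.nuclei),
            "n_dead": scene.n_dead,
            "field_size": [scene.field_width_px, scene.field_height_px],
            "well_center_xy": list(scene.well_center_xy),
            "well_radius_px": scene.well_radius_px,
            "background_level": scene.background_level,
            "noise_sd": scene.noise_sd,
            "out_of_well_level": scene.out_of_well_level,
            "files": files,
            "ground_truth": truth_name,
        }
        manifest_path = out_dir / f"{well_id}_manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        manifest["manifest_path"] = str(manifest_path)
        return manifest
    except OSError as exc:
        raise OSError(f"failed writing scene to {out_dir}: {exc}") from exc
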