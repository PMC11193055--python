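"""Nuclei detection in fluorescence well images.

The processing chain mirrors a plate-based image-cytometry workflow:
grayscale conversion to unit-scaled intensities, masking of everything
outside the analyzed well with the image average, light median smoothing,
and multiscale Laplacian-of-Gaussian (LoG) blob detection with overlap
pruning.  Each surviving blob is counted as one nucleus.

All intensities are unit-scaled to [0, 1] at ingest; the detection
threshold (default 0.005) is defined on the scale-normalized negative LoG
response of those unit intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "ChannelImage",
    "DetectionParams",
    "Blob",
    "BlobSet",
    "to_grayscale",
    "mask_outside_well",
    "median_smooth",
    "log_response_volume",
    "scale_space_maxima",
    "prune_overlapping",
    "detect_blobs",
    "count_image",
]

REC709_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class ChannelImage:
    """One grayscale fluorescence field with channel/well metadata.

    ``pixels`` holds unit-scaled intensities in [0, 1].  ``channel`` is
    "hoechst" (all nuclei) or "pi" (dead nuclei only).
    """

    pixels: np.ndarray
    channel: str = "hoechst"
    well_id: str = ""
    tile_index: Optional[int] = None
    magnification_note: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("ChannelImage expects a non-empty 2-D array")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError(
                "ChannelImage intensities must be unit-scaled to [0, 1]; "
                f"got range [{px.min():.4g}, {px.max():.4g}]"
            )
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))
        if self.channel not in ("hoechst", "pi"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DetectionParams:
    """LoG blob-detection settings (defaults are the screening pipeline's)."""

    min_sigma: float = 1.5
    max_sigma: float = 4.0
    num_sigma: int = 10
    threshold: float = 0.005
    overlap: float = 0.35
    exclude_borders: bool = False
    median_neighborhood: Tuple[int, int] = (4, 4)

    def __post_init__(self):
        if not 0 < self.min_sigma <= self.max_sigma:
            raise ValueError("require 0 < min_sigma <= max_sigma")
        if self.num_sigma < 1:
            raise ValueError("num_sigma must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if not 0 <= self.overlap <= 1:
            raise ValueError("overlap must be in [0, 1]")

    def sigmas(self) -> np.ndarray:
        """Linear sigma grid, inclusive of both endpoints."""
        return np.linspace(self.min_sigma, self.max_sigma, self.num_sigma)


@dataclass(frozen=True)
class Blob:
    """A detected nucleus candidate: center (y, x), scale and LoG response."""

    y: float
    x: float
    sigma: float
    response: float

    @property
    def radius(self) -> float:
        """Model-disk radius for overlap geometry (2-D LoG convention)."""
        return self.sigma * math.sqrt(2.0)


@dataclass(frozen=True)
class BlobSet:
    blobs: Tuple[Blob, ...]
    params: DetectionParams
    source: str = ""

    def __len__(self) -> int:
        return len(self.blobs)

    def __iter__(self):
        return iter(self.blobs)

    def as_array(self) -> np.ndarray:
        """(n, 4) array of y, x, sigma, response."""
        if not self.blobs:
            return np.empty((0, 4))
        return np.array([(b.y, b.x, b.sigma, b.response) for b in self.blobs])


def to_grayscale(image: np.ndarray, channel: str = "hoechst",
                 well_id: str = "", tile_index: Optional[int] = None) -> ChannelImage:
    """Convert a raw 2-D or 3-channel array to a unit-scaled ChannelImage.

    Integer inputs are divided by their dtype maximum; color images are
    collapsed with Rec.709 luminance weights.
    """
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise ValueError(f"expected 3 color channels, got {arr.shape[2]}")
        arr = arr @ np.asarray(REC709_WEIGHTS)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    return ChannelImage(arr, channel=channel, well_id=well_id, tile_index=tile_index)


def mask_outside_well(image: ChannelImage, well_center_xy: Tuple[float, float],
                      well_radius_px: float) -> ChannelImage:
    """Replace pixels outside the well disk by the full-image mean.

    The mean is taken over the ORIGINAL image in one pass, so bright
    artifacts outside the well cannot seed spurious blob detections.
    """
    if well_radius_px <= 0:
        raise ValueError("well radius must be positive")
    h, w = image.shape
    cx, cy = well_center_xy
    yy, xx = np.ogrid[:h, :w]
    outside = (xx - cx) ** 2 + (yy - cy) ** 2 > well_radius_px ** 2
    if not outside.any():
        return image
    px = image.pixels.copy()
    px[outside] = image.pixels.mean()
    return replace(image, pixels=px)


def median_smooth(image: ChannelImage,
                  neighborhood: Tuple[int, int] = (4, 4)) -> ChannelImage:
    """Median-filter the image (default 4x4 neighborhood) to suppress noise.

    Even-sized windows are anchored with the extra row/column toward
    increasing index; borders are handled by reflection.
    """
    ny, nx = neighborhood
    if ny < 1 or nx < 1:
        raise ValueError("neighborhood dimensions must be >= 1")
    # scipy anchors even windows with the extra sample toward decreasing
    # index; origin=-1 shifts the window to [i-1, i+2] for size 4.
    origin = tuple(-1 if n % 2 == 0 else 0 for n in neighborhood)
    px = ndi.median_filter(image.pixels, size=neighborhood, mode="reflect",
                           origin=origin)
    return replace(image, pixels=px)


def log_response_volume(pixels: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Scale-normalized negative LoG response, shape (n_sigma, h, w).

    Bright-on-dark spots produce positive maxima; the sigma**2 factor makes
    responses comparable across scales.
    """
    pixels = np.asarray(pixels, dtype=float)
    cube = np.empty((len(sigmas),) + pixels.shape)
    for i, s in enumerate(sigmas):
        cube[i] = -(s ** 2) * ndi.gaussian_laplace(pixels, s, mode="reflect")
    return cube


# Offsets of the 26 neighbors in the (scale, y, x) response volume, paired
# with whether the CENTER voxel wins a response tie against that neighbor.
# Ties go to the lexicographically lowest (y, x, scale) voxel.
_NEIGHBOR_OFFSETS = [
    (ds, dy, dx)
    for ds in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (ds, dy, dx) != (0, 0, 0)
]


def _center_wins_tie(ds: int, dy: int, dx: int) -> bool:
    return (dy, dx, ds) > (0, 0, 0)


def scale_space_maxima(cube: np.ndarray, threshold: float) -> np.ndarray:
    """Local maxima of the (scale, y, x) response volume above threshold.

    A voxel is kept when its response is strictly greater than each of its
    26 neighbors, except that exact ties within a plateau are resolved in
    favor of the lexicographically lowest (y, x, scale) voxel.  Volume
    borders keep their peaks (missing neighbors never veto).  Returns an
    (n, 3) int array of (s, y, x) indices sorted by (y, x, s).
    """
    padded = np.pad(cube, 1, mode="constant", constant_values=-np.inf)
    S, H, W = cube.shape
    keep = cube >= threshold
    for ds, dy, dx in _NEIGHBOR_OFFSETS:
        if not keep.any():
            break
        nb = padded[1 + ds:1 + ds + S, 1 + dy:1 + dy + H, 1 + dx:1 + dx + W]
        if _center_wins_tie(ds, dy, dx):
            keep &= cube >= nb
        else:
            keep &= cube > nb
    idx = np.argwhere(keep)
    order = np.lexsort((idx[:, 0], idx[:, 2], idx[:, 1]))
    return idx[order]


def _disk_overlap_fraction(d: float, r1: float, r2: float) -> float:
    """Area of the lens shared by two disks, divided by the smaller disk."""
    rs, rl = (r1, r2) if r1 <= r2 else (r2, r1)
    if d >= rs + rl:
        return 0.0
    if d <= rl - rs or d == 0.0:
        return 1.0
    # standard circle-circle intersection (lens) area
    a1 = rs ** 2 * math.acos((d ** 2 + rs ** 2 - rl ** 2) / (2 * d * rs))
    a2 = rl ** 2 * math.acos((d ** 2 + rl ** 2 - rs ** 2) / (2 * d * rl))
    a3 = 0.5 * math.sqrt(max(0.0, (-d + rs + rl) * (d + rs - rl)
                             * (d - rs + rl) * (d + rs + rl)))
    return (a1 + a2 - a3) / (math.pi * rs ** 2)


def prune_overlapping(blobs: Sequence[Blob], overlap: float) -> Tuple[Blob, ...]:
    """Drop the weaker of any two blobs whose model disks overlap too much.

    Each blob is a disk of radius sigma*sqrt(2); when the shared area
    exceeds ``overlap`` of the smaller disk, the larger-sigma blob wins
    (equal sigmas: higher response; still tied: lower (y, x)).  The greedy
    sweep in priority order is deterministic and idempotent.
    """
    blobs = list(blobs)
    if len(blobs) < 2:
        return tuple(sorted(blobs, key=lambda b: (b.y, b.x)))
    priority = sorted(range(len(blobs)),
                      key=lambda i: (-blobs[i].sigma, -blobs[i].response,
                                     blobs[i].y, blobs[i].x))
    pts = np.array([(b.y, b.x) for b in blobs])
    max_reach = 2.0 * max(b.radius for b in blobs)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(max_reach, output_type="ndarray")
    adjacency: dict[int, list[int]] = {}
    for i, j in pairs:
        bi, bj = blobs[i], blobs[j]
        d = math.hypot(bi.y - bj.y, bi.x - bj.x)
        if _disk_overlap_fraction(d, bi.radius, bj.radius) > overlap:
            adjacency.setdefault(i, []).append(j)
            adjacency.setdefault(j, []).append(i)
    rank = {idx: r for r, idx in enumerate(priority)}
    alive = [True] * len(blobs)
    for idx in priority:
        if not alive[idx]:
            continue
        for other in adjacency.get(idx, ()):
            if alive[other] and rank[other] > rank[idx]:
                alive[other] = False
    survivors = [b for i, b in enumerate(blobs) if alive[i]]
    return tuple(sorted(survivors, key=lambda b: (b.y, b.x)))


def detect_blobs(image: ChannelImage, params: DetectionParams = DetectionParams(),
                 prune: bool = True) -> BlobSet:
    """Multiscale LoG blob detection on a preprocessed channel image.

    Candidates are local maxima of the scale-normalized negative LoG
    response over a linear sigma grid, thresholded, then overlap-pruned.
    ``prune=False`` returns the raw scale-space maxima (used by the
    brute-force equivalence tests).
    """
    sigmas = params.sigmas()
    support = 2 * int(4.0 * params.max_sigma + 0.5) + 1
    if min(image.shape) < support:
        raise ValueError(
            f"image {image.shape} smaller than the largest LoG filter "
            f"support ({support} px at sigma={params.max_sigma})"
        )
    cube = log_response_volume(image.pixels, sigmas)
    idx = scale_space_maxima(cube, params.threshold)
    blobs = [Blob(y=float(y), x=float(x), sigma=float(sigmas[s]),
                  response=float(cube[s, y, x])) for s, y, x in idx]
    if prune:
        blobs = prune_overlapping(blobs, params.overlap)
    else:
        blobs = tuple(sorted(blobs, key=lambda b: (b.y, b.x)))
    source = image.well_id or ""
    if image.tile_index is not None:
        source += f"_tile{image.tile_index}"
    return BlobSet(blobs=tuple(blobs), params=params,
                   source=f"{source}:{image.channel}" if source else image.channel)


RIM_MARGIN_PX = 2.0


def count_image(image: ChannelImage, params: DetectionParams = DetectionParams(),
                well_center_xy: Optional[Tuple[float, float]] = None,
                well_radius_px: Optional[float] = None) -> int:
    """Nucleus count for one channel image: mask -> smooth -> detect.

    Masking is applied only when the well geometry is given; callers with
    full-frame subarea images skip it.  Average-masking leaves a circular
    intensity step at the mask boundary whenever the image mean differs
    from the local background, and the LoG responds along that circle, so
    blobs centered within RIM_MARGIN_PX of (or beyond) the mask radius are
    discarded as rim artifacts rather than counted as nuclei.
    """
    masked = well_center_xy is not None and well_radius_px is not None
    if masked:
        image = mask_outside_well(image, well_center_xy, well_radius_px)
    image = median_smooth(image, params.median_neighborhood)
    blobs = detect_blobs(image, params)
    if not masked:
        return len(blobs)
    cx, cy = well_center_xy
    keep_r = well_radius_px - RIM_MARGIN_PX
    return sum(1 for b in blobs if math.hypot(b.y - cy, b.x - cx) < keep_r)
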