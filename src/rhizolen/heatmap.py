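"""Gaussian point-density heatmaps for root-point supervision.

The points (detection + regression) estimator is trained against a
"density estimation" map: a unit-peak Gaussian ``exp(-d^2 / (2 sigma^2))``
centred on every annotated root point, rendered on a grid that may be a
downscaled copy of the image.  Overlapping kernels are combined with an
element-wise maximum by default, which keeps the map magnitude independent
of how densely an annotator clicked along a root; a clipped-sum variant is
available.  Peak decoding exists for visual inspection of annotations and
predictions, not for computing root length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max

from .annotation_io import ConfigurationError, ImageAnnotation

__all__ = ["DensityMap", "render_heatmap", "render_points_map", "decode_peaks", "overlay"]


@dataclass
class DensityMap:
    """Single-channel map in [0, 1] with Gaussian bumps at annotated points."""

    grid: np.ndarray  # (H, W) float
    sigma_px: float   # Gaussian std, in map pixels
    scale: float      # map resolution / image resolution

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # (H, W)


def render_points_map(
    points: np.ndarray,
    shape: tuple[int, int],
    sigma_px: float,
    mode: str = "max",
) -> np.ndarray:
    """Render Gaussian bumps at ``points`` (x, y in map coordinates) on an (H, W) grid.

    Kernels are evaluated over the full grid (no truncation), so the result is
    exactly the per-pixel max (or clipped sum) over points.
    """
    if sigma_px <= 0:
        raise ConfigurationError(f"sigma_px must be positive, got {sigma_px}")
    if mode not in ("max", "sum"):
        raise ConfigurationError(f"unknown overlap mode {mode!r}")
    h, w = shape
    grid = np.zeros((h, w), dtype=np.float64)
    if len(points) == 0:
        return grid
    xs = np.arange(w, dtype=np.float64)
    ys = np.arange(h, dtype=np.float64)
    inv = 1.0 / (2.0 * sigma_px * sigma_px)
    for x, y in np.asarray(points, dtype=np.float64):
        bump = np.exp(-((ys - y)[:, None] ** 2 + (xs - x)[None, :] ** 2) * inv)
        if mode == "max":
            np.maximum(grid, bump, out=grid)
        else:
            grid += bump
    if mode == "sum":
        np.clip(grid, 0.0, 1.0, out=grid)
    return grid


def render_heatmap(
    ann: ImageAnnotation,
    sigma_px: float = 2.0,
    scale: float = 0.25,
    mode: str = "max",
) -> DensityMap:
    """Render the supervision heatmap of an annotated image.

    ``scale`` is the map-to-image resolution ratio (map size is the floor of
    image size x scale); ``sigma_px`` is the Gaussian std in *map* pixels.
    Annotated point coordinates are scaled, not re-annotated.  An image with
    no roots yields an all-zero map.
    """
    if not 0 < scale <= 1:
        raise ConfigurationError(f"scale must be in (0, 1], got {scale}")
    w, h = ann.camera.image_size_px
    mw, mh = int(math.floor(w * scale)), int(math.floor(h * scale))
    pts = ann.all_points() * scale
    grid = render_points_map(pts, (mh, mw), sigma_px, mode=mode)
    return DensityMap(grid=grid, sigma_px=float(sigma_px), scale=float(scale))


def decode_peaks(
    dmap: DensityMap,
    min_value: float = 0.5,
    min_separation_px: float = 4.0,
) -> np.ndarray:
    """Local maxima of the map above ``min_value``, at least ``min_separation_px``
    apart (distances in image pixels), returned as (n, 2) image-resolution (x, y).
    """
    if min_value <= 0 or min_separation_px <= 0:
        raise ConfigurationError("min_value and min_separation_px must be positive")
    sep_map = max(1, int(round(min_separation_px * dmap.scale)))
    rc = peak_local_max(
        dmap.grid, min_distance=sep_map, threshold_abs=min_value, exclude_border=False
    )
    if rc.size == 0:
        return np.empty((0, 2))
    xy = rc[:, ::-1].astype(float) / dmap.scale
    return xy


def overlay(image: np.ndarray, dmap: DensityMap, alpha: float = 0.6) -> np.ndarray:
    """Alpha-blend the heatmap in red over a grayscale/RGB image (uint8 out).

    For auditing annotations and predictions the way annotation tools draw
    point overlays on the raw frame.
    """
    from skimage.transform import resize

    img = np.asarray(image)
    if img.dtype != np.float64:
        img = img.astype(np.float64) / (255.0 if img.dtype == np.uint8 else 1.0)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    hm = resize(dmap.grid, img.shape[:2], order=1, anti_aliasing=False)
    out = img.copy()
    out[..., 0] = np.clip(img[..., 0] * (1 - alpha * hm) + alpha * hm, 0, 1)
    out[..., 1] = img[..., 1] * (1 - alpha * hm)
    out[..., 2] = img[..., 2] * (1 - alpha * hm)
    return (out * 255).round().astype(np.uint8)
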