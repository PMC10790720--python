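"""Synthetic minirhizotron image generator with exact point annotations.

Generates MR-like frames — soil-textured background, uneven illumination,
curved roots drawn as anti-aliased strokes, water-bubble and scratch
artifacts, sensor noise — together with the generating polylines, so every
image carries an exact point annotation and TRL label.  Root geometry is
sampled in physical mm coordinates inside a fixed world window and projected
through the camera profile, so the "manual" (low-contrast, 624x450 px) and
"automated" (high-contrast, higher-resolution) systems image the same class
of scenes at different quality; this is what makes cross-system transfer
experiments on synthetic data meaningful.

All randomness flows from a single :class:`numpy.random.Generator`; images
are written as PNG so byte-identical regeneration under a fixed seed holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .annotation_io import (
    AUTOMATED_SIM_CAMERA,
    MANUAL_CAMERA,
    CameraProfile,
    DatasetIndex,
    ImageAnnotation,
    IndexRecord,
    RootPolyline,
    save_annotations,
)

__all__ = [
    "SceneSpec",
    "manual_scene_spec",
    "automated_scene_spec",
    "sample_root_polyline",
    "render_image",
    "generate_dataset",
]

#: Shared physical window (mm) in which root geometry is sampled, chosen as the
#: manual camera's field of view so the same world fits both systems' frames.
DEFAULT_WORLD_MM = (18.0, 13.5)


@dataclass(frozen=True)
class SceneSpec:
    """Scene statistics for one synthetic acquisition campaign."""

    camera: CameraProfile
    world_mm: tuple[float, float] = DEFAULT_WORLD_MM
    p_empty: float = 0.3                      # fraction of zero-root images
    max_roots: int = 4                        # 1..max_roots roots when not empty
    n_points_range: tuple[int, int] = (5, 15)  # annotation clicks per root
    step_mm_range: tuple[float, float] = (1.5, 3.0)  # click spacing along the root
    heading_sigma_rad: float = 0.35           # curvature of the random-heading walk
    root_width_mm_range: tuple[float, float] = (0.4, 1.0)
    contrast: float = 0.30                    # root-over-soil intensity lift, [0, 1] units
    illumination_amp: float = 0.10            # multiplicative gradient amplitude
    bubble_rate: float = 0.6                  # mean bubbles per image (Poisson)
    scratch_rate: float = 0.6                 # mean scratches per image (Poisson)
    noise_std: float = 0.02                   # additive sensor noise, [0, 1] units
    background_level: float = 0.45
    texture_mm: float = 0.8                   # soil granule correlation length
    texture_amp: float = 0.05
    seed: int | None = None                   # used when no rng is passed explicitly

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_empty <= 1.0:
            raise ValueError("p_empty must be in [0, 1]")
        for name in ("contrast", "illumination_amp", "bubble_rate", "scratch_rate",
                     "noise_std", "texture_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def manual_scene_spec(**overrides) -> SceneSpec:
    """Study conditions of the manual Bartz-style system: low contrast, uneven
    incandescent illumination, noisier frames."""
    base = dict(
        camera=MANUAL_CAMERA,
        contrast=0.14,
        illumination_amp=0.25,
        noise_std=0.045,
        texture_amp=0.06,
        bubble_rate=0.7,
        scratch_rate=0.8,
    )
    base.update(overrides)
    return SceneSpec(**base)


def automated_scene_spec(**overrides) -> SceneSpec:
    """Study conditions of the automated RootCam-style system: LED lighting,
    higher resolution, clearly visible roots."""
    base = dict(
        camera=AUTOMATED_SIM_CAMERA,
        contrast=0.30,
        illumination_amp=0.08,
        noise_std=0.02,
        texture_amp=0.05,
        bubble_rate=0.6,
        scratch_rate=0.5,
    )
    base.update(overrides)
    return SceneSpec(**base)


# ---------------------------------------------------------------------------
# geometry


def _sample_polyline_mm(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Random-heading walk in mm inside the world window."""
    ww, wh = spec.world_mm
    n_pts = int(rng.integers(spec.n_points_range[0], spec.n_points_range[1] + 1))
    start = rng.uniform((0.05 * ww, 0.05 * wh), (0.95 * ww, 0.95 * wh))
    heading = rng.uniform(0.0, 2.0 * math.pi)
    pts = [start]
    for _ in range(n_pts - 1):
        step = rng.uniform(*spec.step_mm_range)
        heading += rng.normal(0.0, spec.heading_sigma_rad)
        nxt = pts[-1] + step * np.array([math.cos(heading), math.sin(heading)])
        pts.append(nxt)
    pts = np.array(pts)
    pts[:, 0] = np.clip(pts[:, 0], 0.0, ww)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, wh)
    return pts


def _mm_to_px(pts_mm: np.ndarray, cam: CameraProfile) -> np.ndarray:
    w, h = cam.image_size_px
    pts = pts_mm / cam.pixel_pitch_mm
    pts[:, 0] = np.clip(pts[:, 0], 0.0, w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, h - 1)
    return pts


def sample_root_polyline(spec: SceneSpec, rng: np.random.Generator) -> RootPolyline:
    """Sample one curved root and project it into the camera's pixel frame.

    The returned polyline IS the ground truth: its pixel length times the
    camera pitch is the root's contribution to the image TRL, exactly.
    """
    return RootPolyline(_mm_to_px(_sample_polyline_mm(spec, rng), spec.camera))


# ---------------------------------------------------------------------------
# rasterization


def _stroke(canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
    """Max-composite an anti-aliased thick segment onto ``canvas`` (in place)."""
    h, w = canvas.shape
    pad = radius + 1.5
    x0 = max(0, int(math.floor(min(p0[0], p1[0]) - pad)))
    x1 = min(w, int(math.ceil(max(p0[0], p1[0]) + pad)) + 1)
    y0 = max(0, int(math.floor(min(p0[1], p1[1]) - pad)))
    y1 = min(h, int(math.ceil(max(p0[1], p1[1]) + pad)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=np.float64)
    ys = np.arange(y0, y1, dtype=np.float64)
    px, py = np.meshgrid(xs, ys)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0.0:
        dist = np.hypot(px - p0[0], py - p0[1])
    else:
        t = np.clip(((px - p0[0]) * d[0] + (py - p0[1]) * d[1]) / len2, 0.0, 1.0)
        dist = np.hypot(px - (p0[0] + t * d[0]), py - (p0[1] + t * d[1]))
    # soft 1-px anti-aliased edge around the stroke radius
    patch = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    np.maximum(canvas[y0:y1, x0:x1], patch, out=canvas[y0:y1, x0:x1])


def _draw_polyline(canvas: np.ndarray, pts: np.ndarray, radius: float) -> None:
    if len(pts) == 1:
        _stroke(canvas, pts[0], pts[0], radius)
        return
    for a, b in zip(pts[:-1], pts[1:]):
        _stroke(canvas, a, b, radius)


def _correlated_noise(shape: tuple[int, int], sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with correlation length ``sigma`` px.

    Large sigmas are rendered on a coarse grid and bilinearly upsampled,
    which is visually equivalent and much cheaper than filtering at full
    resolution.
    """
    h, w = shape
    factor = max(1, int(sigma / 2.0))
    hs, ws = max(h // factor + 2, 4), max(w // factor + 2, 4)
    base = gaussian_filter(rng.standard_normal((hs, ws)), sigma=sigma / factor,
                           truncate=3.0)
    if factor > 1:
        from skimage.transform import resize

        base = resize(base, (h, w), order=1, anti_aliasing=False, mode="edge")
    else:
        base = base[:h, :w]
    s = base.std()
    return base / s if s > 0 else base


def _soil_background(spec: SceneSpec, shape: tuple[int, int],
                     rng: np.random.Generator) -> np.ndarray:
    pitch = spec.camera.pixel_pitch_mm
    sigma = max(spec.texture_mm / pitch * 0.5, 0.5)
    fine = _correlated_noise(shape, sigma, rng)
    coarse = _correlated_noise(shape, 4 * sigma, rng)
    return spec.background_level + spec.texture_amp * (0.7 * fine + 0.6 * coarse)


def _illumination(spec: SceneSpec, shape: tuple[int, int],
                  rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    theta = rng.uniform(0.0, 2.0 * math.pi)
    gx = np.linspace(-0.5, 0.5, w)[None, :]
    gy = np.linspace(-0.5, 0.5, h)[:, None]
    grad = math.cos(theta) * gx + math.sin(theta) * gy
    # mild radial falloff emulating a ring of point lights around the lens
    r2 = gx**2 + gy**2
    vign = 1.0 - 0.6 * spec.illumination_amp * r2 / r2.max()
    return (1.0 + spec.illumination_amp * grad * rng.uniform(0.5, 1.0)) * vign


def _add_artifacts(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> None:
    h, w = img.shape
    pitch = spec.camera.pixel_pitch_mm
    # water bubbles: bright rings with slightly darkened interiors
    for _ in range(int(rng.poisson(spec.bubble_rate))):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        r = rng.uniform(0.5, 2.0) / pitch
        x0, x1 = max(0, int(cx - r - 3)), min(w, int(cx + r + 4))
        y0, y1 = max(0, int(cy - r - 3)), min(h, int(cy + r + 4))
        if x0 >= x1 or y0 >= y1:
            continue
        px, py = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        d = np.hypot(px - cx, py - cy)
        rim = np.clip(1.5 - np.abs(d - r), 0.0, 1.0)
        img[y0:y1, x0:x1] += 0.25 * rim - 0.06 * (d < r)
    # scratches on the tube wall: long thin bright strokes that can look like roots
    scratch = np.zeros_like(img)
    for _ in range(int(rng.poisson(spec.scratch_rate))):
        p0 = rng.uniform((0, 0), (w - 1, h - 1))
        ang = rng.uniform(0.0, 2.0 * math.pi)
        length = rng.uniform(0.3, 0.9) * min(w, h)
        p1 = p0 + length * np.array([math.cos(ang), math.sin(ang)])
        p1 = np.clip(p1, 0, (w - 1, h - 1))
        _stroke(scratch, p0, p1, radius=rng.uniform(0.6, 1.3))
    img += 0.6 * spec.contrast * scratch if spec.contrast > 0 else 0.08 * scratch


def render_image(
    polylines: list[RootPolyline],
    spec: SceneSpec,
    rng: np.random.Generator,
    image_id: str = "synthetic",
    tube_id: str | None = None,
    depth_index: int | None = None,
    date: str | None = None,
) -> tuple[np.ndarray, ImageAnnotation]:
    """Rasterize a scene into a uint8 grayscale frame plus its exact annotation."""
    w, h = spec.camera.image_size_px
    img = _soil_background(spec, (h, w), rng)
    img *= _illumination(spec, (h, w), rng)
    _add_artifacts(img, spec, rng)
    pitch = spec.camera.pixel_pitch_mm
    for poly in polylines:
        mask = np.zeros((h, w), dtype=np.float64)
        width_mm = rng.uniform(*spec.root_width_mm_range)
        _draw_polyline(mask, poly.points, radius=max(0.5 * width_mm / pitch, 0.6))
        shade = rng.uniform(0.8, 1.0)  # per-root brightness variation
        img += spec.contrast * shade * mask
    img += rng.normal(0.0, spec.noise_std, size=(h, w))
    out = np.clip(img, 0.0, 1.0)
    ann = ImageAnnotation(
        image_id=image_id,
        roots=list(polylines),
        camera=spec.camera,
        tube_id=tube_id,
        depth_index=depth_index,
        date=date,
    )
    return (out * 255.0).round().astype(np.uint8), ann


def _sample_scene(spec: SceneSpec, rng: np.random.Generator) -> list[RootPolyline]:
    if rng.uniform() < spec.p_empty:
        return []
    n_roots = int(rng.integers(1, spec.max_roots + 1))
    return [sample_root_polyline(spec, rng) for _ in range(n_roots)]


def generate_dataset(
    n: int,
    spec: SceneSpec,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
    depths_per_tube: int = 8,
    date: str = "2021-06-01",
    prefix: str = "img",
) -> DatasetIndex:
    """Generate ``n`` annotated PNG frames under ``out_dir``.

    Images are assigned round-robin to tubes of ``depths_per_tube`` consecutive
    depth positions so depth profiles (RLD) can be computed downstream.  Writes
    ``images.csv`` / ``points.csv`` / ``cameras.json`` in the annotation schema
    and returns the loaded-equivalent index.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(n):
        image_id = f"{prefix}_{i:05d}"
        polys = _sample_scene(spec, rng)
        img, ann = render_image(
            polys,
            spec,
            rng,
            image_id=image_id,
            tube_id=f"tube{i // depths_per_tube + 1:03d}",
            depth_index=i % depths_per_tube,
            date=date,
        )
        rel = f"images/{image_id}.png"
        Image.fromarray(img, mode="L").save(img_dir / f"{image_id}.png", format="PNG")
        records.append(IndexRecord(path=rel, annotation=ann, base_dir=str(out_dir)))
    index = DatasetIndex(records)
    save_annotations(index, out_dir)
    return index
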