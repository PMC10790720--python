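"""Data model, geometry and serialization for point-annotated minirhizotron images.

Minirhizotron (MR) root annotation tools such as Rootfly record each root as an
ordered chain of clicked points; the chain's polyline length, converted through
the camera's pixel pitch, is the root's length in mm, and the per-image total
root length (TRL) is the sum over all annotated roots.  This module holds the
camera profiles of the two MR acquisition systems, the polyline/annotation
containers, a CSV/JSON serialization of the annotation schema, and the random
dataset splitter used to form train/validation/test sets.

Coordinates are 0-based pixels, ``x`` = column, ``y`` = row, origin at the
top-left of the stored (possibly cropped) image.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CameraProfile",
    "RootPolyline",
    "ImageAnnotation",
    "IndexRecord",
    "DatasetIndex",
    "AnnotationError",
    "ConfigurationError",
    "MANUAL_CAMERA",
    "AUTOMATED_CAMERA",
    "AUTOMATED_SIM_CAMERA",
    "BUILTIN_CAMERAS",
    "pixel_pitch_mm",
    "polyline_length_px",
    "image_trl_mm",
    "load_annotations",
    "save_annotations",
    "split_dataset",
]

SPLITS = ("train", "val", "test")


class AnnotationError(ValueError):
    """Invalid annotation content (empty polyline, out-of-bounds point, bad row)."""


class ConfigurationError(ValueError):
    """Invalid configuration (camera profile, split fractions, missing metadata)."""


class AnisotropicPitchWarning(UserWarning):
    """Width- and height-axis pixel pitches of a camera profile disagree by > 1%."""


# the automated system's printed specs are themselves anisotropic, so this
# warning would otherwise fire on every profile reconstruction
warnings.simplefilter("once", AnisotropicPitchWarning)


# ---------------------------------------------------------------------------
# camera profiles


@dataclass(frozen=True)
class CameraProfile:
    """Optical/geometric description of one MR acquisition system.

    ``fov_mm`` and ``size_px`` describe the native sensor frame; ``crop_px``,
    when set, is the size of the stored image after border cropping.  Cropping
    removes pixels without rescaling, so the pixel pitch is always computed
    from the native frame.  ``depth_step_mm`` is the camera travel between
    consecutive images along the observation tube.
    """

    name: str
    fov_mm: tuple[float, float]
    size_px: tuple[int, int]
    depth_step_mm: float
    crop_px: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        fw, fh = self.fov_mm
        pw, ph = self.size_px
        if not (fw > 0 and fh > 0 and math.isfinite(fw) and math.isfinite(fh)):
            raise ConfigurationError(f"camera {self.name!r}: fov_mm must be positive")
        if not (pw > 0 and ph > 0):
            raise ConfigurationError(f"camera {self.name!r}: size_px must be positive")
        if self.depth_step_mm <= 0:
            raise ConfigurationError(f"camera {self.name!r}: depth_step_mm must be positive")
        if self.crop_px is not None:
            cw, ch = self.crop_px
            if not (0 < cw <= pw and 0 < ch <= ph):
                raise ConfigurationError(
                    f"camera {self.name!r}: crop_px must fit inside size_px"
                )
        wp, hp = fw / pw, fh / ph
        if abs(wp - hp) / wp > 0.01:
            # The printed automated-system numbers are themselves ~15% anisotropic,
            # so this is a warning, not an error; the width pitch is the scalar pitch.
            warnings.warn(
                f"camera {self.name!r}: pixel pitch is anisotropic "
                f"(width {wp:.6g} vs height {hp:.6g} mm/px); using width pitch",
                AnisotropicPitchWarning,
                stacklevel=2,
            )

    @property
    def pixel_pitch_mm(self) -> float:
        """Scalar mm-per-pixel, width axis of the native frame."""
        return self.fov_mm[0] / self.size_px[0]

    @property
    def image_size_px(self) -> tuple[int, int]:
        """(width, height) of the stored image: the crop if set, else the sensor."""
        return self.crop_px if self.crop_px is not None else self.size_px

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "fov_mm": list(self.fov_mm),
            "size_px": list(self.size_px),
            "depth_step_mm": self.depth_step_mm,
        }
        if self.crop_px is not None:
            d["crop_px"] = list(self.crop_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CameraProfile":
        allowed = {"name", "fov_mm", "size_px", "depth_step_mm", "crop_px"}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown camera profile keys: {sorted(unknown)}")
        crop = d.get("crop_px")
        fields = dict(
            name=str(d["name"]),
            fov_mm=tuple(float(v) for v in d["fov_mm"]),
            size_px=tuple(int(v) for v in d["size_px"]),
            depth_step_mm=float(d["depth_step_mm"]),
            crop_px=tuple(int(v) for v in crop) if crop is not None else None,
        )
        builtin = BUILTIN_CAMERAS.get(fields["name"])
        if builtin is not None and all(getattr(builtin, k) == v for k, v in fields.items()):
            return builtin  # avoid re-validating (and re-warning about) known profiles
        return cls(**fields)


def pixel_pitch_mm(cam: CameraProfile) -> float:
    """mm per pixel of ``cam`` (width-axis pitch of the native sensor frame)."""
    return cam.pixel_pitch_mm


#: Bartz-style manual MR camera: 18 x 13.5 mm viewed at 640 x 480 px, stored
#: images cropped to 624 x 450 px, images every 13.5 mm along the tube.
MANUAL_CAMERA = CameraProfile(
    name="manual",
    fov_mm=(18.0, 13.5),
    size_px=(640, 480),
    depth_step_mm=13.5,
    crop_px=(624, 450),
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    #: RootCam-style automated MR camera: 25 x 19 mm at 2952 x 1944 px,
    #: images every 18.75 mm.  The printed pitch is anisotropic; width wins.
    AUTOMATED_CAMERA = CameraProfile(
        name="automated",
        fov_mm=(25.0, 19.0),
        size_px=(2952, 1944),
        depth_step_mm=18.75,
    )
    #: Automated profile rendered at quarter resolution (desk-scale synthetic
    #: default); same field of view and depth step as the full-resolution system.
    AUTOMATED_SIM_CAMERA = CameraProfile(
        name="automated_sim",
        fov_mm=(25.0, 19.0),
        size_px=(738, 486),
        depth_step_mm=18.75,
    )

BUILTIN_CAMERAS: dict[str, CameraProfile] = {
    c.name: c for c in (MANUAL_CAMERA, AUTOMATED_CAMERA, AUTOMATED_SIM_CAMERA)
}


# ---------------------------------------------------------------------------
# polylines and annotations


@dataclass
class RootPolyline:
    """One annotated root: ordered (x, y) pixel coordinates, length >= 1."""

    points: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise AnnotationError("polyline needs an (n, 2) array with n >= 1")
        if not np.all(np.isfinite(pts)):
            raise AnnotationError("polyline coordinates must be finite")
        self.points = pts

    def length_px(self) -> float:
        return polyline_length_px(self)

    def reversed(self) -> "RootPolyline":
        return RootPolyline(self.points[::-1].copy())


def polyline_length_px(poly: RootPolyline) -> float:
    """Length of the connected point chain, in pixels (0 for a single point)."""
    pts = poly.points
    if pts.shape[0] == 1:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


@dataclass
class ImageAnnotation:
    """All root polylines of one MR image plus acquisition metadata."""

    image_id: str
    roots: list[RootPolyline]
    camera: CameraProfile
    tube_id: str | None = None
    depth_index: int | None = None
    date: str | None = None

    def __post_init__(self) -> None:
        w, h = self.camera.image_size_px
        for k, poly in enumerate(self.roots):
            pts = poly.points
            if (
                pts[:, 0].min() < 0
                or pts[:, 1].min() < 0
                or pts[:, 0].max() > w - 1
                or pts[:, 1].max() > h - 1
            ):
                raise AnnotationError(
                    f"image {self.image_id!r}, root {k}: point outside the "
                    f"{w}x{h} image bounds"
                )

    @property
    def trl_mm(self) -> float:
        return image_trl_mm(self)

    def all_points(self) -> np.ndarray:
        """All annotated points of the image, stacked (n, 2); empty (0, 2) if none."""
        if not self.roots:
            return np.empty((0, 2))
        return np.concatenate([p.points for p in self.roots], axis=0)


def image_trl_mm(ann: ImageAnnotation) -> float:
    """Total root length of the image in mm: sum of polyline lengths x pixel pitch."""
    if ann.camera is None:  # defensive; dataclass normally guarantees it
        raise ConfigurationError(f"image {ann.image_id!r} has no camera profile")
    pitch = ann.camera.pixel_pitch_mm
    return float(sum(polyline_length_px(p) for p in ann.roots) * pitch)


# ---------------------------------------------------------------------------
# dataset index


@dataclass
class IndexRecord:
    path: str
    annotation: ImageAnnotation
    split: str | None = None
    #: directory the index was loaded from; relative ``path`` values resolve
    #: against it, which keeps the on-disk schema relocatable
    base_dir: str | None = None

    def resolve_path(self) -> Path:
        p = Path(self.path)
        if p.is_absolute() or self.base_dir is None:
            return p
        return Path(self.base_dir) / p


@dataclass
class DatasetIndex:
    """Ordered collection of (image path, annotation) records with split labels."""

    records: list[IndexRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> "DatasetIndex":
        if split not in SPLITS:
            raise ConfigurationError(f"unknown split {split!r}; expected one of {SPLITS}")
        return DatasetIndex([r for r in self.records if r.split == split])

    def image_ids(self) -> list[str]:
        return [r.annotation.image_id for r in self.records]

    def trl_mm(self) -> np.ndarray:
        return np.array([r.annotation.trl_mm for r in self.records])

    def cameras(self) -> dict[str, CameraProfile]:
        return {r.annotation.camera.name: r.annotation.camera for r in self.records}


# ---------------------------------------------------------------------------
# serialization
#
# Directory layout: <dir>/images.csv (one row per image) and <dir>/points.csv
# (one row per annotated point).  A ``.json`` path stores the same content in
# one document.  Cameras are embedded so an index is self-describing.


def _index_to_tables(index: DatasetIndex) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    img_rows, pt_rows = [], []
    cams: dict[str, CameraProfile] = {}
    for rec in index.records:
        ann = rec.annotation
        cams[ann.camera.name] = ann.camera
        img_rows.append(
            {
                "image_id": ann.image_id,
                "path": rec.path,
                "camera": ann.camera.name,
                "tube_id": ann.tube_id if ann.tube_id is not None else "",
                "depth_index": ann.depth_index if ann.depth_index is not None else "",
                "date": ann.date if ann.date is not None else "",
                "split": rec.split if rec.split is not None else "",
            }
        )
        for rid, poly in enumerate(ann.roots):
            for pid, (x, y) in enumerate(poly.points):
                pt_rows.append(
                    {
                        "image_id": ann.image_id,
                        "root_id": rid,
                        "point_index": pid,
                        "x_px": float(x),
                        "y_px": float(y),
                    }
                )
    images = pd.DataFrame(
        img_rows,
        columns=["image_id", "path", "camera", "tube_id", "depth_index", "date", "split"],
    )
    points = pd.DataFrame(
        pt_rows, columns=["image_id", "root_id", "point_index", "x_px", "y_px"]
    )
    return images, points, [c.to_dict() for c in cams.values()]


def save_annotations(index: DatasetIndex, path: str | Path) -> None:
    """Write an index to ``path``: a directory (CSV schema) or a ``.json`` file."""
    path = Path(path)
    images, points, cameras = _index_to_tables(index)
    if path.suffix.lower() == ".json":
        doc = {
            "cameras": cameras,
            "images": images.to_dict(orient="records"),
            "points": points.to_dict(orient="records"),
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.mkdir(parents=True, exist_ok=True)
        images.to_csv(path / "images.csv", index=False)
        points.to_csv(path / "points.csv", index=False)
        (path / "cameras.json").write_text(json.dumps(cameras, indent=1))


def _blank(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v) == ""


def _build_index(
    images: pd.DataFrame,
    points: pd.DataFrame,
    cameras: dict[str, CameraProfile],
    base_dir: str | None = None,
) -> DatasetIndex:
    required_img = {"image_id", "path", "camera"}
    if not required_img <= set(images.columns):
        raise AnnotationError(
            f"images table is missing columns {sorted(required_img - set(images.columns))}"
        )
    required_pt = {"image_id", "root_id", "point_index", "x_px", "y_px"}
    if len(points) and not required_pt <= set(points.columns):
        raise AnnotationError(
            f"points table is missing columns {sorted(required_pt - set(points.columns))}"
        )

    by_image: dict[str, list[RootPolyline]] = {}
    if len(points):
        for (image_id, root_id), grp in points.groupby(["image_id", "root_id"], sort=False):
            grp = grp.sort_values("point_index")
            xy = grp[["x_px", "y_px"]].to_numpy(dtype=float)
            if not np.all(np.isfinite(xy)) or xy.min() < 0:
                raise AnnotationError(
                    f"image {image_id!r}, root {root_id}: invalid point coordinates"
                )
            by_image.setdefault(str(image_id), []).append(RootPolyline(xy))

    records: list[IndexRecord] = []
    for row in images.to_dict(orient="records"):
        image_id = str(row["image_id"])
        cam_name = str(row["camera"])
        cam = cameras.get(cam_name, BUILTIN_CAMERAS.get(cam_name))
        if cam is None:
            raise AnnotationError(f"image {image_id!r}: unknown camera {cam_name!r}")
        try:
            ann = ImageAnnotation(
                image_id=image_id,
                roots=by_image.get(image_id, []),
                camera=cam,
                tube_id=None if _blank(row.get("tube_id")) else str(row["tube_id"]),
                depth_index=None
                if _blank(row.get("depth_index"))
                else int(float(row["depth_index"])),
                date=None if _blank(row.get("date")) else str(row["date"]),
            )
        except AnnotationError as exc:
            raise AnnotationError(f"record {image_id!r}: {exc}") from exc
        split = None if _blank(row.get("split")) else str(row["split"])
        if split is not None and split not in SPLITS:
            raise AnnotationError(f"record {image_id!r}: unknown split label {split!r}")
        records.append(
            IndexRecord(path=str(row["path"]), annotation=ann, split=split,
                        base_dir=base_dir)
        )
    return DatasetIndex(records)


def load_annotations(path: str | Path) -> DatasetIndex:
    """Load an index saved by :func:`save_annotations` (directory or ``.json``)."""
    path = Path(path)
    if path.is_dir():
        images = pd.read_csv(path / "images.csv", dtype={"image_id": str})
        pts_path = path / "points.csv"
        points = (
            pd.read_csv(pts_path, dtype={"image_id": str})
            if pts_path.exists()
            else pd.DataFrame(columns=["image_id", "root_id", "point_index", "x_px", "y_px"])
        )
        cam_path = path / "cameras.json"
        cameras = (
            {d["name"]: CameraProfile.from_dict(d) for d in json.loads(cam_path.read_text())}
            if cam_path.exists()
            else {}
        )
    elif path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        cameras = {d["name"]: CameraProfile.from_dict(d) for d in doc.get("cameras", [])}
        images = pd.DataFrame(
            doc["images"],
            columns=["image_id", "path", "camera", "tube_id", "depth_index", "date", "split"],
        )
        points = pd.DataFrame(
            doc.get("points", []),
            columns=["image_id", "root_id", "point_index", "x_px", "y_px"],
        )
    else:
        raise AnnotationError(f"no annotation index at {path}")
    base = path if path.is_dir() else path.parent
    return _build_index(images, points, cameras, base_dir=str(base))


# ---------------------------------------------------------------------------
# dataset splitting


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer split sizes summing exactly to ``n`` (largest-remainder rounding)."""
    quotas = [n * f for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (quotas[i] - counts[i], -i), reverse=True
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def split_dataset(
    index: DatasetIndex,
    fractions: Sequence[float] = (0.73, 0.09, 0.18),
    seed: int = 0,
) -> DatasetIndex:
    """Randomly partition the images into train/val/test splits.

    ``fractions`` are the (train, val, test) shares — the study protocols are
    73/9/18 for the manual-camera corpus and 72/10/18 for the automated one.
    Sizes follow largest-remainder rounding so they sum exactly to ``len(index)``;
    the assignment is a seeded permutation, identical for identical seeds.
    """
    if len(fractions) != len(SPLITS):
        raise ConfigurationError("fractions must be (train, val, test)")
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-6:
        raise ConfigurationError(f"split fractions must sum to 1, got {tuple(fractions)}")
    n = len(index)
    counts = _largest_remainder_counts(n, fractions)
    order = np.random.default_rng(seed).permutation(n)
    labels: list[str | None] = [None] * n
    pos = 0
    for split, c in zip(SPLITS, counts):
        for i in order[pos : pos + c]:
            labels[int(i)] = split
        pos += c
    return DatasetIndex(
        [replace(rec, split=labels[i]) for i, rec in enumerate(index.records)]
    )


def concat_indices(indices: Iterable[DatasetIndex]) -> DatasetIndex:
    """Concatenate several indices into one (records are shared, not copied)."""
    out: list[IndexRecord] = []
    for idx in indices:
        out.extend(idx.records)
    return DatasetIndex(out)
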