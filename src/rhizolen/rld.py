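"""Root length density (RLD) profiles over depth and time.

RLD expresses the per-image total root length per unit imaged area, in
cm/cm²: ``RLD = (TRL/10) / (fov_w_cm * fov_h_cm)`` for the camera's nominal
observation window.  Profiles are rows of (tube, date, depth) with depth in
mm derived from the image's depth index and the camera's depth step; GT and
model-estimate profiles share keys so they can be joined for side-by-side
comparison plots.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_io import CameraProfile, ConfigurationError, DatasetIndex

__all__ = ["compute_rld", "profile", "paired_profile", "plot_profiles"]


def compute_rld(trl_mm: float, cam: CameraProfile) -> float:
    """TRL (mm) in one frame -> RLD in cm per cm² of the nominal window."""
    if trl_mm < 0:
        raise ConfigurationError("TRL must be >= 0")
    fov_w_cm = cam.fov_mm[0] / 10.0
    fov_h_cm = cam.fov_mm[1] / 10.0
    return (trl_mm / 10.0) / (fov_w_cm * fov_h_cm)


def _depth_mm(depth_index: int, cam: CameraProfile, top_offset_mm: float) -> float:
    return top_offset_mm + depth_index * cam.depth_step_mm


def profile(
    index: DatasetIndex,
    predictions: Mapping[str, float] | pd.DataFrame | None = None,
    source: str = "gt",
    top_offset_mm: float = 0.0,
) -> pd.DataFrame:
    """Build an RLD profile table: one row per (tube_id, date, depth_mm).

    ``source="gt"`` uses annotated TRLs; ``source="model"`` reads per-image
    estimates from ``predictions`` (a mapping or a DataFrame with columns
    ``image_id, trl_mm_est``).  Every record must carry tube/depth metadata.
    """
    if source not in ("gt", "model"):
        raise ConfigurationError(f"unknown profile source {source!r}")
    est: dict[str, float] = {}
    if source == "model":
        if predictions is None:
            raise ConfigurationError("source='model' requires predictions")
        if isinstance(predictions, pd.DataFrame):
            est = dict(zip(predictions["image_id"].astype(str),
                           predictions["trl_mm_est"].astype(float)))
        else:
            est = {str(k): float(v) for k, v in predictions.items()}

    rows = []
    for rec in index:
        ann = rec.annotation
        if ann.tube_id is None or ann.depth_index is None:
            raise ConfigurationError(
                f"image {ann.image_id!r} lacks tube/depth metadata required for RLD"
            )
        if source == "gt":
            trl = ann.trl_mm
        else:
            if ann.image_id not in est:
                raise ConfigurationError(f"no prediction for image {ann.image_id!r}")
            trl = max(est[ann.image_id], 0.0)
        rows.append(
            {
                "tube_id": ann.tube_id,
                "date": ann.date if ann.date is not None else "",
                "depth_mm": _depth_mm(ann.depth_index, ann.camera, top_offset_mm),
                "trl_mm": trl,
                "rld": compute_rld(trl, ann.camera),
            }
        )
    df = pd.DataFrame(rows, columns=["tube_id", "date", "depth_mm", "trl_mm", "rld"])
    out = (
        df.groupby(["tube_id", "date", "depth_mm"], as_index=False)[["trl_mm", "rld"]]
        .sum()
        .sort_values(["tube_id", "date", "depth_mm"], kind="mergesort")
        .reset_index(drop=True)
    )
    out["source"] = source
    return out


def paired_profile(
    index: DatasetIndex,
    predictions: Mapping[str, float] | pd.DataFrame,
    top_offset_mm: float = 0.0,
) -> pd.DataFrame:
    """GT and model profiles joined on (tube_id, date, depth_mm)."""
    gt = profile(index, source="gt", top_offset_mm=top_offset_mm)
    md = profile(index, predictions=predictions, source="model",
                 top_offset_mm=top_offset_mm)
    keys = ["tube_id", "date", "depth_mm"]
    merged = gt.merge(md, on=keys, suffixes=("_gt", "_model"))
    return merged[keys + ["rld_gt", "rld_model"]]


def plot_profiles(paired: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write one depth-profile PNG per (tube, date), GT vs model side by side."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (tube, date), grp in paired.groupby(["tube_id", "date"]):
        grp = grp.sort_values("depth_mm")
        fig, ax = plt.subplots(figsize=(4, 5))
        ax.plot(grp["rld_gt"], grp["depth_mm"], "r-o", label="manual annotation")
        ax.plot(grp["rld_model"], grp["depth_mm"], "b-s", label="model estimate")
        ax.invert_yaxis()
        ax.set_xlabel("RLD (cm/cm²)")
        ax.set_ylabel("depth (mm)")
        ax.set_title(f"{tube} {date}".strip())
        ax.legend()
        fig.tight_layout()
        path = out_dir / f"rld_{tube}_{date or 'nodate'}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
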