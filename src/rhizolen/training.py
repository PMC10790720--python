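"""Training, model selection and fine-tuning for the TRL estimators.

The loss is ``w_h * MSE(predicted heatmap, Gaussian GT heatmap) + w_t *
smooth-L1(TRL)`` — the heatmap term exists only for the points model.  After
every epoch the mean relative deviation (MRD) on the validation set is
recorded, computed over root-bearing images only, and the checkpoint returned
is the best-epoch snapshot (minimum validation MRD, earliest epoch on ties).

Augmentation is restricted to horizontal/vertical flips: flips preserve root
length, whereas any scaling augmentation would corrupt the mm label.
Everything (data order, initialization via the model config, augmentation)
is driven by seeded generators, so identical seeds reproduce identical runs.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._nn import DTYPE, Adam
from .annotation_io import ConfigurationError, DatasetIndex, concat_indices
from .evaluation import abs_delta_rl, mrd
from .heatmap import render_points_map
from .models import ModelConfig, load_image_gray, preprocess_image

log = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainLog", "train", "train_joint", "finetune", "predict_index"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    The full study protocol trains for 300 epochs; smaller desk-scale runs
    simply pass a smaller ``epochs``.  ``weight_heatmap`` is ignored by the
    regression model.  ``smooth_l1_beta`` is in units of the model's
    ``output_scale_mm`` (beta = 1 means the loss turns linear one output
    scale away from the target).
    """

    epochs: int = 300
    batch_size: int = 8
    lr: float = 3e-3
    weight_heatmap: float = 1.0
    weight_trl: float = 1.0
    smooth_l1_beta: float = 1.0
    augment: bool = True
    heatmap_mode: str = "max"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.weight_heatmap < 0 or self.weight_trl < 0:
            raise ConfigurationError("loss weights must be >= 0")
        if self.weight_heatmap == 0 and self.weight_trl == 0:
            raise ConfigurationError("at least one loss weight must be > 0")


@dataclass
class TrainLog:
    """Per-epoch train losses and validation metrics."""

    rows: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["epoch", "train_loss", "val_mrd"])

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def best_val_mrd(self) -> float:
        return self.rows[self.best_epoch]["val_mrd"]


@dataclass
class _Arrays:
    """Pre-loaded training tensors for one dataset split."""

    x: np.ndarray            # (N, 1, H, W) standardized frames
    y: np.ndarray            # (N,) GT TRL in mm
    maps: np.ndarray | None  # (N, mh, mw) GT heatmaps (points kind only)
    ids: list[str]


def _load_arrays(index: DatasetIndex, cfg: ModelConfig, want_maps: bool,
                 mode: str = "max") -> _Arrays:
    if len(index) == 0:
        raise ConfigurationError("dataset split is empty")
    xs, ys, maps, ids = [], [], [], []
    mw, mh = cfg.map_size
    for rec in index:
        ann = rec.annotation
        img = load_image_gray(rec.resolve_path())
        xs.append(preprocess_image(img, cfg.in_size))
        ys.append(ann.trl_mm)
        ids.append(ann.image_id)
        if want_maps:
            w0, h0 = ann.camera.image_size_px
            pts = ann.all_points()
            pts = pts * np.array([mw / w0, mh / h0])
            maps.append(
                render_points_map(pts, (mh, mw), cfg.sigma_px, mode=mode).astype(DTYPE)
            )
    return _Arrays(
        x=np.stack(xs).astype(DTYPE),
        y=np.array(ys, dtype=np.float64),
        maps=np.stack(maps) if want_maps else None,
        ids=ids,
    )


def _forward_trl(model, x: np.ndarray, batch: int = 32) -> np.ndarray:
    out = []
    for i in range(0, len(x), batch):
        out.append(model.forward(x[i : i + batch])["trl"])
    return np.concatenate(out).astype(np.float64)


def predict_index(model, index: DatasetIndex) -> pd.DataFrame:
    """Run the model over every record; returns ``image_id, trl_mm, trl_mm_est``."""
    arrays = _load_arrays(index, model.config, want_maps=False)
    est = _forward_trl(model, arrays.x)
    return pd.DataFrame(
        {"image_id": arrays.ids, "trl_mm": arrays.y, "trl_mm_est": est}
    )


def _val_metric(model, val: _Arrays) -> float:
    est = _forward_trl(model, val.x)
    if np.any(val.y > 0):
        return mrd(val.y, est)
    # degenerate validation set with no root-bearing images: fall back to the
    # mean absolute error so selection is still defined
    return abs_delta_rl(val.y, est)


def _smooth_l1_and_grad(pred_mm, y_mm, scale, beta):
    u = (pred_mm - y_mm) / scale
    a = np.abs(u)
    loss = np.where(a < beta, 0.5 * u * u, beta * (a - 0.5 * beta))
    dpred = np.clip(u, -beta, beta) / scale
    return float(loss.mean()), dpred / len(u)


def _run_epochs(model, tr: _Arrays, val: _Arrays, config: TrainConfig,
                rng: np.random.Generator) -> TrainLog:
    is_points = model.kind == "points"
    opt = Adam(model.params(), lr=config.lr)
    scale = model.config.output_scale_mm
    n = len(tr.x)
    logbook = TrainLog()
    best_state, best_mrd = None, np.inf
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = tr.x[idx]
            yb = tr.y[idx]
            mb = tr.maps[idx] if is_points and tr.maps is not None else None
            if config.augment:
                flips = rng.integers(0, 2, size=2)
                if flips[0]:
                    xb = xb[:, :, :, ::-1]
                    mb = mb[:, :, ::-1] if mb is not None else None
                if flips[1]:
                    xb = xb[:, :, ::-1, :]
                    mb = mb[:, ::-1, :] if mb is not None else None
                xb = np.ascontiguousarray(xb)
                mb = np.ascontiguousarray(mb) if mb is not None else None
            out = model.forward(xb)
            loss_t, dtrl = _smooth_l1_and_grad(out["trl"], yb, scale, config.smooth_l1_beta)
            loss = config.weight_trl * loss_t
            dtrl = config.weight_trl * dtrl
            dheat = None
            if is_points and config.weight_heatmap > 0 and mb is not None:
                diff = out["heatmap"] - mb
                loss += config.weight_heatmap * float((diff * diff).mean())
                dheat = (config.weight_heatmap * 2.0 / diff.size) * diff
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; lower the learning rate "
                    f"or check the input data"
                )
            opt.zero_grad()
            model.backward(dtrl.astype(DTYPE), dheat.astype(DTYPE) if dheat is not None else None)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_mrd = _val_metric(model, val)
        logbook.rows.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_mrd": val_mrd}
        )
        if val_mrd < best_mrd:  # strict: earliest epoch wins ties
            best_mrd = val_mrd
            best_state = model.state_dict()
            logbook.best_epoch = epoch
        log.info("epoch %d: train_loss=%.5f val_mrd=%.4f", epoch,
                 epoch_loss / n_batches, val_mrd)
    model.load_state_dict(best_state)
    return logbook


def train(model, train_index: DatasetIndex, val_index: DatasetIndex,
          config: TrainConfig) -> tuple[object, TrainLog]:
    """Train ``model`` and return it loaded with the best-epoch weights.

    Model selection follows the study protocol: the epoch minimizing the
    validation MRD (over images with roots) is kept.
    """
    if len(train_index) == 0:
        raise ConfigurationError("training set is empty")
    train_ids = set(train_index.image_ids())
    if train_ids & set(val_index.image_ids()):
        raise ConfigurationError("train and validation sets overlap")
    is_points = model.kind == "points"
    tr = _load_arrays(train_index, model.config, want_maps=is_points,
                      mode=config.heatmap_mode)
    val = _load_arrays(val_index, model.config, want_maps=False)
    model.init_output_bias(float(tr.y.mean()))
    rng = np.random.default_rng(config.seed)
    logbook = _run_epochs(model, tr, val, config, rng)
    return model, logbook


def train_joint(model, train_indices: Sequence[DatasetIndex],
                val_indices: Sequence[DatasetIndex],
                config: TrainConfig) -> tuple[object, TrainLog]:
    """Train on the concatenation of several datasets (e.g. manual + automated).

    Frames are resized to the common model input; each image's mm label comes
    from its own camera pitch, so mixing acquisition systems is safe.
    """
    return train(model, concat_indices(train_indices), concat_indices(val_indices), config)


def finetune(model, extra_index: DatasetIndex, k: int, val_index: DatasetIndex,
             config: TrainConfig, rng: np.random.Generator | None = None
             ) -> tuple[object, TrainLog]:
    """Continue training a model on ``k`` root-bearing images from a new dataset.

    Emulates the transfer-learning protocol: the entire network is fine-tuned
    (no frozen layers) on a small sample of annotated images from the target
    acquisition system; only images with roots are eligible.  ``k = 0``
    returns an unchanged copy of the model.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = copy.deepcopy(model)
    if k == 0:
        return model, TrainLog()
    rooted = [rec for rec in extra_index if rec.annotation.trl_mm > 0]
    if k > len(rooted):
        raise ConfigurationError(
            f"requested k={k} fine-tuning images but only {len(rooted)} "
            f"root-bearing images are available"
        )
    chosen = [rooted[i] for i in rng.choice(len(rooted), size=k, replace=False)]
    sub = DatasetIndex(list(chosen))
    tr = _load_arrays(sub, model.config, want_maps=model.kind == "points",
                      mode=config.heatmap_mode)
    val = _load_arrays(val_index, model.config, want_maps=False)
    logbook = _run_epochs(model, tr, val, config, rng)
    return model, logbook
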