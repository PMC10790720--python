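"""The two segmentation-free TRL estimators.

Both architectures map a grayscale MR frame to a scalar total root length in
mm.  The *regression* model is a multiple-scale direct regressor: a strided
convolutional encoder whose per-stage globally pooled features feed a small
fully connected head.  The *points* (detection + regression, D+R) model adds
a decoder branch that emits a sigmoid point-density heatmap at map scale; the
scalar head reads the pooled encoder features together with the predicted
heatmap, so the length estimate is driven by the detected root points.  The
scalar output passes through a softplus, enforcing TRL >= 0 by construction.

Networks are built on the in-repo NumPy engine (:mod:`rhizolen._nn`) and are
deliberately compact so that full training runs complete on one CPU core.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import _nn
from ._nn import Conv2d, Linear, ReLU, UpsampleNearest2
from .annotation_io import ConfigurationError
from .heatmap import DensityMap

__all__ = [
    "ModelConfig",
    "RegressionNet",
    "PointsNet",
    "build_model",
    "predict_trl",
    "load_image_gray",
    "preprocess_image",
    "save_checkpoint",
    "load_checkpoint",
]

MODEL_KINDS = ("regression", "points")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters shared by both estimators.

    ``in_size`` is the (width, height) every frame is resized to before the
    forward pass; mm labels always come from the original camera pitch, so
    resizing never corrupts the target.  ``map_scale`` fixes the heatmap grid
    at ``floor(in_size * map_scale)``; ``sigma_px`` is the Gaussian std of the
    supervision bumps in map pixels.  ``output_scale_mm`` is the unit of the
    softplus head (the head works in units of this scale, keeping optimizer
    dynamics independent of the mm magnitude of the labels).
    """

    in_size: tuple[int, int] = (144, 96)
    channels: tuple[int, int, int] = (12, 24, 32)
    decoder_channels: int = 16
    head_hidden: int = 32
    map_scale: float = 0.25
    sigma_px: float = 2.0
    output_scale_mm: float = 10.0
    init_seed: int = 0

    @property
    def map_size(self) -> tuple[int, int]:
        """(width, height) of the heatmap grid."""
        return (
            int(math.floor(self.in_size[0] * self.map_scale)),
            int(math.floor(self.in_size[1] * self.map_scale)),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        allowed = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - allowed
        if unknown:
            raise ConfigurationError(f"unknown model config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("in_size", "channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class _Encoder:
    """Three strided stages; returns per-stage activations for multi-scale pooling."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c0, c1, c2 = cfg.channels
        self.conv0 = Conv2d(1, c0, k=5, stride=2, rng=rng, name="enc0")
        self.conv1 = Conv2d(c0, c1, k=3, stride=2, rng=rng, name="enc1")
        self.conv2 = Conv2d(c1, c2, k=3, stride=2, rng=rng, name="enc2")
        self.r0, self.r1, self.r2 = ReLU(), ReLU(), ReLU()

    def params(self):
        return self.conv0.params() + self.conv1.params() + self.conv2.params()

    def forward(self, x):
        f0 = self.r0.forward(self.conv0.forward(x))
        f1 = self.r1.forward(self.conv1.forward(f0))
        f2 = self.r2.forward(self.conv2.forward(f1))
        return f0, f1, f2

    def backward(self, df0_extra, df1_extra, df2):
        df1 = self.conv2.backward(self.r2.backward(df2))
        if df1_extra is not None:
            df1 = df1 + df1_extra
        df0 = self.conv1.backward(self.r1.backward(df1))
        if df0_extra is not None:
            df0 = df0 + df0_extra
        return self.conv0.backward(self.r0.backward(df0))


class _BaseNet:
    kind: str = ""

    def __init__(self, config: ModelConfig):
        self.config = config
        self._params: list[_nn.Param] = []

    def params(self) -> list[_nn.Param]:
        return self._params

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self._params))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self._params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self._params:
            if p.name not in state:
                raise ConfigurationError(f"checkpoint is missing parameter {p.name!r}")
            if state[p.name].shape != p.value.shape:
                raise ConfigurationError(f"shape mismatch for parameter {p.name!r}")
            p.value = state[p.name].astype(_nn.DTYPE).copy()
            p.grad = np.zeros_like(p.value)

    def init_output_bias(self, mean_trl_mm: float) -> None:
        """Initialize the softplus head bias at the training-set mean TRL."""
        self.head_out.b.value[...] = _nn.softplus_inverse(
            mean_trl_mm / self.config.output_scale_mm
        )

    def _head_forward(self, feats: np.ndarray):
        h = self.head_relu.forward(self.head_fc.forward(feats))
        z = self.head_out.forward(h)[:, 0]
        trl = _nn.softplus(z) * self.config.output_scale_mm
        self._z = z
        return trl

    def _head_backward(self, dtrl: np.ndarray) -> np.ndarray:
        dz = dtrl * _nn.sigmoid(self._z) * self.config.output_scale_mm
        dh = self.head_out.backward(dz[:, None].astype(_nn.DTYPE))
        return self.head_fc.backward(self.head_relu.backward(dh))


class RegressionNet(_BaseNet):
    """Direct multiple-scale image -> TRL regressor."""

    kind = "regression"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.init_seed)
        self.enc = _Encoder(config, rng)
        feat = sum(config.channels)
        self.head_fc = Linear(feat, config.head_hidden, rng=rng, name="head_fc")
        self.head_relu = ReLU()
        self.head_out = Linear(config.head_hidden, 1, rng=rng, name="head_out")
        self._params = self.enc.params() + self.head_fc.params() + self.head_out.params()

    def forward(self, x: np.ndarray) -> dict:
        f0, f1, f2 = self.enc.forward(x)
        g = np.concatenate(
            [_nn.global_avg_pool(f0), _nn.global_avg_pool(f1), _nn.global_avg_pool(f2)],
            axis=1,
        )
        trl = self._head_forward(g)
        self._shapes = (f0.shape, f1.shape, f2.shape)
        return {"trl": trl, "heatmap": None}

    def backward(self, dtrl: np.ndarray, dheatmap=None) -> None:
        dg = self._head_backward(dtrl)
        s0, s1, s2 = self._shapes
        c0, c1, _ = self.config.channels
        dg0, dg1, dg2 = dg[:, :c0], dg[:, c0 : c0 + c1], dg[:, c0 + c1 :]
        self.enc.backward(
            _nn.global_avg_pool_backward(dg0, s0),
            _nn.global_avg_pool_backward(dg1, s1),
            _nn.global_avg_pool_backward(dg2, s2),
        )


class PointsNet(_BaseNet):
    """Detection + regression estimator: heatmap branch feeding the scalar head."""

    kind = "points"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = np.random.default_rng(config.init_seed)
        self.enc = _Encoder(config, rng)
        c2 = config.channels[2]
        dc = config.decoder_channels
        self.up = UpsampleNearest2()
        self.dec1 = Conv2d(c2, dc, k=3, stride=1, rng=rng, name="dec1")
        self.dec_relu = ReLU()
        self.dec2 = Conv2d(dc, 1, k=1, stride=1, pad=0, rng=rng, name="dec2")
        feat = sum(config.channels) + 1  # pooled stages + mean of predicted heatmap
        self.head_fc = Linear(feat, config.head_hidden, rng=rng, name="head_fc")
        self.head_relu = ReLU()
        self.head_out = Linear(config.head_hidden, 1, rng=rng, name="head_out")
        self._params = (
            self.enc.params()
            + self.dec1.params()
            + self.dec2.params()
            + self.head_fc.params()
            + self.head_out.params()
        )

    def forward(self, x: np.ndarray) -> dict:
        f0, f1, f2 = self.enc.forward(x)
        d = self.dec_relu.forward(self.dec1.forward(self.up.forward(f2)))
        logits_full = self.dec2.forward(d)
        mw, mh = self.config.map_size
        logits = logits_full[:, :, :mh, :mw]
        hm = _nn.sigmoid(logits)
        g = np.concatenate(
            [
                _nn.global_avg_pool(f0),
                _nn.global_avg_pool(f1),
                _nn.global_avg_pool(f2),
                hm.mean(axis=(1, 2, 3))[:, None],
            ],
            axis=1,
        )
        trl = self._head_forward(g)
        self._cache = (f0.shape, f1.shape, f2.shape, logits_full.shape, hm)
        return {"trl": trl, "heatmap": hm[:, 0]}

    def backward(self, dtrl: np.ndarray, dheatmap: np.ndarray | None = None) -> None:
        s0, s1, s2, full_shape, hm = self._cache
        dg = self._head_backward(dtrl)
        c0, c1, c2 = self.config.channels
        dg0 = dg[:, :c0]
        dg1 = dg[:, c0 : c0 + c1]
        dg2 = dg[:, c0 + c1 : c0 + c1 + c2]
        dmean = dg[:, -1]
        dhm = np.zeros_like(hm)
        dhm += (dmean / hm[0].size)[:, None, None, None]
        if dheatmap is not None:
            dhm += dheatmap[:, None, :, :]
        dlogits = (dhm * hm * (1.0 - hm)).astype(_nn.DTYPE)
        dlogits_full = np.zeros(full_shape, dtype=_nn.DTYPE)
        mw, mh = self.config.map_size
        dlogits_full[:, :, :mh, :mw] = dlogits
        dd = self.dec2.backward(dlogits_full)
        df2_dec = self.up.backward(self.dec1.backward(self.dec_relu.backward(dd)))
        df2 = _nn.global_avg_pool_backward(dg2, s2) + df2_dec
        self.enc.backward(
            _nn.global_avg_pool_backward(dg0, s0),
            _nn.global_avg_pool_backward(dg1, s1),
            df2,
        )


def build_model(kind: str, config: ModelConfig | dict | None = None):
    """Construct a freshly initialized estimator of the given kind.

    Initialization is deterministic in ``config.init_seed``: the same config
    yields bit-identical parameters.
    """
    if config is None:
        config = ModelConfig()
    elif isinstance(config, dict):
        config = ModelConfig.from_dict(config)
    if kind == "regression":
        return RegressionNet(config)
    if kind == "points":
        return PointsNet(config)
    raise ConfigurationError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


# ---------------------------------------------------------------------------
# image I/O and preprocessing


def load_image_gray(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as grayscale float32 in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float32)
    return arr / 255.0


def preprocess_image(img: np.ndarray, in_size: tuple[int, int]) -> np.ndarray:
    """Resize to the model input grid and standardize per image -> (1, H, W) float32."""
    img = np.asarray(img, dtype=np.float32)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.5:  # uint8-range content
        img = img / 255.0
    w, h = in_size
    if img.shape != (h, w):
        pil = Image.fromarray(img, mode="F")
        img = np.asarray(pil.resize((w, h), Image.BILINEAR), dtype=np.float32)
    mu, sd = float(img.mean()), float(img.std())
    return ((img - mu) / (sd + 1e-6))[None, :, :].astype(np.float32)


def predict_trl(model, image, resize: bool = True):
    """Estimate TRL (mm) for one image (path or array).

    Returns the scalar for the regression kind, or ``(trl, DensityMap)`` for
    the points kind.  Raises if the frame does not match the model input size
    and resizing is disabled.
    """
    if isinstance(image, (str, Path)):
        image = load_image_gray(image)
    w, h = model.config.in_size
    if not resize and image.shape[:2] != (h, w):
        raise ConfigurationError(
            f"image size {image.shape[1]}x{image.shape[0]} does not match model "
            f"input {w}x{h} and resizing is disabled"
        )
    x = preprocess_image(image, model.config.in_size)[None]
    out = model.forward(x)
    trl = float(out["trl"][0])
    if model.kind == "points":
        dmap = DensityMap(
            grid=out["heatmap"][0].astype(float),
            sigma_px=model.config.sigma_px,
            scale=model.config.map_scale,
        )
        return trl, dmap
    return trl


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model, path: str | Path, meta: dict | None = None) -> None:
    """Serialize kind, config, parameters and metadata to an ``.npz`` file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"kind": model.kind, "config": model.config.to_dict(), "meta": meta or {}}
    buf = io.BytesIO()
    np.savez(
        buf,
        __header__=np.frombuffer(json.dumps(header, sort_keys=True).encode(), dtype=np.uint8),
        **model.state_dict(),
    )
    path.write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path):
    """Load a checkpoint; returns ``(model, meta)``."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        state = {k: z[k] for k in z.files if k != "__header__"}
    model = build_model(header["kind"], ModelConfig.from_dict(header["config"]))
    model.load_state_dict(state)
    return model, header.get("meta", {})
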