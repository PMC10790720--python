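"""Evaluation metrics for TRL estimation and the root/no-root classifier.

For ground-truth lengths ``y_i`` (mm) and estimates ``yhat_i`` over ``n``
images the suite comprises:

* ``|dRL|``   — mean absolute difference, ``(1/n) sum |y_i - yhat_i|`` (mm);
* ``MRD``     — mean relative deviation ``(1/n') sum |y_i - yhat_i| / y_i``
  over the ``n'`` images with roots (``y_i > 0`` only — relative error is
  undefined on empty frames);
* ``NRMSE``   — root mean square error normalized by the GT range
  ``y_max - y_min``;
* ``1 - FVU`` — fraction of explained variance, ``1 - SSE / SST``, i.e. the
  model against the trivial constant-mean estimator;
* ``R^2``     — squared Pearson correlation between ``y`` and ``yhat``.

``R^2`` and ``1 - FVU`` are distinct statistics (they coincide only for a
least-squares-calibrated predictor) and are reported separately.

The binary classifier labels a frame "no roots" when the model's TRL
estimate falls strictly below a threshold chosen as the 80th percentile of
the estimates on the zero-GT validation images; below-threshold frames get a
reported TRL of 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_io import ConfigurationError

__all__ = [
    "UndefinedMetricError",
    "EvalReport",
    "RootPresenceThreshold",
    "abs_delta_rl",
    "mrd",
    "nrmse",
    "explained_fraction",
    "r_squared",
    "evaluate",
    "select_threshold",
    "classify_image",
    "classification_error",
]


class UndefinedMetricError(ValueError):
    """The metric's precondition does not hold for this pair set."""


def _pairs(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise UndefinedMetricError("empty pair set")
    if y.shape != yhat.shape:
        raise UndefinedMetricError("y and yhat differ in length")
    if np.any(y < 0) or np.any(yhat < 0):
        raise UndefinedMetricError("TRL values must be non-negative")
    return y, yhat


def abs_delta_rl(y, yhat) -> float:
    """Mean absolute difference |dRL| in mm."""
    y, yhat = _pairs(y, yhat)
    return float(np.abs(y - yhat).mean())


def mrd(y, yhat) -> float:
    """Mean relative deviation over root-bearing images (y > 0), as a fraction."""
    y, yhat = _pairs(y, yhat)
    mask = y > 0
    if not mask.any():
        raise UndefinedMetricError("MRD needs at least one image with roots (y > 0)")
    return float((np.abs(y[mask] - yhat[mask]) / y[mask]).mean())


def nrmse(y, yhat) -> float:
    """RMSE normalized by the ground-truth range of the evaluated set."""
    y, yhat = _pairs(y, yhat)
    spread = y.max() - y.min()
    if spread <= 0:
        raise UndefinedMetricError("NRMSE is undefined when all GT values are equal")
    return float(np.sqrt(np.mean((y - yhat) ** 2)) / spread)


def explained_fraction(y, yhat) -> float:
    """1 - FVU: one minus SSE over the variance around the GT mean (<= 1)."""
    y, yhat = _pairs(y, yhat)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0:
        raise UndefinedMetricError("1 - FVU is undefined when all GT values are equal")
    return 1.0 - float(((y - yhat) ** 2).sum()) / sst


def r_squared(y, yhat) -> float:
    """Squared Pearson correlation between GT and estimated TRL."""
    y, yhat = _pairs(y, yhat)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise UndefinedMetricError("R^2 is undefined when either variable is constant")
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class EvalReport:
    """The five-metric report over one (GT, estimate) pair set.

    Metrics whose preconditions fail (e.g. MRD on a set with no root-bearing
    images) are reported as NaN; the individual metric functions raise instead.
    """

    abs_delta_rl_mm: float
    mrd: float
    nrmse: float
    r_squared: float
    explained_fraction: float
    n: int
    n_with_roots: int

    def to_dict(self) -> dict:
        return {
            "abs_delta_rl_mm": self.abs_delta_rl_mm,
            "mrd": self.mrd,
            "nrmse": self.nrmse,
            "r_squared": self.r_squared,
            "explained_fraction": self.explained_fraction,
            "n": self.n,
            "n_with_roots": self.n_with_roots,
        }


def evaluate(y, yhat) -> EvalReport:
    """Compute the full metric suite, NaN-filling metrics that are undefined."""
    y, yhat = _pairs(y, yhat)

    def _try(fn):
        try:
            return fn(y, yhat)
        except UndefinedMetricError:
            return float("nan")

    return EvalReport(
        abs_delta_rl_mm=abs_delta_rl(y, yhat),
        mrd=_try(mrd),
        nrmse=_try(nrmse),
        r_squared=_try(r_squared),
        explained_fraction=_try(explained_fraction),
        n=int(y.size),
        n_with_roots=int((y > 0).sum()),
    )


# ---------------------------------------------------------------------------
# binary root-presence classification


@dataclass(frozen=True)
class RootPresenceThreshold:
    """TRL threshold below which a frame is declared root-free."""

    threshold_mm: float
    source_percentile: float
    source_model_kind: str | None = None

    def __post_init__(self) -> None:
        if self.threshold_mm < 0:
            raise ConfigurationError("threshold must be >= 0")


def select_threshold(
    y_val,
    yhat_val,
    percentile: float = 80.0,
    model_kind: str | None = None,
    min_empty: int = 5,
) -> RootPresenceThreshold:
    """Pick the classification threshold from the validation set.

    The threshold is the empirical ``percentile`` of the model's TRL
    estimates on the zero-GT validation images, with linear interpolation
    between order statistics in the exclusive (n+1) convention (the
    ``weibull`` method): for estimates (0, 0, 0, 0, 1) the 80th percentile
    is 0.8.
    """
    y_val, yhat_val = _pairs(y_val, yhat_val)
    empty = yhat_val[y_val == 0]
    if empty.size < min_empty:
        raise ConfigurationError(
            f"threshold selection needs >= {min_empty} zero-GT validation images, "
            f"got {empty.size}"
        )
    thr = float(np.percentile(empty, percentile, method="weibull"))
    return RootPresenceThreshold(
        threshold_mm=thr, source_percentile=percentile, source_model_kind=model_kind
    )


def classify_image(
    estimate_mm: float, threshold: RootPresenceThreshold | float
) -> tuple[str, float]:
    """Classify one frame; returns ``(label, reported_trl_mm)``.

    The label is "no_roots" iff the estimate is strictly below the threshold
    (an estimate equal to the threshold counts as "has_roots"), and a
    "no_roots" frame gets a reported TRL of 0.
    """
    thr = threshold.threshold_mm if isinstance(threshold, RootPresenceThreshold) else float(threshold)
    if thr < 0:
        raise ConfigurationError("threshold must be >= 0")
    if estimate_mm < thr:
        return "no_roots", 0.0
    return "has_roots", float(estimate_mm)


def classification_error(y, yhat, threshold: RootPresenceThreshold | float) -> float:
    """Misclassification rate of the root/no-root decision over a labeled set."""
    y, yhat = _pairs(y, yhat)
    pred_has = np.array([classify_image(v, threshold)[0] == "has_roots" for v in yhat])
    true_has = y > 0
    return float((pred_has != true_has).mean())
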