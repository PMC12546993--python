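"""One-step and recursive multi-step forecasting.

Forecasts take a recent original-scale window of W time steps per taxon,
standardize it with the model's stored parameters, rebuild the change
stream, run the forward pass and invert the transform. Multi-step
forecasts are produced recursively: each predicted step is appended to the
window (dropping the oldest step) and the change stream is recomputed so
the appended delta stays the difference of consecutive window values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TrainedModel
from .preprocess import (
    StandardizationParams,
    apply_standardizer,
    invert_standardizer,
)
from .training import predict_batch

__all__ = [
    "ForecastResult",
    "predict_one_step",
    "predict_multi_step",
    "inverse_transform",
]


@dataclass
class ForecastResult:
    """Predictions for H future steps on both scales."""

    horizon: int
    taxon_ids: list[str]
    standardized: np.ndarray  # (D, H)
    original: np.ndarray  # (D, H)
    origin_time: int | None = None
    variant: str = "fusion"

    def __post_init__(self) -> None:
        self.standardized = np.asarray(self.standardized, dtype=float)
        self.original = np.asarray(self.original, dtype=float)
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.standardized.shape != (len(self.taxon_ids), self.horizon):
            raise ValueError("standardized predictions have the wrong shape")
        if self.original.shape != self.standardized.shape:
            raise ValueError("original/standardized shapes disagree")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, taxon in enumerate(self.taxon_ids):
            for h in range(self.horizon):
                rows.append(
                    {
                        "taxon": taxon,
                        "origin_time": self.origin_time,
                        "step": h + 1,
                        "predicted_standardized": self.standardized[i, h],
                        "predicted_original": self.original[i, h],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def inverse_transform(
    standardized: np.ndarray, params: StandardizationParams
) -> np.ndarray:
    """Map standardized values back to the original scale, x * sd + mean."""
    return invert_standardizer(standardized, params)


def _check_window(trained: TrainedModel, window: np.ndarray) -> np.ndarray:
    window = np.asarray(window, dtype=float)
    cfg = trained.config
    d = len(trained.standardizer.taxon_ids)
    if window.ndim != 2 or window.shape[0] != d:
        raise ValueError(
            f"window must be ({d}, W) matching the trained taxa, "
            f"got {window.shape}"
        )
    if window.shape[1] != cfg.window:
        raise ValueError(
            f"window length {window.shape[1]} != model window {cfg.window}"
        )
    return window


def _one_step_standardized(
    trained: TrainedModel, std_window: np.ndarray
) -> np.ndarray:
    """Predict the next standardized step (D,) from a standardized window."""
    pred = predict_batch(
        trained.model, std_window[None, :, :], trained.a_hat
    )
    return pred[0, :, 0]


def predict_one_step(
    trained: TrainedModel,
    recent_window: np.ndarray,
    origin_time: int | None = None,
) -> ForecastResult:
    """Forecast the next time step from an original-scale (D, W) window."""
    window = _check_window(trained, recent_window)
    std_window = apply_standardizer(window, trained.standardizer)
    std_pred = _one_step_standardized(trained, std_window)[:, None]
    return ForecastResult(
        horizon=1,
        taxon_ids=list(trained.standardizer.taxon_ids),
        standardized=std_pred,
        original=inverse_transform(std_pred, trained.standardizer),
        origin_time=origin_time,
        variant=trained.model.variant,
    )


def predict_multi_step(
    trained: TrainedModel,
    recent_window: np.ndarray,
    horizon: int,
    origin_time: int | None = None,
) -> ForecastResult:
    """Recursive H-step forecast (H = 1 coincides with predict_one_step).

    Each predicted standardized step is appended to the rolling window and
    the oldest step dropped; the change stream is recomputed from the
    updated window at every recursion, keeping the appended delta equal to
    the difference of consecutive window values.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    window = _check_window(trained, recent_window)
    std_window = apply_standardizer(window, trained.standardizer)
    preds = np.empty((window.shape[0], horizon))
    rolling = std_window.copy()
    for h in range(horizon):
        step = _one_step_standardized(trained, rolling)
        preds[:, h] = step
        rolling = np.concatenate([rolling[:, 1:], step[:, None]], axis=1)
    return ForecastResult(
        horizon=horizon,
        taxon_ids=list(trained.standardizer.taxon_ids),
        standardized=preds,
        original=inverse_transform(preds, trained.standardizer),
        origin_time=origin_time,
        variant=trained.model.variant,
    )
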