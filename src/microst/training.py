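"""Training with best-MAE checkpointing, metrics, and the ablation harness.

The loss is the mean absolute error itself (the model is selected and
reported on MAE, so optimizing a squared loss would mismatch selection).
Validation MAE is computed every epoch on the standardized scale and the
weights from the best epoch — not the last — are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Forecaster, ModelConfig, TrainedModel, build_variant
from .nn.autograd import Tensor
from .nn.optim import Adam
from .preprocess import SeriesTensor, StandardizationParams, invert_standardizer

__all__ = [
    "mae",
    "smape",
    "TrainingHistory",
    "train",
    "evaluate",
    "ablation_run",
    "window_change_stream",
]


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error, (1/m) * sum |y_i - yhat_i|."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must share a shape")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(y - yhat)))


def smape(y: np.ndarray, yhat: np.ndarray) -> float:
    """Symmetric mean absolute percentage error in [0, 200].

    Per-term |y - yhat| / ((|y| + |yhat|) / 2) * 100; terms with
    y = yhat = 0 contribute 0 (the 0/0 convention).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must share a shape")
    if y.size == 0:
        raise ValueError("empty input")
    denom = (np.abs(y) + np.abs(yhat)) / 2
    num = np.abs(y - yhat)
    terms = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    return float(np.mean(terms) * 100)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_mae: float = float("inf")
    seed: int | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "train_loss": self.train_loss,
                "val_mae": self.val_mae,
            }
        ).to_csv(path, sep="\t", index=False)


def window_change_stream(windows: np.ndarray) -> np.ndarray:
    """Per-window change stream: first differences, zero at position 0."""
    delta = np.zeros_like(windows)
    delta[:, :, 1:] = np.diff(windows, axis=2)
    return delta


def _forward_batch(model: Forecaster, batch: np.ndarray, a_hat: np.ndarray):
    change = window_change_stream(batch)
    if model.variant == "lstm":
        return model(batch)
    return model(batch, change, a_hat)


def predict_batch(
    model: Forecaster, windows: np.ndarray, a_hat: np.ndarray
) -> np.ndarray:
    """Standardized-scale predictions (B, N, H) without building gradients."""
    return _forward_batch(model, np.asarray(windows, dtype=float), a_hat).data


def train(
    variant: str,
    train_set: SeriesTensor,
    val_set: SeriesTensor,
    a_hat: np.ndarray,
    standardizer: StandardizationParams,
    config: ModelConfig | None = None,
    epochs: int = 100,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[TrainedModel, TrainingHistory]:
    """Train a variant with Adam on L1 loss; return best-epoch weights.

    Fully reproducible: the seed drives weight initialization and batch
    shuffling. Aborts with a diagnostic if the loss goes non-finite.
    """
    if train_set.n_windows == 0 or val_set.n_windows == 0:
        raise ValueError("train and validation sets must be non-empty")
    if config is None:
        config = ModelConfig(
            n_taxa=train_set.n_taxa,
            window=train_set.window,
            horizon=train_set.horizon,
        )
    config = replace(config, seed=seed)
    model = build_variant(variant, config)
    opt = Adam(model.parameters(), lr=lr)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(seed).spawn(1)[0]
    )
    history = TrainingHistory(seed=seed)
    best_state = model.state_dict()
    n = train_set.n_windows
    for epoch in range(epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = train_set.values[idx]
            target = train_set.horizon_targets[idx]
            pred = _forward_batch(model, batch, a_hat)
            loss = (pred - Tensor(target)).abs().mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (lr={lr}); aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * idx.size)
        history.train_loss.append(sum(losses) / n)
        val_pred = predict_batch(model, val_set.values, a_hat)
        val_mae = mae(val_set.horizon_targets, val_pred)
        history.val_mae.append(val_mae)
        if val_mae < history.best_val_mae:
            history.best_val_mae = val_mae
            history.best_epoch = epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    trained = TrainedModel(
        model=model, standardizer=standardizer, a_hat=np.asarray(a_hat, float)
    )
    return trained, history


def evaluate(
    trained: TrainedModel,
    dataset: SeriesTensor,
    original_scale: bool = True,
) -> dict:
    """MAE and sMAPE per horizon step and pooled.

    ``dataset`` must be on the standardized scale of the model's own
    standardizer; original-scale metrics invert that transform.
    """
    if dataset.scale != "standardized":
        raise ValueError("evaluate expects a standardized-scale dataset")
    if dataset.n_taxa != len(trained.standardizer.taxon_ids):
        raise ValueError("dataset taxa do not match the model's standardizer")
    pred = predict_batch(trained.model, dataset.values, trained.a_hat)
    target = dataset.horizon_targets
    h = dataset.horizon
    out: dict = {
        "mae_standardized": mae(target, pred),
        "smape_standardized": smape(target, pred),
        "per_horizon_mae_standardized": [
            mae(target[:, :, i], pred[:, :, i]) for i in range(h)
        ],
    }
    if original_scale:
        # invert per window: axis 1 is the taxa axis
        inv = trained.standardizer
        pred_o = np.stack(
            [invert_standardizer(p, inv) for p in pred]
        )
        target_o = np.stack([invert_standardizer(t, inv) for t in target])
        out["mae_original"] = mae(target_o, pred_o)
        out["smape_original"] = smape(target_o, pred_o)
        out["per_horizon_mae_original"] = [
            mae(target_o[:, :, i], pred_o[:, :, i]) for i in range(h)
        ]
    return out


def ablation_run(
    train_set: SeriesTensor,
    val_set: SeriesTensor,
    a_hat: np.ndarray,
    standardizer: StandardizationParams,
    seeds: list[int],
    config: ModelConfig | None = None,
    variants: tuple[str, ...] = ("fusion", "stgcn2s", "lstm"),
    dataset_name: str = "synthetic",
    **train_kwargs,
) -> pd.DataFrame:
    """Train every variant on identical splits per seed.

    Returns a tidy table (dataset, algorithm, seed, best_val_mae,
    best_epoch) plus per-variant mean/sd rows aggregated over seeds — the
    shape of a three-model ablation comparison.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    rows = []
    for seed in seeds:
        for variant in variants:
            _, history = train(
                variant,
                train_set,
                val_set,
                a_hat,
                standardizer,
                config=config,
                seed=seed,
                **train_kwargs,
            )
            rows.append(
                {
                    "dataset": dataset_name,
                    "algorithm": variant,
                    "seed": seed,
                    "best_val_mae": history.best_val_mae,
                    "best_epoch": history.best_epoch,
                }
            )
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variant mean and sd of best validation MAE over seeds."""
    return (
        table.groupby(["dataset", "algorithm"], sort=False)["best_val_mae"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mae_mean", "std": "mae_sd", "count": "n_seeds"})
    )
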