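"""Standardization, change stream, windowing and train/eval splitting.

Abundances are Z-scored per taxon with parameters fitted on training data
only; the "change stream" is the first difference between adjacent time
steps (zero-padded at t=0 so both streams share one shape); sliding windows
of width W with an H-step target form the 3-D series tensor fed to the
forecaster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import AbundanceTable

__all__ = [
    "StandardizationParams",
    "SeriesTensor",
    "drop_zero_features",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
    "make_change_stream",
    "make_windows",
    "split_series",
    "prepare_datasets",
]


@dataclass
class StandardizationParams:
    """Per-taxon Z-score parameters (population sd, zero sd mapped to 1)."""

    taxon_ids: list[str]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.taxon_ids) == self.means.size == self.sds.size):
            raise ValueError("taxon_ids, means and sds must align")
        if np.any(self.sds <= 0):
            raise ValueError("sds must be positive after degeneracy handling")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"taxon": self.taxon_ids, "mean": self.means, "sd": self.sds}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StandardizationParams":
        df = pd.read_csv(path, sep="\t")
        return cls(
            taxon_ids=df["taxon"].astype(str).tolist(),
            means=df["mean"].to_numpy(),
            sds=df["sd"].to_numpy(),
        )


@dataclass
class SeriesTensor:
    """Windowed series: values (N, D, W) with targets (N, D, H).

    ``scale`` records whether entries are standardized or original-scale.
    Window n covers time columns [start_n, start_n + W); its target covers
    the H columns immediately after, so targets never leak into inputs.
    """

    values: np.ndarray
    horizon_targets: np.ndarray
    scale: str = "standardized"
    window_starts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.horizon_targets = np.asarray(self.horizon_targets, dtype=float)
        if self.values.ndim != 3 or self.horizon_targets.ndim != 3:
            raise ValueError("values and targets must be 3-D (N, D, T/H)")
        if self.values.shape[:2] != self.horizon_targets.shape[:2]:
            raise ValueError("values/targets disagree on (N, D)")
        if self.values.shape[2] < 2:
            raise ValueError("window length must be at least 2")
        if not np.all(np.isfinite(self.values)) or not np.all(
            np.isfinite(self.horizon_targets)
        ):
            raise ValueError("series tensor entries must be finite")
        if self.scale not in ("standardized", "original"):
            raise ValueError("scale must be 'standardized' or 'original'")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def window(self) -> int:
        return self.values.shape[2]

    @property
    def horizon(self) -> int:
        return self.horizon_targets.shape[2]

    def subset(self, idx) -> "SeriesTensor":
        idx = np.asarray(idx)
        return SeriesTensor(
            values=self.values[idx],
            horizon_targets=self.horizon_targets[idx],
            scale=self.scale,
            window_starts=(
                self.window_starts[idx] if self.window_starts is not None else None
            ),
        )


def drop_zero_features(table: AbundanceTable) -> AbundanceTable:
    """Remove taxa with zero abundance in every sample."""
    nonzero = np.flatnonzero(table.values.any(axis=1))
    if nonzero.size == 0:
        raise ValueError("all taxa are zero in every sample")
    if nonzero.size == table.n_taxa:
        return table
    return table.select_taxa(nonzero)


def fit_standardizer(
    train_values: np.ndarray, taxon_ids: list[str] | None = None
) -> StandardizationParams:
    """Fit per-taxon mean and population (divisor-n) standard deviation.

    Constant taxa get sd substituted to 1 so they standardize to zeros
    instead of NaN.
    """
    values = np.asarray(train_values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D taxa x samples array with >= 2 samples")
    means = values.mean(axis=1)
    sds = values.std(axis=1)  # population sd, ddof=0
    sds = np.where(sds == 0, 1.0, sds)
    if taxon_ids is None:
        taxon_ids = [f"taxon_{i}" for i in range(values.shape[0])]
    return StandardizationParams(taxon_ids=list(taxon_ids), means=means, sds=sds)


def apply_standardizer(
    values: np.ndarray, params: StandardizationParams
) -> np.ndarray:
    """Z-score: (x - mu_i) / sigma_i per taxon row."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != params.means.size:
        raise ValueError(
            f"{values.shape[0]} rows but {params.means.size} fitted taxa"
        )
    return (values - params.means[:, None]) / params.sds[:, None]


def invert_standardizer(
    standardized: np.ndarray, params: StandardizationParams
) -> np.ndarray:
    """Inverse Z-score: x * sigma_i + mu_i per taxon row."""
    standardized = np.asarray(standardized, dtype=float)
    if standardized.shape[0] != params.means.size:
        raise ValueError(
            f"{standardized.shape[0]} rows but {params.means.size} fitted taxa"
        )
    return standardized * params.sds[:, None] + params.means[:, None]


def make_change_stream(series: np.ndarray) -> np.ndarray:
    """First differences along time, zero-padded at t=0.

    Delta[:, t] = x[:, t] - x[:, t-1] for t >= 1 and Delta[:, 0] = 0, so the
    change stream has the same (D, T) shape as the abundance stream.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 2:
        raise ValueError("series must be (D, T) with T >= 2")
    delta = np.zeros_like(series)
    delta[:, 1:] = np.diff(series, axis=1)
    return delta


def make_windows(
    series: np.ndarray,
    window: int,
    horizon: int = 1,
    stride: int = 1,
    scale: str = "standardized",
) -> SeriesTensor:
    """Slice a (D, T) series into N sliding windows with H-step targets.

    With stride 1 there are N = T - W - H + 1 windows; window n covers
    columns [n, n+W) and its target columns [n+W, n+W+H).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be 2-D (D, T)")
    d, t = series.shape
    if window < 2 or horizon < 1 or stride < 1:
        raise ValueError("window >= 2, horizon >= 1, stride >= 1 required")
    if t < window + horizon:
        raise ValueError(
            f"series length {t} shorter than window {window} + horizon {horizon}"
        )
    starts = np.arange(0, t - window - horizon + 1, stride)
    values = np.stack([series[:, s : s + window] for s in starts])
    targets = np.stack(
        [series[:, s + window : s + window + horizon] for s in starts]
    )
    return SeriesTensor(
        values=values, horizon_targets=targets, scale=scale, window_starts=starts
    )


def split_series(
    n_items: int,
    train_fraction: float = 0.8,
    mode: str = "chronological",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split item indices into train and eval sets.

    Chronological (default): the first floor(fraction * n) items train, the
    rest evaluate — overlapping windows make random splits leaky, and 0.7
    gives the 7:3 variant. Random mode shuffles with the seed first.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if n_items < 2:
        raise ValueError("need at least 2 items to split")
    n_train = int(np.floor(train_fraction * n_items))
    n_train = min(max(n_train, 1), n_items - 1)
    if mode == "chronological":
        idx = np.arange(n_items)
    elif mode == "random":
        idx = np.random.default_rng(seed).permutation(n_items)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return idx[:n_train].copy(), idx[n_train:].copy()


def prepare_datasets(
    values: np.ndarray,
    window: int,
    horizon: int = 1,
    train_fraction: float = 0.8,
    taxon_ids: list[str] | None = None,
) -> tuple[SeriesTensor, SeriesTensor, StandardizationParams]:
    """Standardize, window and chronologically split a (D, T) series.

    The standardizer is fitted on the training time range only (the columns
    spanned by the training windows and their targets) so evaluation data
    never informs the scaling; the same parameters then standardize the
    whole series before windowing.
    """
    values = np.asarray(values, dtype=float)
    d, t = values.shape
    n_windows = t - window - horizon + 1
    if n_windows < 2:
        raise ValueError("series too short for a train/eval split")
    train_idx, eval_idx = split_series(n_windows, train_fraction)
    # last time column touched by any training window or its target
    train_end = int(train_idx[-1]) + window + horizon
    params = fit_standardizer(values[:, :train_end], taxon_ids=taxon_ids)
    standardized = apply_standardizer(values, params)
    tensor = make_windows(standardized, window, horizon)
    return tensor.subset(train_idx), tensor.subset(eval_idx), params
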