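"""The two-stream spatio-temporal graph forecaster and its ablation variants.

Three variants share one codebase:

``fusion``
    Two streams (standardized abundance, and its first differences — the
    change stream), each a stack of temporal-convolution / graph-convolution
    sandwiches, plus a deep recurrent (LSTM) branch on the abundance stream;
    per-node features from all branches are concatenated and mapped by a
    fully connected head to the next H standardized abundances per taxon.
``stgcn2s``
    The two convolutional streams without the recurrent branch.
``lstm``
    The recurrent branch and head only; no graph, no change stream.

Input windows are (B, N, T): batch, taxa (graph nodes), time steps. The
graph is the normalized co-occurrence adjacency Ahat; the spatial blocks
are the only cross-node information path, which makes the full forward
node-permutation equivariant when Ahat is permuted consistently.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor, concat, einsum2
from .nn.layers import Linear, Module, SpatialMix, StackedLSTM, TemporalConvGLU
from .preprocess import StandardizationParams

__all__ = [
    "ModelConfig",
    "Forecaster",
    "build_variant",
    "VARIANTS",
    "temporal_block_forward",
    "spatial_block_forward",
    "save_checkpoint",
    "load_checkpoint",
    "TrainedModel",
]

VARIANTS = ("fusion", "stgcn2s", "lstm")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The recurrent hidden size defaults to the window length (one unit per
    time step); ``n_blocks`` counts temporal-spatial-temporal sandwiches
    per stream.
    """

    n_taxa: int
    window: int = 8
    horizon: int = 1
    channels: int = 16
    kernel_size: int = 3
    n_blocks: int = 2
    lstm_layers: int = 5
    lstm_hidden: int | None = None
    change_stream_lstm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size > self.window:
            raise ValueError("kernel_size must not exceed window")
        for name in ("n_taxa", "window", "horizon", "channels", "kernel_size",
                     "n_blocks", "lstm_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.lstm_hidden is None:
            self.lstm_hidden = self.window


class _Stream(Module):
    """Temporal -> spatial -> temporal sandwiches over one input stream."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        c = config.channels
        self.sandwiches = []
        c_in = 1
        for _ in range(config.n_blocks):
            self.sandwiches.append(
                [
                    TemporalConvGLU(c_in, c, config.kernel_size, rng),
                    SpatialMix(c, c, rng),
                    TemporalConvGLU(c, c, config.kernel_size, rng),
                ]
            )
            c_in = c

    def named_parameters(self, prefix: str = ""):
        for si, sandwich in enumerate(self.sandwiches):
            for bi, block in enumerate(sandwich):
                yield from block.named_parameters(f"{prefix}sandwiches.{si}.{bi}.")

    def __call__(self, x: Tensor, a_hat: np.ndarray) -> Tensor:
        """x: (B, N, T) -> per-node features (B, N, C) from the last step."""
        b, n, t = x.shape
        h = x.reshape(b, 1, n, t)
        for t_in, spatial, t_out in self.sandwiches:
            h = t_in(h)
            h = spatial(h, a_hat)
            h = t_out(h)
        return h[:, :, :, -1].transpose((0, 2, 1))  # (B, N, C)


class Forecaster(Module):
    """One of the three variants; see the module docstring."""

    def __init__(self, config: ModelConfig, variant: str = "fusion"):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; one of {VARIANTS}")
        self.config = config
        self.variant = variant
        rng = np.random.default_rng(config.seed)
        feat = 0
        if variant in ("fusion", "stgcn2s"):
            self.abundance_stream = _Stream(config, rng)
            self.change_stream = _Stream(config, rng)
            feat += 2 * config.channels
        if variant in ("fusion", "lstm"):
            self.lstm = StackedLSTM(
                1, config.lstm_hidden, config.lstm_layers, rng
            )
            feat += config.lstm_hidden
            if variant == "fusion" and config.change_stream_lstm:
                self.change_lstm = StackedLSTM(
                    1, config.lstm_hidden, config.lstm_layers, rng
                )
                feat += config.lstm_hidden
        self.head = Linear(feat, config.horizon, rng)

    # -- forward -----------------------------------------------------------
    def _lstm_features(self, branch: StackedLSTM, x: Tensor) -> Tensor:
        b, n, t = x.shape
        flat = x.reshape(b * n, t, 1)
        return branch(flat).reshape(b, n, branch.hidden)

    def __call__(
        self,
        abundance: Tensor | np.ndarray,
        change: Tensor | np.ndarray | None = None,
        a_hat: np.ndarray | None = None,
    ) -> Tensor:
        """Windows (B, N, T) -> predictions (B, N, H), standardized scale."""
        x = abundance if isinstance(abundance, Tensor) else Tensor(abundance)
        if x.ndim != 3 or x.shape[1] != self.config.n_taxa:
            raise ValueError(
                f"expected (B, {self.config.n_taxa}, T) abundance window"
            )
        if x.shape[2] != self.config.window:
            raise ValueError(
                f"window length {x.shape[2]} != configured {self.config.window}"
            )
        feats = []
        if self.variant in ("fusion", "stgcn2s"):
            if change is None:
                raise ValueError(f"{self.variant} needs the change stream")
            if a_hat is None:
                raise ValueError(f"{self.variant} needs the adjacency Ahat")
            dx = change if isinstance(change, Tensor) else Tensor(change)
            if dx.shape != x.shape:
                raise ValueError("abundance and change windows must share shape")
            feats.append(self.abundance_stream(x, a_hat))
            feats.append(self.change_stream(dx, a_hat))
        if self.variant in ("fusion", "lstm"):
            feats.append(self._lstm_features(self.lstm, x))
            if getattr(self, "change_lstm", None) is not None:
                feats.append(self._lstm_features(self.change_lstm, dx))
        merged = feats[0] if len(feats) == 1 else concat(feats, axis=2)
        return self.head(merged)


def build_variant(name: str, config: ModelConfig) -> Forecaster:
    """Construct a variant by name (``fusion``, ``stgcn2s`` or ``lstm``)."""
    return Forecaster(config, variant=name)


# -- functional block surfaces (spec'd layouts, used directly in tests) ----

def temporal_block_forward(
    x: np.ndarray | Tensor,
    weight: np.ndarray,
    bias: np.ndarray,
    activation: str = "glu",
) -> Tensor:
    """Causal temporal convolution on a (B, C_in, N, T) tensor.

    ``weight`` has shape (C_out_total, C_in, k); the time axis is
    left-zero-padded so entry t only sees times <= t and length is kept.
    With ``activation='glu'`` C_out_total must be even: the first half is
    the linear path, the second the sigmoid gate.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    weight = np.asarray(weight, dtype=float)
    c_total, c_in, k = weight.shape
    block = TemporalConvGLU.__new__(TemporalConvGLU)
    block.activation = activation
    block.kernel_size = k
    block.c_out = c_total // 2 if activation == "glu" else c_total
    if activation == "glu" and c_total % 2:
        raise ValueError("glu needs an even number of output channels")
    block.weight = Tensor(weight)
    block.bias = Tensor(np.asarray(bias, dtype=float))
    return block(x)


def spatial_block_forward(
    x: np.ndarray | Tensor,
    a_hat: np.ndarray,
    mix: np.ndarray | None = None,
) -> Tensor:
    """Graph aggregation on a (B, N, T, C) tensor: out = einsum(Ahat, x).

    lfs[b, i, t, c] = sum_j Ahat[i, j] * x[b, j, t, c], optionally followed
    by a (C, C') channel mix. No non-linearity here — this is the bare
    contraction the spatial block is built around.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    a_hat = np.asarray(a_hat, dtype=float)
    if a_hat.shape != (x.shape[1], x.shape[1]):
        raise ValueError(
            f"Ahat {a_hat.shape} does not match node axis {x.shape[1]}"
        )
    lfs = einsum2("ij,bjtc->bitc", Tensor(a_hat), x)
    if mix is not None:
        lfs = einsum2("co,bjtc->bjto", Tensor(np.asarray(mix, dtype=float)), lfs)
    return lfs


# -- checkpointing ---------------------------------------------------------

@dataclass
class TrainedModel:
    """A forecaster bundled with everything needed to use it later."""

    model: Forecaster
    standardizer: StandardizationParams
    a_hat: np.ndarray

    @property
    def config(self) -> ModelConfig:
        return self.model.config


CHECKPOINT_FORMAT = "microst-checkpoint-v1"


def save_checkpoint(trained: TrainedModel, path: str | Path) -> Path:
    """Single-file .npz archive: config JSON, weights, standardizer, Ahat."""
    path = Path(path)
    meta = {
        "format": CHECKPOINT_FORMAT,
        "variant": trained.model.variant,
        "config": asdict(trained.config),
        "taxon_ids": trained.standardizer.taxon_ids,
    }
    arrays = {
        f"weights/{k}": v for k, v in trained.model.state_dict().items()
    }
    np.savez(
        path,
        _meta=np.array(json.dumps(meta, sort_keys=True)),
        _means=trained.standardizer.means,
        _sds=trained.standardizer.sds,
        _a_hat=trained.a_hat,
        **arrays,
    )
    # np.savez appends .npz when the name lacks it; report the real file
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_checkpoint(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no checkpoint at {path}")
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["_meta"]))
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"unrecognized checkpoint format in {path}")
        config = ModelConfig(**meta["config"])
        model = Forecaster(config, variant=meta["variant"])
        state = {
            k[len("weights/") :]: archive[k]
            for k in archive.files
            if k.startswith("weights/")
        }
        model.load_state_dict(state)
        standardizer = StandardizationParams(
            taxon_ids=meta["taxon_ids"],
            means=archive["_means"],
            sds=archive["_sds"],
        )
        a_hat = archive["_a_hat"]
    return TrainedModel(model=model, standardizer=standardizer, a_hat=a_hat)
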