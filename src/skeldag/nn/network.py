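"""The 10-layer linear-map CNN with per-layer DAG channel expansion.

Every layer applies, in order: DAG expansion of the previous activation
(``[X, X S^T, X T^T]``, tripling the channel count — skipped at layer 1,
whose input is the raw 3-channel feature), a per-position linear map that
sets the layer's channel width, batch-norm + ReLU, a ``(9, 1)`` temporal
convolution (stride 2 on the time axis at layers 5 and 8), and a second
batch-norm + ReLU.

A stream tensor of ``2R`` rows holds two sub-features (joint part and
skeleton part) of ``R`` rows each; each passes through its own tower, the
tower outputs are globally average-pooled over time and joints, concatenated,
and a final linear map produces one logit per action class.  With the default
widths the pooled head input is 2 x 256 = 512 and the output 49 classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..topology import DagMatrices
from .layers import (
    DTYPE,
    BatchNorm,
    DagExpand,
    Dense,
    GlobalAvgPool,
    Layer,
    LinearMap,
    ReLU,
    TemporalConv,
    softmax,
)

#: Channel widths of the ten layers (printed architecture).
DEFAULT_CHANNELS: tuple[int, ...] = (64, 64, 64, 64, 128, 128, 128, 256, 256, 256)
#: 1-based indices of the layers whose convolution strides by 2 in time.
STRIDE2_LAYERS: tuple[int, ...] = (5, 8)
RAW_CHANNELS = 3


@dataclass(frozen=True)
class LayerSpec:
    """Channel/stride bookkeeping for one layer of a tower."""

    index: int  # 1-based
    linear_in: int
    linear_out: int
    kernel: int = 9
    stride: int = 1
    pad: int = 4


def make_layer_specs(
    channels: tuple[int, ...] = DEFAULT_CHANNELS,
    stride2_layers: tuple[int, ...] = STRIDE2_LAYERS,
    kernel: int = 9,
    pad: int = 4,
) -> list[LayerSpec]:
    """Derive layer specs: layer 1 maps the raw 3 channels, every later
    layer maps 3x the previous conv width (the DAG expansion factor)."""
    specs = []
    for i, c_out in enumerate(channels, start=1):
        c_in = RAW_CHANNELS if i == 1 else 3 * channels[i - 2]
        specs.append(
            LayerSpec(
                index=i,
                linear_in=c_in,
                linear_out=c_out,
                kernel=kernel,
                stride=2 if i in stride2_layers else 1,
                pad=pad,
            )
        )
    return specs


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    Defaults follow the printed architecture: 49 classes, channel widths
    64/128/256, batch 32, momentum SGD.  The learning-rate schedule is a
    step decay (multiply by ``lr_decay`` every ``lr_step`` epochs).
    """

    n_classes: int = 49
    channels: tuple[int, ...] = DEFAULT_CHANNELS
    stride2_layers: tuple[int, ...] = STRIDE2_LAYERS
    kernel: int = 9
    pad: int = 4
    use_dag: bool = True
    input_norm: bool = True
    share_tower_weights: bool = False
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 15
    lr_decay: float = 0.5
    lr_step: int = 10
    seed: int = 0

    @property
    def head_width(self) -> int:
        return 2 * self.channels[-1]

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["channels"] = list(self.channels)
        d["stride2_layers"] = list(self.stride2_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        d["stride2_layers"] = tuple(d["stride2_layers"])
        return cls(**d)


class Tower:
    """One 10-layer stack processing a single (R, 18, C) sub-feature."""

    def __init__(
        self,
        specs: list[LayerSpec],
        dag: DagMatrices,
        rng: np.random.Generator,
        use_dag: bool = True,
        input_norm: bool = True,
    ):
        self.specs = specs
        # normalizing the raw pixel-scale channels at entry keeps the first
        # linear map well-conditioned regardless of frame resolution
        self.input_bn: BatchNorm | None = BatchNorm(RAW_CHANNELS) if input_norm else None
        self.blocks: list[list[Layer]] = []
        for spec in specs:
            block: list[Layer] = []
            if spec.index > 1:
                block.append(DagExpand(dag.source, dag.target, enabled=use_dag))
            block += [
                LinearMap(spec.linear_in, spec.linear_out, rng),
                BatchNorm(spec.linear_out),
                ReLU(),
                TemporalConv(
                    spec.linear_out,
                    spec.linear_out,
                    rng,
                    kernel=spec.kernel,
                    stride=spec.stride,
                    pad=spec.pad,
                ),
                BatchNorm(spec.linear_out),
                ReLU(),
            ]
            self.blocks.append(block)

    def layers(self) -> list[Layer]:
        head = [self.input_bn] if self.input_bn is not None else []
        return head + [l for block in self.blocks for l in block]

    def forward(
        self, x: np.ndarray, train: bool = True, trace: list | None = None
    ) -> np.ndarray:
        if self.input_bn is not None:
            x = self.input_bn.forward(x, train)
        for spec, block in zip(self.specs, self.blocks):
            it = iter(block)
            if spec.index > 1:
                x = next(it).forward(x, train)
            if trace is not None:
                entry = {"layer": spec.index, "linear_in": x.shape[1:]}
            for layer in it:
                x = layer.forward(x, train)
                if trace is not None and isinstance(layer, LinearMap):
                    entry["linear_out"] = x.shape[1:]
            if trace is not None:
                entry["conv_out"] = x.shape[1:]
                trace.append(entry)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for block in reversed(self.blocks):
            for layer in reversed(block):
                g = layer.backward(g)
        if self.input_bn is not None:
            g = self.input_bn.backward(g)
        return g


class TwoTowerClassifier:
    """Two parallel towers (joint / skeleton sub-features) plus a linear head.

    Input is a batch of stream tensors ``(N, 2R, 18, 3)``; the first R rows
    feed the joint tower and the rest the skeleton tower.  Towers have
    separate weights unless ``config.share_tower_weights``.
    """

    def __init__(self, config: ModelConfig, dag: DagMatrices):
        self.config = config
        rng = np.random.default_rng(config.seed)
        specs = make_layer_specs(
            config.channels, config.stride2_layers, config.kernel, config.pad
        )
        self.joint_tower = Tower(
            specs, dag, rng, use_dag=config.use_dag, input_norm=config.input_norm
        )
        self.skeleton_tower = (
            self.joint_tower
            if config.share_tower_weights
            else Tower(
                specs, dag, rng, use_dag=config.use_dag, input_norm=config.input_norm
            )
        )
        self.pool_j = GlobalAvgPool()
        self.pool_s = GlobalAvgPool()
        self.head = Dense(config.head_width, config.n_classes, rng)

    # -- plumbing -------------------------------------------------------

    def layers(self) -> list[Layer]:
        ls = self.joint_tower.layers()
        if self.skeleton_tower is not self.joint_tower:
            ls += self.skeleton_tower.layers()
        return ls + [self.head]

    def zero_grad(self) -> None:
        for l in self.layers():
            l.zero_grad()

    def state_dict(self) -> dict:
        state = {}
        for i, l in enumerate(self.layers()):
            for k, v in l.params.items():
                state[f"{i}.{k}"] = v.copy()
            if isinstance(l, BatchNorm):
                state[f"{i}.running_mean"] = l.running_mean.copy()
                state[f"{i}.running_var"] = l.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, l in enumerate(self.layers()):
            for k in l.params:
                l.params[k][...] = state[f"{i}.{k}"]
            if isinstance(l, BatchNorm):
                l.running_mean[...] = state[f"{i}.running_mean"]
                l.running_var[...] = state[f"{i}.running_var"]

    # -- forward/backward ----------------------------------------------

    def _split(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if x.ndim != 4 or x.shape[1] % 2 or x.shape[-1] != RAW_CHANNELS:
            raise ValueError(
                f"expected (N, 2R, 18, {RAW_CHANNELS}) stream batch, got {x.shape}"
            )
        half = x.shape[1] // 2
        return x[:, :half], x[:, half:]

    def forward(
        self, x: np.ndarray, train: bool = True, trace: dict | None = None
    ) -> np.ndarray:
        """Logits ``(N, n_classes)`` for a batch of stream tensors."""
        # float64 input is honoured (used for high-precision gradient
        # verification); everything else runs in float32
        dtype = np.float64 if np.asarray(x).dtype == np.float64 else DTYPE
        xj, xs = self._split(np.ascontiguousarray(x, dtype=dtype))
        tj = [] if trace is not None else None
        ts = [] if trace is not None else None
        if self.skeleton_tower is self.joint_tower:
            # Shared weights: one pass over the stacked batch keeps the
            # layer caches consistent for backward.
            y = self.joint_tower.forward(
                np.concatenate([xj, xs], axis=0), train, tj
            )
            yj, ys = y[: len(xj)], y[len(xj) :]
            ts = tj
        else:
            yj = self.joint_tower.forward(xj, train, tj)
            ys = self.skeleton_tower.forward(xs, train, ts)
        hj = self.pool_j.forward(yj, train)
        hs = self.pool_s.forward(ys, train)
        h = np.concatenate([hj, hs], axis=1)
        logits = self.head.forward(h, train)
        if trace is not None:
            trace["joint_tower"] = tj
            trace["skeleton_tower"] = ts
            trace["head_in"] = h.shape[1]
            trace["head_out"] = logits.shape[1]
        return logits

    def backward(self, g_logits: np.ndarray) -> None:
        gh = self.head.backward(g_logits)
        w = self.config.channels[-1]
        gj = self.pool_j.backward(gh[:, :w])
        gs = self.pool_s.backward(gh[:, w:])
        if self.skeleton_tower is self.joint_tower:
            self.joint_tower.backward(np.concatenate([gj, gs], axis=0))
        else:
            self.skeleton_tower.backward(gs)
            self.joint_tower.backward(gj)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Softmax class probabilities in evaluation mode (running BN stats)."""
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)


def shape_trace(model: TwoTowerClassifier, n_rows: int = 1200) -> dict:
    """Run one dummy stream through the model and record per-layer shapes."""
    x = np.zeros((1, n_rows, 18, RAW_CHANNELS), dtype=DTYPE)
    trace: dict = {}
    model.forward(x, train=True, trace=trace)
    return trace


def fuse_scores(
    spatial_scores: np.ndarray, motion_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class-score fusion: the arithmetic mean of the two per-class
    probability vectors (or batches of them), and the argmax prediction
    with ties broken toward the lower class index."""
    a = np.asarray(spatial_scores, dtype=float)
    b = np.asarray(motion_scores, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"score shapes differ: {a.shape} vs {b.shape}")
    fused = (a + b) / 2.0
    return fused, fused.argmax(axis=-1)


def save_checkpoint(model: TwoTowerClassifier, path) -> None:
    """Single-archive checkpoint: parameters, running stats and config."""
    import json

    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path, dag: DagMatrices) -> TwoTowerClassifier:
    import json

    with np.load(path) as data:
        config = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode())
        )
        model = TwoTowerClassifier(config, dag)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
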