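"""Model configuration, construction, encoding and prediction.

The architecture has three sequential sections:

1. a convolutional stem followed by dual linear/nonlinear path blocks,
   with max pooling between stages reducing the spatial axis;
2. residual dilated convolution blocks that widen the receptive field at
   constant resolution;
3. a fixed B-spline spatial-basis transform that compresses the spatial
   bins to a small number of basis coefficients, followed by fully
   connected layers and a sigmoid output giving per-target peak
   probabilities at the sequence centre.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .layers import (
    BatchNorm1d,
    Conv1d,
    Dense,
    DilatedResidualBlock,
    DualPathBlock,
    Flatten,
    MaxPool1d,
    ReLU,
    Sequential,
    SplineTransform,
)
from .spline import spline_basis

__all__ = ["ModelConfig", "SequenceModel", "build_model", "one_hot", "TINY_PRESET"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ModelConfig:
    """Hyperparameters for the sequence model.

    The pooling schedule must map ``seq_len`` to exactly ``n_spatial_bins``
    spatial positions before the spline-basis transform, and ``spline_df``
    cannot exceed the bin count.
    """

    seq_len: int = 4000
    n_targets: int = 1
    channels: int = 64
    stem_kernel: int = 9
    n_dual_blocks: int = 2
    dual_kernel: int = 5
    pool_factors: tuple[int, ...] = (4, 4)
    dilations: tuple[int, ...] = (2, 4)
    dilated_kernel: int = 3
    n_spatial_bins: int = 250
    spline_df: int = 16
    hidden: int = 256
    init_seed: int = 0

    def __post_init__(self) -> None:
        self.pool_factors = tuple(self.pool_factors)
        self.dilations = tuple(self.dilations)
        prod = int(np.prod(self.pool_factors)) if self.pool_factors else 1
        if self.seq_len % prod != 0 or self.seq_len // prod != self.n_spatial_bins:
            raise ValueError(
                f"pooling schedule {self.pool_factors} maps seq_len "
                f"{self.seq_len} to {self.seq_len // prod if self.seq_len % prod == 0 else 'a non-integer number of'} "
                f"spatial positions, but n_spatial_bins={self.n_spatial_bins}"
            )
        if self.spline_df > self.n_spatial_bins:
            raise ValueError("spline_df cannot exceed n_spatial_bins")
        if len(self.pool_factors) != self.n_dual_blocks:
            raise ValueError("need one pool factor per dual-path block")

    def n_parameters(self) -> int:
        """Closed-form trainable parameter count."""
        c, k = self.channels, self.dual_kernel
        n = 4 * self.stem_kernel * c + c + 2 * c  # stem conv + its batchnorm
        # dual blocks: linear + nonlinear convs + branch batchnorm
        n += self.n_dual_blocks * (2 * (c * k * c + c) + 2 * c)
        n += len(self.dilations) * (c * self.dilated_kernel * c + c + 2 * c)
        n += self.hidden * (c * self.spline_df) + self.hidden  # post-spline dense
        n += self.n_targets * self.hidden + self.n_targets  # output layer
        return n

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        raw = json.loads(text)
        raw["pool_factors"] = tuple(raw["pool_factors"])
        raw["dilations"] = tuple(raw["dilations"])
        return cls(**raw)


#: Miniature preset used by desk-scale tests: short sequences, few channels.
TINY_PRESET = dict(
    seq_len=512,
    channels=32,
    stem_kernel=11,
    n_dual_blocks=2,
    dual_kernel=5,
    pool_factors=(4, 4),
    dilations=(2, 4),
    dilated_kernel=3,
    n_spatial_bins=32,
    spline_df=8,
    hidden=64,
)


def one_hot(sequences: Sequence[str]) -> np.ndarray:
    """Encode sequences as ``(n, 4, L)``; ``N`` becomes 0.25 per channel."""
    if not sequences:
        return np.zeros((0, 4, 0))
    length = len(sequences[0])
    for i, seq in enumerate(sequences):
        if len(seq) != length:
            raise ValueError(
                f"sequence {i} has length {len(seq)}, expected {length}"
            )
    out = np.zeros((len(sequences), 4, length))
    for i, seq in enumerate(sequences):
        codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        for base, ch in _BASE_INDEX.items():
            out[i, ch, codes == ord(base)] = 1.0
        is_n = codes == ord("N")
        if is_n.any():
            out[i, :, is_n] = 0.25
    return out


class SequenceModel:
    """The assembled network plus its configuration."""

    def __init__(self, config: ModelConfig, net: Sequential):
        self.config = config
        self.net = net

    # -- inference -----------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def predict(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Sigmoid probabilities, batched, deterministic."""
        if x.ndim != 3 or x.shape[1] != 4 or x.shape[2] != self.config.seq_len:
            raise ValueError(
                f"expected input of shape (n, 4, {self.config.seq_len}), "
                f"got {x.shape}"
            )
        chunks = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(x[i : i + batch_size], train=False)
            chunks.append(1.0 / (1.0 + np.exp(-logits)))
        return np.concatenate(chunks, axis=0) if chunks else np.zeros((0, self.config.n_targets))

    def predict_sequences(self, sequences: Sequence[str], batch_size: int = 128) -> np.ndarray:
        for i, seq in enumerate(sequences):
            if len(seq) != self.config.seq_len:
                raise ValueError(
                    f"sequence {i} has length {len(seq)}, model expects "
                    f"{self.config.seq_len}"
                )
        return self.predict(one_hot(list(sequences)), batch_size=batch_size)

    # -- training support ----------------------------------------------

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean per-target binary cross-entropy; backpropagates gradients
        into the layers' gradient slots."""
        logits = self.forward_logits(x, train=True)
        probs = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        loss = -np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps))
        grad = (probs - y) / y.size
        self.net.backward(grad)
        return float(loss)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self.forward_logits(x, train=False)
        probs = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        return float(
            -np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps))
        )

    def parameters(self) -> dict[str, np.ndarray]:
        return self.net.parameters()

    def gradients(self) -> dict[str, np.ndarray]:
        return self.net.gradients()

    def get_state(self) -> dict[str, dict[str, np.ndarray]]:
        return {
            "params": {k: v.copy() for k, v in self.parameters().items()},
            "buffers": {k: v.copy() for k, v in self.net.buffers().items()},
        }

    def set_state(self, state: dict[str, dict[str, np.ndarray]]) -> None:
        self.net.set_parameters(state["params"])
        self.net.set_buffers(state["buffers"])

    # -- persistence ---------------------------------------------------

    def save(self, path: str) -> None:
        arrays = {f"param::{k}": v for k, v in self.parameters().items()}
        arrays.update({f"buffer::{k}": v for k, v in self.net.buffers().items()})
        np.savez(path, __config__=self.config.to_json(), **arrays)

    @classmethod
    def load(cls, path: str) -> "SequenceModel":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig.from_json(str(data["__config__"]))
            model = build_model(config)
            state = {
                "params": {
                    k[len("param::") :]: data[k]
                    for k in data.files
                    if k.startswith("param::")
                },
                "buffers": {
                    k[len("buffer::") :]: data[k]
                    for k in data.files
                    if k.startswith("buffer::")
                },
            }
        model.set_state(state)
        return model


def build_model(config: ModelConfig) -> SequenceModel:
    """Assemble the three-section network from a validated config."""
    rng = np.random.default_rng(config.init_seed)
    c = config.channels
    layers: list = [
        Conv1d(4, c, config.stem_kernel, rng=rng),
        BatchNorm1d(c),
        ReLU(),
    ]
    # pooling precedes each dual-path stage so the expensive blocks run at
    # reduced spatial resolution
    for i in range(config.n_dual_blocks):
        layers.append(MaxPool1d(config.pool_factors[i]))
        layers.append(DualPathBlock(c, c, config.dual_kernel, rng=rng))
    for d in config.dilations:
        layers.append(DilatedResidualBlock(c, config.dilated_kernel, d, rng=rng))
    basis = spline_basis(config.n_spatial_bins, config.spline_df)
    layers.append(SplineTransform(basis))
    layers.append(Flatten())
    layers.append(Dense(c * config.spline_df, config.hidden, rng=rng))
    layers.append(ReLU())
    out = Dense(config.hidden, config.n_targets, rng=rng)
    out.W *= 0.1  # keep initial logits near zero for a sane starting loss
    layers.append(out)
    model = SequenceModel(config, Sequential(layers))
    actual = sum(p.size for p in model.parameters().values())
    assert actual == config.n_parameters(), (actual, config.n_parameters())
    return model
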