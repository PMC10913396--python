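"""SPREd edge-prediction model architectures.

Two complementary 1-D CNNs score candidate TF→gene edges from the stacked
pairwise-relationship features:

* **SPREd-SP** (single pair) scores one TF–gene decision per sample.  Input
  is an (nTF + 1) x F matrix (the fixed TF paired with every TF, then with
  the target gene; F = 5 feature channels by default).  The TF–TF rows and
  the single TF–gene row pass through *separate* stacks of two
  conv(1)-batchnorm-ReLU blocks (F→16, 16→1); the concatenated
  (nTF + 1)-vector feeds a 128-unit ReLU layer and then a single output
  logit.

* **SPREd-ML** (multi label) scores all nTF candidates of a gene at once.
  Input is an (nTF^2 + nTF) x F matrix (ordered TF–TF pairs, then TF–gene
  pairs).  Each block passes through its own shared conv(1)+ReLU kernel
  producing feature maps of lengths nTF^2 and nTF; both maps are fully
  connected to nTF output logits, with dropout 0.3 on the connections from
  the TF–gene map (training mode only).

The "convolutions" are kernel-size-1 channel mixers: pair rows are an
unordered set, so the only meaningful convolution axis is the feature
channel within a row, with weights shared across rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .features import FEATURE_ORDER, MlDataset, SpDataset

__all__ = [
    "SpModelConfig",
    "MlModelConfig",
    "SPREdSP",
    "SPREdML",
    "sp_forward",
    "ml_forward",
    "score_edges",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class SpModelConfig:
    n_tf: int
    n_features: int = len(FEATURE_ORDER)
    conv1_channels: int = 16
    conv2_channels: int = 1
    hidden_units: int = 128
    dropout_rate: float = 0.0


@dataclass(frozen=True)
class MlModelConfig:
    n_tf: int
    n_features: int = len(FEATURE_ORDER)
    dropout_rate: float = 0.3


def _conv_bn_stack(cfg: SpModelConfig, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Linear(cfg.n_features, cfg.conv1_channels, rng),
        nn.BatchNorm(cfg.conv1_channels),
        nn.ReLU(),
        nn.Linear(cfg.conv1_channels, cfg.conv2_channels, rng),
        nn.BatchNorm(cfg.conv2_channels),
        nn.ReLU(),
    )


class SPREdSP:
    """Single-pair edge classifier."""

    kind = "sp"

    def __init__(self, config: SpModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.branch_tf = _conv_bn_stack(config, rng)
        self.branch_tg = _conv_bn_stack(config, rng)
        n_map = config.n_tf + 1
        self.dense1 = nn.Linear(n_map, config.hidden_units, rng)
        self.relu = nn.ReLU()
        self.dense2 = nn.Linear(config.hidden_units, 1, rng)

    def parameters(self) -> list[nn.Parameter]:
        return (
            self.branch_tf.parameters()
            + self.branch_tg.parameters()
            + self.dense1.parameters()
            + self.dense2.parameters()
        )

    def forward(self, x_tf: np.ndarray, x_tg: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch; x_tf (B, nTF, F), x_tg (B, 1, F) -> (B,)."""
        b, n_tf, f = x_tf.shape
        if n_tf != self.config.n_tf or f != self.config.n_features:
            raise ValueError(
                f"expected TF-TF block (B, {self.config.n_tf}, "
                f"{self.config.n_features}), got {x_tf.shape}"
            )
        if x_tg.shape != (b, 1, f):
            raise ValueError(f"expected TF-gene block {(b, 1, f)}, got {x_tg.shape}")
        t = self.branch_tf.forward(x_tf, training=training)[..., 0]  # (B, nTF)
        g = self.branch_tg.forward(x_tg, training=training)[..., 0]  # (B, 1)
        v = np.concatenate([t, g], axis=1)  # (B, nTF + 1)
        self._split = t.shape[1]
        h = self.relu.forward(self.dense1.forward(v, training), training)
        return self.dense2.forward(h, training)[:, 0]

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.dense2.backward(grad_logits[:, None])
        g = self.dense1.backward(self.relu.backward(g))
        gt, gg = g[:, : self._split], g[:, self._split :]
        self.branch_tf.backward(gt[..., None])
        self.branch_tg.backward(gg[..., None])

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i}"] = p.value.copy()
        for name, branch in (("tf", self.branch_tf), ("tg", self.branch_tg)):
            for j, layer in enumerate(branch.layers):
                if isinstance(layer, nn.BatchNorm):
                    state[f"bn_{name}_{j}_mean"] = layer.running_mean.copy()
                    state[f"bn_{name}_{j}_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"p{i}"]
        for name, branch in (("tf", self.branch_tf), ("tg", self.branch_tg)):
            for j, layer in enumerate(branch.layers):
                if isinstance(layer, nn.BatchNorm):
                    layer.running_mean[...] = state[f"bn_{name}_{j}_mean"]
                    layer.running_var[...] = state[f"bn_{name}_{j}_var"]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())


class SPREdML:
    """Multi-label edge classifier (all TFs of one gene at once)."""

    kind = "ml"

    def __init__(self, config: MlModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.conv_tt = nn.Linear(config.n_features, 1, rng)
        self.relu_tt = nn.ReLU()
        self.conv_tg = nn.Linear(config.n_features, 1, rng)
        self.relu_tg = nn.ReLU()
        self.dropout = nn.Dropout(config.dropout_rate, rng)
        n_map = config.n_tf * config.n_tf + config.n_tf
        self.dense = nn.Linear(n_map, config.n_tf, rng)

    def parameters(self) -> list[nn.Parameter]:
        return (
            self.conv_tt.parameters()
            + self.conv_tg.parameters()
            + self.dense.parameters()
        )

    def forward(self, x_tt: np.ndarray, x_tg: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch; x_tt (B, nTF^2, F), x_tg (B, nTF, F) -> (B, nTF)."""
        n_tf, f = self.config.n_tf, self.config.n_features
        b = x_tt.shape[0]
        if x_tt.shape != (b, n_tf * n_tf, f):
            raise ValueError(
                f"expected TF-TF block {(b, n_tf * n_tf, f)}, got {x_tt.shape}"
            )
        if x_tg.shape != (b, n_tf, f):
            raise ValueError(f"expected TF-gene block {(b, n_tf, f)}, got {x_tg.shape}")
        a = self.relu_tt.forward(self.conv_tt.forward(x_tt, training), training)[..., 0]
        g = self.relu_tg.forward(self.conv_tg.forward(x_tg, training), training)[..., 0]
        g = self.dropout.forward(g, training=training)
        v = np.concatenate([a, g], axis=1)
        self._split = a.shape[1]
        return self.dense.forward(v, training)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.dense.backward(grad_logits)
        ga, gg = g[:, : self._split], g[:, self._split :]
        self.conv_tt.backward(self.relu_tt.backward(ga[..., None]))
        gg = self.dropout.backward(gg)
        self.conv_tg.backward(self.relu_tg.backward(gg[..., None]))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"p{i}"]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())


def sp_forward(model: SPREdSP, x_tf: np.ndarray, x_tg: np.ndarray) -> np.ndarray:
    """Evaluation-mode logits for single-pair inputs."""
    return model.forward(x_tf, x_tg, training=False)


def ml_forward(model: SPREdML, x_tt: np.ndarray, x_tg: np.ndarray) -> np.ndarray:
    """Evaluation-mode logits for multi-label inputs."""
    return model.forward(x_tt, x_tg, training=False)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def score_edges(model: SPREdSP | SPREdML, dataset: SpDataset | MlDataset) -> np.ndarray:
    """Edge scores in (0, 1) for every sample of a featurized dataset.

    For SP the result is one score per (TF, gene) sample; for ML one row of
    nTF scores per gene sample.
    """
    if isinstance(model, SPREdSP):
        logits = model.forward(dataset.x_tf, dataset.x_tg, training=False)
    else:
        logits = model.forward(dataset.x_tt, dataset.x_tg, training=False)
    return _sigmoid(logits)


def save_checkpoint(model: SPREdSP | SPREdML, path: str | Path) -> None:
    """Write a checkpoint: JSON architecture descriptor + npz weights."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    desc = {"kind": model.kind, "config": model.config.__dict__}
    path.with_suffix(".json").write_text(json.dumps(desc, indent=2))
    np.savez(path.with_suffix(".npz"), **model.state_dict())


def load_checkpoint(path: str | Path, seed: int = 0) -> SPREdSP | SPREdML:
    path = Path(path)
    desc = json.loads(path.with_suffix(".json").read_text())
    cfg = desc["config"]
    if desc["kind"] == "sp":
        model: SPREdSP | SPREdML = SPREdSP(SpModelConfig(**cfg), seed=seed)
    else:
        model = SPREdML(MlModelConfig(**cfg), seed=seed)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
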