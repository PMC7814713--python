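"""Model layer: configurable U-Net behind an open architecture registry.

Any callable ``builder(config: UNetConfig, input_shape, seed) -> model`` can
be registered under a name and selected from the pipeline configuration;
the bundled ``"unet"`` builder constructs the standard 2D/3D U-Net on the
package's numpy backend.  A model must honour the shape contract: it maps a
batch ``(n, *spatial, in_channels)`` to per-voxel class probabilities
``(n, *spatial, n_classes)`` that are non-negative and sum to one across
the class axis.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np

from . import metrics as metrics_mod
from .errors import ConfigurationError, ModelIOError, ValidationError
from .nn import Adam, UNet


@dataclasses.dataclass
class UNetConfig:
    """Architecture hyperparameters of the standard U-Net.

    ``depth`` is the number of 2x pooling steps, so every input spatial size
    must be divisible by ``2 ** depth``.
    """

    n_dims: int = 3
    in_channels: int = 1
    n_classes: int = 2
    base_filters: int = 32
    depth: int = 4
    batch_norm: bool = False
    dropout: float = 0.0
    architecture: str = "unet"

    def __post_init__(self) -> None:
        if self.n_dims not in (2, 3):
            raise ConfigurationError(f"n_dims must be 2 or 3, got {self.n_dims}")
        if self.in_channels < 1:
            raise ConfigurationError("in_channels must be >= 1")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.base_filters < 1:
            raise ConfigurationError("base_filters must be >= 1")
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")


def check_divisibility(config: UNetConfig, input_shape: Sequence[int]) -> None:
    if len(input_shape) != config.n_dims:
        raise ConfigurationError(
            f"input shape {tuple(input_shape)} has {len(input_shape)} axes, "
            f"expected {config.n_dims}"
        )
    div = 2 ** config.depth
    for axis, size in enumerate(input_shape):
        if size % div != 0:
            raise ConfigurationError(
                f"input axis {axis} (size {size}) is not divisible by "
                f"2^depth = {div}; choose a compatible patch shape or depth"
            )


class SegmentationModel:
    """Trainable model honouring the backend-neutral contract.

    Wraps the network with an optimizer and a named training loss;
    ``predict`` runs in evaluation mode and chunks large patch sets.
    """

    def __init__(self, net: UNet, config: UNetConfig,
                 input_shape: Tuple[int, ...]):
        self.net = net
        self.config = config
        self.input_shape = tuple(input_shape)
        self.optimizer: Optional[Adam] = None
        self.loss_name: Optional[str] = None
        self._loss_fn = None
        self._loss_grad = None

    @property
    def n_classes(self) -> int:
        return self.config.n_classes

    def compile(self, learning_rate: float, loss: str) -> "SegmentationModel":
        if learning_rate <= 0:
            raise ConfigurationError("learning rate must be > 0")
        self._loss_fn, self._loss_grad = metrics_mod.get_loss(loss)
        self.loss_name = loss
        self.optimizer = Adam(self.net.parameters(), learning_rate)
        return self

    def train_on_batch(self, x: np.ndarray, y_onehot: np.ndarray
                       ) -> Tuple[float, np.ndarray]:
        """One gradient step; returns (batch-mean loss, predicted probs).

        The loss is evaluated per batch member and averaged, and the
        probability gradient is scaled accordingly.
        """
        if self.optimizer is None:
            raise ConfigurationError("model must be compiled before training")
        probs = self.net.forward(x, training=True)
        n = x.shape[0]
        losses = [float(self._loss_fn(y_onehot[i], probs[i])) for i in range(n)]
        dprobs = np.stack(
            [self._loss_grad(y_onehot[i], probs[i]) for i in range(n)]
        ) / n
        self.optimizer.zero_grad()
        self.net.backward(dprobs)
        self.optimizer.step()
        return float(np.mean(losses)), probs

    def predict(self, patches: np.ndarray,
                offsets: Optional[Sequence[Tuple[int, ...]]] = None,
                batch_size: int = 8) -> np.ndarray:
        """Per-voxel class probabilities for a stack of patches."""
        outs = [
            self.net.forward(patches[i:i + batch_size], training=False)
            for i in range(0, len(patches), batch_size)
        ]
        return np.concatenate(outs, axis=0)


ArchitectureBuilder = Callable[[UNetConfig, Tuple[int, ...], int], SegmentationModel]

_ARCHITECTURE_REGISTRY: Dict[str, ArchitectureBuilder] = {}


def register_architecture(name: str, builder: ArchitectureBuilder) -> None:
    if name in _ARCHITECTURE_REGISTRY:
        raise ConfigurationError(f"architecture {name!r} is already registered")
    if not callable(builder):
        raise ValidationError("architecture builder must be callable")
    _ARCHITECTURE_REGISTRY[name] = builder


def get_architecture(name: str) -> ArchitectureBuilder:
    if name not in _ARCHITECTURE_REGISTRY:
        raise ConfigurationError(
            f"unknown architecture {name!r}; registered: {sorted(_ARCHITECTURE_REGISTRY)}"
        )
    return _ARCHITECTURE_REGISTRY[name]


def build_unet(config: UNetConfig, input_shape: Sequence[int],
               seed: int = 0) -> SegmentationModel:
    """Build the standard U-Net after validating the 2^depth divisibility."""
    check_divisibility(config, input_shape)
    net = UNet(ndim=config.n_dims, in_channels=config.in_channels,
               n_classes=config.n_classes, base_filters=config.base_filters,
               depth=config.depth, batch_norm=config.batch_norm,
               dropout=config.dropout, seed=seed)
    return SegmentationModel(net, config, tuple(input_shape))


def build_model(config: UNetConfig, input_shape: Sequence[int],
                seed: int = 0) -> SegmentationModel:
    """Build whatever architecture ``config.architecture`` names."""
    builder = get_architecture(config.architecture)
    model = builder(config, tuple(input_shape), seed)
    _validate_contract(model, config, tuple(input_shape))
    return model


def _validate_contract(model, config: UNetConfig, input_shape: Tuple[int, ...]) -> None:
    probe = np.zeros((1,) + input_shape + (config.in_channels,), dtype=np.float32)
    out = model.predict(probe)
    expected = (1,) + input_shape + (config.n_classes,)
    if tuple(out.shape) != expected:
        raise ValidationError(
            f"architecture {config.architecture!r} violates the shape contract: "
            f"{tuple(out.shape)} != {expected}"
        )
    sums = out.sum(axis=-1)
    if out.min() < -1e-6 or np.abs(sums - 1.0).max() > 1e-4:
        raise ValidationError(
            f"architecture {config.architecture!r} must output per-voxel class "
            "probabilities summing to 1"
        )


register_architecture("unet", build_unet)


def reset_architectures() -> None:
    """Restore the registry to the bundled builders (test isolation helper)."""
    _ARCHITECTURE_REGISTRY.clear()
    _ARCHITECTURE_REGISTRY["unet"] = build_unet


# --------------------------------------------------------------- persistence

_MODEL_FORMAT = "segpipe-model-v1"


def save_model(model: SegmentationModel, path: str) -> str:
    """Serialize config plus all parameter arrays into one .npz file."""
    meta = {
        "format": _MODEL_FORMAT,
        "config": dataclasses.asdict(model.config),
        "input_shape": list(model.input_shape),
        "loss": model.loss_name,
        "learning_rate": (model.optimizer.learning_rate
                          if model.optimizer is not None else None),
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.net.parameters())}
    # batch-norm running statistics are state, not parameters
    stats = _collect_bn_stats(model.net)
    arrays.update({f"bnstat_{i}": s for i, s in enumerate(stats)})
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_model(path: str) -> SegmentationModel:
    """Rebuild a model from :func:`save_model` output; predictions round-trip."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format") != _MODEL_FORMAT:
                raise ModelIOError(f"{path} is not a recognized model file")
            config = UNetConfig(**meta["config"])
            model = build_model(config, tuple(meta["input_shape"]))
            params = model.net.parameters()
            for i, p in enumerate(params):
                stored = data[f"param_{i}"]
                if stored.shape != p.value.shape:
                    raise ModelIOError(f"parameter {i} shape mismatch in {path}")
                p.value[...] = stored
            stats = _collect_bn_stats(model.net)
            for i, s in enumerate(stats):
                s[...] = data[f"bnstat_{i}"]
    except ModelIOError:
        raise
    except Exception as exc:
        raise ModelIOError(f"could not load model from {path}: {exc}") from exc
    if meta.get("loss") and meta.get("learning_rate"):
        model.compile(meta["learning_rate"], meta["loss"])
    return model


def _collect_bn_stats(net: UNet):
    stats = []
    blocks = [b for level in net.enc_blocks for b in level]
    blocks += net.bottleneck
    blocks += [b for level in net.dec_blocks for b in level]
    for b in blocks:
        if b.bn is not None:
            stats.extend([b.bn.running_mean, b.bn.running_var])
    return stats


# -------------------------------------------------------------- model stubs

class OracleModel:
    """Prediction stub returning the one-hot ground truth at each offset.

    Used to exercise the prediction round trip in isolation from learning:
    fed through patching, merging and decoding it must reproduce the truth.
    Requires the caller to pass patch offsets.
    """

    def __init__(self, truth_onehot: np.ndarray):
        self.truth = truth_onehot
        self.n_classes = truth_onehot.shape[-1]

    def predict(self, patches: np.ndarray, offsets=None, batch_size: int = 8
                ) -> np.ndarray:
        if offsets is None:
            raise ValidationError("OracleModel needs patch offsets")
        patch_shape = patches.shape[1:-1]
        out = np.empty(patches.shape[:-1] + (self.n_classes,), dtype=np.float32)
        for i, off in enumerate(offsets):
            slicer = tuple(slice(o, o + p) for o, p in zip(off, patch_shape))
            out[i] = self.truth[slicer]
        return out


class ConstantModel:
    """Stub predicting one fixed class everywhere."""

    def __init__(self, n_classes: int, label: int = 0):
        self.n_classes = n_classes
        self.label = label

    def predict(self, patches: np.ndarray, offsets=None, batch_size: int = 8
                ) -> np.ndarray:
        out = np.zeros(patches.shape[:-1] + (self.n_classes,), dtype=np.float32)
        out[..., self.label] = 1.0
        return out
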