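"""The hybrid BiLSTM-LSTM emotion classifier and its ablation variants.

The proposed stack reads a segmented EEG window as a sequence — time steps
along the window, the channels forming the per-step feature vector — and
maps it to a class-probability distribution:

    BiLSTM(128) -> BiLSTM(64) -> Dropout(0.5) -> LSTM(32) -> Dense softmax

The two bidirectional layers capture forward and backward temporal context,
the dropout layer regularizes, the final unidirectional layer condenses the
sequence into one feature vector, and the softmax head classifies.  Three
ablation stacks (a shallower BiLSTM+LSTM, BiLSTM+BiLSTM, and a single LSTM)
isolate the contribution of each component.

Training minimizes categorical cross-entropy with Adam (learning rate
0.001, batch size 32, 5 epochs by default).  Everything runs on the NumPy
backend in ``_backend``; with a fixed seed runs are exactly reproducible.

An optional decimation factor average-pools the window along time before
the network; full-resolution windows of thousands of steps train slowly on
CPU, and band-power class structure survives moderate pooling.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _backend as B
from .errors import ValidationError
from .segmentation import Segment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a model stack."""

    kind: str  # "bidirectional-recurrent" | "recurrent" | "dropout" | "dense"
    units: int | None = None
    rate: float | None = None
    activation: str | None = None

    def __post_init__(self) -> None:
        if self.kind in ("bidirectional-recurrent", "recurrent", "dense"):
            if not self.units or self.units < 1:
                raise ValidationError(f"{self.kind} layer needs positive units")
        elif self.kind == "dropout":
            if self.rate is None or not (0.0 <= self.rate < 1.0):
                raise ValidationError("dropout layer needs rate in [0, 1)")
        else:
            raise ValidationError(f"unknown layer kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """An ordered layer stack plus the input/output geometry."""

    layers: tuple[LayerSpec, ...]
    n_classes: int
    input_feature_dim: int
    sequence_length: int

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.input_feature_dim < 1 or self.sequence_length < 1:
            raise ValidationError("input dimensions must be positive")
        last = self.layers[-1]
        if last.kind != "dense" or last.activation != "softmax" or last.units != self.n_classes:
            raise ValidationError("final layer must be dense-softmax with n_classes outputs")
        object.__setattr__(self, "layers", tuple(self.layers))

    def to_dict(self) -> dict:
        return {
            "layers": [asdict(l) for l in self.layers],
            "n_classes": self.n_classes,
            "input_feature_dim": self.input_feature_dim,
            "sequence_length": self.sequence_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            layers=tuple(LayerSpec(**l) for l in d["layers"]),
            n_classes=d["n_classes"],
            input_feature_dim=d["input_feature_dim"],
            sequence_length=d["sequence_length"],
        )


def proposed_model(input_feature_dim: int, sequence_length: int, n_classes: int = 2,
                   dropout_rate: float = 0.5) -> ModelSpec:
    """The proposed hybrid stack: BiLSTM(128) -> BiLSTM(64) -> dropout -> LSTM(32) -> softmax."""
    return ModelSpec(
        layers=(
            LayerSpec("bidirectional-recurrent", units=128),
            LayerSpec("bidirectional-recurrent", units=64),
            LayerSpec("dropout", rate=dropout_rate),
            LayerSpec("recurrent", units=32),
            LayerSpec("dense", units=n_classes, activation="softmax"),
        ),
        n_classes=n_classes,
        input_feature_dim=input_feature_dim,
        sequence_length=sequence_length,
    )


#: Ablation stack names -> layer builders (dense-softmax head appended).
_ABLATIONS = {
    "bilstm128-d05-lstm64": (
        LayerSpec("bidirectional-recurrent", units=128),
        LayerSpec("dropout", rate=0.5),
        LayerSpec("recurrent", units=64),
    ),
    "bilstm128-d05-bilstm64": (
        LayerSpec("bidirectional-recurrent", units=128),
        LayerSpec("dropout", rate=0.5),
        LayerSpec("bidirectional-recurrent", units=64),
    ),
    "lstm128-d02": (
        LayerSpec("recurrent", units=128),
        LayerSpec("dropout", rate=0.2),
    ),
}

ABLATION_NAMES: tuple[str, ...] = tuple(_ABLATIONS)


def ablation_models(name: str, input_feature_dim: int = 32, sequence_length: int = 4032,
                    n_classes: int = 2) -> ModelSpec:
    """One of the three ablation stacks, by name, with a softmax head appended."""
    if name not in _ABLATIONS:
        raise ValidationError(
            f"unknown ablation {name!r}; valid names: {', '.join(ABLATION_NAMES)}"
        )
    return ModelSpec(
        layers=(*_ABLATIONS[name], LayerSpec("dense", units=n_classes, activation="softmax")),
        n_classes=n_classes,
        input_feature_dim=input_feature_dim,
        sequence_length=sequence_length,
    )


def model_spec(name: str, input_feature_dim: int, sequence_length: int,
               n_classes: int = 2) -> ModelSpec:
    """Resolve a model by name: "proposed" or an ablation identifier."""
    if name == "proposed":
        return proposed_model(input_feature_dim, sequence_length, n_classes)
    return ablation_models(name, input_feature_dim, sequence_length, n_classes)


def parameter_count(spec: ModelSpec) -> int:
    """Closed-form trainable-parameter count.

    A gated recurrent layer with input width d and h units has
    4*h*(d + h + 1) parameters (four gate blocks of input weights, recurrent
    weights and biases); a bidirectional layer doubles that and outputs 2h
    features per step; a dense layer has d*c + c.
    """
    d = spec.input_feature_dim
    total = 0
    for layer in spec.layers:
        if layer.kind == "recurrent":
            total += 4 * layer.units * (d + layer.units + 1)
            d = layer.units
        elif layer.kind == "bidirectional-recurrent":
            total += 2 * 4 * layer.units * (d + layer.units + 1)
            d = 2 * layer.units
        elif layer.kind == "dense":
            total += d * layer.units + layer.units
            d = layer.units
        # dropout holds no parameters
    return total


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam, lr 0.001, batch 32, 5 epochs by default."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 5
    seed: int = 0
    deterministic_mode: bool = True
    clip_norm: float | None = 5.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("learning_rate, batch_size and epochs must be positive")


class RecurrentClassifier:
    """A built (initialized) model: layers with weights, fit/predict methods.

    The NumPy backend is deterministic: a fixed ``seed`` fixes the weight
    initialization, and ``TrainConfig.seed`` fixes shuffling and dropout, so
    repeated runs are bit-identical (``deterministic_mode`` is recorded for
    interface parity; no nondeterministic kernels exist in this backend).
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.layers: list[B.Layer] = []
        d = spec.input_feature_dim
        n_rec = sum(l.kind.endswith("recurrent") for l in spec.layers)
        seen_rec = 0
        for idx, l in enumerate(spec.layers):
            if l.kind == "bidirectional-recurrent":
                seen_rec += 1
                self.layers.append(B.Bidirectional(
                    d, l.units, rng, return_sequences=seen_rec < n_rec,
                    name=f"L{idx}_bilstm{l.units}"))
                d = 2 * l.units
            elif l.kind == "recurrent":
                seen_rec += 1
                self.layers.append(B.LSTM(
                    d, l.units, rng, return_sequences=seen_rec < n_rec,
                    name=f"L{idx}_lstm{l.units}"))
                d = l.units
            elif l.kind == "dropout":
                self.layers.append(B.Dropout(l.rate, name=f"L{idx}_dropout"))
            elif l.kind == "dense":
                self.layers.append(B.Dense(d, l.units, rng, name=f"L{idx}_dense"))
                d = l.units

    # -- parameter bookkeeping ------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            out.update(layer.parameters())
        return out

    def parameter_tally(self) -> dict[str, int]:
        """Per-weight-matrix sizes — the independent check of the closed form."""
        return {k: int(v.size) for k, v in self.parameters().items()}

    def n_parameters(self) -> int:
        return sum(self.parameter_tally().values())

    # -- forward / training ---------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=B.F32)
        if X.ndim != 3 or X.shape[1:] != (self.spec.sequence_length,
                                          self.spec.input_feature_dim):
            raise ValidationError(
                f"expected input of shape (n, {self.spec.sequence_length}, "
                f"{self.spec.input_feature_dim}), got {X.shape}"
            )
        return X

    def _forward(self, X: np.ndarray, train: bool, rng) -> np.ndarray:
        y = X
        for layer in self.layers:
            y = layer.forward(y, train, rng)
        return y

    def fit(self, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None):
        """Minimize cross-entropy with Adam; returns the per-epoch history.

        ``X`` is (n, sequence_length, input_feature_dim); ``y`` integer class
        indices.  History holds per-epoch mean training loss and accuracy.
        """
        config = config or TrainConfig()
        X = self._check_input(X)
        y = np.asarray(y, dtype=np.int64)
        if y.shape != (X.shape[0],):
            raise ValidationError(f"labels shape {y.shape} does not match {X.shape[0]} inputs")
        if y.min() < 0 or y.max() >= self.spec.n_classes:
            raise ValidationError("labels must be class indices in [0, n_classes)")
        rng = np.random.default_rng(config.seed)
        opt = B.Adam(self.parameters(), learning_rate=config.learning_rate,
                     clip_norm=config.clip_norm)
        history = {"loss": [], "accuracy": []}
        n = X.shape[0]
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            losses, hits = [], 0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                logits = self._forward(X[idx], train=True, rng=rng)
                loss, dlogits = B.softmax_cross_entropy(logits, y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch}")
                hits += int((logits.argmax(axis=1) == y[idx]).sum())
                losses.append(loss * len(idx))
                grad = dlogits
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                grads = {}
                for layer in self.layers:
                    grads.update(layer.gradients())
                opt.step(grads)
            history["loss"].append(sum(losses) / n)
            history["accuracy"].append(hits / n)
            logger.debug("epoch %d: loss %.4f acc %.3f", epoch,
                         history["loss"][-1], history["accuracy"][-1])
        self.history = history
        return history

    def predict_proba(self, X: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Class-probability vectors: non-negative rows summing to 1."""
        X = self._check_input(X)
        out = []
        for start in range(0, X.shape[0], batch_size):
            logits = self._forward(X[start : start + batch_size], train=False, rng=None)
            out.append(B.softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- persistence ----------------------------------------------------------

    def save_weights(self, path) -> None:
        np.savez(Path(path), **self.parameters())

    def load_weights(self, path) -> None:
        with np.load(Path(path)) as f:
            params = self.parameters()
            missing = set(params) - set(f.files)
            if missing:
                raise ValidationError(f"weight file lacks arrays: {sorted(missing)}")
            for k, v in params.items():
                v[...] = f[k]


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
          config: TrainConfig | None = None) -> tuple[RecurrentClassifier, dict]:
    """Build a classifier from ``spec``, fit it, and return (model, history)."""
    config = config or TrainConfig()
    model = RecurrentClassifier(spec, seed=config.seed)
    history = model.fit(X, y, config)
    return model, history


# ---------------------------------------------------------------------------
# Segment batching
# ---------------------------------------------------------------------------


def as_sequence_batch(segments: Sequence[Segment], decimation: int = 1,
                      scale: float = 1.0 / 50.0) -> np.ndarray:
    """Stack segments into a (n, time, channels) float32 batch.

    Segment signals are channels x N; the network wants time-major steps.
    ``decimation`` average-pools along time by that factor (N must divide),
    and ``scale`` maps microvolt-scale amplitudes into the unit range where
    the gate nonlinearities are responsive.  A fixed global scale (rather
    than per-segment normalization) preserves between-class amplitude
    structure.
    """
    if not segments:
        raise ValidationError("cannot batch zero segments")
    n = segments[0].window_size
    if any(s.signal.shape != segments[0].signal.shape for s in segments):
        raise ValidationError("all segments must share the same channels x N shape")
    if decimation < 1 or n % decimation != 0:
        raise ValidationError(
            f"decimation {decimation} must divide the window size {n}"
        )
    X = np.stack([s.signal for s in segments]).astype(B.F32)  # (n, ch, N)
    if decimation > 1:
        ns, ch, _ = X.shape
        X = X.reshape(ns, ch, n // decimation, decimation).mean(axis=3)
    return np.transpose(X, (0, 2, 1)) * B.F32(scale)
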