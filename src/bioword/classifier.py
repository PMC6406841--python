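"""Multi-branch convolutional classifier over concatenated pair vectors.

A protein pair is represented by the concatenation of its two Bio2Vec
sequence vectors (2K components).  A convolution filter of window h slides
over the vector components: c_i = F(w . S_{i:i+h-1}) + b (the bias is added
after the nonlinearity, as the feature-map definition is written), yielding
a feature map of length K - h + 1 that is max-pooled to one scalar per
filter.  Three subnetworks process the pair vector in parallel — the first
applies two convolution+pooling stages, the second and third one each, with
different kernel windows — and linear projections bring their outputs to 64,
32 and 128 features.  The 224-dimensional concatenation passes through
dropout and a fully connected sigmoid unit producing the interaction
probability.

Training minimizes binary cross-entropy with the Nadam optimizer
(Adam with Nesterov momentum), mini-batches of 64, dropout applied during
training only, and early stopping on validation loss; the best-validation
parameter snapshot is returned.  All gradients are hand-derived and verified
against finite differences in the test suite.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "PairFeature", "ConvFilter", "FeatureMap", "ClassifierModel", "ClassifierError",
    "conv_feature_map", "max_pool", "build_classifier", "train_classifier",
    "predict_pairs", "make_pair_feature", "save_model", "load_model",
]


class ClassifierError(ValueError):
    """Raised for invalid architectures, inputs or training sets."""


_NONLINEARITIES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "relu": lambda x: np.maximum(x, 0.0),
    "tanh": np.tanh,
    "identity": lambda x: x,
}


@dataclass(frozen=True)
class PairFeature:
    """A 2K-dim concatenated pair vector with an optional binary label."""

    values: np.ndarray
    label: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 1 or not np.all(np.isfinite(self.values)):
            raise ClassifierError("pair feature must be a finite 1-D vector")
        if self.label is not None and self.label not in (0, 1):
            raise ClassifierError("pair label must be 0, 1 or None")


def make_pair_feature(vec_a: np.ndarray, vec_b: np.ndarray,
                      label: Optional[int] = None) -> PairFeature:
    """Concatenate two sequence vectors into a pair feature."""
    a = np.asarray(vec_a, dtype=np.float64)
    b = np.asarray(vec_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ClassifierError("pair members must share the embedding dimension")
    return PairFeature(np.concatenate([a, b]), label)


@dataclass(frozen=True)
class ConvFilter:
    """A single convolution filter: weights w, bias b, window h, nonlinearity F."""

    weights: np.ndarray
    bias: float
    nonlinearity: str = "relu"

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=np.float64))
        if self.weights.ndim != 1 or len(self.weights) < 1:
            raise ClassifierError("filter weights must be a non-empty 1-D vector")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ClassifierError(f"unknown nonlinearity {self.nonlinearity!r}")

    @property
    def window(self) -> int:
        return len(self.weights)


FeatureMap = np.ndarray


def conv_feature_map(inputs: np.ndarray, filt: ConvFilter) -> FeatureMap:
    """Slide one filter across a K-vector: c_i = F(w . S_{i:i+h-1}) + b."""
    x = np.asarray(inputs, dtype=np.float64)
    if x.ndim != 1:
        raise ClassifierError("conv input must be a 1-D vector")
    h, K = filt.window, len(x)
    if h > K:
        raise ClassifierError(f"filter window {h} exceeds input length {K}")
    windows = np.lib.stride_tricks.sliding_window_view(x, h)
    return _NONLINEARITIES[filt.nonlinearity](windows @ filt.weights) + filt.bias


def max_pool(feature_map: FeatureMap) -> float:
    """The max-over-time feature of one map."""
    fm = np.asarray(feature_map, dtype=np.float64)
    if fm.size == 0:
        raise ClassifierError("cannot max-pool an empty feature map")
    return float(fm.max())


class _ConvPoolStage:
    """f filters of window h over a length-K vector, ReLU, max-pool -> f features."""

    def __init__(self, n_filters: int, window: int, rng: np.random.Generator,
                 fan_in: int):
        scale = math.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, scale, size=(n_filters, window))
        self.b = np.zeros(n_filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: Optional[tuple] = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = self.W.shape[1]
        if X.shape[1] < h:
            raise ClassifierError(
                f"input length {X.shape[1]} is shorter than filter window {h}"
            )
        windows = np.lib.stride_tricks.sliding_window_view(X, h, axis=1)  # (B,P,h)
        Z = windows @ self.W.T  # (B, P, f)
        A = np.maximum(Z, 0.0) + self.b  # c_i = F(w.x) + b
        amax = A.argmax(axis=1)  # (B, f)
        pooled = np.take_along_axis(A, amax[:, None, :], axis=1)[:, 0, :]
        self._cache = (windows, Z, amax, X.shape)
        return pooled

    def backward(self, dY: np.ndarray) -> np.ndarray:
        windows, Z, amax, x_shape = self._cache
        B, P, f = Z.shape
        self.db += dY.sum(axis=0)
        dZ = np.zeros_like(Z)
        b_idx = np.repeat(np.arange(B), f)
        f_idx = np.tile(np.arange(f), B)
        p_idx = amax.ravel()
        relu_gate = (Z[b_idx, p_idx, f_idx] > 0).astype(np.float64)
        dZ[b_idx, p_idx, f_idx] = dY.ravel() * relu_gate
        self.dW += np.einsum("bpf,bph->fh", dZ, windows)
        dX = np.zeros(x_shape)
        h = self.W.shape[1]
        dXw = dZ @ self.W  # (B, P, h)
        for p in range(P):
            dX[:, p : p + h] += dXw[:, p, :]
        return dX

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._X: Optional[np.ndarray] = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._X = X
        return X @ self.W.T + self.b

    def backward(self, dY: np.ndarray) -> np.ndarray:
        self.dW += dY.T @ self._X
        self.db += dY.sum(axis=0)
        return dY @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Relu:
    def __init__(self):
        self._mask: Optional[np.ndarray] = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._mask = X > 0
        return np.maximum(X, 0.0)

    def backward(self, dY: np.ndarray) -> np.ndarray:
        return dY * self._mask

    def params(self):
        return []


class _Nadam:
    """Adam with Nesterov momentum (the Nadam update rule)."""

    def __init__(self, lr: float = 0.002, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] = []
        self.v: list[np.ndarray] = []

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        if not self.m:
            self.m = [np.zeros_like(p) for p, _ in params]
            self.v = [np.zeros_like(p) for p, _ in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** (self.t + 1))
            v_hat = self.v[i] / (1 - b2 ** self.t)
            update = (b1 * m_hat + (1 - b1) * g / (1 - b1 ** self.t))
            p -= self.lr * update / (np.sqrt(v_hat) + self.eps)


@dataclass
class _Subnet:
    stages: list[_ConvPoolStage]
    projection: _Dense
    activation: _Relu

    def forward(self, X: np.ndarray) -> np.ndarray:
        out = X
        for stage in self.stages:
            out = stage.forward(out)
        return self.activation.forward(self.projection.forward(out))

    def backward(self, dY: np.ndarray) -> np.ndarray:
        d = self.projection.backward(self.activation.backward(dY))
        for stage in reversed(self.stages):
            d = stage.backward(d)
        return d

    def params(self):
        out = []
        for stage in self.stages:
            out.extend(stage.params())
        out.extend(self.projection.params())
        return out


@dataclass
class ClassifierModel:
    """The trained multi-branch CNN plus its training state."""

    input_dimension: int
    subnet_widths: tuple[int, ...]
    subnets: list[_Subnet]
    head: _Dense
    dropout_rate: float
    config: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict)

    @property
    def penultimate_width(self) -> int:
        return sum(self.subnet_widths)

    def _forward_logits(self, X: np.ndarray, *, train: bool = False,
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
        feats = np.concatenate([sn.forward(X) for sn in self.subnets], axis=1)
        if train and self.dropout_rate > 0:
            keep = 1.0 - self.dropout_rate
            self._drop_mask = (rng.random(feats.shape) < keep) / keep
            feats = feats * self._drop_mask
        else:
            self._drop_mask = None
        self._feats_shape = [sn.projection.W.shape[0] for sn in self.subnets]
        return self.head.forward(feats)[:, 0]

    def _backward_from_logits(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None])
        if self._drop_mask is not None:
            d = d * self._drop_mask
        offset = 0
        for sn, width in zip(self.subnets, self._feats_shape):
            sn.backward(d[:, offset : offset + width])
            offset += width

    def _params(self):
        out = []
        for sn in self.subnets:
            out.extend(sn.params())
        out.extend(self.head.params())
        return out

    def _zero_grads(self) -> None:
        for _, g in self._params():
            g[...] = 0.0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.input_dimension:
            raise ClassifierError(
                f"expected input of dimension {self.input_dimension}, got shape {X.shape}"
            )
        return _stable_sigmoid(self._forward_logits(X, train=False))


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


#: (filters per conv stage, kernel window) per subnet; subnet 1 has two stages
_DEFAULT_TOPOLOGY = (
    ((32, 3), (16, 3)),
    ((32, 5),),
    ((32, 7),),
)
SUBNET_WIDTHS = (64, 32, 128)


def build_classifier(
    input_dimension: int,
    dropout_rate: float = 0.5,
    random_seed: int = 0,
    subnet_widths: tuple[int, ...] = SUBNET_WIDTHS,
    topology=_DEFAULT_TOPOLOGY,
) -> ClassifierModel:
    """Build the three-subnetwork convolutional model.

    Subnet 1 applies two convolution+pooling stages, subnets 2 and 3 one
    each, with kernel windows 3/5/7 by default; a trainable linear projection
    after the last pooling brings each subnet to its output width (64, 32 and
    128), and the concatenated 224 features feed dropout plus a fully
    connected sigmoid output.
    """
    if input_dimension < 1:
        raise ClassifierError("input dimension must be positive")
    if len(subnet_widths) != len(topology):
        raise ClassifierError("one output width per subnet is required")
    largest_window = max(w for stages in topology for _, w in stages)
    if input_dimension < largest_window:
        raise ClassifierError(
            f"input dimension {input_dimension} is shorter than the largest "
            f"filter window {largest_window}"
        )
    if not (0 <= dropout_rate < 1):
        raise ClassifierError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(random_seed)
    subnets: list[_Subnet] = []
    for stages_spec, width in zip(topology, subnet_widths):
        length = input_dimension
        stages: list[_ConvPoolStage] = []
        for n_filters, window in stages_spec:
            if length < window:
                raise ClassifierError(
                    f"stage input length {length} shorter than window {window}"
                )
            stages.append(_ConvPoolStage(n_filters, window, rng, fan_in=window))
            length = n_filters
        subnets.append(_Subnet(stages, _Dense(length, width, rng), _Relu()))
    head = _Dense(sum(subnet_widths), 1, rng)
    return ClassifierModel(
        input_dimension=input_dimension,
        subnet_widths=tuple(subnet_widths),
        subnets=subnets,
        head=head,
        dropout_rate=dropout_rate,
        config={
            "dropout_rate": dropout_rate,
            "random_seed": random_seed,
            "subnet_widths": list(subnet_widths),
            "topology": [[list(s) for s in stages] for stages in topology],
        },
    )


def _stack_features(features: Sequence[PairFeature], need_labels: bool):
    if not features:
        raise ClassifierError("feature collection must be non-empty")
    dims = {len(f.values) for f in features}
    if len(dims) != 1:
        raise ClassifierError(f"inconsistent feature dimensions {sorted(dims)}")
    X = np.stack([f.values for f in features])
    if not need_labels:
        return X, None
    if any(f.label is None for f in features):
        raise ClassifierError("training requires a label on every pair feature")
    y = np.array([f.label for f in features], dtype=np.float64)
    return X, y


def _batch_loss_and_grads(model: ClassifierModel, X: np.ndarray, y: np.ndarray,
                          *, train: bool, rng: Optional[np.random.Generator]) -> float:
    model._zero_grads()
    logits = model._forward_logits(X, train=train, rng=rng)
    p = _stable_sigmoid(logits)
    eps = 1e-12
    loss = -float(np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    model._backward_from_logits((p - y) / len(y))
    return loss


def _validation_loss(model: ClassifierModel, X: np.ndarray, y: np.ndarray) -> float:
    p = model.predict_proba(X)
    eps = 1e-12
    return -float(np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def train_classifier(
    features: Sequence[PairFeature],
    validation: Sequence[PairFeature],
    dropout_rate: float = 0.5,
    batch_size: int = 64,
    learning_rate: float = 0.002,
    max_epochs: int = 200,
    patience: int = 10,
    random_seed: int = 0,
    model: Optional[ClassifierModel] = None,
) -> ClassifierModel:
    """Train the pair classifier with Nadam, dropout and early stopping.

    Minimizes binary cross-entropy in mini-batches (default 64) with dropout
    active during training only.  Training stops when the validation loss
    has not improved for *patience* epochs (or at *max_epochs*) and the
    best-validation parameter snapshot is restored.  Reproducible given
    *random_seed*.
    """
    X_train, y_train = _stack_features(features, need_labels=True)
    X_val, y_val = _stack_features(validation, need_labels=True)
    if X_train.shape[1] != X_val.shape[1]:
        raise ClassifierError("training and validation dimensions differ")
    if len(np.unique(y_train)) < 2:
        raise ClassifierError("training set contains a single class")
    if model is None:
        model = build_classifier(X_train.shape[1], dropout_rate=dropout_rate,
                                 random_seed=random_seed)
    elif model.input_dimension != X_train.shape[1]:
        raise ClassifierError("model input dimension does not match the features")

    rng = np.random.default_rng(random_seed + 1)
    optimizer = _Nadam(lr=learning_rate)
    n = len(X_train)
    best_val = math.inf
    best_state = None
    stale = 0
    train_losses: list[float] = []
    val_losses: list[float] = []
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            batch = order[start : start + batch_size]
            loss = _batch_loss_and_grads(model, X_train[batch], y_train[batch],
                                         train=True, rng=rng)
            optimizer.step(model._params())
            epoch_loss += loss
            n_batches += 1
        val_loss = _validation_loss(model, X_val, y_val)
        train_losses.append(epoch_loss / n_batches)
        val_losses.append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = copy.deepcopy([p for p, _ in model._params()])
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    if best_state is not None:
        for (p, _), saved in zip(model._params(), best_state):
            p[...] = saved
    model.history = {
        "train_loss": train_losses,
        "val_loss": val_losses,
        "best_val_loss": best_val,
        "epochs_run": len(train_losses),
    }
    model.config.update({
        "batch_size": batch_size,
        "learning_rate": learning_rate,
        "max_epochs": max_epochs,
        "patience": patience,
        "train_seed": random_seed,
    })
    return model


def predict_pairs(
    model: ClassifierModel, features: Sequence[PairFeature]
) -> np.ndarray:
    """Interaction probabilities for each pair (dropout disabled)."""
    X, _ = _stack_features(features, need_labels=False)
    return model.predict_proba(X)


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Serialize the model (parameters + config echo) to a single .npz file."""
    arrays: dict[str, np.ndarray] = {}
    for i, (p, _) in enumerate(model._params()):
        arrays[f"param_{i}"] = p
    meta = dict(model.config)
    meta["input_dimension"] = model.input_dimension
    meta["history"] = model.history
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path) -> ClassifierModel:
    data = np.load(path)
    meta = json.loads(bytes(data["_meta"]).decode())
    topology = tuple(tuple(tuple(s) for s in stages) for stages in meta["topology"])
    model = build_classifier(
        meta["input_dimension"],
        dropout_rate=meta["dropout_rate"],
        random_seed=meta.get("random_seed", 0),
        subnet_widths=tuple(meta["subnet_widths"]),
        topology=topology,
    )
    for i, (p, _) in enumerate(model._params()):
        p[...] = data[f"param_{i}"]
    model.config = {k: v for k, v in meta.items() if k not in ("history", "input_dimension")}
    model.history = meta.get("history", {})
    return model
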