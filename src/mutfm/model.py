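"""Three-branch classifier for sparse binary mutation vectors.

The network maps a binary feature vector ``x`` of length N to class logits by
summing three branches:

* **wide** — a linear layer ``W x + b`` capturing marginal (single-gene)
  effects;
* **fm** — a factorization machine: every feature i carries a latent vector
  ``v_i`` of dimension K, and second-order interactions enter through
  ``sum_{i<j} <v_i, v_j> x_i x_j``, computed in O(NK) via the sum-of-squares
  identity.  The K per-component interaction terms are projected to the C
  class logits by a learned linear map (``fm_mode="per_class"``).  A literal
  scalar mode is also provided in which the single interaction sum is added
  to every logit — softmax is invariant to that shift, so the scalar variant
  cannot affect predictions; it exists to document that degeneracy.
* **deep** — the same embeddings sum-pooled to a K-vector and passed through
  an MLP (ReLU + dropout) ending in a C-unit linear head, capturing
  higher-order structure.

Logits from enabled branches are summed and softmax-normalised.  All
computation is plain NumPy; gradients live in :mod:`mutfm.training`.
"""

from __future__ import annotations


import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "ModelConfig",
    "ModelParams",
    "PredictionBatch",
    "init_params",
    "forward_linear",
    "fm_interaction_vector",
    "forward_fm",
    "forward_deep",
    "forward",
    "softmax",
    "save_checkpoint",
    "load_checkpoint",
]

VALID_BRANCHES = ("wide", "fm", "deep")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults mirror the reference configuration: 244 input genes, 4 subtype
    classes, embedding dimension K=4, MLP hidden sizes (64, 32), dropout 0.5.
    """

    n_features: int = 244
    n_classes: int = 4
    embedding_dim: int = 4
    hidden_sizes: tuple[int, ...] = (64, 32)
    dropout_rate: float = 0.5
    fm_mode: str = "per_class"  # or "scalar"
    branches: tuple[str, ...] = ("wide", "fm", "deep")

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        self.branches = tuple(self.branches)
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if not self.branches:
            raise ValueError("at least one branch must be enabled")
        bad = set(self.branches) - set(VALID_BRANCHES)
        if bad:
            raise ValueError(f"unknown branch(es): {sorted(bad)}")
        if self.fm_mode not in ("per_class", "scalar"):
            raise ValueError(f"fm_mode must be 'per_class' or 'scalar', got {self.fm_mode}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["branches"] = list(self.branches)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        return cls(**dict(d))


@dataclass
class ModelParams:
    """All weights of the three-branch model.

    ``W_linear`` (C x N) and ``b`` (C) belong to the wide branch; ``V``
    (N x K) holds the latent vector of every feature, shared by the FM and
    deep branches; ``fm_projection`` (C x K) maps FM interaction components
    to class logits in per-class mode; ``mlp_weights``/``mlp_biases`` are the
    dense layers K -> hidden... -> C.
    """

    W_linear: np.ndarray
    b: np.ndarray
    V: np.ndarray
    fm_projection: np.ndarray
    mlp_weights: list[np.ndarray]
    mlp_biases: list[np.ndarray]

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.W_linear.copy(),
            self.b.copy(),
            self.V.copy(),
            self.fm_projection.copy(),
            [w.copy() for w in self.mlp_weights],
            [b.copy() for b in self.mlp_biases],
        )

    def named_arrays(self) -> list[tuple[str, np.ndarray]]:
        out = [
            ("W_linear", self.W_linear),
            ("b", self.b),
            ("V", self.V),
            ("fm_projection", self.fm_projection),
        ]
        for i, (w, bb) in enumerate(zip(self.mlp_weights, self.mlp_biases)):
            out.append((f"mlp_w{i}", w))
            out.append((f"mlp_b{i}", bb))
        return out

    def validate(self, config: ModelConfig) -> None:
        n, c, k = config.n_features, config.n_classes, config.embedding_dim
        if self.W_linear.shape != (c, n):
            raise ValueError(f"W_linear shape {self.W_linear.shape} != {(c, n)}")
        if self.b.shape != (c,):
            raise ValueError(f"b shape {self.b.shape} != {(c,)}")
        if self.V.shape != (n, k):
            raise ValueError(f"V shape {self.V.shape} != {(n, k)}")
        if self.fm_projection.shape != (c, k):
            raise ValueError(f"fm_projection shape {self.fm_projection.shape} != {(c, k)}")
        sizes = [k, *config.hidden_sizes, c]
        for i, (w, bb) in enumerate(zip(self.mlp_weights, self.mlp_biases)):
            if w.shape != (sizes[i], sizes[i + 1]) or bb.shape != (sizes[i + 1],):
                raise ValueError(f"MLP layer {i} has inconsistent shape {w.shape}")
        for name, a in self.named_arrays():
            if not np.isfinite(a).all():
                raise ValueError(f"non-finite values in {name}")


@dataclass
class PredictionBatch:
    """Logits, softmax probabilities and argmax class indices for a batch."""

    logits: np.ndarray
    probabilities: np.ndarray
    predicted_class: np.ndarray


def init_params(config: ModelConfig, rng: np.random.Generator) -> ModelParams:
    """Seeded initialisation: N(0, 0.01) embeddings, fan-in-scaled uniform
    dense layers (Kaiming-style bound sqrt(1/fan_in)), zero biases."""
    n, c, k = config.n_features, config.n_classes, config.embedding_dim

    def dense(fan_in: int, fan_out: int) -> np.ndarray:
        bound = np.sqrt(1.0 / fan_in)
        return rng.uniform(-bound, bound, size=(fan_in, fan_out))

    W_linear = np.ascontiguousarray(dense(n, c).T)
    b = np.zeros(c)
    V = rng.normal(0.0, 0.01, size=(n, k))
    fm_projection = np.ascontiguousarray(dense(k, c).T)
    sizes = [k, *config.hidden_sizes, c]
    mlp_weights = [dense(sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]
    mlp_biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    return ModelParams(W_linear, b, V, fm_projection, mlp_weights, mlp_biases)


def _as_batch(x: np.ndarray, n_features: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != n_features:
        raise ValueError(f"expected (*, {n_features}) input, got shape {x.shape}")
    return x


def validate_binary(x: np.ndarray) -> np.ndarray:
    """Reject inputs that are not exactly 0/1."""
    x = np.asarray(x, dtype=np.float64)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("input vectors must be binary (entries 0 or 1)")
    return x


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward_linear(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Wide branch: affine map ``W x + b`` -> per-class logits."""
    single = np.asarray(x).ndim == 1
    x = _as_batch(x, params.W_linear.shape[1])
    out = x @ params.W_linear.T + params.b
    return out[0] if single else out


def fm_interaction_vector(x: np.ndarray, V: np.ndarray) -> np.ndarray:
    """K-vector of pairwise interaction components.

    Component k is  0.5 * [(sum_i x_i v_ik)^2 - sum_i x_i^2 v_ik^2]; summing
    over k gives exactly sum_{i<j} <v_i, v_j> x_i x_j.
    """
    single = np.asarray(x).ndim == 1
    x = _as_batch(x, V.shape[0])
    s = x @ V
    q = (x * x) @ (V * V)
    f = 0.5 * (s * s - q)
    return f[0] if single else f


def forward_fm(x: np.ndarray, params: ModelParams, config: ModelConfig) -> np.ndarray:
    """FM branch logits: projected interaction vector, or broadcast scalar."""
    single = np.asarray(x).ndim == 1
    f = np.atleast_2d(fm_interaction_vector(x, params.V))
    if config.fm_mode == "per_class":
        out = f @ params.fm_projection.T
    else:  # scalar: the single interaction sum added to every class logit
        out = np.repeat(f.sum(axis=1, keepdims=True), config.n_classes, axis=1)
    return out[0] if single else out


def forward_deep(
    x: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Deep branch: sum-pooled embedding -> MLP with ReLU and dropout.

    Dropout (inverted, rate ``config.dropout_rate``) is applied after each
    hidden activation only when ``training_mode`` is true; inference is
    deterministic.
    """
    single = np.asarray(x).ndim == 1
    x = _as_batch(x, params.V.shape[0])
    h = x @ params.V  # sum-pooled embedding, batch x K
    n_layers = len(params.mlp_weights)
    if training_mode and config.dropout_rate > 0 and rng is None:
        rng = np.random.default_rng()
    for i, (w, b) in enumerate(zip(params.mlp_weights, params.mlp_biases)):
        h = h @ w + b
        if i < n_layers - 1:  # hidden layers: ReLU (+ dropout); head is linear
            h = np.maximum(h, 0.0)
            if training_mode and config.dropout_rate > 0:
                keep = 1.0 - config.dropout_rate
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
    return h[0] if single else h


def forward(
    x_batch: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> PredictionBatch:
    """Full forward pass: sum enabled branch logits, softmax-normalise."""
    x = validate_binary(x_batch)
    x = _as_batch(x, config.n_features)
    logits = np.zeros((x.shape[0], config.n_classes))
    if "wide" in config.branches:
        logits += np.atleast_2d(forward_linear(x, params))
    if "fm" in config.branches:
        logits += np.atleast_2d(forward_fm(x, params, config))
    if "deep" in config.branches:
        logits += np.atleast_2d(
            forward_deep(x, params, config, training_mode=training_mode, rng=rng)
        )
    probs = softmax(logits)
    return PredictionBatch(
        logits=logits, probabilities=probs, predicted_class=probs.argmax(axis=1)
    )


def save_checkpoint(
    path: str | Path, params: ModelParams, config: ModelConfig, extra: Mapping | None = None
) -> None:
    """Single-file portable checkpoint: JSON header + text-encoded arrays.

    Arrays are stored at full float64 precision so a round-trip restores
    bit-identical inference.
    """
    header = {"config": config.to_dict(), "extra": dict(extra or {})}
    arrays = {}
    for name, a in params.named_arrays():
        arrays[name] = {"shape": list(a.shape), "data": [float(v) for v in a.ravel()]}
    payload = {"header": header, "arrays": arrays}
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelConfig, dict]:
    payload = json.loads(Path(path).read_text())
    config = ModelConfig.from_dict(payload["header"]["config"])

    def arr(name: str) -> np.ndarray:
        a = payload["arrays"][name]
        return np.asarray(a["data"], dtype=np.float64).reshape(a["shape"])

    n_layers = len(config.hidden_sizes) + 1
    params = ModelParams(
        W_linear=arr("W_linear"),
        b=arr("b"),
        V=arr("V"),
        fm_projection=arr("fm_projection"),
        mlp_weights=[arr(f"mlp_w{i}") for i in range(n_layers)],
        mlp_biases=[arr(f"mlp_b{i}") for i in range(n_layers)],
    )
    params.validate(config)
    return params, config, payload["header"]["extra"]
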