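"""Training recipe and scikit-learn estimator for the three-branch model.

Optimisation follows a fixed recipe: Adam (lr 1e-3, betas 0.9/0.999),
mini-batches of 64 drawn *with replacement* with probability proportional to
inverse class frequency (so every class is expected uniformly in each batch
without altering the loss), plain unweighted cross-entropy, L2 weight decay
1e-3 on the wide weights, the FM projection and the MLP weights (not on
embeddings or biases), learning-rate halving when the validation loss
plateaus for 10 epochs, and early stopping with the same patience.  The
parameters with the best validation loss are retained.

Gradients are derived by hand and computed in NumPy; they are checked
against finite differences in the test suite.  All randomness (validation
split, initialisation, sampling, dropout) derives from a single seed through
named sub-streams, so a run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .evaluation import EvaluationReport, evaluate_probabilities
from .feature_selection import PathwayCollection, select_pathway_representatives
from .maf_io import BinaryMutationMatrix
from .model import (
    ModelConfig,
    ModelParams,
    forward,
    init_params,
    softmax,
    validate_binary,
)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "FoldAssignment",
    "inverse_frequency_weights",
    "make_stratified_folds",
    "train",
    "cross_validate",
    "WideDeepFMClassifier",
]

_SUBSTREAMS = ("init", "sampler", "dropout", "val_split", "folds")


def substream_seeds(seed: int) -> dict[str, int]:
    """Named child seeds (all < 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_SUBSTREAMS))
    return {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(_SUBSTREAMS, children)
    }


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults are the reference recipe)."""

    lr: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    weight_decay: float = 1e-3
    lr_decay_factor: float = 0.5
    lr_patience: int = 10
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 300
    seed: int = 0
    val_fraction: float = 0.1
    weighted_sampling: bool = True  # False: uniform mini-batch sampling

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        for name in ("lr", "batch_size", "max_epochs", "lr_patience", "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.adam_betas = tuple(self.adam_betas)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["adam_betas"] = list(self.adam_betas)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrainConfig":
        return cls(**dict(d))


@dataclass
class TrainHistory:
    """Per-epoch losses and learning rate, plus stopping diagnostics."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "lr": self.lr,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class FoldAssignment:
    """Mapping from sample index to cross-validation fold id."""

    fold_of_sample: np.ndarray
    k: int

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)

    def to_tsv(self, path: str | Path, sample_ids: Sequence[str] | None = None) -> None:
        ids = (
            list(sample_ids)
            if sample_ids is not None
            else [str(i) for i in range(len(self.fold_of_sample))]
        )
        pd.DataFrame({"sample_id": ids, "fold": self.fold_of_sample}).to_csv(
            path, sep="\t", index=False
        )


def inverse_frequency_weights(labels: Sequence) -> np.ndarray:
    """Per-sample weight 1 / count(class of sample); unnormalised.

    Sampling with replacement proportional to these weights makes every
    class equally likely in expectation within a mini-batch.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    _, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    return 1.0 / counts[inv]


def make_stratified_folds(labels: Sequence, k: int, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold partition (class proportions preserved per fold)."""
    labels = np.asarray(labels)
    n = labels.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples n={n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    fold_of_sample = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        fold_of_sample[test_idx] = fold
    return FoldAssignment(fold_of_sample=fold_of_sample, k=k)


# ---------------------------------------------------------------------------
# forward/backward and Adam


def _forward_cache(
    X: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    training_mode: bool,
    dropout_rng: np.random.Generator | None,
) -> tuple[np.ndarray, dict]:
    """Batch forward pass retaining intermediates needed for backprop."""
    cache: dict = {"X": X}
    B = X.shape[0]
    logits = np.zeros((B, config.n_classes))
    S = X @ params.V  # batch x K; FM sum term and pooled embedding
    cache["S"] = S
    if "wide" in config.branches:
        logits += X @ params.W_linear.T + params.b
    if "fm" in config.branches:
        Q = X @ (params.V * params.V)  # x binary: x_i^2 = x_i
        F = 0.5 * (S * S - Q)
        cache["F"] = F
        if config.fm_mode == "per_class":
            logits += F @ params.fm_projection.T
        else:
            logits += F.sum(axis=1, keepdims=True)
    if "deep" in config.branches:
        h = S
        acts, masks = [], []
        n_layers = len(params.mlp_weights)
        keep = 1.0 - config.dropout_rate
        for i, (w, bb) in enumerate(zip(params.mlp_weights, params.mlp_biases)):
            a = h @ w + bb
            if i < n_layers - 1:
                r = np.maximum(a, 0.0)
                if training_mode and config.dropout_rate > 0:
                    mask = (dropout_rng.random(r.shape) < keep) / keep
                else:
                    mask = np.ones_like(r)
                acts.append((h, a))
                masks.append(mask)
                h = r * mask
            else:
                acts.append((h, a))
                h = a
        logits += h
        cache["acts"] = acts
        cache["masks"] = masks
    return logits, cache


def _zero_grads(params: ModelParams) -> dict[str, np.ndarray]:
    g = {name: np.zeros_like(a) for name, a in params.named_arrays()}
    return g


def _backward(
    G: np.ndarray, params: ModelParams, config: ModelConfig, cache: dict
) -> dict[str, np.ndarray]:
    """Backpropagate dLoss/dlogits ``G`` (batch x C) through enabled branches."""
    X = cache["X"]
    S = cache["S"]
    grads = _zero_grads(params)
    dS = np.zeros_like(S)
    if "wide" in config.branches:
        grads["W_linear"] += G.T @ X
        grads["b"] += G.sum(axis=0)
    if "fm" in config.branches:
        F = cache["F"]
        if config.fm_mode == "per_class":
            grads["fm_projection"] += G.T @ F
            dF = G @ params.fm_projection
        else:
            dF = np.repeat(G.sum(axis=1, keepdims=True), F.shape[1], axis=1)
        # F_k = 0.5 (S_k^2 - Q_k), S = X V, Q = X (V*V)
        dS += dF * S
        grads["V"] += -(X.T @ dF) * params.V  # Q path: dQ = -0.5 dF, dV = 2V X^T dQ
    if "deep" in config.branches:
        acts, masks = cache["acts"], cache["masks"]
        n_layers = len(params.mlp_weights)
        d = G
        for i in range(n_layers - 1, -1, -1):
            h_in, a = acts[i]
            if i < n_layers - 1:  # hidden layer: undo dropout mask, then ReLU
                d = d * masks[i] * (a > 0)
            grads[f"mlp_w{i}"] += h_in.T @ d
            grads[f"mlp_b{i}"] += d.sum(axis=0)
            d = d @ params.mlp_weights[i].T
        dS += d
    grads["V"] += X.T @ dS
    return grads


def batch_loss_and_grads(
    X: np.ndarray,
    y_codes: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    training_mode: bool = True,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy over the batch and gradients w.r.t. all params."""
    B = X.shape[0]
    logits, cache = _forward_cache(X, params, config, training_mode, dropout_rng)
    probs = softmax(logits)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(B), y_codes] + eps)))
    G = probs.copy()
    G[np.arange(B), y_codes] -= 1.0
    G /= B
    return loss, _backward(G, params, config, cache)


def _mean_ce(
    X: np.ndarray, y_codes: np.ndarray, params: ModelParams, config: ModelConfig
) -> float:
    logits, _ = _forward_cache(X, params, config, training_mode=False, dropout_rng=None)
    probs = softmax(logits)
    return float(-np.mean(np.log(probs[np.arange(len(y_codes)), y_codes] + 1e-12)))


class _Adam:
    """Adam with per-array L2 weight decay added to the gradient."""

    def __init__(self, params: ModelParams, config: "TrainConfig", decayed: set[str]):
        self.lr = config.lr
        self.b1, self.b2 = config.adam_betas
        self.eps = config.adam_eps
        self.wd = config.weight_decay
        self.decayed = decayed
        self.m = {n: np.zeros_like(a) for n, a in params.named_arrays()}
        self.v = {n: np.zeros_like(a) for n, a in params.named_arrays()}
        self.t = 0

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, arr in params.named_arrays():
            g = grads[name]
            if name in self.decayed and self.wd > 0:
                g = g + self.wd * arr
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * (g * g)
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _decayed_arrays(params: ModelParams, config: ModelConfig) -> set[str]:
    """L2 targets: wide weights, FM projection, MLP weights of enabled
    branches; embeddings V and all biases are exempt."""
    decayed: set[str] = set()
    if "wide" in config.branches:
        decayed.add("W_linear")
    if "fm" in config.branches and config.fm_mode == "per_class":
        decayed.add("fm_projection")
    if "deep" in config.branches:
        decayed.update(f"mlp_w{i}" for i in range(len(params.mlp_weights)))
    return decayed


def train(
    train_matrix: np.ndarray | BinaryMutationMatrix,
    train_labels: Sequence,
    config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
) -> tuple[ModelParams, TrainHistory]:
    """Fit the model with the full recipe; returns best-validation params.

    A stratified ``val_fraction`` carve-out of the training data drives both
    the plateau LR scheduler and early stopping (independent patience
    counters; the scheduler is consulted first each epoch).  An epoch is
    ``ceil(n / batch_size)`` weighted draws with replacement.
    """
    config = config or TrainConfig()
    X = train_matrix.values if isinstance(train_matrix, BinaryMutationMatrix) else train_matrix
    X = validate_binary(np.asarray(X, dtype=np.float64))
    y = np.asarray(train_labels)
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    if model_config is None:
        model_config = ModelConfig(n_features=X.shape[1], n_classes=len(classes))
    if model_config.n_features != X.shape[1]:
        raise ValueError(
            f"model expects {model_config.n_features} features, matrix has {X.shape[1]}"
        )

    seeds = substream_seeds(config.seed)
    idx_tr, idx_val = train_test_split(
        np.arange(X.shape[0]),
        test_size=config.val_fraction,
        stratify=y_codes,
        random_state=seeds["val_split"],
    )
    X_tr, y_tr = X[idx_tr], y_codes[idx_tr]
    X_val, y_val = X[idx_val], y_codes[idx_val]

    rng_init = np.random.default_rng(seeds["init"])
    rng_sampler = np.random.default_rng(seeds["sampler"])
    rng_dropout = np.random.default_rng(seeds["dropout"])
    params = init_params(model_config, rng_init)
    opt = _Adam(params, config, _decayed_arrays(params, model_config))

    if config.weighted_sampling:
        w = inverse_frequency_weights(y_tr)
        p = w / w.sum()
    else:
        p = np.full(len(y_tr), 1.0 / len(y_tr))
    n_tr = X_tr.shape[0]
    batches_per_epoch = int(np.ceil(n_tr / config.batch_size))

    history = TrainHistory()
    best_val = np.inf
    best_params = params.copy()
    best_epoch = 0
    lr_wait = 0
    stop_wait = 0
    for epoch in range(config.max_epochs):
        losses = []
        for _ in range(batches_per_epoch):
            take = rng_sampler.choice(n_tr, size=min(config.batch_size, n_tr), p=p)
            loss, grads = batch_loss_and_grads(
                X_tr[take],
                y_tr[take],
                params,
                model_config,
                training_mode=True,
                dropout_rng=rng_dropout,
            )
            opt.step(params, grads)
            losses.append(loss)
        val_loss = _mean_ce(X_val, y_val, params, model_config)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.lr.append(opt.lr)

        improved = val_loss < best_val - config.early_stop_min_delta
        if improved:
            best_val = val_loss
            best_params = params.copy()
            best_epoch = epoch
            lr_wait = 0
            stop_wait = 0
        else:
            # scheduler first, then early stopper (independent counters)
            lr_wait += 1
            if lr_wait > config.lr_patience:
                opt.lr *= config.lr_decay_factor
                lr_wait = 0
            stop_wait += 1
            if stop_wait > config.early_stop_patience:
                history.stopped_early = True
                break
    history.best_epoch = best_epoch
    return best_params, history


def cross_validate(
    matrix: np.ndarray | BinaryMutationMatrix,
    labels: Sequence,
    k: int = 5,
    config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    pathways: PathwayCollection | None = None,
    threshold: float = 0.005,
    reselect_per_fold: bool = True,
) -> tuple[list[EvaluationReport], dict[str, tuple[float, float]], FoldAssignment]:
    """Stratified k-fold cross-validation of the full pipeline.

    When a pathway collection is supplied, feature selection is re-run on
    each fold's training partition (strict leakage control; set
    ``reselect_per_fold=False`` to select once on all training folds'
    union — still never on the held-out fold of another split).  Returns the
    per-fold reports, {metric: (mean, sd)} aggregates, and the fold map.
    """
    config = config or TrainConfig()
    is_bmm = isinstance(matrix, BinaryMutationMatrix)
    X_full = matrix.values if is_bmm else np.asarray(matrix)
    y = np.asarray(labels)
    classes = sorted(map(str, np.unique(y)))
    folds = make_stratified_folds(y, k, seed=substream_seeds(config.seed)["folds"])

    reports: list[EvaluationReport] = []
    for fold in range(k):
        test_idx = folds.indices(fold)
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        fold_cfg = TrainConfig.from_dict({**config.to_dict(), "seed": config.seed + fold})
        if pathways is not None:
            if not is_bmm:
                raise ValueError("pathway-based selection requires a BinaryMutationMatrix")
            sub = matrix.subset_samples(train_idx)
            fs = select_pathway_representatives(sub, y[train_idx], pathways, threshold)
            cols = [matrix.gene_ids.index(g) for g in fs.genes]
            X_tr, X_te = X_full[np.ix_(train_idx, cols)], X_full[np.ix_(test_idx, cols)]
            mc = ModelConfig.from_dict(
                {
                    **(model_config.to_dict() if model_config else ModelConfig().to_dict()),
                    "n_features": len(cols),
                    "n_classes": len(classes),
                }
            )
        else:
            X_tr, X_te = X_full[train_idx], X_full[test_idx]
            mc = model_config
        params, _ = train(X_tr, y[train_idx], fold_cfg, mc)
        mc_used = mc if mc is not None else ModelConfig(
            n_features=X_tr.shape[1], n_classes=len(np.unique(y[train_idx]))
        )
        pred = forward(X_te, params, mc_used, training_mode=False)
        fold_classes = sorted(map(str, np.unique(y[train_idx])))
        reports.append(
            evaluate_probabilities(y[test_idx].astype(str), pred.probabilities, fold_classes)
        )

    agg: dict[str, tuple[float, float]] = {}
    keys = ("accuracy", "macro_precision", "macro_recall", "macro_f1", "macro_auc_ovr")
    for key in keys:
        vals = np.array([r.as_flat_dict().get(key, np.nan) for r in reports], dtype=float)
        vals = vals[np.isfinite(vals)]
        agg[key] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return reports, agg, folds


class WideDeepFMClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn classifier wrapping the three-branch model and recipe.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`;
    ``branches`` selects architecture ablations (e.g. ``("wide",)`` is exactly
    multinomial logistic regression).  Inputs must be binary 0/1 arrays.

    Examples
    --------
    >>> clf = WideDeepFMClassifier(max_epochs=30, random_state=0)
    >>> clf.fit(X_train, y_train).score(X_test, y_test)  # doctest: +SKIP
    """

    def __init__(
        self,
        embedding_dim: int = 4,
        hidden_sizes: tuple[int, ...] = (64, 32),
        dropout_rate: float = 0.5,
        fm_mode: str = "per_class",
        branches: tuple[str, ...] = ("wide", "fm", "deep"),
        lr: float = 1e-3,
        weight_decay: float = 1e-3,
        lr_decay_factor: float = 0.5,
        lr_patience: int = 10,
        early_stop_patience: int = 10,
        early_stop_min_delta: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 300,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.hidden_sizes = hidden_sizes
        self.dropout_rate = dropout_rate
        self.fm_mode = fm_mode
        self.branches = branches
        self.lr = lr
        self.weight_decay = weight_decay
        self.lr_decay_factor = lr_decay_factor
        self.lr_patience = lr_patience
        self.early_stop_patience = early_stop_patience
        self.early_stop_min_delta = early_stop_min_delta
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _configs(self, n_features: int, n_classes: int) -> tuple[ModelConfig, TrainConfig]:
        mc = ModelConfig(
            n_features=n_features,
            n_classes=n_classes,
            embedding_dim=self.embedding_dim,
            hidden_sizes=tuple(self.hidden_sizes),
            dropout_rate=self.dropout_rate,
            fm_mode=self.fm_mode,
            branches=tuple(self.branches),
        )
        tc = TrainConfig(
            lr=self.lr,
            weight_decay=self.weight_decay,
            lr_decay_factor=self.lr_decay_factor,
            lr_patience=self.lr_patience,
            early_stop_patience=self.early_stop_patience,
            early_stop_min_delta=self.early_stop_min_delta,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            val_fraction=self.val_fraction,
            seed=self.random_state,
        )
        return mc, tc

    def fit(self, X, y):
        X = X.values if isinstance(X, BinaryMutationMatrix) else np.asarray(X)
        X = validate_binary(np.asarray(X, dtype=np.float64))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        mc, tc = self._configs(X.shape[1], len(self.classes_))
        self.config_ = mc
        self.params_, self.history_ = train(X, y, tc, mc)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        X = X.values if isinstance(X, BinaryMutationMatrix) else np.asarray(X)
        pred = forward(
            np.asarray(X, dtype=np.float64), self.params_, self.config_, training_mode=False
        )
        return pred.probabilities

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
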