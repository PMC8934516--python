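"""Semi-supervised graph convolutional network for interface residues.

The model is the two-hidden-layer spectral GCN of Kipf & Welling applied
transductively to a block-diagonal residue graph. Each layer propagates

    Z(h+1) = sigma( A_hat Z(h) W(h) ),      A_hat = D^(-1/2) (A + I) D^(-1/2)

with ReLU activations on the two hidden layers (35 and 32 units), a 2-unit
softmax output head, and dropout 0.5 on layer inputs during training.
Training is full-batch gradient descent (learning rate 0.001, at most 1500
epochs) on the mean cross-entropy over *training-mask nodes only*; the
validation loss is monitored every epoch and training stops early once it
has not improved for ``patience`` consecutive epochs, restoring the
parameters of the best validation epoch.

Two degree conventions for D in the normalization are supported: the
``weighted`` row-sum of A + I (default — the graph weights are real-valued)
and the ``unweighted`` count of incident edges plus one. They coincide on
binary adjacencies.

Everything is implemented directly over numpy / scipy.sparse with analytic
gradients, so the backward pass can be verified against finite differences.
The scikit-learn estimator :class:`GCNInterfaceClassifier` is the primary
interface; :func:`train` / :func:`predict` are thin functional wrappers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin

from .dataset import MaskedDataset

logger = logging.getLogger(__name__)

DegreeMode = Literal["weighted", "unweighted"]


class GCNConfigError(ValueError):
    """Raised on invalid configuration or shape mismatches."""


@dataclass
class GCNConfig:
    """Hyperparameters of the classifier (defaults are the reference setup)."""

    hidden_sizes: tuple[int, int] = (35, 32)
    learning_rate: float = 0.001
    dropout: float = 0.5
    max_epochs: int = 1500
    patience: int = 50
    seed: int = 0
    degree_mode: DegreeMode = "weighted"
    use_bias: bool = False
    class_weight: Literal["balanced"] | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise GCNConfigError("learning_rate must be > 0")
        if not 0 <= self.dropout < 1:
            raise GCNConfigError("dropout must be in [0, 1)")
        if self.max_epochs < 1:
            raise GCNConfigError("max_epochs must be >= 1")


@dataclass
class GCNParams:
    """Layer weight matrices (and optional biases), input to output order."""

    weights: list[np.ndarray]
    biases: list[np.ndarray] | None = None

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0],) + tuple(w.shape[1] for w in self.weights)


@dataclass
class TrainHistory:
    """Per-epoch training diagnostics."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def normalize_adjacency(
    A: sp.spmatrix | np.ndarray, degree_mode: DegreeMode = "weighted"
) -> sp.csr_matrix:
    """Symmetric normalization D^(-1/2) (A + I) D^(-1/2).

    ``weighted`` uses the row sums of A + I as degrees; ``unweighted`` uses
    the number of nonzero entries of each row of A + I (incident edges plus
    the self-loop). A + I guarantees every degree is at least 1, so no node
    is isolated.
    """
    A = sp.csr_matrix(A, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise GCNConfigError(f"adjacency must be square, got {A.shape}")
    if (abs(A - A.T) > 1e-12).nnz:
        raise GCNConfigError("adjacency must be symmetric")
    if A.nnz and A.data.min() < 0:
        raise GCNConfigError("adjacency must be nonnegative")
    A_tilde = (A + sp.identity(A.shape[0], format="csr")).tocsr()
    if degree_mode == "weighted":
        degrees = np.asarray(A_tilde.sum(axis=1)).ravel()
    elif degree_mode == "unweighted":
        degrees = np.diff(A_tilde.indptr).astype(float)
    else:
        raise GCNConfigError(f"unknown degree_mode {degree_mode!r}")
    inv_sqrt = sp.diags(1.0 / np.sqrt(degrees))
    return (inv_sqrt @ A_tilde @ inv_sqrt).tocsr()


def glorot_init(
    layer_sizes: Sequence[int], rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded Glorot-uniform weights: U(+-sqrt(6 / (fan_in + fan_out)))."""
    weights = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
    return weights


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _forward_pass(
    A_hat: sp.spmatrix,
    X: np.ndarray,
    params: GCNParams,
    dropout_rate: float,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, dict]:
    """Propagate through all layers; returns probabilities plus caches.

    Dropout (inverted scaling) is applied to every layer's input when an
    ``rng`` is supplied; passing ``rng=None`` disables it (inference).
    """
    n_layers = len(params.weights)
    Z = np.asarray(X, dtype=float)
    cache: dict = {"inputs": [], "drop_masks": [], "pre": []}
    for h, W in enumerate(params.weights):
        if rng is not None and dropout_rate > 0:
            keep = 1.0 - dropout_rate
            mask = (rng.random(Z.shape) < keep) / keep
        else:
            mask = None
        dropped = Z * mask if mask is not None else Z
        pre = A_hat @ dropped @ W
        if params.biases is not None:
            pre = pre + params.biases[h]
        cache["inputs"].append(dropped)
        cache["drop_masks"].append(mask)
        cache["pre"].append(pre)
        Z = _relu(pre) if h < n_layers - 1 else pre
    probs = _softmax(Z)
    cache["probs"] = probs
    return probs, cache


def gcn_forward(
    A_hat: sp.spmatrix,
    X: np.ndarray,
    params: GCNParams,
    dropout_active: bool = False,
    seed: int = 0,
    dropout_rate: float = 0.5,
) -> np.ndarray:
    """N x 2 class probabilities from the normalized adjacency and features."""
    if X.shape[1] != params.weights[0].shape[0]:
        raise GCNConfigError(
            f"feature width {X.shape[1]} does not match first layer "
            f"fan-in {params.weights[0].shape[0]}"
        )
    rng = np.random.default_rng(seed) if dropout_active else None
    probs, _ = _forward_pass(A_hat, X, params, dropout_rate, rng)
    return probs


def masked_loss(
    probabilities: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> float:
    """Mean cross-entropy over masked nodes only."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GCNConfigError("mask selects no nodes")
    p = np.clip(probabilities[mask], 1e-12, 1.0)
    y = np.asarray(labels)[mask]
    log_lik = np.log(p[np.arange(y.size), y])
    if class_weights is None:
        return float(-log_lik.mean())
    w = class_weights[y]
    return float(-(w * log_lik).sum() / w.sum())


def _loss_and_grads(
    A_hat: sp.spmatrix,
    X: np.ndarray,
    params: GCNParams,
    labels: np.ndarray,
    mask: np.ndarray,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    class_weights: np.ndarray | None = None,
) -> tuple[float, list[np.ndarray], list[np.ndarray] | None]:
    """Masked cross-entropy and its analytic gradients wrt every layer."""
    mask = np.asarray(mask, dtype=bool)
    probs, cache = _forward_pass(A_hat, X, params, dropout_rate, rng)
    loss = masked_loss(probs, labels, mask, class_weights)

    y = np.asarray(labels)
    n, k = probs.shape
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    if class_weights is None:
        node_w = mask.astype(float)
        norm = mask.sum()
    else:
        node_w = np.where(mask, class_weights[y], 0.0)
        norm = node_w.sum()
    dpre = (probs - onehot) * (node_w / norm)[:, None]

    grads_w: list[np.ndarray] = [np.empty(0)] * len(params.weights)
    grads_b: list[np.ndarray] | None = (
        [np.empty(0)] * len(params.weights) if params.biases is not None else None
    )
    for h in range(len(params.weights) - 1, -1, -1):
        propagated = A_hat @ cache["inputs"][h]
        grads_w[h] = propagated.T @ dpre
        if grads_b is not None:
            grads_b[h] = dpre.sum(axis=0)
        if h > 0:
            d_input = (A_hat @ dpre) @ params.weights[h].T  # A_hat is symmetric
            if cache["drop_masks"][h] is not None:
                d_input = d_input * cache["drop_masks"][h]
            dpre = d_input * (cache["pre"][h - 1] > 0)
    return loss, grads_w, grads_b


class GCNInterfaceClassifier(ClassifierMixin, BaseEstimator):
    """Transductive GCN node classifier with a scikit-learn interface.

    The adjacency (raw, un-normalized composite weights) and node masks are
    passed to :meth:`fit` alongside the stacked feature matrix ``X`` and
    label vector ``y``. Because the model is transductive, :meth:`fit`
    already computes probabilities for every node; :meth:`predict_proba`
    with no arguments returns them, or accepts a new ``(X, adjacency)``
    pair for inference with the fitted weights.

    Parameters follow the reference setup: hidden sizes (35, 32), learning
    rate 0.001, dropout 0.5, at most 1500 full-batch epochs with
    patience-50 early stopping on validation loss.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, int] = (35, 32),
        learning_rate: float = 0.001,
        dropout: float = 0.5,
        max_epochs: int = 1500,
        patience: int = 50,
        seed: int = 0,
        degree_mode: DegreeMode = "weighted",
        use_bias: bool = False,
        class_weight: Literal["balanced"] | None = None,
        decision_threshold: float = 0.5,
    ):
        self.hidden_sizes = hidden_sizes
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.degree_mode = degree_mode
        self.use_bias = use_bias
        self.class_weight = class_weight
        self.decision_threshold = decision_threshold

    # -- estimator API ---------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        adjacency: sp.spmatrix | np.ndarray | None = None,
        train_mask: np.ndarray | None = None,
        val_mask: np.ndarray | None = None,
    ) -> "GCNInterfaceClassifier":
        config = GCNConfig(
            hidden_sizes=tuple(self.hidden_sizes),
            learning_rate=self.learning_rate,
            dropout=self.dropout,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.seed,
            degree_mode=self.degree_mode,
            use_bias=self.use_bias,
            class_weight=self.class_weight,
        )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise GCNConfigError("X must be 2-D and aligned with y")
        n = X.shape[0]
        if adjacency is None:
            adjacency = sp.csr_matrix((n, n))
        if train_mask is None:
            train_mask = np.ones(n, dtype=bool)
        train_mask = np.asarray(train_mask, dtype=bool)
        if not train_mask.any():
            raise GCNConfigError("train_mask selects no nodes")
        monitor_mask = (
            np.asarray(val_mask, dtype=bool) if val_mask is not None else train_mask
        )
        if val_mask is not None and not monitor_mask.any():
            raise GCNConfigError("val_mask selects no nodes")
        if np.unique(y[train_mask]).size < 2:
            raise GCNConfigError("training nodes contain a single class")

        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]

        A_hat = normalize_adjacency(adjacency, config.degree_mode)
        rng = np.random.default_rng(config.seed)
        layer_sizes = (X.shape[1], *config.hidden_sizes, 2)
        params = GCNParams(
            weights=glorot_init(layer_sizes, rng),
            biases=[np.zeros(s) for s in layer_sizes[1:]] if config.use_bias else None,
        )
        class_weights = None
        if config.class_weight == "balanced":
            counts = np.bincount(y[train_mask], minlength=2).astype(float)
            class_weights = train_mask.sum() / (2.0 * np.maximum(counts, 1.0))

        history = TrainHistory()
        best_loss = np.inf
        best_params: GCNParams | None = None
        since_improve = 0

        from .evaluation import roc_auc  # local import to avoid a cycle

        for epoch in range(config.max_epochs):
            loss, grads_w, grads_b = _loss_and_grads(
                A_hat, X, params, y, train_mask,
                dropout_rate=config.dropout, rng=rng,
                class_weights=class_weights,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check feature scaling"
                )
            for h, g in enumerate(grads_w):
                params.weights[h] = params.weights[h] - config.learning_rate * g
            if grads_b is not None and params.biases is not None:
                for h, g in enumerate(grads_b):
                    params.biases[h] = params.biases[h] - config.learning_rate * g

            probs, _ = _forward_pass(A_hat, X, params, 0.0, None)
            monitor_loss = masked_loss(probs, y, monitor_mask, class_weights)
            history.train_loss.append(loss)
            history.val_loss.append(monitor_loss)
            scores = probs[:, 1]
            if np.unique(y[monitor_mask]).size == 2:
                auc, _ = roc_auc(y, scores, monitor_mask)
            else:
                auc = float("nan")
            history.val_auc.append(auc)

            if monitor_loss < best_loss - 1e-12:
                best_loss = monitor_loss
                best_params = GCNParams(
                    weights=[w.copy() for w in params.weights],
                    biases=[b.copy() for b in params.biases] if params.biases else None,
                )
                history.best_epoch = epoch
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= config.patience:
                    history.stop_reason = (
                        f"validation loss plateau ({config.patience} epochs)"
                    )
                    break
        else:
            history.stop_reason = "max_epochs reached"

        self.params_ = best_params if best_params is not None else params
        self.history_ = history
        self.config_ = config
        self.A_hat_ = A_hat
        self.X_ = X
        probs, _ = _forward_pass(A_hat, X, self.params_, 0.0, None)
        self.proba_ = probs
        self.best_epoch_ = history.best_epoch
        return self

    def predict_proba(
        self,
        X: np.ndarray | None = None,
        adjacency: sp.spmatrix | np.ndarray | None = None,
    ) -> np.ndarray:
        """N x 2 class probabilities (dropout off).

        With no arguments, returns the transductive probabilities for the
        nodes seen at fit time.
        """
        self._check_fitted()
        if X is None:
            return self.proba_.copy()
        X = np.asarray(X, dtype=float)
        if adjacency is None:
            adjacency = sp.csr_matrix((X.shape[0], X.shape[0]))
        A_hat = normalize_adjacency(adjacency, self.config_.degree_mode)
        probs, _ = _forward_pass(A_hat, X, self.params_, 0.0, None)
        return probs

    def predict(
        self,
        X: np.ndarray | None = None,
        adjacency: sp.spmatrix | np.ndarray | None = None,
    ) -> np.ndarray:
        """Hard 0/1 labels at the decision threshold (default 0.5)."""
        proba = self.predict_proba(X, adjacency)
        return (proba[:, 1] >= self.decision_threshold).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise GCNConfigError("classifier is not fitted")

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Serialize fitted weights + config to a JSON container."""
        self._check_fitted()
        payload = {
            "config": asdict(self.config_),
            "weights": [w.tolist() for w in self.params_.weights],
            "biases": (
                [b.tolist() for b in self.params_.biases]
                if self.params_.biases is not None else None
            ),
            "best_epoch": self.best_epoch_,
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "GCNInterfaceClassifier":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        est = cls(**{k: v for k, v in cfg.items()})
        est.config_ = GCNConfig(**cfg)
        est.params_ = GCNParams(
            weights=[np.array(w) for w in payload["weights"]],
            biases=(
                [np.array(b) for b in payload["biases"]]
                if payload["biases"] is not None else None
            ),
        )
        est.best_epoch_ = payload["best_epoch"]
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = est.params_.weights[0].shape[0]
        return est


def train(
    dataset: MaskedDataset, config: GCNConfig | None = None
) -> tuple[GCNParams, TrainHistory]:
    """Fit the classifier on a masked dataset; returns (params, history)."""
    config = config or GCNConfig()
    est = GCNInterfaceClassifier(
        hidden_sizes=config.hidden_sizes,
        learning_rate=config.learning_rate,
        dropout=config.dropout,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=config.seed,
        degree_mode=config.degree_mode,
        use_bias=config.use_bias,
        class_weight=config.class_weight,
    )
    est.fit(
        dataset.features,
        dataset.labels,
        adjacency=dataset.composite.weights,
        train_mask=dataset.train_mask,
        val_mask=dataset.val_mask if dataset.val_mask.any() else None,
    )
    return est.params_, est.history_


def predict(params: GCNParams, A_hat: sp.spmatrix, X: np.ndarray) -> np.ndarray:
    """Interface (positive-class) probability per node, dropout off."""
    return gcn_forward(A_hat, X, params, dropout_active=False)[:, 1]
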