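"""Whole-network training by sequential feedback-free layer fitting.

Layers are fitted strictly in order: layer ``l`` sees only the data as
transformed by the already-frozen layers ``1..l-1`` plus the labels, and
is itself frozen before layer ``l+1`` exists.  No information ever flows
backwards — there is no loss gradient, no backward pass, and each layer's
weights are solved once, in closed form, after a single streaming pass
over the data.  The readout layer is fitted by ridge regression of the
final hidden representation directly onto the one-hot labels, so the
model's scores are label estimates.

Estimators follow the scikit-learn protocol (``fit`` / ``predict`` /
``decision_function``, ``get_params``/``set_params``) and compose with
sklearn model selection.  Four fitting modes are supported:

``fp``
    full forward-projection targets g(aQ) + g(yU) for every hidden layer;
``rf``
    random features — hidden weights stay at their seeded random draws
    and only the readout is fitted;
``label_projection`` / ``noisy_label_projection``
    degraded baselines whose hidden targets are yU (rank-limited by the
    label dimension) or yU plus Gaussian noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .layers import ConvSpec, FPConvLayer, FPDenseLayer, global_avg_pool
from .linear_solver import RidgeAccumulator, RidgePenalty
from .targets import TargetMode, derive_seed

__all__ = [
    "ForwardProjectionClassifier",
    "ForwardProjectionConvClassifier",
    "ArchitectureSpec",
    "evaluate",
    "few_shot_harness",
    "save_model",
    "load_model",
]

_FIT_MODES = ("fp", "rf", "label_projection", "noisy_label_projection")


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, y)
    out = np.zeros((len(y), len(classes)), dtype=np.float64)
    out[np.arange(len(y)), idx] = 1.0
    return out


def _coerce_labels(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept integer/str labels or a one-hot matrix; return (labels, classes)."""
    y = np.asarray(y)
    if y.ndim == 2:
        if y.shape[1] < 2:
            raise ValueError("one-hot label matrix must have >= 2 columns")
        y = np.argmax(y, axis=1)
    classes = np.unique(y)
    return y, classes


class _BaseFPClassifier(ClassifierMixin, BaseEstimator):
    """Shared layer-wise fitting machinery; subclasses build the stack."""

    def _more_tags(self):  # pragma: no cover
        return {"non_deterministic": False}

    # subclasses implement ---------------------------------------------
    def _build_layers(self, input_shape: tuple[int, ...], m_label: int) -> list:
        raise NotImplementedError

    def _readout_features(self, a: np.ndarray) -> np.ndarray:
        """Map the last hidden activation to the readout's input rows."""
        return a

    # ------------------------------------------------------------------
    def _penalty(self) -> RidgePenalty:
        return RidgePenalty(lam=self.lam, mode=self.penalty_mode)

    def _target_mode(self) -> TargetMode:
        sd = self.noise_sd if self.fit_mode == "noisy_label_projection" else 0.0
        mode = "fp" if self.fit_mode == "rf" else self.fit_mode
        return TargetMode(mode, sd)

    def _batch_slices(self, n: int):
        bs = self.batch_size or n
        return [slice(i, min(i + bs, n)) for i in range(0, n, bs)]

    def fit(self, X, y):
        if self.fit_mode not in _FIT_MODES:
            raise ValueError(f"fit_mode must be one of {_FIT_MODES}")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty dataset")
        labels, classes = _coerce_labels(y)
        if len(labels) != X.shape[0]:
            raise ValueError("X and y have inconsistent sample counts")
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        self.classes_ = classes
        yhot = _one_hot(labels, classes)
        m_label = len(classes)
        self.input_shape_ = X.shape[1:]
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else int(np.prod(X.shape[1:]))

        self.layers_ = self._build_layers(X.shape[1:], m_label)
        penalty = self._penalty()
        mode = self._target_mode()
        slices = self._batch_slices(X.shape[0])

        for l, layer in enumerate(self.layers_):
            if self.fit_mode == "rf":
                layer.set_random_weights()
                continue

            def stream(l=l):
                for sl in slices:
                    a = X[sl]
                    for prev in self.layers_[:l]:
                        a = prev.forward(a)
                    yield a, yhot[sl]

            layer.fit(
                stream,
                penalty=penalty,
                mode=mode,
                noise_seed=derive_seed(self.random_state, 500 + l),
            )

        # readout: ridge regression of final features onto one-hot labels
        acc = RidgeAccumulator(self._readout_dim(), m_label)
        for sl in slices:
            a = X[sl]
            for layer in self.layers_:
                a = layer.forward(a)
            acc.update(self._readout_features(a), yhot[sl])
        self.readout_W_ = acc.solve(penalty)
        self.train_residuals_ = [layer.train_residual for layer in self.layers_]
        return self

    def _readout_dim(self) -> int:
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        """Final hidden representation (the readout's input features)."""
        check_is_fitted(self, "readout_W_")
        a = self._check_X(X)
        for layer in self.layers_:
            a = layer.forward(a)
        return self._readout_features(a)

    def hidden_activations(self, X, upto: int) -> np.ndarray:
        """Activations entering hidden layer ``upto`` (0-based): the input
        itself for ``upto=0``, else the output of layer ``upto-1``."""
        check_is_fitted(self, "readout_W_")
        a = self._check_X(X)
        for layer in self.layers_[:upto]:
            a = layer.forward(a)
        return a

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match fitted shape {self.input_shape_}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        """Readout membrane potentials (pre-softmax label scores), (B, m_L)."""
        return self.transform(X) @ self.readout_W_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)


class ForwardProjectionClassifier(_BaseFPClassifier):
    """Multi-layer perceptron trained by forward projection.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Widths of the hidden layers, in order.
    activation : str
        Neuronal activation ``f`` applied to membrane potentials
        (``relu``, ``tanh``, ``sign``, ``identity``, ``modulo``,
        ``polynomial``).
    target_nonlinearity : str
        Element-wise ``g`` used in the target generator (default ``sign``).
    fit_mode : {"fp", "rf", "label_projection", "noisy_label_projection"}
    lam, penalty_mode : ridge penalty (see RidgePenalty).
    noise_sd : float
        Noise standard deviation for the noisy-label-projection baseline.
    batch_size : int or None
        Streaming batch size (None = single batch).
    random_state : int
        Root seed; all projection draws derive from it deterministically.
    """

    def __init__(
        self,
        hidden_layer_sizes: Sequence[int] = (100,),
        activation: str = "relu",
        target_nonlinearity: str = "sign",
        fit_mode: str = "fp",
        lam: float = 1e-2,
        penalty_mode: str = "trace_scaled",
        noise_sd: float = 1.0,
        batch_size: int | None = 512,
        random_state: int = 0,
    ) -> None:
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.target_nonlinearity = target_nonlinearity
        self.fit_mode = fit_mode
        self.lam = lam
        self.penalty_mode = penalty_mode
        self.noise_sd = noise_sd
        self.batch_size = batch_size
        self.random_state = random_state

    def _build_layers(self, input_shape, m_label):
        if len(input_shape) != 1:
            raise ValueError(
                f"{type(self).__name__} expects 2-D X; got sample shape {input_shape}"
            )
        widths = [input_shape[0], *self.hidden_layer_sizes]
        return [
            FPDenseLayer(
                widths[i],
                widths[i + 1],
                m_label,
                f=self.activation,
                g=self.target_nonlinearity,
                seed=derive_seed(self.random_state, i),
            )
            for i in range(len(widths) - 1)
        ]

    def _readout_dim(self) -> int:
        return self.layers_[-1].m_out


class ForwardProjectionConvClassifier(_BaseFPClassifier):
    """Convolutional network trained by forward projection.

    The stack follows the block convention: block ``l`` holds two
    convolutional layers with ``base_filters * 2**(l-1)`` filters and
    kernel size ``kernel_size`` — the first with stride 1 ('same'
    padding), the second with stride 2 ('valid').  The final feature map
    is aggregated by global average pooling before the dense readout.
    Accepts ``X`` shaped (B, C, L) for 1-D signals/sequences or
    (B, C, H, W) for images.
    """

    def __init__(
        self,
        n_blocks: int = 2,
        base_filters: int = 8,
        kernel_size: int = 3,
        activation: str = "relu",
        target_nonlinearity: str = "sign",
        fit_mode: str = "fp",
        lam: float = 1e-2,
        penalty_mode: str = "trace_scaled",
        noise_sd: float = 1.0,
        batch_size: int | None = 128,
        subsample: float | None = None,
        random_state: int = 0,
    ) -> None:
        self.n_blocks = n_blocks
        self.base_filters = base_filters
        self.kernel_size = kernel_size
        self.activation = activation
        self.target_nonlinearity = target_nonlinearity
        self.fit_mode = fit_mode
        self.lam = lam
        self.penalty_mode = penalty_mode
        self.noise_sd = noise_sd
        self.batch_size = batch_size
        self.subsample = subsample
        self.random_state = random_state

    def _build_layers(self, input_shape, m_label):
        if len(input_shape) not in (2, 3):
            raise ValueError(
                "expected (C, L) or (C, H, W) sample shape, got " f"{input_shape}"
            )
        ndim = len(input_shape) - 1
        kernel = self.kernel_size if ndim == 1 else (self.kernel_size, self.kernel_size)
        layers = []
        in_channels = input_shape[0]
        for b in range(self.n_blocks):
            filters = self.base_filters * 2**b
            for j, (stride, padding) in enumerate(((1, "same"), (2, "valid"))):
                layers.append(
                    FPConvLayer(
                        in_channels,
                        ConvSpec(filters, kernel, stride=stride, padding=padding),
                        m_label,
                        f=self.activation,
                        g=self.target_nonlinearity,
                        seed=derive_seed(self.random_state, 2 * b + j),
                        subsample=self.subsample,
                    )
                )
                in_channels = filters
        return layers

    def _readout_features(self, a: np.ndarray) -> np.ndarray:
        return global_avg_pool(a)

    def _readout_dim(self) -> int:
        return self.layers_[-1].m_out


@dataclass
class ArchitectureSpec:
    """Declarative architecture description used by the CLI and model files.

    ``kind`` is ``mlp``, ``cnn1d`` or ``cnn2d``; the remaining fields map
    onto estimator constructor parameters.
    """

    kind: str = "mlp"
    hidden_layer_sizes: tuple = (100,)
    n_blocks: int = 2
    base_filters: int = 8
    kernel_size: int = 3
    activation: str = "relu"
    target_nonlinearity: str = "sign"

    def to_estimator(self, **overrides) -> _BaseFPClassifier:
        if self.kind == "mlp":
            return ForwardProjectionClassifier(
                hidden_layer_sizes=tuple(self.hidden_layer_sizes),
                activation=self.activation,
                target_nonlinearity=self.target_nonlinearity,
                **overrides,
            )
        if self.kind in ("cnn1d", "cnn2d"):
            return ForwardProjectionConvClassifier(
                n_blocks=self.n_blocks,
                base_filters=self.base_filters,
                kernel_size=self.kernel_size,
                activation=self.activation,
                target_nonlinearity=self.target_nonlinearity,
                **overrides,
            )
        raise ValueError(f"unknown architecture kind {self.kind!r}")


def _scores_for_auc(scores: np.ndarray, labels: np.ndarray, classes: np.ndarray) -> float:
    """Binary AUC (positive class = classes[1]) or macro one-vs-rest AUC."""
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("AUC undefined: dataset contains a single class")
    if len(classes) == 2:
        return float(roc_auc_score(labels == classes[1], scores[:, 1]))
    aucs = []
    for c, cls in enumerate(classes):
        pos = labels == cls
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos, scores[:, c]))
    return float(np.mean(aucs))


def evaluate(model: _BaseFPClassifier, X, y) -> dict:
    """Test metrics: ``accuracy`` as a fraction and ``auc`` on the 0-100
    scale (binary AUC for two classes, macro one-vs-rest otherwise)."""
    labels, _ = _coerce_labels(y)
    scores = model.decision_function(X)
    pred = model.classes_[np.argmax(scores, axis=1)]
    acc = float(np.mean(pred == labels))
    auc = 100.0 * _scores_for_auc(scores, labels, model.classes_)
    return {"auc": auc, "accuracy": acc}


def few_shot_harness(
    estimator: _BaseFPClassifier,
    X_train,
    y_train,
    X_test,
    y_test,
    n_per_class: Sequence[int | None],
    n_repeats: int = 5,
    random_state: int = 0,
):
    """Repeated class-stratified few-shot fitting and held-out evaluation.

    For each ``n`` in ``n_per_class`` (``None`` = use all training data),
    draws ``n_repeats`` stratified subsamples without replacement within
    class, clones and fits the estimator on each, and evaluates on the
    fixed test split.  Returns a pandas DataFrame with mean and standard
    deviation of test AUC and accuracy per cell.
    """
    import pandas as pd
    from sklearn.base import clone

    X_train = np.asarray(X_train, dtype=np.float64)
    labels, classes = _coerce_labels(y_train)
    rows = []
    for n in n_per_class:
        aucs, accs = [], []
        # common random numbers: the model seed and subsample stream depend
        # only on the repeat index, so cells are paired across shot counts
        for rep in range(n_repeats):
            rng = np.random.default_rng(derive_seed(random_state, rep))
            if n is None:
                idx = np.arange(len(labels))
            else:
                parts = []
                for cls in classes:
                    pool = np.nonzero(labels == cls)[0]
                    if n > len(pool):
                        raise ValueError(
                            f"requested {n} samples for class {cls!r} but only "
                            f"{len(pool)} are available"
                        )
                    parts.append(rng.choice(pool, size=n, replace=False))
                idx = np.concatenate(parts)
            est = clone(estimator)
            est.set_params(random_state=derive_seed(random_state, 9000, rep))
            est.fit(X_train[idx], labels[idx])
            metrics = evaluate(est, X_test, y_test)
            aucs.append(metrics["auc"])
            accs.append(metrics["accuracy"])
        rows.append(
            {
                "n_per_class": -1 if n is None else n,
                "auc_mean": float(np.mean(aucs)),
                "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                "accuracy_mean": float(np.mean(accs)),
                "accuracy_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# -- model persistence ----------------------------------------------------


def save_model(model: _BaseFPClassifier, directory: str | Path) -> None:
    """Write a fitted model to a directory: JSON manifest + weight files.

    Projection pairs are recorded by seed and dimensions and regenerated
    at load time (they are deterministic in the seed)."""
    check_is_fitted(model, "readout_W_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "estimator": type(model).__name__,
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in model.get_params().items()},
        "classes": np.asarray(model.classes_).tolist(),
        "input_shape": list(model.input_shape_),
        "train_residuals": model.train_residuals_,
        "layer_fit_modes": [layer.fit_mode for layer in model.layers_],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for i, layer in enumerate(model.layers_):
        np.save(directory / f"layer_{i:02d}_W.npy", layer.W)
    np.save(directory / "readout_W.npy", model.readout_W_)


def load_model(directory: str | Path) -> _BaseFPClassifier:
    """Rebuild a saved model; layer weights are loaded, projection pairs
    regenerated from their recorded seeds."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cls = {
        "ForwardProjectionClassifier": ForwardProjectionClassifier,
        "ForwardProjectionConvClassifier": ForwardProjectionConvClassifier,
    }[manifest["estimator"]]
    params = dict(manifest["params"])
    if "hidden_layer_sizes" in params:
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
    model = cls(**params)
    model.classes_ = np.asarray(manifest["classes"])
    model.input_shape_ = tuple(manifest["input_shape"])
    model.n_features_in_ = (
        model.input_shape_[0]
        if len(model.input_shape_) == 1
        else int(np.prod(model.input_shape_))
    )
    model.layers_ = model._build_layers(model.input_shape_, len(model.classes_))
    for i, layer in enumerate(model.layers_):
        layer.W = np.load(directory / f"layer_{i:02d}_W.npy")
        layer.fitted = True
        layer.fit_mode = manifest["layer_fit_modes"][i]
        layer.train_residual = manifest["train_residuals"][i]
    model.readout_W_ = np.load(directory / "readout_W.npy")
    model.train_residuals_ = manifest["train_residuals"]
    return model
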