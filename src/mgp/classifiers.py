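"""Classifier families and the training/evaluation protocol.

Three families are supported: logistic regressions over hand-engineered
features (color moments; texture statistics + PCA) and a parametric
family of depth-1..12 CNNs.  All are scored with repeated two-fold
cross-validation in which every image is a test item exactly once per
repeat, and per-image scores are averaged across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import nn
from .synthetic import IMAGE_SIZE

MAX_DEPTH = 12
MAX_POOL_STAGES = 3

HYPERPARAMETER_NAMES = (
    "filters_base",
    "filter_growth",
    "kernel_size",
    "pool_size",
    "fc_units",
    "dropout_rate",
    "init_learning_rate",
    "momentum",
    "l2_penalty",
    "batch_size",
    "lr_decay",
)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def score_to_class(score: float) -> str:
    """Prediction scores below 0.5 are glass; 0.5 or greater is mirror."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return "glass" if score < 0.5 else "mirror"


def labels_to_binary(labels) -> np.ndarray:
    """Map labels to {0: glass, 1: mirror}; ambiguous classes inherit
    their generator's class."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iufb":
        return arr.astype(int)
    out = np.empty(arr.shape, dtype=int)
    for i, v in enumerate(arr.ravel()):
        if v in ("mirror", "amb_mirror"):
            out.ravel()[i] = 1
        elif v in ("glass", "amb_glass"):
            out.ravel()[i] = 0
        else:
            raise ValueError(f"unknown label {v!r}")
    return out


def accuracy(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    y = labels_to_binary(labels)
    if scores.shape[0] != y.shape[0]:
        raise ValueError("scores and labels have different lengths")
    pred = (scores >= 0.5).astype(int)
    return float((pred == y).mean())


# ---------------------------------------------------------------------------
# Logistic regression on features
# ---------------------------------------------------------------------------

class LogisticModel:
    """Thin deterministic wrapper exposing fit / predict_score."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed
        self._clf: LogisticRegression | None = None

    def fit(self, X: np.ndarray, labels) -> "LogisticModel":
        y = labels_to_binary(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("logistic regression requires both classes in the training set")
        self._clf = LogisticRegression(
            C=self.C, max_iter=5000, tol=1e-10, random_state=self.seed, solver="lbfgs"
        )
        self._clf.fit(np.asarray(X, dtype=float), y)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("model not fitted")
        proba = self._clf.predict_proba(np.atleast_2d(np.asarray(X, dtype=float)))
        return proba[:, list(self._clf.classes_).index(1)]

    @property
    def coef_(self) -> np.ndarray:
        return self._clf.coef_.ravel()


def fit_logistic(features: np.ndarray, labels, C: float = 1.0, seed: int = 0) -> LogisticModel:
    return LogisticModel(C=C, seed=seed).fit(features, labels)


# ---------------------------------------------------------------------------
# Parametric CNN family
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNNSpec:
    """Depth plus the 11 architecture/training hyperparameters.

    ``head`` selects the read-out: "dense" (dropout -> fully connected ->
    softmax) or "gap" (global average pooling -> fully connected ->
    softmax), the latter required for class activation mapping.
    """

    depth: int = 3
    filters_base: int = 8
    filter_growth: float = 1.0
    kernel_size: int = 3
    pool_size: int = 2
    fc_units: int = 16
    dropout_rate: float = 0.2
    init_learning_rate: float = 0.05
    momentum: float = 0.9
    l2_penalty: float = 1e-4
    batch_size: int = 32
    lr_decay: float = 0.1
    head: str = "dense"

    def __post_init__(self) -> None:
        if not 1 <= self.depth <= MAX_DEPTH:
            raise ValueError(f"depth must lie in 1..{MAX_DEPTH}")
        if self.head not in ("dense", "gap"):
            raise ValueError("head must be 'dense' or 'gap'")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")

    @property
    def pooled_blocks(self) -> tuple[int, ...]:
        """Indices of blocks containing max pooling: only the last
        min(depth, 3) blocks pool."""
        n_pool = min(self.depth, MAX_POOL_STAGES)
        return tuple(range(self.depth - n_pool, self.depth))

    def filters(self, block: int) -> int:
        return max(1, int(round(self.filters_base * self.filter_growth**block)))

    def hyperparameters(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in HYPERPARAMETER_NAMES}


def spatial_sizes(spec: CNNSpec, input_size: int = IMAGE_SIZE) -> list[int]:
    """Spatial size after each block; raises on pooling underflow."""
    size = input_size
    sizes = []
    for b in range(spec.depth):
        if b in spec.pooled_blocks:
            if size % spec.pool_size or size // spec.pool_size < 1:
                raise ValueError(
                    f"spatial size {size} cannot be pooled by {spec.pool_size} at block {b}"
                )
            size //= spec.pool_size
        sizes.append(size)
    return sizes


class CNNModel:
    """CNN classifier with fit / predict_score and activation capture."""

    def __init__(self, spec: CNNSpec, seed: int = 0,
                 max_epochs: int = 30, patience: int = 3, val_fraction: float = 0.2):
        self.spec = spec
        self.seed = seed
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.net = build_network(spec, seed)
        self.history: list[float] = []

    # -- data plumbing ----------------------------------------------------
    @staticmethod
    def _to_input(images: np.ndarray) -> np.ndarray:
        """(n, H, W, C) float32, centered on zero."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return np.ascontiguousarray(x - 0.5)

    # -- training ---------------------------------------------------------
    def fit(self, images: np.ndarray, labels, val_images=None, val_labels=None) -> "CNNModel":
        x = self._to_input(images)
        y = labels_to_binary(labels)
        if x.shape[0] == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.seed)
        if val_images is None:
            n_val = max(1, int(round(self.val_fraction * x.shape[0])))
            perm = rng.permutation(x.shape[0])
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            xv, yv = x[val_idx], y[val_idx]
            x, y = x[tr_idx], y[tr_idx]
        else:
            xv, yv = self._to_input(val_images), labels_to_binary(val_labels)
        if x.shape[0] == 0 or xv.shape[0] == 0:
            raise ValueError("empty train/validation split")

        opt = nn.SGDMomentum(
            self.net, self.spec.init_learning_rate, self.spec.momentum,
            self.spec.l2_penalty, self.spec.lr_decay,
        )
        best_acc, best_params, since_best = -1.0, None, 0
        self.history = []
        bs = max(2, int(self.spec.batch_size))
        for epoch in range(self.max_epochs):
            opt.epoch = epoch
            order = rng.permutation(x.shape[0])
            for start in range(0, len(order), bs):
                idx = order[start : start + bs]
                if len(idx) < 2:
                    continue  # batch norm needs >= 2 samples
                probs = self.net.forward(x[idx], train=True)
                self.net.backward(probs, y[idx])
                opt.step()
            val_acc = accuracy(self.net.forward(xv)[:, 1], yv)
            self.history.append(val_acc)
            if val_acc > best_acc:
                best_acc, best_params, since_best = val_acc, self.net.get_params(), 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_params is not None:
            self.net.set_params(best_params)
        self._recalibrate_batchnorm(np.concatenate([x, xv]), bs)
        return self

    def _recalibrate_batchnorm(self, x: np.ndarray, batch: int) -> None:
        """Replace lagging running statistics with the average batch
        statistics of the final weights (short trainings leave the
        exponential running averages far behind the weights)."""
        bns = [layer for layer in self.net.layers if isinstance(layer, nn.BatchNorm)]
        if not bns:
            return
        acc = {id(bn): ([], []) for bn in bns}
        saved = [(bn.momentum, bn.running_mean.copy(), bn.running_var.copy()) for bn in bns]
        for bn in bns:
            bn.momentum = 0.0  # running stats = current batch stats
        n_batches = 0
        for start in range(0, x.shape[0], batch):
            xb = x[start : start + batch]
            if xb.shape[0] < 2:
                continue
            self.net.forward(xb, train=True)
            n_batches += 1
            for bn in bns:
                acc[id(bn)][0].append(bn.running_mean.copy())
                acc[id(bn)][1].append(bn.running_var.copy())
        for bn, (mom, rm, rv) in zip(bns, saved):
            bn.momentum = mom
            if n_batches:
                bn.running_mean = np.mean(acc[id(bn)][0], axis=0)
                bn.running_var = np.mean(acc[id(bn)][1], axis=0)
            else:
                bn.running_mean, bn.running_var = rm, rv

    # -- inference --------------------------------------------------------
    def predict_score(self, images: np.ndarray, batch: int = 256) -> np.ndarray:
        x = self._to_input(images)
        out = [self.net.forward(x[i : i + batch])[:, 1] for i in range(0, x.shape[0], batch)]
        return np.concatenate(out) if out else np.empty(0)

    def activations(self, images: np.ndarray, batch: int = 256) -> dict[str, np.ndarray]:
        x = self._to_input(images)
        chunks: list[dict[str, np.ndarray]] = []
        for i in range(0, x.shape[0], batch):
            _, acts = self.net.forward(x[i : i + batch], capture=True)
            chunks.append(acts)
        return {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        """Checkpoint: weights as .npz plus a JSON sidecar with the spec
        and training settings."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        params = self.net.get_params()
        np.savez(directory / "weights.npz", **{f"p{i}": p for i, p in enumerate(params)})
        sidecar = {
            "spec": asdict(self.spec),
            "seed": self.seed,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "val_fraction": self.val_fraction,
            "history": self.history,
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "CNNModel":
        import json
        from pathlib import Path

        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        model = cls(
            CNNSpec(**sidecar["spec"]), seed=sidecar["seed"],
            max_epochs=sidecar["max_epochs"], patience=sidecar["patience"],
            val_fraction=sidecar["val_fraction"],
        )
        with np.load(directory / "weights.npz") as data:
            model.net.set_params([data[f"p{i}"] for i in range(len(data.files))])
        model.history = list(sidecar["history"])
        return model

    def stage_names(self) -> list[str]:
        names = ["input"]
        names += [v for _, v in sorted(self.net.stage_names.items()) if v != "input"]
        names.append("output")
        return names

    def n_params(self) -> int:
        return self.net.n_params()


def build_network(spec: CNNSpec, seed: int = 0, input_size: int = IMAGE_SIZE) -> nn.Network:
    """Instantiate the network for ``spec`` (input 64x64x3, two-unit
    softmax output)."""
    sizes = spatial_sizes(spec, input_size)  # validates pooling
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    stages: dict[int, str] = {-1: "input"}
    c_in = 3
    for b in range(spec.depth):
        f = spec.filters(b)
        layers.append(nn.Conv2D(c_in, f, spec.kernel_size, rng))
        layers.append(nn.BatchNorm(f))
        layers.append(nn.ReLU())
        stages[len(layers) - 1] = f"relu{b + 1}"
        if b in spec.pooled_blocks:
            layers.append(nn.MaxPool(spec.pool_size))
        c_in = f
    if spec.head == "gap":
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Dropout(spec.dropout_rate, rng))
        layers.append(nn.Dense(c_in, 2, rng))
        stages[len(layers) - 1] = "fc"
    else:
        layers.append(nn.Flatten())
        layers.append(nn.Dropout(spec.dropout_rate, rng))
        flat = c_in * sizes[-1] * sizes[-1]
        layers.append(nn.Dense(flat, spec.fc_units, rng))
        layers.append(nn.ReLU())
        stages[len(layers) - 1] = "fc"
        layers.append(nn.Dense(spec.fc_units, 2, rng))
    return nn.Network(layers, stages)


def build_cnn(spec: CNNSpec, seed: int = 0, **train_kwargs) -> CNNModel:
    return CNNModel(spec, seed=seed, **train_kwargs)


def train_cnn(model: CNNModel, images: np.ndarray, labels,
              val_images=None, val_labels=None) -> CNNModel:
    """Train with early stopping (patience = 3 validations); the weights
    of the best validation epoch are retained."""
    return model.fit(images, labels, val_images, val_labels)


# ---------------------------------------------------------------------------
# Cross-validation protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainProtocol:
    n_folds: int = 2
    n_repeats: int = 10
    patience: int = 3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds != 2:
            raise ValueError("the protocol fixes two-fold cross-validation")


def crossval_predict(
    classifier_factory,
    X: np.ndarray,
    labels,
    protocol: TrainProtocol = TrainProtocol(),
    return_per_repeat: bool = False,
):
    """Repeated two-fold cross-validation scores.

    ``classifier_factory(seed)`` must return an object with
    ``fit(X, labels)`` and ``predict_score(X)``.  Each repeat re-splits
    the data at random; every item is scored exactly once per repeat as
    a test item, and the final score is the mean across repeats.
    """
    X = np.asarray(X)
    y = labels_to_binary(labels)
    n = X.shape[0]
    if n < 2 or min(np.bincount(y, minlength=2)) < 1:
        raise ValueError("need at least one item per class")
    rng = np.random.default_rng(protocol.master_seed)
    per_repeat = np.empty((protocol.n_repeats, n))
    for rep in range(protocol.n_repeats):
        # stratified random halves so both folds contain both classes
        fold = np.empty(n, dtype=int)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            fold[idx[: len(idx) // 2]] = 0
            fold[idx[len(idx) // 2 :]] = 1
        for f in (0, 1):
            train_idx = np.flatnonzero(fold != f)
            test_idx = np.flatnonzero(fold == f)
            seed = int(rng.integers(0, 2**31 - 1))
            try:
                model = classifier_factory(seed)
                model.fit(X[train_idx], y[train_idx])
                per_repeat[rep, test_idx] = model.predict_score(X[test_idx])
            except Exception as exc:  # pragma: no cover - context only
                raise RuntimeError(f"classifier failed in repeat {rep}, fold {f}") from exc
    scores = per_repeat.mean(axis=0)
    if return_per_repeat:
        return scores, per_repeat
    return scores


__all__ = [
    "CNNModel",
    "CNNSpec",
    "HYPERPARAMETER_NAMES",
    "LogisticModel",
    "TrainProtocol",
    "accuracy",
    "build_cnn",
    "build_network",
    "crossval_predict",
    "fit_logistic",
    "labels_to_binary",
    "score_to_class",
    "spatial_sizes",
    "train_cnn",
]
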