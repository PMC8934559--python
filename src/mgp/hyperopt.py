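"""Depth-wise hyperparameter search maximizing correlation with
simulated-observer judgments on the diagnostic set.

Each trial samples the 11 CNN hyperparameters, trains with two-fold
cross-validation on the training pool, and scores the Pearson
correlation between the fold-averaged model predictions and the human
mean ratings on held-out diagnostic images.  The default strategy is
sequential model-based optimization (Gaussian-process surrogate with
expected improvement); uniform random search is the fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .classifiers import CNNModel, CNNSpec, accuracy, labels_to_binary

# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def human_correlation_objective(model_scores, human_mean_ratings) -> float:
    """Pearson correlation between model scores and human mean ratings."""
    s = np.asarray(model_scores, dtype=float).ravel()
    h = np.asarray(human_mean_ratings, dtype=float).ravel()
    if s.shape != h.shape:
        raise ValueError("misaligned score/rating vectors")
    if s.size < 3:
        raise ValueError("need at least 3 images")
    if s.std() == 0 or h.std() == 0:
        raise ValueError("zero-variance input to the correlation objective")
    return float(np.corrcoef(s, h)[0, 1])


# ---------------------------------------------------------------------------
# Search space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dimension:
    """One hyperparameter range.

    kind: "int" | "float" | "logfloat" | "choice"
    """

    kind: str
    low: float = 0.0
    high: float = 1.0
    choices: tuple = ()

    def sample(self, u: float):
        if self.kind == "int":
            return int(self.low + math.floor(u * (self.high - self.low + 1 - 1e-12)))
        if self.kind == "float":
            return self.low + u * (self.high - self.low)
        if self.kind == "logfloat":
            return float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        if self.kind == "choice":
            return self.choices[int(u * len(self.choices) * (1 - 1e-12))]
        raise ValueError(f"unknown dimension kind {self.kind!r}")


@dataclass(frozen=True)
class SearchSpace:
    """Ranges for the 11 CNNSpec hyperparameters (log scale where
    positive-only).  The desk-scale defaults keep networks cheap."""

    dims: dict = field(default_factory=lambda: {
        "filters_base": Dimension("int", 4, 10),
        "filter_growth": Dimension("float", 1.0, 1.5),
        "kernel_size": Dimension("choice", choices=(3, 5)),
        "pool_size": Dimension("choice", choices=(2,)),
        "fc_units": Dimension("int", 8, 32),
        "dropout_rate": Dimension("float", 0.0, 0.5),
        "init_learning_rate": Dimension("logfloat", 1e-2, 0.2),
        "momentum": Dimension("float", 0.5, 0.95),
        "l2_penalty": Dimension("logfloat", 1e-6, 1e-2),
        "batch_size": Dimension("choice", choices=(16, 32, 64)),
        "lr_decay": Dimension("logfloat", 1e-3, 0.5),
    })

    def __post_init__(self) -> None:
        for name, d in self.dims.items():
            if d.kind == "choice" and not d.choices:
                raise ValueError(f"empty choice range for {name}")

    @property
    def names(self) -> list[str]:
        return list(self.dims)

    def spec_from_unit(self, u: np.ndarray, depth: int, head: str = "dense") -> CNNSpec:
        values = {n: self.dims[n].sample(float(ui)) for n, ui in zip(self.names, u)}
        return CNNSpec(depth=depth, head=head, **values)

    def sample_unit(self, rng: np.random.Generator) -> np.ndarray:
        return rng.random(len(self.dims))


# ---------------------------------------------------------------------------
# Trial evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialResult:
    spec: CNNSpec
    objective_r: float
    heldout_accuracy: float
    seed: int
    error: str | None = None


@dataclass
class Evaluator:
    """Trains a spec with two-fold CV on the training pool and computes
    the human-correlation objective on the diagnostic set.

    Diagnostic images are never used for training; ids are audited on
    every call.
    """

    train_images: np.ndarray
    train_labels: np.ndarray
    train_ids: list[str]
    diag_images: np.ndarray
    diag_ratings: np.ndarray
    diag_ids: list[str]
    max_epochs: int = 8
    n_folds: int = 2

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.diag_ids)
        if overlap:
            raise ValueError(
                f"diagnostic images appear in the training pool: {sorted(overlap)[:5]}"
            )
        self.train_y = labels_to_binary(self.train_labels)

    def evaluate(self, spec: CNNSpec, seed: int) -> TrialResult:
        rng = np.random.default_rng(seed)
        n = self.train_images.shape[0]
        fold = np.empty(n, dtype=int)
        for cls in (0, 1):
            idx = rng.permutation(np.flatnonzero(self.train_y == cls))
            fold[idx[: len(idx) // 2]] = 0
            fold[idx[len(idx) // 2 :]] = 1
        diag_scores = np.zeros(self.diag_images.shape[0])
        accs = []
        for f in range(self.n_folds):
            tr = np.flatnonzero(fold != f)
            te = np.flatnonzero(fold == f)
            model = CNNModel(spec, seed=int(rng.integers(0, 2**31 - 1)),
                             max_epochs=self.max_epochs)
            model.fit(self.train_images[tr], self.train_y[tr])
            accs.append(accuracy(model.predict_score(self.train_images[te]), self.train_y[te]))
            diag_scores += model.predict_score(self.diag_images)
        diag_scores /= self.n_folds
        r = human_correlation_objective(diag_scores, self.diag_ratings)
        return TrialResult(spec=spec, objective_r=r,
                           heldout_accuracy=float(np.mean(accs)), seed=seed)


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float) -> np.ndarray:
    sd = np.maximum(sd, 1e-9)
    z = (mu - best) / sd
    return (mu - best) * norm.cdf(z) + sd * norm.pdf(z)


def search_depth(
    depth: int,
    space: SearchSpace,
    evaluator: Evaluator,
    n_iter: int = 200,
    strategy: str = "surrogate",
    seed: int = 0,
    n_init: int = 5,
) -> tuple[TrialResult, pd.DataFrame]:
    """Hyperparameter search at a fixed depth.

    Returns the best trial and a trace table whose ``best_so_far``
    column is monotone nondecreasing.  Failed trials are recorded and
    the search continues.
    """
    if strategy not in ("surrogate", "random"):
        raise ValueError("strategy must be 'surrogate' or 'random'")
    rng = np.random.default_rng(seed)
    units: list[np.ndarray] = []
    results: list[TrialResult] = []
    rows = []
    best: TrialResult | None = None
    for it in range(n_iter):
        if strategy == "random" or it < n_init or not any(
            np.isfinite(r.objective_r) for r in results
        ):
            u = space.sample_unit(rng)
        else:
            u = _propose_surrogate(space, units, results, rng)
        spec = space.spec_from_unit(u, depth)
        trial_seed = int(rng.integers(0, 2**31 - 1))
        try:
            res = evaluator.evaluate(spec, trial_seed)
        except Exception as exc:
            res = TrialResult(spec=spec, objective_r=float("-inf"),
                              heldout_accuracy=float("nan"), seed=trial_seed, error=str(exc))
        units.append(u)
        results.append(res)
        if res.error is None and (best is None or res.objective_r > best.objective_r):
            best = res
        rows.append(
            {
                "iteration": it,
                "objective_r": res.objective_r,
                "heldout_accuracy": res.heldout_accuracy,
                "best_so_far": best.objective_r if best is not None else float("-inf"),
                "error": res.error,
                **{f"hp_{k}": v for k, v in spec.hyperparameters().items()},
            }
        )
    if best is None:
        raise RuntimeError(f"all {n_iter} trials failed at depth {depth}")
    return best, pd.DataFrame(rows)


def _propose_surrogate(
    space: SearchSpace,
    units: list[np.ndarray],
    results: list[TrialResult],
    rng: np.random.Generator,
    n_candidates: int = 256,
) -> np.ndarray:
    ok = [i for i, r in enumerate(results) if np.isfinite(r.objective_r)]
    X = np.array([units[i] for i in ok])
    y = np.array([results[i].objective_r for i in ok])
    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5, length_scale=np.full(X.shape[1], 0.3)),
        alpha=1e-4,
        normalize_y=True,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    gp.fit(X, y)
    cand = rng.random((n_candidates, X.shape[1]))
    mu, sd = gp.predict(cand, return_std=True)
    ei = _expected_improvement(mu, sd, y.max())
    return cand[int(np.argmax(ei))]


def validate_instances(
    best_spec: CNNSpec,
    evaluator: Evaluator,
    n_instances: int = 30,
    seeds: list[int] | None = None,
) -> dict:
    """Re-train ``n_instances`` of a fixed spec, differing only in the
    initial random state; the headline value is the maximum instance."""
    if seeds is None:
        seeds = list(range(n_instances))
    if len(seeds) != n_instances:
        raise ValueError("need one seed per instance")
    values = [evaluator.evaluate(best_spec, int(s)).objective_r for s in seeds]
    arr = np.asarray(values)
    return {
        "values": values,
        "mean": float(arr.mean()),
        "sd": float(arr.std()),
        "max": float(arr.max()),
    }


def depth_sweep(
    depths,
    space: SearchSpace,
    evaluator: Evaluator,
    n_iter: int = 10,
    strategy: str = "surrogate",
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Identical-budget search per depth; returns the per-depth table
    and the argmax depth.  Per-depth searches are seeded independently
    of sweep order."""
    rows = []
    for depth in depths:
        depth_seed = int(np.random.default_rng((seed, depth)).integers(0, 2**31 - 1))
        best, _ = search_depth(depth, space, evaluator, n_iter=n_iter,
                               strategy=strategy, seed=depth_seed)
        rows.append({"depth": depth, "best_objective_r": best.objective_r,
                     "best_accuracy": best.heldout_accuracy})
    table = pd.DataFrame(rows)
    argmax = int(table.loc[table["best_objective_r"].idxmax(), "depth"])
    return table, argmax


__all__ = [
    "Dimension",
    "Evaluator",
    "SearchSpace",
    "TrialResult",
    "depth_sweep",
    "human_correlation_objective",
    "search_depth",
    "validate_instances",
]
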