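"""Feature-matrix standardization and PCA reduction.

Both transforms are fitted once (typically on the complete feature
matrix) and then re-applied to held-out rows; the fitted parameters are
carried in a :class:`FeatureTransform` that serializes to/from JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class FeatureTransform:
    kind: str  # "zscore" | "pca"
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    components: np.ndarray | None = None  # (k, p) rows are principal axes
    explained_variance_ratio: np.ndarray | None = None
    n_retained: int | None = None
    extra: dict = field(default_factory=dict)

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.kind == "zscore":
            sd = np.where(self.sd > 0, self.sd, 1.0)
            out = (X - self.mean) / sd
            out[:, self.sd <= 0] = 0.0
            return out
        if self.kind == "pca":
            return (X - self.mean) @ self.components[: self.n_retained].T
        raise ValueError(f"unknown transform kind {self.kind!r}")

    def to_json(self) -> str:
        payload = {"kind": self.kind, "n_retained": self.n_retained, "extra": self.extra}
        for name in ("mean", "sd", "components", "explained_variance_ratio"):
            v = getattr(self, name)
            payload[name] = None if v is None else np.asarray(v).tolist()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, s: str) -> "FeatureTransform":
        d = json.loads(s)
        kwargs = {"kind": d["kind"], "n_retained": d["n_retained"], "extra": d.get("extra", {})}
        for name in ("mean", "sd", "components", "explained_variance_ratio"):
            v = d[name]
            kwargs[name] = None if v is None else np.asarray(v, dtype=np.float64)
        return cls(**kwargs)


def zscore(X: np.ndarray) -> tuple[np.ndarray, FeatureTransform]:
    """Column-wise standardization (population sd); constant columns -> 0."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("zscore fit requires a matrix with >= 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    t = FeatureTransform(kind="zscore", mean=mean, sd=sd)
    return t.apply(X), t


def pca_reduce(
    X: np.ndarray, cum_var_threshold: float = 0.99
) -> tuple[np.ndarray, FeatureTransform]:
    """Project onto the smallest leading principal subspace whose
    cumulative explained variance reaches ``cum_var_threshold``."""
    if not 0.0 < cum_var_threshold <= 1.0:
        raise ValueError("cum_var_threshold must lie in (0, 1]")
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca_reduce requires a matrix with >= 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered matrix; rows of Vt are principal axes
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = svals**2 / X.shape[0]
    total = var.sum()
    if total <= 0:
        ratio = np.zeros_like(var)
        k = 1
    else:
        ratio = var / total
        cum = np.cumsum(ratio)
        k = int(np.searchsorted(cum, cum_var_threshold - 1e-12) + 1)
        k = min(k, len(ratio))
    t = FeatureTransform(
        kind="pca",
        mean=mean,
        components=Vt,
        explained_variance_ratio=ratio,
        n_retained=k,
    )
    return t.apply(X), t
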