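"""Two-stage representational similarity analysis.

First-stage RDMs are absolute differences of scalar prediction scores
(or Euclidean distances between layer activation vectors); the
second-stage classifier dissimilarity matrix (CDM) holds 1 - Pearson
correlation between the upper triangles of first-stage RDMs, optionally
augmented with random-score control RDMs.  Classical (metric) MDS embeds
the CDM via eigendecomposition of the double-centered squared-distance
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RDM:
    matrix: np.ndarray  # (n, n) symmetric, zero diagonal
    source: str
    image_ids: tuple[str, ...] | None = None

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        return self.matrix[iu]


@dataclass(frozen=True)
class CDM:
    matrix: np.ndarray  # (m, m)
    sources: tuple[str, ...]


def build_rdm(scores, source: str = "", image_ids=None) -> RDM:
    """RDM of absolute score differences: entry (i, j) = |s_i - s_j|."""
    s = np.asarray(scores, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("need at least 2 scores")
    mat = np.abs(s[:, None] - s[None, :])
    ids = tuple(image_ids) if image_ids is not None else None
    return RDM(matrix=mat, source=source, image_ids=ids)


def build_activation_rdm(activations: np.ndarray, source: str = "", image_ids=None) -> RDM:
    """RDM of Euclidean distances between flattened activation vectors."""
    a = np.atleast_2d(np.asarray(activations, dtype=float))
    sq = (a**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (a @ a.T), 0.0)
    ids = tuple(image_ids) if image_ids is not None else None
    return RDM(matrix=np.sqrt(d2), source=source, image_ids=ids)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom <= 0:
        raise ValueError("zero-variance RDM upper triangle")
    return float((a * b).sum() / denom)


def rdm_dissimilarity(r1: RDM, r2: RDM) -> float:
    """1 - Pearson correlation of the two upper triangles (in [0, 2])."""
    if r1.matrix.shape != r2.matrix.shape:
        raise ValueError("RDMs have different sizes")
    if r1.image_ids is not None and r2.image_ids is not None and r1.image_ids != r2.image_ids:
        raise ValueError("RDMs carry mismatched image orderings")
    return 1.0 - _pearson(r1.upper(), r2.upper())


def build_cdm(rdms: list[RDM], n_random_controls: int = 10, seed=0) -> CDM:
    """Second-stage dissimilarity matrix over RDM sources.

    Appends ``n_random_controls`` control RDMs built from i.i.d. uniform
    scores on the same image ordering.
    """
    if not rdms:
        raise ValueError("need at least one RDM")
    n = rdms[0].matrix.shape[0]
    ids = rdms[0].image_ids
    all_rdms = list(rdms)
    rng = np.random.default_rng(seed)
    for i in range(n_random_controls):
        all_rdms.append(build_rdm(rng.uniform(0, 1, n), source=f"random{i + 1}", image_ids=ids))
    m = len(all_rdms)
    mat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = rdm_dissimilarity(all_rdms[i], all_rdms[j])
    return CDM(matrix=mat, sources=tuple(r.source for r in all_rdms))


def mds_embed(cdm: CDM | np.ndarray, n_dims: int = 3) -> tuple[np.ndarray, float]:
    """Classical metric MDS.

    Returns (coordinates (m, k), cumulative explained-variance fraction
    of the retained positive eigenvalues).  If fewer than ``n_dims``
    positive eigenvalues exist, the embedding is truncated.
    """
    D = cdm.matrix if isinstance(cdm, CDM) else np.asarray(cdm, dtype=float)
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    k = min(n_dims, n_pos)
    if k == 0:
        return np.zeros((m, n_dims)), 0.0
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    explained = float(evals[:k].sum() / evals[pos].sum())
    return coords, explained


def noise_ceiling(rating_matrix: np.ndarray) -> tuple[float, float, float]:
    """Leave-one-out inter-observer correlation bound.

    ``rating_matrix`` is (observers, images).  For each observer, the
    Pearson correlation with the mean of the remaining observers is
    computed; returns (mean, min, max).
    """
    R = np.asarray(rating_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] < 3:
        raise ValueError("need at least 3 observers")
    rs = []
    for i in range(R.shape[0]):
        others = np.delete(R, i, axis=0).mean(axis=0)
        rs.append(_pearson(R[i], others))
    rs = np.asarray(rs)
    return float(rs.mean()), float(rs.min()), float(rs.max())


def layerwise_dissimilarity(
    model, images: np.ndarray, human_ratings: np.ndarray, stages: list[str] | None = None
) -> dict[str, float]:
    """Per-stage 1 - Pearson between the stage RDM and the human RDM.

    ``model`` must expose ``activations(images) -> {stage: (n, d)}``;
    stage RDMs use Euclidean distance between flattened activations and
    the human RDM uses mean normalized ratings.
    """
    acts = model.activations(images)
    if stages is None:
        stages = model.stage_names()
    missing = [s for s in stages if s not in acts]
    if missing:
        raise ValueError(f"model has no stage(s) {missing}")
    human = build_rdm(human_ratings, source="human")
    out = {}
    for stage in stages:
        a = acts[stage]
        if stage == "output":
            rdm = build_rdm(a[:, 1], source=stage)  # mirror-unit score
        else:
            rdm = build_activation_rdm(a, source=stage)
        out[stage] = rdm_dissimilarity(rdm, human)
    return out


__all__ = [
    "CDM",
    "RDM",
    "build_activation_rdm",
    "build_cdm",
    "build_rdm",
    "layerwise_dissimilarity",
    "mds_embed",
    "noise_ceiling",
    "rdm_dissimilarity",
]
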