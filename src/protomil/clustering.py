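"""Hierarchical prototype discovery via affinity propagation (AP).

The phenotype function maps all training bags to a small set of
prototype embeddings in two stages: stage 1 runs AP inside each bag,
keeping its exemplars (actual instance rows, ``c_i`` per bag); stage 2
runs AP on the union of all stage-1 exemplars across bags, yielding the
final ``L`` prototypes with ``L < sum(c_i)``. Fitting uses training
bags only; at inference the saved prototypes are loaded.

Similarity between points is the negative normalized Euclidean distance
raised to a power: rows are L2-normalized, then
``S[a, b] = -(||x_a_hat - x_b_hat||_2) ** beta``. With beta = 2 this is
an affine function of cosine similarity. AP itself is the standard
responsibility/availability message passing of Frey & Dueck with a
damping factor (default 0.5) against oscillation, the self-similarity
(preference) set to the median off-diagonal similarity unless given
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .bags import FeatureBag
from .errors import DataError, ParameterError

__all__ = [
    "SimilarityConfig",
    "PrototypeSet",
    "APResult",
    "similarity_matrix",
    "affinity_propagation",
    "cluster_bag",
    "build_prototypes",
    "net_similarity",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """Similarity and AP iteration parameters.

    beta: exponent applied to the normalized Euclidean distance.
    damping: message damping factor in [0.5, 1).
    preference: "median" (of off-diagonal similarities) or an explicit value.
    max_bag_instances: bags larger than this are seeded-subsampled before
        stage-1 AP (AP is O(n^2) in memory; real bags reach 1e5 patches).
    """

    beta: float = 2.0
    damping: float = 0.5
    max_iter: int = 200
    convergence_iter: int = 15
    preference: str | float = "median"
    jitter: float = 0.0
    max_bag_instances: int = 10_000

    def __post_init__(self):
        if not (0.5 <= self.damping < 1.0):
            raise ParameterError("damping must lie in [0.5, 1)")
        if not (self.max_iter >= self.convergence_iter >= 1):
            raise ParameterError("require max_iter >= convergence_iter >= 1")
        if self.beta <= 0:
            raise ParameterError("beta must be positive")


@dataclass
class PrototypeSet:
    """Final prototypes with stage-1 provenance.

    Every row of ``embeddings`` is an exact row of the stage-1 exemplar
    union (itself a set of actual instance rows), so prototypes are real
    data points, not averages.
    """

    embeddings: np.ndarray  # (L, d1)
    stage1_counts: list[int]  # c_i per training bag
    bag_ids: list[str]
    sim_config: SimilarityConfig = field(default_factory=SimilarityConfig)

    @property
    def L(self) -> int:
        return self.embeddings.shape[0]

    @property
    def d1(self) -> int:
        return self.embeddings.shape[1]

    @property
    def stage1_union_size(self) -> int:
        return int(sum(self.stage1_counts))


class APResult(NamedTuple):
    exemplars: list[int]  # sorted original indices
    assignment: np.ndarray  # length-n vector of exemplar indices
    converged: bool


def similarity_matrix(X: np.ndarray, cfg: SimilarityConfig | None = None) -> np.ndarray:
    """Pairwise similarity: -(normalized Euclidean distance)^beta.

    Rows are L2-normalized first (zero rows stay zero); the result is
    exactly symmetric with a zero diagonal and all entries <= 0.
    """
    cfg = cfg or SimilarityConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise DataError("similarity_matrix expects a non-empty 2-D matrix")
    if not np.isfinite(X).all():
        raise DataError("similarity_matrix: non-finite input")
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xh = np.divide(X, norms, out=np.zeros_like(X), where=norms > 0)
    if X.shape[0] == 1:
        return np.zeros((1, 1))
    D = squareform(pdist(Xh))
    S = -(D**cfg.beta)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 0.0)
    return S


def _preference_value(S: np.ndarray, cfg: SimilarityConfig) -> float:
    if isinstance(cfg.preference, str):
        if cfg.preference != "median":
            raise ParameterError(f"unknown preference '{cfg.preference}'")
        n = S.shape[0]
        off = S[~np.eye(n, dtype=bool)]
        return float(np.median(off)) if off.size else 0.0
    return float(cfg.preference)


def affinity_propagation(
    S: np.ndarray, cfg: SimilarityConfig | None = None, seed: int = 0
) -> APResult:
    """Exemplar selection by damped responsibility/availability passing.

    The diagonal of a copy of S is set to the preference; messages are
    updated as ``new = damping * old + (1 - damping) * update`` until the
    exemplar set is stable for ``convergence_iter`` sweeps or ``max_iter``
    is reached. Each point is assigned to the exemplar maximizing its
    similarity (exemplars to themselves; equal-similarity ties go to the
    lowest index). If no exemplar emerges (fully degenerate input), the
    result falls back to a single exemplar at index 0 with
    ``converged=False``.
    """
    cfg = cfg or SimilarityConfig()
    S = np.array(S, dtype=np.float64)
    n = S.shape[0]
    if n == 1:
        return APResult([0], np.zeros(1, dtype=np.int64), True)
    pref = _preference_value(S, cfg)
    np.fill_diagonal(S, pref)
    if cfg.jitter > 0:
        rng = np.random.default_rng(seed)
        S = S + cfg.jitter * rng.standard_normal(S.shape)

    A = np.zeros((n, n))
    R = np.zeros((n, n))
    lam = cfg.damping
    idx = np.arange(n)
    stable = 0
    prev_ex: np.ndarray | None = None
    converged = False
    for _ in range(cfg.max_iter):
        # responsibilities
        AS = A + S
        top = AS.argmax(axis=1)
        first = AS[idx, top]
        AS[idx, top] = -np.inf
        second = AS.max(axis=1)
        AS[idx, top] = first
        Rnew = S - first[:, None]
        Rnew[idx, top] = S[idx, top] - second
        R = lam * R + (1.0 - lam) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0.0, colsum[None, :] - Rp)
        Anew[idx, idx] = colsum - Rp.diagonal()
        A = lam * A + (1.0 - lam) * Anew

        ex = np.flatnonzero(np.diag(A + R) > 0)
        if prev_ex is not None and ex.size and np.array_equal(ex, prev_ex):
            stable += 1
            if stable >= cfg.convergence_iter:
                converged = True
                break
        else:
            stable = 0
        prev_ex = ex

    exemplars = np.flatnonzero(np.diag(A + R) > 0)
    if exemplars.size == 0:
        return APResult([0], np.zeros(n, dtype=np.int64), False)
    # medoid refinement (standard final step of the reference procedure):
    # within each cluster, move the exemplar to the point maximizing the
    # intra-cluster similarity sum, then re-assign.
    cl = np.argmax(S[:, exemplars], axis=1)
    cl[exemplars] = np.arange(exemplars.size)
    for k in range(exemplars.size):
        members = np.flatnonzero(cl == k)
        j = members[np.argmax(S[np.ix_(members, members)].sum(axis=0))]
        exemplars[k] = j
    exemplars = np.unique(exemplars)
    assignment = exemplars[np.argmax(S[:, exemplars], axis=1)]
    assignment[exemplars] = exemplars
    return APResult(sorted(int(e) for e in exemplars), assignment.astype(np.int64), converged)


def net_similarity(S: np.ndarray, preference: float, exemplars: np.ndarray) -> float:
    """AP objective: sum of point-to-exemplar similarities + preferences."""
    S = np.asarray(S, dtype=np.float64)
    exemplars = np.asarray(exemplars)
    sub = S[:, exemplars].max(axis=1)
    sub[exemplars] = 0.0
    return float(sub.sum() + preference * len(exemplars))


def cluster_bag(
    bag: FeatureBag, cfg: SimilarityConfig | None = None, seed: int = 0
) -> np.ndarray:
    """Stage-1 AP on one bag; returns its exemplar rows (``c_i x d1``).

    The returned rows are exact rows of the bag's feature matrix. Bags
    larger than ``cfg.max_bag_instances`` are subsampled (seeded,
    without replacement) before clustering.
    """
    cfg = cfg or SimilarityConfig()
    feats = bag.features
    if feats.shape[0] > cfg.max_bag_instances:
        rng = np.random.default_rng(seed)
        keep = np.sort(
            rng.choice(feats.shape[0], size=cfg.max_bag_instances, replace=False)
        )
        feats = feats[keep]
    S = similarity_matrix(feats, cfg)
    res = affinity_propagation(S, cfg, seed=seed)
    return feats[np.asarray(res.exemplars, dtype=np.int64)]


def build_prototypes(
    train_bags: list[FeatureBag], cfg: SimilarityConfig | None = None, seed: int = 0
) -> PrototypeSet:
    """Two-stage prototype discovery on training bags only.

    Stage-1 exemplars from every bag are pooled into the union C and a
    second AP pass selects the final prototypes, strictly fewer than the
    union size whenever the union holds more than one point (if the
    second pass degenerately keeps every point, it is rerun with a more
    negative preference and, failing that, reduced to the single best
    exemplar by net similarity).
    """
    cfg = cfg or SimilarityConfig()
    if not train_bags:
        raise ParameterError("build_prototypes requires at least one training bag")
    stage1 = [cluster_bag(b, cfg, seed=seed) for b in train_bags]
    counts = [s.shape[0] for s in stage1]
    union = np.vstack(stage1)
    total = union.shape[0]
    if total == 1:
        return PrototypeSet(union.copy(), counts, [b.bag_id for b in train_bags], cfg)

    S = similarity_matrix(union, cfg)
    res = affinity_propagation(S, cfg, seed=seed)
    if len(res.exemplars) >= total:
        low = SimilarityConfig(
            beta=cfg.beta,
            damping=cfg.damping,
            max_iter=cfg.max_iter,
            convergence_iter=cfg.convergence_iter,
            preference=2.0 * float(S.min()) - 1.0,
            jitter=cfg.jitter,
            max_bag_instances=cfg.max_bag_instances,
        )
        res = affinity_propagation(S, low, seed=seed)
        if len(res.exemplars) >= total:
            pref = _preference_value(S, cfg)
            best = max(range(total), key=lambda k: net_similarity(S, pref, np.array([k])))
            res = APResult([best], np.full(total, best, dtype=np.int64), False)
    embeddings = union[np.asarray(res.exemplars, dtype=np.int64)]
    return PrototypeSet(embeddings, counts, [b.bag_id for b in train_bags], cfg)
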