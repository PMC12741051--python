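"""Weakly supervised linear metric learning over component distance matrices.

The emergent distance is a weighted sum ``D = sum_i w_i d_i`` of unit-scaled
component matrices. Weights are learned by exhaustive grid search: every
weight vector is combined, Ward-clustered, cut at a fractional height h, and
scored by element-centric similarity against partial ground-truth class
labels; the top-k vectors per h are averaged, and the stabilized weights are
the average over the plateau region of h.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .compare import element_centric_similarity
from .datatypes import DistanceMatrix, LigomapError, Partition
from .tree import build_tree, cut_fractional

DEFAULT_WEIGHT_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.1), 2))
DEFAULT_H_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.1), 2))


@dataclass(frozen=True)
class WeightVector:
    """Mapping measure -> positive weight, with grid provenance."""

    weights: tuple[tuple[str, float], ...]
    provenance: str = "grid"

    def __post_init__(self):
        object.__setattr__(
            self, "weights", tuple((m, float(w)) for m, w in self.weights)
        )
        if any(w <= 0 for _, w in self.weights):
            raise LigomapError("weights must be positive")

    @classmethod
    def from_dict(cls, d, provenance="grid"):
        return cls(tuple(d.items()), provenance)

    def as_dict(self) -> dict[str, float]:
        return dict(self.weights)

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[m] for m in order])


@dataclass
class WeightTrajectory:
    """Per-h summary of the grid search: top-k mean/SD weights and best S_EC."""

    measure_ids: tuple[str, ...]
    h_values: tuple[float, ...]
    mean_weights: np.ndarray  # (n_h, n_measures)
    sd_weights: np.ndarray
    best_sec: np.ndarray  # (n_h,)
    top_k: int = 100

    def __post_init__(self):
        hs = np.asarray(self.h_values)
        if (np.diff(hs) <= 0).any() or hs.min() <= 0 or hs.max() >= 1:
            raise LigomapError("h values must be strictly increasing in (0, 1)")
        if self.top_k < 1:
            raise LigomapError("top_k must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, h in enumerate(self.h_values):
            row = {"h": h, "best_sec": float(self.best_sec[i])}
            for j, m in enumerate(self.measure_ids):
                row[f"mean_{m}"] = float(self.mean_weights[i, j])
                row[f"sd_{m}"] = float(self.sd_weights[i, j])
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_weight_grid(
    measure_ids: Sequence[str], grid: Sequence[float] = DEFAULT_WEIGHT_GRID
) -> list[WeightVector]:
    """Full Cartesian product of grid values over measures, lexicographic order."""
    if not measure_ids or not len(grid):
        raise LigomapError("measures and grid must be non-empty")
    return [
        WeightVector(tuple(zip(measure_ids, combo)))
        for combo in itertools.product(sorted(set(grid)), repeat=len(measure_ids))
    ]


def combine(matrices: Sequence[DistanceMatrix], w: WeightVector) -> DistanceMatrix:
    """Elementwise weighted sum of scaled component matrices (the emergent distance)."""
    wd = w.as_dict()
    ids = [m.measure_id for m in matrices]
    if set(ids) != set(wd) or len(ids) != len(wd):
        raise LigomapError("weights must cover exactly the given measures")
    labels = matrices[0].labels
    total = np.zeros_like(matrices[0].values)
    for m in matrices:
        if not m.scaled:
            raise LigomapError(f"matrix {m.measure_id} is not unit-scaled")
        if m.labels != labels:
            raise LigomapError("matrices must share an identical label set")
        total = total + wd[m.measure_id] * m.values
    return DistanceMatrix(labels, total, measure_id="emergent", scaled=False)


def _rescaled_for_tree(d: DistanceMatrix) -> DistanceMatrix:
    """Re-scale a combined matrix to [0, 1] so fractional cutoffs are comparable."""
    v = d.values
    off = ~np.eye(d.n, dtype=bool)
    mn, mx = v[off].min(), v[off].max()
    if mx == mn:
        out = np.zeros_like(v)
    else:
        out = (v - mn) / (mx - mn)
        np.fill_diagonal(out, 0.0)
    return DistanceMatrix(d.labels, out, "emergent", scaled=True)


def score_weight_vector(
    matrices: Sequence[DistanceMatrix],
    w: WeightVector,
    labels: Partition,
    h_values: Sequence[float],
    alpha: float = 0.9,
) -> np.ndarray:
    """S_EC against ``labels`` of the emergent tree of ``w`` cut at each h."""
    d = _rescaled_for_tree(combine(matrices, w))
    tree = build_tree(d)
    elements = d.labels
    truth = Partition({e: labels.assignment[e] for e in elements})
    return np.array(
        [
            element_centric_similarity(cut_fractional(tree, h), truth, alpha=alpha)
            for h in h_values
        ]
    )


def learn_weights(
    matrices: Sequence[DistanceMatrix],
    labels: Partition,
    grid: Sequence[float] = DEFAULT_WEIGHT_GRID,
    h_grid: Sequence[float] = DEFAULT_H_GRID,
    top_k: int = 100,
    plateau_start: float = 0.9,
    alpha: float = 0.9,
) -> tuple[WeightTrajectory, WeightVector]:
    """Exhaustive grid search for emergent-metric weights.

    For each h, every grid weight vector is scored by S_EC of the cut
    emergent tree against the class labels; the ``top_k`` best vectors'
    weights are averaged (ties broken by enumeration order). The stabilized
    vector is the mean of those per-h means over ``h >= plateau_start``.
    """
    if labels.n_clusters < 2:
        raise LigomapError("labels must contain at least two classes")
    measure_ids = tuple(m.measure_id for m in matrices)
    vectors = enumerate_weight_grid(measure_ids, grid)
    if top_k > len(vectors):
        raise LigomapError("top_k exceeds the weight-grid size")
    h_values = tuple(sorted(h_grid))
    scores = np.empty((len(vectors), len(h_values)))
    for i, w in enumerate(vectors):
        scores[i] = score_weight_vector(matrices, w, labels, h_values, alpha=alpha)
    warr = np.array([v.as_array(measure_ids) for v in vectors])
    mean_w = np.empty((len(h_values), len(measure_ids)))
    sd_w = np.empty_like(mean_w)
    best = np.empty(len(h_values))
    for j in range(len(h_values)):
        # stable sort keeps enumeration order among S_EC ties
        order = np.argsort(-scores[:, j], kind="stable")[:top_k]
        mean_w[j] = warr[order].mean(axis=0)
        sd_w[j] = warr[order].std(axis=0)
        best[j] = scores[order[0], j]
    traj = WeightTrajectory(measure_ids, h_values, mean_w, sd_w, best, top_k=top_k)
    plateau = np.asarray(h_values) >= plateau_start
    if not plateau.any():
        raise LigomapError("no h values at or beyond the plateau start")
    stabilized = WeightVector(
        tuple(zip(measure_ids, mean_w[plateau].mean(axis=0))), provenance="stabilized"
    )
    return traj, stabilized


class EmergentMetricLearner(TransformerMixin, BaseEstimator):
    """Learn emergent-distance weights by grid search (sklearn estimator).

    ``fit(X, y)`` takes a list of scaled :class:`DistanceMatrix` (or an
    array of shape (n_measures, n, n) with ``measure_ids`` supplied) and
    per-protein class labels; ``transform(X)`` returns the combined emergent
    matrix under the learned stabilized weights.

    Attributes
    ----------
    weights_ : dict measure -> stabilized weight
    trajectory_ : WeightTrajectory over the h grid
    best_sec_ : best S_EC observed at any h
    """

    def __init__(
        self,
        grid: Sequence[float] = DEFAULT_WEIGHT_GRID,
        h_grid: Sequence[float] = DEFAULT_H_GRID,
        top_k: int = 100,
        plateau_start: float = 0.9,
        alpha: float = 0.9,
        measure_ids: Optional[Sequence[str]] = None,
    ):
        self.grid = grid
        self.h_grid = h_grid
        self.top_k = top_k
        self.plateau_start = plateau_start
        self.alpha = alpha
        self.measure_ids = measure_ids

    def _as_matrices(self, X) -> list[DistanceMatrix]:
        if all(isinstance(m, DistanceMatrix) for m in X):
            return list(X)
        arr = np.asarray(X, dtype=float)
        ids = self.measure_ids or [f"m{i}" for i in range(arr.shape[0])]
        labels = tuple(str(i) for i in range(arr.shape[1]))
        return [
            DistanceMatrix(labels, arr[i], measure_id=ids[i], scaled=True)
            for i in range(arr.shape[0])
        ]

    def fit(self, X, y):
        mats = self._as_matrices(X)
        if isinstance(y, Partition):
            labels = y
        else:
            labels = Partition.from_labels(mats[0].labels, y)
        self.trajectory_, stabilized = learn_weights(
            mats,
            labels,
            grid=self.grid,
            h_grid=self.h_grid,
            top_k=self.top_k,
            plateau_start=self.plateau_start,
            alpha=self.alpha,
        )
        self.weights_ = stabilized.as_dict()
        self.stabilized_ = stabilized
        self.best_sec_ = float(self.trajectory_.best_sec.max())
        return self

    def transform(self, X) -> DistanceMatrix:
        mats = self._as_matrices(X)
        return combine(mats, self.stabilized_)
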