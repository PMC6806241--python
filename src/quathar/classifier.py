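"""K-nearest-neighbors and the random-subspace KNN ensemble.

The KNN here is written out rather than delegated: prediction assigns a
query to the class with the largest conditional probability
``P(y = j | x) = (1/K)·Σ_{i∈A} 1[y_i = j]`` over the K nearest training
rows A under Euclidean distance, with explicitly deterministic
tie-breaking.  The random-subspace ensemble trains L such learners, each on
feature indices drawn uniformly *with replacement* (duplicates kept) and,
optionally, on a bagged row sample, and combines them by majority vote.

Tie-breaking rules (all deterministic, documented once here):

* equal distances at the K-th neighbor: the lower training-row index wins
  (stable sort order);
* equal class probabilities: the class of the nearest neighbor belonging
  to one of the tied classes wins;
* equal ensemble votes: the first learner's neighbor ordering decides,
  same rule; if the tied classes never occur in that learner, the
  lexicographically smallest class wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from ._rng import substream
from .features import FeatureTable

__all__ = [
    "KNNModel",
    "SubspaceEnsemble",
    "euclidean_distance",
    "knn_predict",
    "subspace_train",
    "subspace_predict",
]


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """√Σ(xᵢ − yᵢ)² for two equal-length feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


@dataclass
class KNNModel:
    """Instance-based classifier: stores the training set, defers all work
    to prediction time."""

    X: np.ndarray
    y: np.ndarray
    k: int = 5

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ValueError("training matrix and labels must align")
        if not 1 <= self.k <= len(self.X):
            raise ValueError(f"k must be in [1, {len(self.X)}], got {self.k}")
        self.classes_ = np.unique(self.y)

    # -- prediction ---------------------------------------------------------

    def _neighbor_order(self, queries: np.ndarray) -> np.ndarray:
        """Training-row indices sorted by distance; ties by lower index."""
        d = cdist(queries, self.X)
        return np.argsort(d, axis=1, kind="stable")

    def predict(self, queries: np.ndarray):
        """Labels and class-probability table for a batch of queries.

        Returns ``(labels (M,), probs (M, C))`` with probability columns
        ordered as ``self.classes_``.
        """
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        if queries.shape[1] != self.X.shape[1]:
            raise ValueError(
                f"query dimension {queries.shape[1]} != training dimension {self.X.shape[1]}"
            )
        order = self._neighbor_order(queries)
        knn = order[:, : self.k]
        y_codes = np.searchsorted(self.classes_, self.y)
        codes = y_codes[knn]  # (M, k)
        C = len(self.classes_)
        probs = np.stack([np.mean(codes == j, axis=1) for j in range(C)], axis=1)
        # winner by probability; only rows with a tied maximum need the
        # nearest-neighbor tie-break loop
        win = np.argmax(probs, axis=1)
        best = probs[np.arange(len(queries)), win]
        tied_rows = np.flatnonzero((probs == best[:, None]).sum(axis=1) > 1)
        labels = self.classes_[win]
        for m in tied_rows:
            labels[m] = self._argmax_class(probs[m], self.y[knn[m]])
        return labels, probs

    def _argmax_class(self, prob_row: np.ndarray, neigh_labels: np.ndarray):
        best = prob_row.max()
        tied = self.classes_[prob_row == best]
        if len(tied) == 1:
            return tied[0]
        tied_set = set(tied.tolist())
        for lab in neigh_labels:  # nearest-first
            if lab in tied_set:
                return lab
        return tied[0]


def knn_predict(model: KNNModel, x: np.ndarray):
    """Single-query convenience wrapper: ``(label, {class: probability})``."""
    labels, probs = model.predict(np.atleast_2d(x))
    return labels[0], dict(zip(model.classes_.tolist(), probs[0]))


@dataclass
class SubspaceEnsemble:
    """L KNN learners on random feature subsets, majority vote."""

    learners: list[KNNModel]
    feature_indices: list[np.ndarray]
    classes_: np.ndarray
    n_features_in: int
    k: int
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_learners(self) -> int:
        return len(self.learners)

    def predict(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        if queries.shape[1] != self.n_features_in:
            raise ValueError(
                f"query dimension {queries.shape[1]} != expected {self.n_features_in}"
            )
        classes = np.sort(self.classes_)
        C = len(classes)
        vote_counts = np.zeros((len(queries), C), dtype=int)
        for model, idx in zip(self.learners, self.feature_indices):
            labels, _ = model.predict(queries[:, idx])
            vote_counts[np.arange(len(queries)), np.searchsorted(classes, labels)] += 1
        win = np.argmax(vote_counts, axis=1)
        best = vote_counts[np.arange(len(queries)), win]
        out = classes[win].astype(object)
        tied_rows = np.flatnonzero((vote_counts == best[:, None]).sum(axis=1) > 1)
        if len(tied_rows):
            first = self.learners[0]
            first_order = first._neighbor_order(
                queries[np.ix_(tied_rows, self.feature_indices[0])]
            )
            for r, m in enumerate(tied_rows):
                tied = set(classes[vote_counts[m] == best[m]].tolist())
                winner = None
                for j in first_order[r]:  # first learner's neighbor ordering
                    if first.y[j] in tied:
                        winner = first.y[j]
                        break
                out[m] = winner if winner is not None else min(tied)
        return out

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a JSON artifact from which predictions replay bit-for-bit."""
        payload = {
            "k": self.k,
            "seed": self.seed,
            "n_features_in": self.n_features_in,
            "params": self.params,
            "classes": [str(c) for c in self.classes_],
            "learners": [
                {
                    "feature_indices": idx.tolist(),
                    "X": model.X.tolist(),
                    "y": [str(v) for v in model.y.tolist()],
                }
                for model, idx in zip(self.learners, self.feature_indices)
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SubspaceEnsemble":
        payload = json.loads(Path(path).read_text())
        learners, indices = [], []
        for entry in payload["learners"]:
            learners.append(
                KNNModel(np.array(entry["X"]), np.array(entry["y"]), payload["k"])
            )
            indices.append(np.array(entry["feature_indices"], dtype=int))
        return cls(
            learners,
            indices,
            np.array(payload["classes"]),
            payload["n_features_in"],
            payload["k"],
            payload["seed"],
            payload.get("params", {}),
        )


def subspace_train(
    table: FeatureTable,
    n_learners: int = 30,
    n_rows: int | None = None,
    n_subspace_features: int | None = None,
    k: int = 5,
    seed: int = 0,
    resample_rows: bool = True,
) -> SubspaceEnsemble:
    """Train the random-subspace KNN ensemble.

    Per learner, ``n_subspace_features`` feature indices are drawn uniformly
    with replacement (default ⌈D/2⌉, duplicates kept as-is) and, when
    ``resample_rows`` is set, ``n_rows`` training rows are drawn with
    replacement (default N, i.e. a bootstrap sample).  All draws come from
    named substreams of ``seed`` and are recorded on the ensemble for exact
    replay.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    N, D = table.X.shape
    n_rows = N if n_rows is None else n_rows
    d_l = int(np.ceil(D / 2)) if n_subspace_features is None else n_subspace_features
    if not 1 <= d_l:
        raise ValueError("n_subspace_features must be >= 1")
    if not 1 <= n_rows <= N:
        raise ValueError(f"n_rows must be in [1, {N}]")
    if n_learners < 1:
        raise ValueError("n_learners must be >= 1")
    learners, indices = [], []
    for l in range(n_learners):
        rng = substream(seed, "learner", l)
        idx = rng.integers(0, D, size=d_l)
        if resample_rows:
            rows = rng.integers(0, N, size=n_rows)
        else:
            rows = rng.permutation(N)[:n_rows]
        learners.append(KNNModel(table.X[np.ix_(rows, idx)], table.labels[rows], k))
        indices.append(idx)
    return SubspaceEnsemble(
        learners,
        indices,
        np.unique(table.labels),
        D,
        k,
        seed,
        params={
            "n_learners": n_learners,
            "n_rows": n_rows,
            "n_subspace_features": d_l,
            "resample_rows": resample_rows,
        },
    )


def subspace_predict(ens: SubspaceEnsemble, x: np.ndarray):
    """Majority-vote class for a single full-dimension query."""
    return ens.predict(np.atleast_2d(x))[0]
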