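"""Isolation forest for sequencing-artifact anomaly scoring.

An isolation forest scores a point by how quickly random axis-aligned
splits isolate it from a training cloud: points in sparse regions of
feature space are separated in few splits, points inside the bulk need
many. The anomaly score is

    s(x) = 2 ** (-E[h(x)] / c(psi))

where ``h(x)`` is the path length of ``x`` through a tree grown on a
subsample of size ``psi`` and ``c(m)`` is the average unsuccessful-search
path length of a binary search tree with ``m`` points:

    c(m) = 2 H(m - 1) - 2 (m - 1) / m   for m > 2,   c(2) = 1,  c(1) = 0

with ``H`` the harmonic number. Scores lie in ``(0, 1]``; higher means more
anomalous. Trees are grown to depth ``ceil(log2(psi))``; unresolved leaves
contribute ``c(leaf_size)`` to the path length.
"""

from __future__ import annotations

import json
import math
import warnings

import numpy as np

from .errors import CalibrationError, UrivarError

DEFAULT_N_TREES = 100
DEFAULT_PSI = 256


def harmonic_number(n: int) -> float:
    """H(n) = sum_{i=1}^{n} 1/i (exact summation)."""
    if n <= 0:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def average_path_length(m: int) -> float:
    """c(m): expected isolation depth of a uniformly random point among m."""
    if m <= 1:
        return 0.0
    if m == 2:
        return 1.0
    return 2.0 * harmonic_number(m - 1) - 2.0 * (m - 1) / m


# A tree is a nested list:  ["leaf", size]  or  [feature, threshold, L, R]
_LEAF = "leaf"


def _grow(X: np.ndarray, idx: np.ndarray, depth: int, limit: int, rng):
    if depth >= limit or len(idx) <= 1:
        return [_LEAF, int(len(idx))]
    sub = X[idx]
    lo = sub.min(axis=0)
    hi = sub.max(axis=0)
    usable = np.flatnonzero(hi > lo)
    if len(usable) == 0:  # all duplicate rows
        return [_LEAF, int(len(idx))]
    f = int(usable[rng.integers(len(usable))])
    split = float(rng.uniform(lo[f], hi[f]))
    left = idx[sub[:, f] < split]
    right = idx[sub[:, f] >= split]
    if len(left) == 0 or len(right) == 0:
        # degenerate draw exactly at the boundary; isolate the extremes
        order = np.argsort(sub[:, f], kind="stable")
        left, right = idx[order[:1]], idx[order[1:]]
    return [
        f,
        split,
        _grow(X, left, depth + 1, limit, rng),
        _grow(X, right, depth + 1, limit, rng),
    ]


def _path_length(tree, x: np.ndarray) -> float:
    depth = 0
    node = tree
    while node[0] != _LEAF:
        f, split = node[0], node[1]
        node = node[2] if x[f] < split else node[3]
        depth += 1
    return depth + average_path_length(node[1])


class IsolationForest:
    """Forest of random isolation trees with a calibratable score cutoff.

    Deterministic for a fixed seed. ``cutoff`` starts as None and is set by
    :func:`urivar.caller.calibrate`; callers refuse to run with an
    uncalibrated model.
    """

    def __init__(
        self,
        n_trees: int = DEFAULT_N_TREES,
        psi: int = DEFAULT_PSI,
        seed: int = 0,
    ) -> None:
        if n_trees < 1:
            raise UrivarError("n_trees must be >= 1")
        if psi < 2:
            raise UrivarError("subsample size psi must be >= 2")
        self.n_trees = int(n_trees)
        self.psi = int(psi)
        self.seed = int(seed)
        self.trees: list = []
        self.n_features: int | None = None
        self.cutoff: float | None = None

    # -- fitting ------------------------------------------------------------

    def fit(self, X: np.ndarray) -> "IsolationForest":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise UrivarError("training matrix must be 2-D and non-empty")
        if not np.all(np.isfinite(X)):
            raise UrivarError("training features must be finite")
        if len(X) < self.psi:
            warnings.warn(
                f"only {len(X)} training vectors; lowering psi from "
                f"{self.psi}",
                stacklevel=2,
            )
            self.psi = max(2, len(X))
        limit = math.ceil(math.log2(self.psi))
        rng = np.random.default_rng(self.seed)
        self.n_features = X.shape[1]
        self.trees = []
        for _ in range(self.n_trees):
            sub = rng.choice(len(X), size=self.psi, replace=False)
            self.trees.append(_grow(X, sub, 0, limit, rng))
        return self

    @property
    def fitted(self) -> bool:
        return bool(self.trees)

    # -- scoring ------------------------------------------------------------

    def mean_path_length(self, X: np.ndarray) -> np.ndarray:
        """E[h(x)] averaged over trees, one value per row of ``X``."""
        if not self.fitted:
            raise UrivarError("forest is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise UrivarError("features must be finite")
        if X.shape[1] != self.n_features:
            raise UrivarError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        out = np.zeros(len(X))
        for i, x in enumerate(X):
            out[i] = sum(_path_length(t, x) for t in self.trees) / self.n_trees
        return out

    def score(self, X: np.ndarray) -> np.ndarray:
        """Anomaly scores s(x) in (0, 1]; higher = more anomalous."""
        eh = self.mean_path_length(X)
        return 2.0 ** (-eh / average_path_length(self.psi))

    def score_one(self, x: np.ndarray) -> float:
        return float(self.score(np.atleast_2d(x))[0])

    def require_calibrated(self) -> float:
        if self.cutoff is None:
            raise CalibrationError(
                "the forest has no calibrated anomaly cutoff; run "
                "calibrate() (CLI: `urivar train`) before calling variants"
            )
        return self.cutoff

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "format_version": "1",
            "n_trees": self.n_trees,
            "psi": self.psi,
            "seed": self.seed,
            "n_features": self.n_features,
            "cutoff": self.cutoff,
            "trees": self.trees,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, separators=(",", ":"))

    @classmethod
    def from_json(cls, path) -> "IsolationForest":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != "1":
            raise UrivarError(
                f"unsupported forest format version: "
                f"{payload.get('format_version')!r}"
            )
        model = cls(
            n_trees=payload["n_trees"],
            psi=payload["psi"],
            seed=payload["seed"],
        )
        model.trees = payload["trees"]
        model.n_features = payload["n_features"]
        model.cutoff = payload["cutoff"]
        return model
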