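"""Dual regression: subject-level connectivity features from resting data.

Stage 1 regresses each resting volume on the group component maps jointly
(multiple regression over space), yielding per-subject component time
courses.  Stage 2 regresses each vertex's time course on each component
time course *separately* (single regressions with intercept) — the
appropriate choice for short runs, where a joint stage-2 fit is poorly
conditioned.  The resulting subject maps are normalised to zero mean and
unit Euclidean norm and prepended with an intercept column to form the
n x (1+K) feature matrix consumed by the predictive model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GroupComponentSet:
    """K group-level spatial component maps over n vertices."""

    maps: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        object.__setattr__(self, "maps", maps)
        if maps.shape[0] < 1:
            raise ValueError("need at least one component map")
        if np.any(np.all(maps == 0, axis=1)):
            raise ValueError("all-zero component map")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n(self) -> int:
        return self.maps.shape[1]


@dataclass(frozen=True)
class ConnectivityFeatures:
    """Subject design matrix X, n x (1+K), intercept first.

    Columns 1..K are the subject's normalised component maps: zero mean,
    unit Euclidean norm.
    """

    X: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be n x (1+K) with K >= 1")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first column must be the intercept (all ones)")

    @property
    def K(self) -> int:
        return self.X.shape[1] - 1

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def component_maps(self) -> np.ndarray:
        return self.X[:, 1:].T


def dual_regression_stage1(ts: np.ndarray, group_maps: GroupComponentSet,
                           ) -> np.ndarray:
    """Spatial multiple regression of each volume on the group maps.

    Group maps are demeaned first so a global offset in the data cannot
    leak into the time courses.  Returns a T x K matrix.
    """
    Y = np.asarray(ts, dtype=float)
    S = group_maps.maps - group_maps.maps.mean(axis=1, keepdims=True)
    if Y.shape[1] != S.shape[1]:
        raise ValueError("time series and maps live on different spaces")
    if Y.shape[0] < S.shape[0]:
        raise ValueError("need at least K time points")
    if np.linalg.matrix_rank(S) < S.shape[0]:
        raise ValueError("group maps are rank deficient after demeaning")
    # For each volume t: ts[t] ~ S.T @ a[t]  =>  A = Y pinv(S)
    coef, *_ = np.linalg.lstsq(S.T, Y.T, rcond=None)
    return coef.T


def dual_regression_stage2_single(ts: np.ndarray, timecourses: np.ndarray,
                                  ) -> np.ndarray:
    """Single regressions: each vertex on each component time course alone.

    The slope with an intercept equals cov(ts_v, tc_k) / var(tc_k), so the
    maps are insensitive to per-vertex offsets.  Returns K x n.
    """
    Y = np.asarray(ts, dtype=float)
    A = np.atleast_2d(np.asarray(timecourses, dtype=float))
    if A.shape[0] != Y.shape[0]:
        raise ValueError("time course length does not match the data")
    Ac = A - A.mean(axis=0, keepdims=True)
    var = np.sum(Ac ** 2, axis=0)
    if np.any(var == 0):
        raise ValueError("zero-variance component time course")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    return (Ac.T @ Yc) / var[:, None]


def normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Demean each map then scale to unit Euclidean norm (idempotent)."""
    M = np.atleast_2d(np.asarray(maps, dtype=float))
    M = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(M, axis=1)
    if np.any(norms == 0):
        raise ValueError("constant map cannot be normalised")
    return M / norms[:, None]


def extract_features(ts: np.ndarray, group_maps: GroupComponentSet,
                     ) -> ConnectivityFeatures:
    """Full feature pipeline: stage 1 -> stage 2 -> normalise -> intercept."""
    tcs = dual_regression_stage1(ts, group_maps)
    subject_maps = dual_regression_stage2_single(ts, tcs)
    normed = normalize_maps(subject_maps)
    X = np.column_stack([np.ones(normed.shape[1]), normed.T])
    return ConnectivityFeatures(X=X)
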