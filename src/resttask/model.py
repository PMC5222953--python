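"""Parcel-wise linear prediction of task activation from connectivity
features.

For each training subject i the coefficients are fitted analytically,
parcel by parcel:  beta_p^(i) = pinv(X_p^(i)) y_p^(i).  An aggregate
beta-hat is the unweighted element-wise mean over training subjects —
all others in leave-one-out, or the control group in the transfer regime —
and a test subject's predicted map is y-hat(v) = X(v, :) @ beta-hat(parcel(v)),
concatenated over parcels to cover every vertex exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dualreg import ConnectivityFeatures
from .spaces import Parcellation

PINV_RCOND = 1e-10  # relative singular-value cutoff for the pseudoinverse


@dataclass(frozen=True)
class ParcelwiseCoefficients:
    """One beta vector of length 1+K per parcel; `subject` tags provenance
    ("aggregate" for a mean model)."""

    betas: np.ndarray  # (P, 1+K)
    subject: str = "aggregate"

    def __post_init__(self) -> None:
        betas = np.asarray(self.betas, dtype=float)
        object.__setattr__(self, "betas", betas)
        if betas.ndim != 2:
            raise ValueError("betas must be P x (1+K)")

    @property
    def P(self) -> int:
        return self.betas.shape[0]


@dataclass(frozen=True)
class PredictedMap:
    """A predicted activation map with its training provenance."""

    values: np.ndarray
    regime: str
    training_subjects: tuple


def fit_subject(X: ConnectivityFeatures, y: np.ndarray,
                parcellation: Parcellation,
                subject: str = "subject") -> ParcelwiseCoefficients:
    """Minimum-norm least-squares fit within each parcel separately."""
    y = np.asarray(y, dtype=float)
    if y.shape != (X.n,):
        raise ValueError("y must be an n-vector on the feature space")
    if parcellation.n != X.n:
        raise ValueError("parcellation and features disagree on n")
    if np.any(~np.isfinite(X.X)) or np.any(~np.isfinite(y)):
        raise ValueError("NaN or inf in inputs")
    q = X.X.shape[1]
    betas = np.empty((parcellation.P, q))
    for p in range(1, parcellation.P + 1):
        idx = parcellation.vertices(p)
        if idx.size <= q:
            warnings.warn(
                f"parcel {p} has {idx.size} vertices for {q} coefficients; "
                "falling back to the minimum-norm solution", RuntimeWarning)
        betas[p - 1] = np.linalg.pinv(X.X[idx], rcond=PINV_RCOND) @ y[idx]
    return ParcelwiseCoefficients(betas=betas, subject=subject)


def aggregate_loo(all_betas: list, leave_out: int) -> ParcelwiseCoefficients:
    """Element-wise mean of all training betas excluding `leave_out`."""
    m = len(all_betas)
    if m < 2:
        raise ValueError("leave-one-out needs at least two subjects")
    if not 0 <= leave_out < m:
        raise ValueError("leave_out index out of range")
    stack = np.stack([b.betas for i, b in enumerate(all_betas)
                      if i != leave_out])
    return ParcelwiseCoefficients(betas=stack.mean(axis=0))


def aggregate_group(all_betas: list, subset) -> ParcelwiseCoefficients:
    """Element-wise mean over the given subject indices."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    stack = np.stack([all_betas[i].betas for i in subset])
    return ParcelwiseCoefficients(betas=stack.mean(axis=0))


def predict(X: ConnectivityFeatures, beta_hat: ParcelwiseCoefficients,
            parcellation: Parcellation, regime: str = "aggregate",
            training_subjects: tuple = ()) -> PredictedMap:
    """y-hat(v) = X(v, :) @ beta-hat(parcel(v)), concatenated over parcels."""
    if parcellation.P != beta_hat.P:
        raise ValueError("coefficients do not cover every parcel")
    if parcellation.n != X.n:
        raise ValueError("parcellation and features disagree on n")
    yhat = np.empty(X.n)
    for p in range(1, parcellation.P + 1):
        idx = parcellation.vertices(p)
        yhat[idx] = X.X[idx] @ beta_hat.betas[p - 1]
    return PredictedMap(values=yhat, regime=regime,
                        training_subjects=tuple(training_subjects))


def fit_global(X: ConnectivityFeatures, y: np.ndarray,
               subject: str = "subject") -> ParcelwiseCoefficients:
    """Single whole-brain model: the P=1 special case of fit_subject."""
    one_parcel = Parcellation(labels=np.ones(X.n, dtype=np.int64), P=1)
    return fit_subject(X, y, one_parcel, subject=subject)


def run_loo(features: list, observed_maps, parcellation: Parcellation):
    """Leave-one-out predictions for every subject.

    Returns (predictions m x n, per-subject ParcelwiseCoefficients).  No
    subject's own beta ever enters their aggregate.
    """
    m = len(features)
    if m < 2:
        raise ValueError("leave-one-out needs at least two subjects")
    observed_maps = np.asarray(observed_maps, dtype=float)
    betas = [fit_subject(features[i], observed_maps[i], parcellation,
                         subject=str(i)) for i in range(m)]
    preds = np.empty_like(observed_maps)
    for j in range(m):
        bhat = aggregate_loo(betas, leave_out=j)
        training = tuple(i for i in range(m) if i != j)
        preds[j] = predict(features[j], bhat, parcellation, regime="loo",
                           training_subjects=training).values
    return preds, betas


def run_transfer(features: list, observed_maps, parcellation: Parcellation,
                 train_idx, test_idx=None, betas: list | None = None):
    """Single aggregate model from `train_idx`, applied to `test_idx`
    (default: every subject).

    Returns (predictions len(test_idx) x n, beta_hat).  Test subjects'
    observed maps never touch the model.
    """
    train_idx = list(train_idx)
    if not train_idx:
        raise ValueError("training group is empty")
    observed_maps = np.asarray(observed_maps, dtype=float)
    if test_idx is None:
        test_idx = list(range(len(features)))
    else:
        test_idx = list(test_idx)
    if not test_idx:
        raise ValueError("test group is empty")
    if betas is None:
        train_betas = [fit_subject(features[i], observed_maps[i], parcellation,
                                   subject=str(i)) for i in train_idx]
        bhat = aggregate_group(train_betas, range(len(train_betas)))
    else:
        bhat = aggregate_group(betas, train_idx)
    preds = np.stack([
        predict(features[j], bhat, parcellation, regime="transfer",
                training_subjects=tuple(train_idx)).values
        for j in test_idx])
    return preds, bhat
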