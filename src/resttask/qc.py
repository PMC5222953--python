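"""Scan-quality metrics: temporal SNR and stimulus-correlated motion."""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.signal import detrend


def tsnr(timeseries: np.ndarray, summary: str = "median"):
    """Temporal signal-to-noise ratio per vertex plus a whole-scan summary.

    tSNR(v) = temporal mean / sd of the linearly detrended residual, so a
    slow scanner drift does not masquerade as noise.  Zero-variance
    vertices are excluded from the summary and reported as NaN.  The
    summary is the median over vertices by default (mean switchable).
    """
    Y = np.asarray(timeseries, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] < 3:
        raise ValueError("need at least three time points")
    mean = Y.mean(axis=0)
    resid = detrend(Y, axis=0, type="linear")
    sd = resid.std(axis=0, ddof=1)
    per_vertex = np.full(Y.shape[1], np.nan)
    ok = sd > 1e-10 * (np.abs(mean) + 1)  # numerically constant -> excluded
    per_vertex[ok] = mean[ok] / sd[ok]
    if not ok.any():
        raise ValueError("every vertex has zero temporal variance")
    reducer = np.median if summary == "median" else np.mean
    return per_vertex, float(reducer(per_vertex[ok]))


def stimulus_correlated_motion(motion: np.ndarray,
                               task_regressor: np.ndarray) -> float:
    """Maximum |Pearson r| between any motion trace and the task regressor.

    Constant traces are skipped; a value near 1 means head motion locked
    to the stimulus, which inflates apparent activation.
    """
    M = np.asarray(motion, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    reg = np.asarray(task_regressor, dtype=float)
    if M.shape[0] != reg.size:
        raise ValueError("motion traces and regressor lengths differ")
    if np.std(reg) == 0:
        raise ValueError("constant task regressor")
    best = 0.0
    any_ok = False
    for col in M.T:
        if np.std(col) == 0:
            continue
        any_ok = True
        best = max(best, abs(float(stats.pearsonr(col, reg)[0])))
    if not any_ok:
        raise ValueError("all motion traces are constant")
    return best
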