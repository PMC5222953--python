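"""First-level task GLM: block designs, double-gamma HRF, high-pass
filtering, and per-vertex least-squares activation maps.

The task is modelled as a boxcar convolved with the canonical double-gamma
haemodynamic response, with an optional temporal-derivative column, and data
and regressors are high-pass filtered consistently (default cutoff 100 s).
The exported activation map is the effect-size (COPE-like) estimate per
vertex; a t-map is available as well since either may serve as the
prediction target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma_dist

# Canonical double-gamma parameters: response peak delay 6 s, undershoot
# delay 16 s, both dispersions 1 s, undershoot ratio 1/6.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 1.0 / 6.0
HRF_DURATION = 32.0

DEFAULT_HIGHPASS_CUTOFF = 100.0  # seconds


@dataclass(frozen=True)
class BlockDesign:
    """On/off block timing in seconds.

    onsets are the starts of the active blocks; all blocks share one
    duration.  The default is the category-fluency run used throughout:
    5 cycles of 30 s task after 30 s baseline.
    """

    onsets: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float).ravel()
        object.__setattr__(self, "onsets", onsets)
        if onsets.size == 0:
            raise ValueError("need at least one block")
        if self.duration <= 0:
            raise ValueError("block duration must be positive")
        if np.any(np.diff(onsets) < self.duration):
            raise ValueError("blocks overlap or onsets are not increasing")

    @classmethod
    def block(cls, n_cycles: int = 5, on: float = 30.0, off: float = 30.0,
              start: float | None = None) -> "BlockDesign":
        """n_cycles of `off` s baseline followed by `on` s task (baseline
        first, so the first onset is at t = off by default)."""
        start = off if start is None else start
        onsets = start + np.arange(n_cycles) * (on + off)
        return cls(onsets=onsets, duration=on)

    @property
    def end(self) -> float:
        return float(self.onsets[-1] + self.duration)


@dataclass(frozen=True)
class DesignMatrix:
    """T x q design with named columns and the filter it was built with."""

    matrix: np.ndarray
    columns: tuple
    TR: float
    highpass_cutoff: float | None

    @property
    def q(self) -> int:
        return self.matrix.shape[1]

    def contrast_for(self, name: str) -> np.ndarray:
        c = np.zeros(self.q)
        c[self.columns.index(name)] = 1.0
        return c


def double_gamma_hrf(dt: float, duration: float = HRF_DURATION) -> np.ndarray:
    """Sample the canonical double-gamma HRF on a dt grid.

    h(t) = g(t; 6, 1) - (1/6) g(t; 16, 1) with g a gamma density; the kernel
    is scaled by dt so convolution approximates the continuous integral.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    peak = _gamma_dist.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP,
                           scale=HRF_PEAK_DISP)
    under = _gamma_dist.pdf(t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP,
                            scale=HRF_UNDERSHOOT_DISP)
    return (peak - HRF_RATIO * under) * dt


def _dct_basis(T: int, TR: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift regressors with periods longer than `cutoff`."""
    k_max = int(np.floor(2.0 * T * TR / cutoff))
    t = np.arange(T)
    cols = [np.ones(T)]
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * (t + 0.5) / T))
    return np.stack(cols, axis=1)


def highpass_filter(series: np.ndarray, cutoff: float, TR: float) -> np.ndarray:
    """Remove slow drifts by regressing out a discrete-cosine basis.

    Fluctuations with periods longer than `cutoff` seconds are attenuated;
    the output is demeaned.  Works on a (T,) vector or a (T, n) matrix.
    """
    if cutoff <= 2 * TR:
        raise ValueError("cutoff must exceed twice the TR")
    y = np.asarray(series, dtype=float)
    flat = y.ndim == 1
    if flat:
        y = y[:, None]
    basis = _dct_basis(y.shape[0], TR, cutoff)
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    out = y - basis @ coef
    return out[:, 0] if flat else out


def boxcar(design: BlockDesign, dt: float, total: float) -> np.ndarray:
    """0/1 stimulus function sampled every dt seconds over `total` seconds."""
    t = np.arange(0.0, total, dt)
    box = np.zeros_like(t)
    for onset in design.onsets:
        box[(t >= onset) & (t < onset + design.duration)] = 1.0
    return box


def task_regressor(design: BlockDesign, TR: float, T: int,
                   dt: float = 0.1) -> np.ndarray:
    """HRF-convolved boxcar sampled at the T frame times (unfiltered)."""
    total = T * TR
    if design.end > total:
        raise ValueError("design extends past the end of the run")
    box = boxcar(design, dt, total + HRF_DURATION)
    conv = np.convolve(box, double_gamma_hrf(dt))[: box.size]
    frame_idx = np.round(np.arange(T) * TR / dt).astype(int)
    return conv[frame_idx]


def build_design_matrix(design: BlockDesign, TR: float, T: int,
                        include_derivative: bool = True,
                        cutoff: float | None = DEFAULT_HIGHPASS_CUTOFF,
                        ) -> DesignMatrix:
    """Intercept + convolved task regressor (+ temporal derivative).

    The non-intercept columns are high-pass filtered with the same cutoff
    later applied to the data, so signal and model stay consistent.
    """
    reg = task_regressor(design, TR, T)
    cols = [np.ones(T), reg]
    names = ["intercept", "task"]
    if include_derivative:
        cols.append(np.gradient(reg, TR))
        names.append("task_derivative")
    X = np.stack(cols, axis=1)
    if cutoff is not None:
        X[:, 1:] = highpass_filter(X[:, 1:], cutoff, TR)
    if np.any(np.all(X == 0, axis=0)):
        raise ValueError("design matrix contains an all-zero column")
    return DesignMatrix(matrix=X, columns=tuple(names), TR=TR,
                        highpass_cutoff=cutoff)


def fit_first_level(timeseries: np.ndarray, design: DesignMatrix,
                    contrast: np.ndarray | None = None,
                    return_t: bool = False):
    """Per-vertex least squares; returns the contrast of parameter
    estimates (effect-size map), optionally with its t-map.

    The data are high-pass filtered with the design's cutoff before
    fitting, mirroring the filtering already applied to the regressors.
    """
    Y = np.asarray(timeseries, dtype=float)
    flat = Y.ndim == 1
    if flat:
        Y = Y[:, None]
    X = design.matrix
    T, q = X.shape
    if Y.shape[0] != T:
        raise ValueError("time series length does not match the design")
    if T <= q:
        raise ValueError("need more time points than regressors")
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("rank-deficient design matrix")
    if contrast is None:
        contrast = design.contrast_for("task")
    contrast = np.asarray(contrast, dtype=float)
    if contrast.size != q:
        raise ValueError("contrast length must equal the column count")
    if design.highpass_cutoff is not None:
        Y = highpass_filter(Y, design.highpass_cutoff, design.TR)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    cope = contrast @ beta
    if not return_t:
        return cope[0] if flat else cope
    resid = Y - X @ beta
    dof = T - q
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    c_var = contrast @ xtx_inv @ contrast
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = cope / np.sqrt(c_var * sigma2)
    if flat:
        return cope[0], tmap[0]
    return cope, tmap
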