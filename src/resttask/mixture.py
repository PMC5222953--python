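"""Gaussian + two-Gamma mixture thresholding and cluster-mass filtering.

Activation maps are thresholded for visualisation in two steps.  First an
expectation-maximisation fit of a three-component mixture — a Gaussian for
the noise around zero, a positive Gamma for activations and a negated Gamma
for deactivations (both anchored at zero) — and the height threshold is the
median of the fitted positive Gamma.  Second, suprathreshold vertices are
grouped into connected clusters and clusters whose mass (the sum of map
values over the cluster) falls below a role-specific threshold are dropped:
240 for observed maps, 120 for predicted maps, whose signal is weaker.
Thresholding is visualisation-grade only and never feeds the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm as norm_dist

from .spaces import ClusterSet, GrayordinateSpace, connected_components

MASS_THRESHOLD_OBSERVED = 240.0
MASS_THRESHOLD_PREDICTED = 120.0
_MIN_WEIGHT = 1e-8


@dataclass
class MixtureFit:
    """Fitted Gaussian + two-Gamma mixture.

    The Gamma components are anchored at zero: the positive Gamma is a
    density on x > 0, the negative one a density on -x > 0.
    """

    weights: np.ndarray        # (pi_gauss, pi_pos, pi_neg), sums to 1
    mean: float
    sd: float
    pos_shape: float
    pos_scale: float
    neg_shape: float
    neg_scale: float
    log_likelihood: float
    iterations: int
    converged: bool
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1) > 1e-8:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.sd <= 0:
            raise ValueError("Gaussian sd must be positive")
        for v in (self.pos_shape, self.pos_scale,
                  self.neg_shape, self.neg_scale):
            if v <= 0:
                raise ValueError("Gamma shapes and scales must be positive")


def _solve_gamma_shape(s: float) -> float:
    """Solve log(k) - digamma(k) = s for the weighted Gamma MLE shape."""
    s = max(s, 1e-10)
    # standard closed-form starting point
    k0 = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
    f = lambda k: np.log(k) - digamma(k) - s
    lo, hi = k0, k0
    while f(lo) < 0:
        lo /= 2
        if lo < 1e-8:
            return 1e-8
    while f(hi) > 0:
        hi *= 2
        if hi > 1e8:
            return 1e8
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)


def _component_densities(x: np.ndarray, w, mu, sd, ps, psc, ns, nsc):
    dens = np.zeros((3, x.size))
    dens[0] = w[0] * norm_dist.pdf(x, loc=mu, scale=sd)
    pos = x > 0
    neg = x < 0
    dens[1, pos] = w[1] * gamma_dist.pdf(x[pos], ps, scale=psc)
    dens[2, neg] = w[2] * gamma_dist.pdf(-x[neg], ns, scale=nsc)
    return dens


def _initial_params(x: np.ndarray, rng: np.random.Generator, jitter: float):
    q25, q75 = np.quantile(x, [0.25, 0.75])
    bulk = x[(x >= q25) & (x <= q75)]
    mu = float(np.mean(bulk))
    sd = max(float((q75 - q25) / 1.349), 1e-6)
    params = {"mu": mu, "sd": sd}
    for sign, key in ((1.0, "pos"), (-1.0, "neg")):
        vals = sign * x
        tail = vals[vals > mu * sign + 2 * sd]
        if tail.size < 10:
            v = vals[vals > 0]
            tail = np.sort(v)[-max(v.size // 20, 5):] if v.size else np.array([])
        if tail.size >= 2 and tail.var() > 0:
            shape = float(tail.mean() ** 2 / tail.var())
            scale = float(tail.var() / tail.mean())
        else:
            shape, scale = 2.0, max(sd, 1e-3)
        shape = float(np.clip(shape, 0.1, 100.0))
        scale = float(np.clip(scale, 1e-6, None))
        w = tail.size / x.size
        params[key] = (shape, scale, max(w, 1e-3))
    if jitter > 0:
        params["mu"] += rng.normal(0, jitter * sd)
        params["sd"] *= float(np.exp(rng.normal(0, jitter)))
        for key in ("pos", "neg"):
            sh, sc, w = params[key]
            params[key] = (sh * float(np.exp(rng.normal(0, jitter))),
                           sc * float(np.exp(rng.normal(0, jitter))), w)
    return params


def _em_once(x: np.ndarray, init: dict, max_iter: int, tol: float):
    n = x.size
    mu, sd = init["mu"], init["sd"]
    ps, psc, wp = init["pos"]
    ns, nsc, wn = init["neg"]
    w = np.array([max(1 - wp - wn, 0.1), wp, wn])
    w /= w.sum()
    ll_hist = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = _component_densities(x, w, mu, sd, ps, psc, ns, nsc)
        tot = dens.sum(axis=0)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.sum(np.log(tot)))
        ll_hist.append(ll)
        resp = dens / tot
        # M-step
        nk = resp.sum(axis=1)
        w = np.maximum(nk / n, _MIN_WEIGHT)
        w /= w.sum()
        # Gaussian
        if nk[0] > 1e-8:
            mu = float(resp[0] @ x / nk[0])
            sd = float(np.sqrt(max(resp[0] @ (x - mu) ** 2 / nk[0], 1e-12)))
        # Gammas (weighted MLE on each tail)
        for ci, sign in ((1, 1.0), (2, -1.0)):
            sel = sign * x > 0
            wsum = resp[ci, sel].sum()
            if wsum < 1e-8 * n:
                continue
            v = sign * x[sel]
            r = resp[ci, sel]
            m1 = float(r @ v / wsum)
            mlog = float(r @ np.log(v) / wsum)
            s = np.log(m1) - mlog
            if s <= 0:
                continue
            shape = _solve_gamma_shape(s)
            scale = m1 / shape
            if ci == 1:
                ps, psc = shape, scale
            else:
                ns, nsc = shape, scale
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    return MixtureFit(weights=w, mean=mu, sd=sd, pos_shape=ps, pos_scale=psc,
                      neg_shape=ns, neg_scale=nsc,
                      log_likelihood=ll_hist[-1], iterations=it,
                      converged=converged, ll_history=np.asarray(ll_hist))


def fit_ggm(values: np.ndarray, max_iter: int = 300, tol: float = 1e-6,
            seed: int = 0, restarts: int = 2) -> MixtureFit:
    """EM fit of the Gaussian + two-Gamma mixture.

    Initialisation takes the Gaussian from the interquartile bulk and each
    Gamma from method-of-moments on its tail; `restarts` jittered restarts
    are run and the best log-likelihood kept.  When one sign is absent from
    the data, the corresponding Gamma weight is pinned near zero.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError("need at least 100 finite values to fit the mixture")
    rng = np.random.default_rng(seed)
    best = None
    for r in range(restarts + 1):
        init = _initial_params(x, rng, jitter=0.0 if r == 0 else 0.3)
        fit = _em_once(x, init, max_iter, tol)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    return best


def threshold_from_fit(fit: MixtureFit) -> float:
    """Height threshold: median of the fitted positive Gamma component."""
    if fit.weights[1] <= 0.01:
        raise ValueError("positive Gamma component has vanishing weight")
    return float(gamma_dist.ppf(0.5, fit.pos_shape, scale=fit.pos_scale))


def cluster_mass(space: GrayordinateSpace, values: np.ndarray,
                 height_threshold: float) -> ClusterSet:
    """Connected suprathreshold clusters and their masses.

    The mass of a cluster is the sum of the map values over its vertices,
    so a narrow cluster of high values can match a wide cluster of low
    values.
    """
    v = np.asarray(values, dtype=float)
    if v.size != space.n:
        raise ValueError("map length must equal the number of vertices")
    active = v > height_threshold
    clusters = connected_components(space, active)
    masses = np.array([v[c].sum() for c in clusters])
    return ClusterSet(clusters=clusters, masses=masses)


def apply_cluster_mass_threshold(clusters: ClusterSet, mass_threshold: float,
                                 n: int) -> np.ndarray:
    """Boolean mask of the vertices in clusters with mass >= threshold."""
    if mass_threshold < 0:
        raise ValueError("mass threshold must be non-negative")
    mask = np.zeros(n, dtype=bool)
    for c, mass in zip(clusters.clusters, clusters.masses):
        if mass >= mass_threshold:
            mask[c] = True
    return mask


def threshold_map(values: np.ndarray, space: GrayordinateSpace,
                  role: str = "observed",
                  mass_threshold: float | None = None,
                  seed: int = 0) -> np.ndarray:
    """Full visualisation threshold: mixture height cut then cluster-mass cut.

    Exactly-zero vertices (e.g. inside lesions) are excluded from the
    mixture fit sample.  If the positive component vanishes — a map with no
    credible positive activation — the returned mask is empty.
    """
    if mass_threshold is None:
        if role == "observed":
            mass_threshold = MASS_THRESHOLD_OBSERVED
        elif role == "predicted":
            mass_threshold = MASS_THRESHOLD_PREDICTED
        else:
            raise ValueError("role must be 'observed' or 'predicted'")
    v = np.asarray(values, dtype=float)
    sample = v[v != 0]
    fit = fit_ggm(sample, seed=seed)
    try:
        height = threshold_from_fit(fit)
    except ValueError:
        return np.zeros(space.n, dtype=bool)
    clusters = cluster_mass(space, v, height)
    return apply_cluster_mass_threshold(clusters, mass_threshold, space.n)
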