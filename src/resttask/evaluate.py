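"""Prediction-quality statistics.

The central object is the m x m similarity matrix of Pearson correlations
between all subjects' observed maps (rows) and all subjects' predicted maps
(columns); its diagonal holds the matched pairs.  Individual identification
is quantified per subject with a one-sample t statistic on the diagonal
minus off-diagonal differences, with a sign-flip permutation null.  The
module also carries the surrounding group statistics: Welch diagonal vs
off-diagonal comparison, pooled two-sample group difference, one-way
pathology ANOVA, Dice overlap, lesion-union exclusion re-analysis,
regime-to-regime agreement, within-group variability, and QC correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SimilarityMatrix:
    """m x m observed-vs-predicted Pearson correlations."""

    S: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("similarity matrix must be square")

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def matched(self) -> np.ndarray:
        return np.diag(self.S)


@dataclass(frozen=True)
class SubjectTestResult:
    """Matched-vs-unmatched permutation test outcome for one subject."""

    subject: int
    t: float
    p: float
    n_perm: int
    significant: bool
    degenerate: bool = False


def _zscore_maps(maps: np.ndarray) -> np.ndarray:
    centred = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    if np.any(norms == 0):
        raise ValueError("constant map: Pearson correlation undefined")
    return centred / norms[:, None]


def similarity_matrix(observed: np.ndarray, predicted: np.ndarray,
                      mask: np.ndarray | None = None) -> SimilarityMatrix:
    """Entry (i, j) = Pearson r(observed_i, predicted_j).

    With a boolean `mask`, correlations use only the vertices where the
    mask is True (e.g. the complement of a lesion union).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted stacks must match in shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != obs.shape[1]:
            raise ValueError("mask length must equal the map length")
        if not mask.any():
            raise ValueError("mask excludes every vertex")
        obs, pred = obs[:, mask], pred[:, mask]
    S = _zscore_maps(obs) @ _zscore_maps(pred).T
    return SimilarityMatrix(S=np.clip(S, -1.0, 1.0), mask=mask)


def normalize_for_display(S: SimilarityMatrix) -> np.ndarray:
    """Row-standardise then column-standardise (visualisation only).

    Statistics are always computed on the raw matrix; this exists for
    heat-map rendering where rows/columns need a common scale.
    """
    M = S.S
    if S.m < 2:
        raise ValueError("need at least two subjects")
    sd_r = M.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd_r == 0):
        raise ValueError("zero-variance row")
    M = (M - M.mean(axis=1, keepdims=True)) / sd_r
    sd_c = M.std(axis=0, ddof=1, keepdims=True)
    if np.any(sd_c == 0):
        raise ValueError("zero-variance column")
    return (M - M.mean(axis=0, keepdims=True)) / sd_c


def _sign_flip_t(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics of sign-flipped copies of d; signs is (B, k) of +-1."""
    k = d.size
    flipped = signs * d
    mean = flipped.mean(axis=1)
    sd = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(k))
    t[sd == 0] = np.sign(mean[sd == 0]) * np.inf
    t[np.isnan(t)] = 0.0  # mean 0 and sd 0: all-zero d
    return t


def sign_flip_ttest(d: np.ndarray, n_perm: int = 10_000,
                    rng: np.random.Generator | None = None,
                    exhaustive: bool = False):
    """One-sided (mean > 0) one-sample t-test with a sign-flip null.

    Exact for independently sign-symmetric d.  Returns (t, p, n_used);
    with `exhaustive`, all 2^k sign patterns are enumerated and p is the
    exact proportion of t* >= t (the Monte-Carlo path uses the add-one
    estimator instead, so its p never reaches 0).
    """
    d = np.asarray(d, dtype=float)
    k = d.size
    if k < 2:
        raise ValueError("need at least two differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate d (zero variance)")
    t_obs = d.mean() / (sd / np.sqrt(k))
    if exhaustive:
        if k > 20:
            raise ValueError("exhaustive enumeration limited to k <= 20")
        patterns = np.arange(2 ** k)[:, None] >> np.arange(k)
        signs = (patterns & 1) * 2 - 1
        t_null = _sign_flip_t(d, signs)
        return float(t_obs), float(np.mean(t_null >= t_obs)), 2 ** k
    rng = np.random.default_rng() if rng is None else rng
    signs = rng.integers(0, 2, size=(n_perm, k)) * 2 - 1
    t_null = _sign_flip_t(d, signs)
    p = float((1 + np.sum(t_null >= t_obs)) / (1 + n_perm))
    return float(t_obs), p, n_perm


def matched_vs_unmatched_test(S: SimilarityMatrix, subject: int,
                              n_perm: int = 10_000,
                              rng: np.random.Generator | None = None,
                              alpha: float = 0.05,
                              axis: str = "row",
                              exhaustive: bool = False) -> SubjectTestResult:
    """One-sided sign-flip permutation t-test that the matched correlation
    exceeds the unmatched ones.

    d_k = S(j, j) - S(j, k) for k != j (row-wise: one observed map against
    all predictions; set axis="column" for the transpose convention).
    t = mean(d) / (sd(d) / sqrt(m - 1)); the null is built by randomly
    flipping the signs of d, and p = (1 + #{t* >= t}) / (1 + n_perm).
    With `exhaustive`, all 2^(m-1) sign patterns are enumerated instead and
    p is the exact proportion with t* >= t.
    """
    m = S.m
    if m < 3:
        raise ValueError("need at least three subjects")
    if not 0 <= subject < m:
        raise ValueError("subject index out of range")
    row = S.S[subject, :] if axis == "row" else S.S[:, subject]
    d = np.delete(S.S[subject, subject] - row, subject)
    k = d.size

    sd = d.std(ddof=1)
    if sd == 0:
        # Degenerate: sign flips cannot move a constant-magnitude d past
        # itself; report the extreme attainable p-value.
        if np.all(d > 0):
            t_obs, p = np.inf, 1.0 / (1 + n_perm)
        elif np.all(d < 0):
            t_obs, p = -np.inf, 1.0
        else:
            t_obs, p = 0.0, 1.0
        return SubjectTestResult(subject=subject, t=float(t_obs), p=float(p),
                                 n_perm=n_perm, significant=p < alpha,
                                 degenerate=True)

    t_obs, p, n_used = sign_flip_ttest(d, n_perm=n_perm, rng=rng,
                                       exhaustive=exhaustive)
    return SubjectTestResult(subject=subject, t=t_obs, p=p,
                             n_perm=n_used, significant=p < alpha)


def evaluate_identification(S: SimilarityMatrix, n_perm: int = 10_000,
                            seed: int = 0, alpha: float = 0.05) -> list:
    """Matched-vs-unmatched test for every subject.

    Each subject's permutation stream is spawned from the master seed so
    results are reproducible and order-independent.
    """
    children = np.random.SeedSequence(seed).spawn(S.m)
    return [matched_vs_unmatched_test(S, j, n_perm=n_perm,
                                      rng=np.random.default_rng(children[j]),
                                      alpha=alpha)
            for j in range(S.m)]


def fraction_significant(results: list) -> float:
    return float(np.mean([r.significant for r in results]))


def dice(maskA, maskB) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 0 when both masks are empty."""
    if isinstance(maskA, (set, frozenset)) or isinstance(maskB, (set, frozenset)):
        sa, sb = set(maskA), set(maskB)
        inter = len(sa & sb)
        total = len(sa) + len(sb)
    else:
        A = np.asarray(maskA)
        B = np.asarray(maskB)
        if A.dtype == bool or B.dtype == bool:
            if A.shape != B.shape:
                raise ValueError("masks live on different spaces")
            inter = np.sum(A & B)
            total = np.sum(A) + np.sum(B)
        else:
            sa, sb = set(np.ravel(A).tolist()), set(np.ravel(B).tolist())
            inter = len(sa & sb)
            total = len(sa) + len(sb)
    if total == 0:
        return 0.0
    return 2.0 * inter / total


def lesion_excluded_evaluation(observed: np.ndarray, predicted: np.ndarray,
                               lesion_masks, n_perm: int = 10_000,
                               seed: int = 0, alpha: float = 0.05):
    """Re-run the similarity analysis after excluding the union of all
    lesions from every subject's maps.

    Returns (SimilarityMatrix, list of SubjectTestResult, union mask).
    """
    masks = [np.asarray(m, dtype=bool) for m in lesion_masks if m is not None]
    if not masks:
        raise ValueError("need at least one lesion mask")
    union = np.logical_or.reduce(masks)
    if union.all():
        raise ValueError("lesion union covers every vertex")
    S = similarity_matrix(observed, predicted, mask=~union)
    results = evaluate_identification(S, n_perm=n_perm, seed=seed, alpha=alpha)
    return S, results, union


def group_difference_ttest(values, labels, group_a="control",
                           group_b="patient"):
    """Pooled-variance two-sample t-test (group_a minus group_b).

    Returns (t, df, p) with df = m - 2.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a = values[labels == group_a]
    b = values[labels == group_b]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two members")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), int(a.size + b.size - 2), float(p)


def diag_offdiag_test(S: SimilarityMatrix):
    """Welch two-sample t comparing matched (diagonal) against unmatched
    (off-diagonal) correlations; returns (t, welch_df, p, degenerate)."""
    if S.m < 3:
        raise ValueError("need at least three subjects")
    diag = np.diag(S.S)
    off = S.S[~np.eye(S.m, dtype=bool)]
    v1, v2 = diag.var(ddof=1), off.var(ddof=1)
    if v1 == 0 and v2 == 0:
        return np.nan, np.nan, np.nan, True
    n1, n2 = diag.size, off.size
    t, p = stats.ttest_ind(diag, off, equal_var=False)
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(t), float(df), float(p), False


def pathology_anova(values, groups):
    """One-way ANOVA of per-subject statistics across pathology groups.

    Returns (F, df1, df2, p) with df = (g - 1, N - g).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [values[groups == g] for g in np.unique(groups)]
    if len(levels) < 2 or any(len(v) < 2 for v in levels):
        raise ValueError("need >= 2 groups with >= 2 members each")
    F, p = stats.f_oneway(*levels)
    g, N = len(levels), values.size
    return float(F), g - 1, N - g, float(p)


def compare_analyses(matched_a, matched_b) -> float:
    """Pearson correlation of per-subject matched similarities between two
    training regimes (e.g. leave-one-out vs transfer)."""
    a = np.asarray(matched_a, dtype=float)
    b = np.asarray(matched_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("the two analyses cover different subjects")
    return float(stats.pearsonr(a, b)[0])


def intersubject_variability(maps: np.ndarray, labels) -> dict:
    """All within-group pairwise Pearson correlations of subject maps.

    Lower correlations mean higher between-subject variability.  Returns
    {group: {"correlations", "mean", "sd"}}.
    """
    maps = np.asarray(maps, dtype=float)
    labels = np.asarray(labels)
    out = {}
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            raise ValueError(f"group {g!r} needs at least two subjects")
        Z = _zscore_maps(maps[idx])
        C = Z @ Z.T
        vals = C[np.triu_indices(idx.size, k=1)]
        out[str(g)] = {"correlations": vals,
                       "mean": float(vals.mean()),
                       "sd": float(vals.std(ddof=1))}
    return out


def qc_correlation(per_subject_stat, measure):
    """Pearson correlation between model performance and a per-subject QC
    scalar; returns (r, two-sided p)."""
    x = np.asarray(per_subject_stat, dtype=float)
    y = np.asarray(measure, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matching vectors with >= 3 subjects")
    if np.std(y) == 0 or np.std(x) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
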