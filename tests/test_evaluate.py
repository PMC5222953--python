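"""Similarity matrices, the per-subject sign-flip test, and the group
statistics around them."""

import numpy as np
import pytest
from scipy import stats

from resttask.evaluate import (SimilarityMatrix, compare_analyses,
                               diag_offdiag_test, dice,
                               evaluate_identification, fraction_significant,
                               group_difference_ttest,
                               intersubject_variability,
                               lesion_excluded_evaluation,
                               matched_vs_unmatched_test,
                               normalize_for_display, pathology_anova,
                               qc_correlation, sign_flip_ttest,
                               similarity_matrix)


def test_similarity_matrix_diagonal_and_affine_invariance(rng):
    maps = rng.normal(size=(6, 80))
    S = similarity_matrix(maps, maps)
    assert np.allclose(np.diag(S.S), 1.0)
    S2 = similarity_matrix(maps, 2.5 * maps + 3.0)
    assert np.allclose(S.S, S2.S, atol=1e-12)


def test_similarity_matrix_matches_pairwise_pearson_oracle(rng):
    obs = rng.normal(size=(5, 60))
    pred = rng.normal(size=(5, 60))
    S = similarity_matrix(obs, pred).S
    for i in range(5):
        for j in range(5):
            assert S[i, j] == pytest.approx(
                stats.pearsonr(obs[i], pred[j])[0], abs=1e-10)


def test_similarity_matrix_mask_restricts_vertices(rng):
    obs = rng.normal(size=(4, 50))
    pred = rng.normal(size=(4, 50))
    mask = np.zeros(50, dtype=bool)
    mask[:30] = True
    S = similarity_matrix(obs, pred, mask=mask).S
    direct = similarity_matrix(obs[:, :30], pred[:, :30]).S
    assert np.allclose(S, direct)
    with pytest.raises(ValueError):
        similarity_matrix(obs, pred, mask=np.zeros(50, dtype=bool))


def test_display_normalization_standardises_columns(rng):
    S = similarity_matrix(rng.normal(size=(5, 40)), rng.normal(size=(5, 40)))
    raw = S.S.copy()
    M = normalize_for_display(S)
    assert np.allclose(M.mean(axis=0), 0, atol=1e-10)
    assert np.allclose(M.std(axis=0, ddof=1), 1, atol=1e-10)
    # identity-like matrix keeps its diagonal maximal per row
    eye = SimilarityMatrix(S=np.eye(5) * 0.9 + 0.05)
    Me = normalize_for_display(eye)
    assert np.all(np.argmax(Me, axis=1) == np.arange(5))
    # display normalisation never mutates the matrix used for statistics
    assert np.array_equal(S.S, raw)


def test_sign_flip_test_degenerate_constant_differences():
    # all d = +0.3: flips can never beat the observed t
    S = np.full((5, 5), 0.2)
    np.fill_diagonal(S, 0.5)
    res = matched_vs_unmatched_test(SimilarityMatrix(S=S), 0, n_perm=999)
    assert res.degenerate and res.p == pytest.approx(1 / 1000)
    res_neg = matched_vs_unmatched_test(SimilarityMatrix(S=-S), 0, n_perm=999)
    assert res_neg.degenerate and res_neg.p == 1.0


def test_sign_flip_test_is_calibrated_on_iid_differences():
    """For iid symmetric d the permutation test rejects at ~alpha."""
    rng = np.random.default_rng(0)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        d = rng.standard_normal(10)
        _, p, _ = sign_flip_ttest(d, n_perm=500, rng=rng)
        rejections += p < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def test_sign_flip_mc_matches_exhaustive_enumeration():
    rng = np.random.default_rng(42)
    d = rng.standard_normal(10) + 0.4
    t_ex, p_ex, n_ex = sign_flip_ttest(d, exhaustive=True)
    assert n_ex == 1024
    t_mc, p_mc, _ = sign_flip_ttest(d, n_perm=10_000,
                                    rng=np.random.default_rng(1))
    assert t_mc == pytest.approx(t_ex)
    mc_err = 3 * np.sqrt(p_ex * (1 - p_ex) / 10_000) + 1e-4
    assert abs(p_mc - p_ex) < mc_err + 2e-3


def test_evaluate_identification_is_seed_reproducible(rng):
    maps = rng.normal(size=(6, 100))
    preds = maps + rng.normal(size=(6, 100))
    S = similarity_matrix(maps, preds)
    a = evaluate_identification(S, n_perm=500, seed=3)
    b = evaluate_identification(S, n_perm=500, seed=3)
    assert [r.p for r in a] == [r.p for r in b]
    assert fraction_significant(a) == np.mean([r.significant for r in a])


def test_dice_examples_and_oracle(rng):
    assert dice({1, 2, 3}, {2, 3, 4}) == pytest.approx(4 / 6)
    assert dice({1, 2}, {1, 2}) == 1.0
    assert dice({1}, {2}) == 0.0
    assert dice(np.zeros(5, bool), np.zeros(5, bool)) == 0.0
    for _ in range(5):
        a = rng.random(40) < 0.4
        b = rng.random(40) < 0.4
        sa, sb = set(np.flatnonzero(a)), set(np.flatnonzero(b))
        oracle = 2 * len(sa & sb) / (len(sa) + len(sb)) if (sa or sb) else 0.0
        assert dice(a, b) == pytest.approx(oracle)


def test_lesion_exclusion_wiring(rng):
    obs = rng.normal(size=(6, 120))
    preds = obs + 0.3 * rng.normal(size=(6, 120))
    with pytest.raises(ValueError):
        lesion_excluded_evaluation(obs, preds, [])
    with pytest.raises(ValueError):
        lesion_excluded_evaluation(obs, preds, [np.ones(120, bool)])
    # adversarial: mask away all the shared signal -> correlations collapse
    signal = rng.normal(size=60)
    obs2 = np.stack([np.concatenate([signal, rng.normal(size=60) * 0.1])
                     for _ in range(6)])
    pred2 = np.stack([np.concatenate([signal, rng.normal(size=60) * 0.1])
                      for _ in range(6)])
    mask = np.zeros(120, bool)
    mask[:60] = True
    S_masked, _, union = lesion_excluded_evaluation(obs2, pred2, [mask],
                                                    n_perm=200)
    S_full = similarity_matrix(obs2, pred2)
    assert union.sum() == 60
    assert np.abs(S_masked.S).mean() < 0.3 < S_full.S.mean()


def test_group_ttest_matches_pooled_oracle():
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([2.0, 4.0, 6.0, 8.0])
    t, df, p = group_difference_ttest(np.concatenate([a, b]),
                                      np.array(["c"] * 3 + ["p"] * 4),
                                      group_a="c", group_b="p")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / 5
    t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 4))
    assert t == pytest.approx(t_oracle)
    assert df == 5
    same = np.array([1.0, 2.0, 1.0, 2.0])
    t0, _, _ = group_difference_ttest(same, np.array(["c", "c", "p", "p"]),
                                      "c", "p")
    assert t0 == pytest.approx(0.0)


def test_diag_offdiag_welch_df_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    S = similarity_matrix(rng.normal(size=(8, 60)),
                          rng.normal(size=(8, 60)))
    t, df, p, degen = diag_offdiag_test(S)
    assert not degen
    diag = np.diag(S.S)
    off = S.S[~np.eye(8, dtype=bool)]
    ref = pingouin.ttest(diag, off, correction=True)
    assert t == pytest.approx(float(ref["T"].iloc[0]), abs=1e-8)
    assert df == pytest.approx(float(ref["dof"].iloc[0]), abs=1e-6)
    const = SimilarityMatrix(S=np.full((4, 4), 0.5))
    assert diag_offdiag_test(const)[3] is True


def test_diag_offdiag_large_on_matched_cohort(default_run):
    t, df, p, _ = diag_offdiag_test(default_run["S"])
    assert t > 5 and p < 1e-4


def test_pathology_anova_identities(rng):
    x = rng.normal(size=12)
    g2 = np.array(["a"] * 6 + ["b"] * 6)
    F, df1, df2, p = pathology_anova(x, g2)
    t, df, _ = group_difference_ttest(x, g2, "a", "b")
    assert F == pytest.approx(t ** 2, abs=1e-10)
    assert (df1, df2) == (1, 10)
    # null simulation: mean F near 1
    Fs = [pathology_anova(np.random.default_rng(s).normal(size=15),
                          np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5))[0]
          for s in range(50)]
    assert 0.5 < np.mean(Fs) < 2.0


def test_compare_analyses_limits():
    assert compare_analyses([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert compare_analyses([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        compare_analyses([1, 2], [1, 2, 3])


def test_intersubject_variability_oracle(rng):
    maps = rng.normal(size=(6, 40))
    labels = np.array(["a"] * 3 + ["b"] * 3)
    out = intersubject_variability(maps, labels)
    pairs = [(0, 1), (0, 2), (1, 2)]
    oracle = [stats.pearsonr(maps[i], maps[j])[0] for i, j in pairs]
    assert np.allclose(sorted(out["a"]["correlations"]), sorted(oracle),
                       atol=1e-10)
    same = np.tile(rng.normal(size=40), (4, 1))
    ident = intersubject_variability(same, np.array(["g"] * 4))
    assert np.allclose(ident["g"]["correlations"], 1.0)


def test_qc_correlation_behaviour(rng):
    t_stats = rng.normal(size=20)
    r, p = qc_correlation(t_stats, t_stats)
    assert r == pytest.approx(1.0)
    # closed-form oracle
    x, y = rng.normal(size=20), rng.normal(size=20)
    r2, _ = qc_correlation(x, y)
    oracle = (np.mean(x * y) - x.mean() * y.mean()) / (np.std(x) * np.std(y))
    assert r2 == pytest.approx(oracle, abs=1e-10)
    rs = [qc_correlation(np.random.default_rng(s).normal(size=30),
                         np.random.default_rng(1000 + s).normal(size=30))[0]
          for s in range(30)]
    assert abs(np.mean(rs)) < 0.15
    with pytest.raises(ValueError):
        qc_correlation(t_stats, np.full(20, 2.0))
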