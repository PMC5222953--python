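"""Synthetic cohort generator: determinism, planted structure, and the
generative properties downstream modules rely on."""

import numpy as np
import pytest

import resttask as rt
from resttask import glm
from resttask.simulate import (decorrelated_timecourses, generate_group_maps,
                               generate_lesion_mask,
                               generate_resting_timeseries,
                               generate_subject_maps, generate_task_map,
                               generate_task_timeseries, save_cohort)
from resttask.spaces import build_lattice_space, connected_components


def small_space():
    return build_lattice_space(30, 30)


def test_group_maps_are_bounded_in_pairwise_correlation(rng):
    space = small_space()
    maps = generate_group_maps(space, 10, rng)
    C = np.corrcoef(maps)
    off = np.abs(C[~np.eye(10, dtype=bool)])
    assert off.max() < 0.5
    # single bump: positive, max 1 at its centre
    single = generate_group_maps(space, 1, np.random.default_rng(0))
    assert single.max() == pytest.approx(1.0)
    assert single.min() >= 0


def test_group_maps_deterministic_and_validate():
    space = small_space()
    a = generate_group_maps(space, 4, np.random.default_rng(9))
    b = generate_group_maps(space, 4, np.random.default_rng(9))
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        generate_group_maps(build_lattice_space(2, 2), 5,
                            np.random.default_rng(0))


def test_subject_maps_spread_behaviour():
    space = small_space()
    rng = np.random.default_rng(3)
    g = generate_group_maps(space, 2, rng)
    assert np.array_equal(generate_subject_maps(g, 0.0, rng, space), g)
    # mean squared deviation grows monotonically in the spread (20 seeds)
    msds = []
    for spread in (0.1, 0.3, 0.9):
        acc = 0.0
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            acc += np.mean((generate_subject_maps(g, spread, r, space) - g) ** 2)
        msds.append(acc / 20)
    assert msds[0] < msds[1] < msds[2]
    # distinct subjects draw distinct maps
    r = np.random.default_rng(5)
    s1 = generate_subject_maps(g, 0.2, r, space)
    s2 = generate_subject_maps(g, 0.2, r, space)
    assert not np.array_equal(s1, s2)
    with pytest.raises(ValueError):
        generate_subject_maps(g, -0.1, r, space)


def test_resting_timeseries_structure(rng):
    maps = generate_group_maps(small_space(), 1, rng)
    ts = generate_resting_timeseries(maps, 30, sigma=0.0, rng=rng)
    # rank-1: every vertex proportional to the single time course
    assert np.linalg.matrix_rank(ts, tol=1e-8) == 1
    maps3 = generate_group_maps(small_space(), 3, np.random.default_rng(0))
    ts3 = generate_resting_timeseries(maps3, 20, sigma=0.0,
                                      rng=np.random.default_rng(1))
    assert np.linalg.matrix_rank(ts3, tol=1e-8) <= 3
    with pytest.raises(ValueError):
        generate_resting_timeseries(maps3, 3, 0.0, rng)


def test_resting_variance_decomposes_into_signal_plus_noise():
    maps = generate_group_maps(small_space(), 2, np.random.default_rng(2))
    maps = maps[:, :100]
    sigma = 2.0
    ts = generate_resting_timeseries(maps, 3000, sigma,
                                     np.random.default_rng(3))
    signal_var = np.sum(maps ** 2, axis=0)  # unit-variance time courses
    expected = signal_var + sigma ** 2
    got = ts.var(axis=0, ddof=1)
    assert np.allclose(got, expected, rtol=0.15)


def test_decorrelated_timecourses_are_exactly_white():
    A = decorrelated_timecourses(40, 5, np.random.default_rng(0))
    assert np.allclose(A.mean(axis=0), 0, atol=1e-12)
    C = np.cov(A.T, ddof=1)
    assert np.allclose(C, np.eye(5), atol=1e-10)


def test_task_map_generation(tiny_cohort):
    c = tiny_cohort
    X = c.truth.true_features[0]
    coupling = c.truth.parcel_coupling
    rng = np.random.default_rng(0)
    y = generate_task_map(X, coupling, c.parcellation, 0.0, rng)
    # zero noise: refitting by least squares leaves zero residual
    for p in range(1, c.parcellation.P + 1):
        idx = c.parcellation.vertices(p)
        beta, res, *_ = np.linalg.lstsq(X.X[idx], y[idx], rcond=None)
        assert np.allclose(X.X[idx] @ beta, y[idx], atol=1e-8)
    # zero coupling -> identically zero
    assert np.allclose(
        generate_task_map(X, np.zeros_like(coupling), c.parcellation, 0.0,
                          rng), 0)
    # intercept-only coupling -> constant within each parcel
    const = np.zeros_like(coupling)
    const[:, 0] = np.arange(1, coupling.shape[0] + 1)
    yc = generate_task_map(X, const, c.parcellation, 0.0, rng)
    for p in range(1, c.parcellation.P + 1):
        vals = yc[c.parcellation.vertices(p)]
        assert np.allclose(vals, p)


def test_task_timeseries_zero_map_and_design_validation(rng):
    design = glm.BlockDesign.block()
    ts = generate_task_timeseries(np.zeros(20), design, 3.0, 101, 0.0, rng)
    assert np.allclose(ts, 0)
    with pytest.raises(ValueError):
        generate_task_timeseries(np.zeros(20), design, 3.0, 50, 0.0, rng)
    reg = glm.task_regressor(design, 3.0, 101)
    elevated = reg > 0.5 * reg.max()
    assert np.sum(np.diff(np.concatenate([[0], elevated.view(np.int8)])) == 1) == 5


def test_lesions_are_connected_and_null_planted_signal(default_cohort):
    c = default_cohort
    space = c.space
    assert generate_lesion_mask(space, 10, 0).sum() == 1
    with pytest.raises(ValueError):
        generate_lesion_mask(space, space.n + 1, 2)
    lesioned = [i for i, m in enumerate(c.truth.lesion_masks) if m is not None]
    assert lesioned, "default cohort should contain lesioned patients"
    for i in lesioned:
        mask = c.truth.lesion_masks[i]
        assert len(connected_components(space, mask)) == 1
        assert np.allclose(c.truth.subject_task_maps[i][mask], 0)
        assert np.allclose(np.stack(c.truth.subject_maps[i])[:, mask], 0)


def test_cohort_determinism_and_layout():
    spec = rt.CohortSpec(n_controls=3, n_patients=2, K=2, P=3, width=16,
                         height=12, T_rest=30, seed=11)
    a = rt.generate_cohort(spec)
    b = rt.generate_cohort(spec)
    assert np.array_equal(a.subjects[0].rest_ts, b.subjects[0].rest_ts)
    assert np.array_equal(a.truth.subject_task_maps, b.truth.subject_task_maps)
    assert a.m == 5 and a.labels.tolist() == ["control"] * 3 + ["patient"] * 2


def test_control_only_cohort_has_no_lesions():
    spec = rt.CohortSpec(n_controls=4, n_patients=0, K=2, P=3, width=16,
                         height=12, T_rest=30, seed=1)
    c = rt.generate_cohort(spec)
    assert all(m is None for m in c.truth.lesion_masks)
    assert set(c.labels) == {"control"}


def test_patients_are_more_variable_than_controls():
    """Within-group pairwise correlations of planted task maps are lower in
    patients, averaged over 10 generator seeds."""
    from resttask.evaluate import intersubject_variability
    diffs = []
    for seed in range(10):
        spec = rt.CohortSpec(n_controls=4, n_patients=4, K=3, P=4, width=24,
                             height=18, T_rest=40, seed=200 + seed)
        c = rt.generate_cohort(spec)
        var = intersubject_variability(c.truth.subject_task_maps, c.labels)
        diffs.append(var["control"]["mean"] - var["patient"]["mean"])
    assert np.mean(diffs) > 0


def test_invalid_specs_are_rejected():
    with pytest.raises(ValueError):
        rt.CohortSpec(subject_spread_control=0.5,
                      subject_spread_patient=0.1).validate()
    with pytest.raises(ValueError):
        rt.CohortSpec(T_rest=5, K=8).validate()
    with pytest.raises(ValueError):
        rt.CohortSpec(lesion_fraction=1.5).validate()


def test_save_cohort_writes_manifest_and_truth_separately(tmp_path,
                                                          tiny_cohort):
    save_cohort(tiny_cohort, tmp_path)
    assert (tmp_path / "manifest.json").exists()
    assert (tmp_path / "parcellation.txt").exists()
    assert (tmp_path / "truth" / "parcel_coupling.tsv").exists()
    assert (tmp_path / "sub-000_rest.tsv").exists()
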