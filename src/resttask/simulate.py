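"""Synthetic fMRI cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
resting time series driven by shared spatial components with smooth
subject-specific deviations, task activation maps linearly coupled —
parcel by parcel — to the subject's own connectivity features, a patient
group with larger between-subject variability than controls, and
signal-nulling lesions in a subset of patients.  Everything is
deterministic under the spec's seed and the planted quantities are kept
in a GroundTruth object so downstream evaluation cannot silently leak
them.

Component time courses are drawn Gaussian and then exactly decorrelated
(column-centred QR, rescaled to unit sample variance).  This makes the
planted subject maps exactly identifiable by dual regression at finite run
length: with merely independent draws the O(1/sqrt(T)) empirical
cross-correlation of time courses mixes components in stage 2 and leaves
an O(K/T) bias in the recovered coupling even at zero noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import glm
from .dualreg import ConnectivityFeatures, GroupComponentSet, normalize_maps
from .model import PINV_RCOND
from .spaces import (GrayordinateSpace, Parcellation, build_lattice_space,
                     graph_ball, winner_takes_all)

PATHOLOGY_WEIGHTS = {"TLE": 42, "TUM": 20, "other": 9}  # clinical mix


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Timing defaults mirror the clinical protocol (85 resting volumes at
    TR 3.5 s; 101 task volumes at TR 3 s; 5 cycles of 30 s on / 30 s off).
    The spatial scale defaults to a 50 x 40 lattice (n = 2,000) with K = 8
    components, P = 10 parcels and 15 + 15 subjects: large enough for
    stable statistics, small enough for seconds-scale runs.  Patients get
    twice the spatial-deviation scale of controls and ~38% of them carry a
    signal-nulling lesion.
    """

    n_controls: int = 15
    n_patients: int = 15
    K: int = 8
    P: int = 10
    width: int = 50
    height: int = 40
    T_rest: int = 85
    TR_rest: float = 3.5
    T_task: int = 101
    TR_task: float = 3.0
    sigma_rest: float = 0.5
    sigma_rest_jitter: float = 0.3   # lognormal sd of per-subject scan quality
    sigma_task: float = 1.0          # task time-series noise
    sigma_task_map: float = 1.0      # subject-specific unmodelled activation
    sigma_task_map_patient_factor: float = 1.5  # pathology adds model mismatch
    subject_spread_control: float = 0.3
    subject_spread_patient: float = 0.6
    lesion_fraction: float = 27 / 71
    lesion_radius: int = 3
    baseline: float = 100.0
    coupling_scale: float | None = None  # default sqrt(n): O(1) map variance
    motion_task_locked_max: float = 0.3
    seed: int = 0

    @property
    def n(self) -> int:
        return self.width * self.height

    @property
    def m(self) -> int:
        return self.n_controls + self.n_patients

    def validate(self) -> None:
        if min(self.n_controls, self.K, self.P, self.width, self.height) < 1:
            raise ValueError("counts must be at least 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.T_rest <= self.K:
            raise ValueError("T_rest must exceed K for stage-1 identifiability")
        if self.subject_spread_control < 0 or self.subject_spread_patient < 0:
            raise ValueError("spreads must be non-negative")
        if self.subject_spread_patient < self.subject_spread_control:
            raise ValueError("patients must vary at least as much as controls")
        if not 0 <= self.lesion_fraction <= 1:
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if self.K > self.n or self.P > self.n:
            raise ValueError("more components than vertices")


@dataclass(frozen=True)
class SubjectDataset:
    subject_id: str
    group: str                       # "control" | "patient"
    pathology: str | None
    rest_ts: np.ndarray              # T_rest x n
    task_ts: np.ndarray              # T_task x n
    lesion_mask: np.ndarray | None   # boolean n-vector
    motion: np.ndarray               # T_task x 6
    sigma_rest: float


@dataclass(frozen=True)
class GroundTruth:
    """Planted quantities, kept separate from the analysed data."""

    group_maps: np.ndarray           # K x n
    subject_maps: list               # per subject K x n (lesion-nulled)
    parcel_coupling: np.ndarray      # P x (1+K), shared across subjects
    subject_task_maps: np.ndarray    # m x n, pre-noise
    lesion_masks: list               # boolean mask or None per subject
    true_features: list              # per subject ConnectivityFeatures


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    space: GrayordinateSpace
    parcellation: Parcellation
    group_maps: GroupComponentSet
    design: glm.BlockDesign
    subjects: list
    truth: GroundTruth

    @property
    def m(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def pathologies(self) -> np.ndarray:
        return np.array([s.pathology if s.pathology else "CON"
                         for s in self.subjects])


def smooth_random_field(space: GrayordinateSpace,
                        rng: np.random.Generator,
                        rounds: int = 10) -> np.ndarray:
    """Unit-norm spatially correlated field via graph-diffusion smoothing."""
    x = rng.standard_normal(space.n)
    A = space.adjacency()
    deg = np.asarray(A.sum(axis=1)).ravel()
    for _ in range(rounds):
        x = (x + A @ x) / (1.0 + deg)
    norm = np.linalg.norm(x)
    return x / norm if norm > 0 else x


def _farthest_point_centres(coords: np.ndarray, K: int,
                            rng: np.random.Generator) -> np.ndarray:
    n = coords.shape[0]
    centres = [int(rng.integers(n))]
    d2 = np.sum((coords - coords[centres[0]]) ** 2, axis=1)
    for _ in range(1, K):
        nxt = int(np.argmax(d2))
        centres.append(nxt)
        d2 = np.minimum(d2, np.sum((coords - coords[nxt]) ** 2, axis=1))
    return np.array(centres)


def generate_group_maps(space: GrayordinateSpace, K: int,
                        rng: np.random.Generator,
                        bump_width: float | None = None) -> np.ndarray:
    """K smooth, approximately non-overlapping bump maps (peak value 1).

    Centres are spread by farthest-point sampling so pairwise correlations
    stay bounded; the bump width defaults to 0.35 sqrt(n / K).
    """
    if K > space.n:
        raise ValueError("more components than vertices")
    if space.coordinates is None:
        raise ValueError("bump generation needs vertex coordinates")
    if bump_width is None:
        bump_width = 0.35 * np.sqrt(space.n / K)
    centres = _farthest_point_centres(space.coordinates, K, rng)
    maps = np.empty((K, space.n))
    for k, c in enumerate(centres):
        d2 = np.sum((space.coordinates - space.coordinates[c]) ** 2, axis=1)
        maps[k] = np.exp(-d2 / (2.0 * bump_width ** 2))
    return maps


def generate_subject_maps(group_maps: np.ndarray, spread: float,
                          rng: np.random.Generator,
                          space: GrayordinateSpace) -> np.ndarray:
    """Group maps plus smooth subject-specific perturbations.

    `spread` is the ratio of the perturbation norm to the group-map norm,
    so spread 0 returns the group maps exactly.
    """
    if spread < 0:
        raise ValueError("spread must be non-negative")
    out = np.array(group_maps, dtype=float, copy=True)
    for k in range(out.shape[0]):
        pert = smooth_random_field(space, rng)
        out[k] += spread * np.linalg.norm(group_maps[k]) * pert
    return out


def decorrelated_timecourses(T: int, K: int,
                             rng: np.random.Generator) -> np.ndarray:
    """T x K time courses with exactly zero mean, unit sample variance and
    zero sample cross-correlation (centred QR of a Gaussian draw)."""
    if T <= K:
        raise ValueError("need more time points than components")
    G = rng.standard_normal((T, K))
    G -= G.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(G)
    Q = Q * np.sign(np.diag(R))  # fix the sign convention deterministically
    return Q * np.sqrt(T - 1)


def generate_resting_timeseries(subject_maps: np.ndarray, T: int,
                                sigma: float, rng: np.random.Generator,
                                baseline: float = 0.0) -> np.ndarray:
    """Y = A S + E: component time courses mixing the subject's spatial
    maps plus white noise at `sigma` (and an optional baseline offset)."""
    S = np.atleast_2d(np.asarray(subject_maps, dtype=float))
    K = S.shape[0]
    if T <= K:
        raise ValueError("T_rest must exceed K")
    A = decorrelated_timecourses(T, K, rng)
    Y = A @ S
    if sigma > 0:
        Y = Y + sigma * rng.standard_normal(Y.shape)
    return Y + baseline


def generate_task_map(features: ConnectivityFeatures,
                      parcel_coupling: np.ndarray,
                      parcellation: Parcellation,
                      sigma: float, rng: np.random.Generator,
                      lesion_mask: np.ndarray | None = None) -> np.ndarray:
    """y(v) = X(v, :) @ coupling(parcel(v)) + noise, with planted signal
    nulled inside the lesion before noise is added."""
    coupling = np.asarray(parcel_coupling, dtype=float)
    if coupling.shape != (parcellation.P, features.X.shape[1]):
        raise ValueError("coupling must be P x (1+K)")
    rows = coupling[parcellation.labels - 1]
    y = np.einsum("ij,ij->i", features.X, rows)
    if lesion_mask is not None:
        y = y * ~np.asarray(lesion_mask, dtype=bool)
    if sigma > 0:
        y = y + sigma * rng.standard_normal(y.shape)
    return y


def generate_task_timeseries(task_map: np.ndarray, design: glm.BlockDesign,
                             TR: float, T: int, sigma: float,
                             rng: np.random.Generator,
                             baseline: float = 0.0) -> np.ndarray:
    """Each vertex's time course is the task map value times the
    HRF-convolved boxcar, plus white noise."""
    reg = glm.task_regressor(design, TR, T)  # validates design vs run length
    Y = np.outer(reg, np.asarray(task_map, dtype=float))
    if sigma > 0:
        Y = Y + sigma * rng.standard_normal(Y.shape)
    return Y + baseline


def generate_lesion_mask(space: GrayordinateSpace, centre: int,
                         radius: int) -> np.ndarray:
    """Connected disc-like mask: all vertices within graph distance
    `radius` of `centre`."""
    return graph_ball(space, centre, radius)


def generate_motion_trace(T: int, rng: np.random.Generator,
                          regressor: np.ndarray | None = None,
                          task_locked_amp: float = 0.0,
                          ar: float = 0.95, scale: float = 0.1) -> np.ndarray:
    """Six AR(1) motion traces, optionally with a task-locked component
    added to the first translation trace."""
    eps = rng.standard_normal((T, 6)) * scale * np.sqrt(1 - ar ** 2)
    M = np.empty((T, 6))
    M[0] = eps[0]
    for t in range(1, T):
        M[t] = ar * M[t - 1] + eps[t]
    if task_locked_amp > 0 and regressor is not None:
        z = (regressor - regressor.mean())
        z = z / (z.std() + 1e-12)
        M[:, 0] += task_locked_amp * scale * z
    return M


def _pathology_assignment(n_patients: int, rng: np.random.Generator):
    names = list(PATHOLOGY_WEIGHTS)
    w = np.array([PATHOLOGY_WEIGHTS[k] for k in names], dtype=float)
    quota = w / w.sum() * n_patients
    counts = np.floor(quota).astype(int)
    rem = n_patients - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(names, counts)
    return rng.permutation(labels)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Full synthetic cohort: controls then patients, reproducible from
    spec.seed, with the GroundTruth retained alongside."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    keys = ss.spawn(4 + spec.m)
    rng_maps = np.random.default_rng(keys[0])
    rng_parc = np.random.default_rng(keys[1])
    rng_coup = np.random.default_rng(keys[2])
    rng_assign = np.random.default_rng(keys[3])

    space = build_lattice_space(spec.width, spec.height)
    gmaps = generate_group_maps(space, spec.K, rng_maps)
    parcel_maps = generate_group_maps(space, spec.P, rng_parc)
    parcellation = winner_takes_all(parcel_maps)

    # Feature columns have unit norm (per-vertex values O(1/sqrt(n))), the
    # intercept column has norm sqrt(n).  Drawing component coefficients at
    # scale sqrt(n) and the intercept at scale 1 makes every column's
    # per-vertex contribution O(1), so parcel offsets do not drown the
    # individual structure in the task maps.
    cscale = spec.coupling_scale
    if cscale is None:
        cscale = np.sqrt(spec.n)
    coupling = rng_coup.normal(size=(spec.P, 1 + spec.K))
    coupling[:, 1:] *= cscale
    # Within a parcel, components whose bumps lie elsewhere are nearly
    # collinear with the intercept, so a raw draw is identifiable only up
    # to the parcel's null space.  Project each parcel's coupling onto the
    # row space of the group-level design restricted to that parcel (same
    # singular-value cutoff as the fit), so the planted vector is the one
    # least-squares recovers in the noise-free limit.
    X_grp = np.column_stack([np.ones(spec.n), normalize_maps(gmaps).T])
    for p in range(1, spec.P + 1):
        idx = parcellation.vertices(p)
        pinv = np.linalg.pinv(X_grp[idx], rcond=PINV_RCOND)
        coupling[p - 1] = pinv @ (X_grp[idx] @ coupling[p - 1])

    pathologies = _pathology_assignment(spec.n_patients, rng_assign)
    n_lesioned = int(round(spec.lesion_fraction * spec.n_patients))
    lesioned = set(rng_assign.choice(spec.n_patients, size=n_lesioned,
                                     replace=False).tolist()) \
        if n_lesioned else set()

    design = glm.BlockDesign.block()
    regressor = glm.task_regressor(design, spec.TR_task, spec.T_task)

    subjects, subj_maps, task_maps, les_masks, feats = [], [], [], [], []
    for i in range(spec.m):
        rng_i = np.random.default_rng(keys[4 + i])
        is_patient = i >= spec.n_controls
        group = "patient" if is_patient else "control"
        spread = (spec.subject_spread_patient if is_patient
                  else spec.subject_spread_control)
        smaps = generate_subject_maps(gmaps, spread, rng_i, space)

        lesion = None
        if is_patient and (i - spec.n_controls) in lesioned:
            centre = int(rng_i.integers(spec.n))
            lesion = generate_lesion_mask(space, centre, spec.lesion_radius)
            smaps = smaps * ~lesion  # lesion nulls resting signal
        X_true = ConnectivityFeatures(
            X=np.column_stack([np.ones(spec.n), normalize_maps(smaps).T]))

        y_signal = generate_task_map(X_true, coupling, parcellation,
                                     sigma=0.0, rng=rng_i,
                                     lesion_mask=lesion)
        sigma_map_i = spec.sigma_task_map * (
            spec.sigma_task_map_patient_factor if is_patient else 1.0)
        y_noisy = y_signal + sigma_map_i * rng_i.standard_normal(spec.n) \
            if sigma_map_i > 0 else y_signal
        task_ts = generate_task_timeseries(y_noisy, design, spec.TR_task,
                                           spec.T_task, spec.sigma_task,
                                           rng_i, baseline=spec.baseline)

        sigma_i = spec.sigma_rest
        if spec.sigma_rest_jitter > 0:
            z = rng_i.standard_normal()
            sigma_i *= float(np.exp(spec.sigma_rest_jitter * z
                                    - spec.sigma_rest_jitter ** 2 / 2))
        rest_ts = generate_resting_timeseries(smaps, spec.T_rest, sigma_i,
                                              rng_i, baseline=spec.baseline)

        amp = float(rng_i.uniform(0, spec.motion_task_locked_max))
        motion = generate_motion_trace(spec.T_task, rng_i, regressor, amp)

        subjects.append(SubjectDataset(
            subject_id=f"sub-{i:03d}", group=group,
            pathology=str(pathologies[i - spec.n_controls]) if is_patient else None,
            rest_ts=rest_ts, task_ts=task_ts, lesion_mask=lesion,
            motion=motion, sigma_rest=sigma_i))
        subj_maps.append(smaps)
        task_maps.append(y_signal)
        les_masks.append(lesion)
        feats.append(X_true)

    truth = GroundTruth(group_maps=gmaps, subject_maps=subj_maps,
                        parcel_coupling=coupling,
                        subject_task_maps=np.stack(task_maps),
                        lesion_masks=les_masks, true_features=feats)
    return Cohort(spec=spec, space=space, parcellation=parcellation,
                  group_maps=GroupComponentSet(maps=gmaps),
                  design=design, subjects=subjects, truth=truth)


def save_cohort(cohort: Cohort, directory) -> None:
    """Directory layout: JSON manifest + per-subject delimited matrices;
    GroundTruth in a separate subdirectory so evaluation code can load the
    data without ever touching the planted truth."""
    from pathlib import Path
    root = Path(directory)
    (root / "truth").mkdir(parents=True, exist_ok=True)
    manifest = {"spec": asdict(cohort.spec),
                "subjects": [{"id": s.subject_id, "group": s.group,
                              "pathology": s.pathology,
                              "sigma_rest": s.sigma_rest}
                             for s in cohort.subjects]}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savetxt(root / "parcellation.txt", cohort.parcellation.labels, fmt="%d")
    np.savetxt(root / "group_maps.tsv", cohort.group_maps.maps,
               delimiter="\t")
    for s in cohort.subjects:
        np.savetxt(root / f"{s.subject_id}_rest.tsv", s.rest_ts, delimiter="\t")
        np.savetxt(root / f"{s.subject_id}_task.tsv", s.task_ts, delimiter="\t")
        np.savetxt(root / f"{s.subject_id}_motion.tsv", s.motion, delimiter="\t")
        if s.lesion_mask is not None:
            np.savetxt(root / f"{s.subject_id}_lesion.txt",
                       s.lesion_mask.astype(int), fmt="%d")
    np.savetxt(root / "truth" / "parcel_coupling.tsv",
               cohort.truth.parcel_coupling, delimiter="\t")
    np.savetxt(root / "truth" / "task_maps.tsv",
               cohort.truth.subject_task_maps, delimiter="\t")
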