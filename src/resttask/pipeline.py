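"""End-to-end orchestration on a synthetic cohort.

run_full_analysis chains the whole study: cohort generation -> first-level
GLM observed maps -> dual-regression features -> leave-one-out and
control-to-patient transfer predictions -> similarity matrix and
per-subject matched-vs-unmatched permutation tests -> group statistics ->
lesion-union exclusion re-analysis -> within-group variability -> QC
metrics and their correlation with performance.  The report is a plain
nested dict (JSON-serialisable) and is byte-reproducible under a fixed
master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import evaluate, glm, mixture, qc
from .dualreg import extract_features
from .model import run_loo, run_transfer
from .simulate import Cohort, CohortSpec, generate_cohort


@dataclass(frozen=True)
class RunConfig:
    spec: CohortSpec = field(default_factory=CohortSpec)
    n_perm: int = 10_000
    alpha: float = 0.05
    exclude_lesions: bool = True
    mass_threshold_observed: float = mixture.MASS_THRESHOLD_OBSERVED
    mass_threshold_predicted: float = mixture.MASS_THRESHOLD_PREDICTED
    threshold_examples: int = 0   # how many subjects to threshold for display
    seed: int = 0                 # master seed for permutation streams
    outdir: str | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")


def observed_task_maps(cohort: Cohort) -> np.ndarray:
    """First-level GLM effect-size maps for every subject."""
    design = glm.build_design_matrix(cohort.design, cohort.spec.TR_task,
                                     cohort.spec.T_task)
    return np.stack([glm.fit_first_level(s.task_ts, design)
                     for s in cohort.subjects])


def connectivity_features(cohort: Cohort) -> list:
    """Dual-regression feature matrices for every subject."""
    return [extract_features(s.rest_ts, cohort.group_maps)
            for s in cohort.subjects]


def _summary(results, labels=None, which=None) -> dict:
    sel = [r for r in results
           if which is None or labels[r.subject] == which]
    n_sig = int(sum(r.significant for r in sel))
    return {"n": len(sel), "n_significant": n_sig,
            "fraction_significant": n_sig / len(sel) if sel else float("nan")}


def run_full_analysis(config: RunConfig) -> dict:
    config.validate()
    cohort = generate_cohort(config.spec)
    m = cohort.m
    labels = cohort.labels
    controls = np.flatnonzero(labels == "control")
    patients = np.flatnonzero(labels == "patient")

    observed = observed_task_maps(cohort)
    features = connectivity_features(cohort)

    # --- leave-one-out regime ----------------------------------------
    loo_preds, betas = run_loo(features, observed, cohort.parcellation)
    S_loo = evaluate.similarity_matrix(observed, loo_preds)
    loo_tests = evaluate.evaluate_identification(
        S_loo, n_perm=config.n_perm, seed=config.seed, alpha=config.alpha)
    t_stats = np.array([r.t for r in loo_tests])

    report: dict = {
        "config": {"n_perm": config.n_perm, "alpha": config.alpha,
                   "seed": config.seed, "spec": asdict(config.spec)},
        "m": m, "n": cohort.spec.n,
        "loo": {
            "matched_r": np.diag(S_loo.S).tolist(),
            "per_subject": [
                {"subject": cohort.subjects[r.subject].subject_id,
                 "group": labels[r.subject],
                 "t": r.t, "p": r.p, "significant": bool(r.significant)}
                for r in loo_tests],
            "overall": _summary(loo_tests),
            "controls": _summary(loo_tests, labels, "control"),
            "patients": _summary(loo_tests, labels, "patient"),
        },
    }

    t_diag, df_diag, p_diag, _ = evaluate.diag_offdiag_test(S_loo)
    report["loo"]["diag_offdiag"] = {"t": t_diag, "df": df_diag, "p": p_diag}

    if controls.size >= 2 and patients.size >= 2:
        t, df, p = evaluate.group_difference_ttest(t_stats, labels)
        report["loo"]["group_difference"] = {"t": t, "df": df, "p": p}
        path = cohort.pathologies[patients]
        if np.unique(path).size >= 2 and \
                np.min(np.bincount(np.unique(path, return_inverse=True)[1])) >= 2:
            F, df1, df2, pF = evaluate.pathology_anova(t_stats[patients], path)
            report["loo"]["pathology_anova"] = {"F": F, "df1": df1,
                                                "df2": df2, "p": pF}

    # --- transfer regime: train on controls, test on patients ---------
    if controls.size and patients.size:
        transfer_preds, _ = run_transfer(features, observed,
                                         cohort.parcellation,
                                         train_idx=controls,
                                         test_idx=patients, betas=betas)
        S_tr = evaluate.similarity_matrix(observed[patients], transfer_preds)
        tr_tests = evaluate.evaluate_identification(
            S_tr, n_perm=config.n_perm, seed=config.seed + 1,
            alpha=config.alpha)
        matched_loo_pat = np.diag(S_loo.S)[patients]
        matched_tr = np.diag(S_tr.S)
        report["transfer"] = {
            "matched_r_patients": matched_tr.tolist(),
            "patients": _summary(tr_tests),
            "loo_vs_transfer_r": evaluate.compare_analyses(matched_loo_pat,
                                                           matched_tr),
        }

    # --- lesion-union exclusion re-analysis ---------------------------
    lesions = [s.lesion_mask for s in cohort.subjects
               if s.lesion_mask is not None]
    if config.exclude_lesions and lesions:
        S_lx, lx_tests, union = evaluate.lesion_excluded_evaluation(
            observed, loo_preds, lesions, n_perm=config.n_perm,
            seed=config.seed + 2, alpha=config.alpha)
        report["lesion_excluded"] = {
            "union_size": int(union.sum()),
            "overall": _summary(lx_tests),
            "controls": _summary(lx_tests, labels, "control"),
            "patients": _summary(lx_tests, labels, "patient"),
        }

    # --- within-group variability ------------------------------------
    if controls.size >= 2 and patients.size >= 2:
        var_obs = evaluate.intersubject_variability(observed, labels)
        var_pred = evaluate.intersubject_variability(loo_preds, labels)
        report["variability"] = {
            kind: {g: {"mean_pairwise_r": v[g]["mean"],
                       "sd_pairwise_r": v[g]["sd"]}
                   for g in v}
            for kind, v in (("observed", var_obs), ("predicted", var_pred))}

    # --- QC metrics ---------------------------------------------------
    design = glm.build_design_matrix(cohort.design, cohort.spec.TR_task,
                                     cohort.spec.T_task)
    reg = design.matrix[:, list(design.columns).index("task")]
    rest_tsnr = [qc.tsnr(s.rest_ts)[1] for s in cohort.subjects]
    task_tsnr = [qc.tsnr(s.task_ts)[1] for s in cohort.subjects]
    stim_corr = [qc.stimulus_correlated_motion(s.motion, reg)
                 for s in cohort.subjects]
    qc_block = {"rest_tsnr": rest_tsnr, "task_tsnr": task_tsnr,
                "stim_corr_motion": stim_corr}
    for name, meas in (("rest_tsnr", rest_tsnr), ("task_tsnr", task_tsnr),
                       ("stim_corr_motion", stim_corr)):
        r, p = evaluate.qc_correlation(t_stats, meas)
        qc_block[f"corr_t_{name}"] = {"r": r, "p": p}
    report["qc"] = qc_block

    # --- visualisation-grade thresholding (optional) ------------------
    if config.threshold_examples > 0:
        masks = []
        for j in range(min(config.threshold_examples, m)):
            mo = mixture.threshold_map(observed[j], cohort.space,
                                       role="observed",
                                       mass_threshold=config.mass_threshold_observed,
                                       seed=config.seed)
            mp = mixture.threshold_map(loo_preds[j], cohort.space,
                                       role="predicted",
                                       mass_threshold=config.mass_threshold_predicted,
                                       seed=config.seed)
            masks.append({"subject": cohort.subjects[j].subject_id,
                          "observed_vertices": int(mo.sum()),
                          "predicted_vertices": int(mp.sum()),
                          "dice": evaluate.dice(mo, mp)})
        report["thresholding"] = masks

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        np.savetxt(out / "similarity_loo.tsv", S_loo.S, delimiter="\t")
        np.savetxt(out / "observed_maps.tsv", observed, delimiter="\t")
        np.savetxt(out / "predicted_maps_loo.tsv", loo_preds, delimiter="\t")
    return report
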