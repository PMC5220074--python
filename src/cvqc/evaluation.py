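"""End-to-end evaluation runs on the canned phantom scenarios.

Each function regenerates its scenario from a seed, runs the relevant
part of the pipeline and returns the headline quantities: QC detection
counts, tSNR group comparison, ICA / dual-regression recovery
correlations, permutation-test validity under the global null, the
before/after-QC significant-voxel comparison, and the wbICA-vs-gmICA
CSF-leakage contrast.
"""

from __future__ import annotations

import numpy as np

from . import preprocess, scenarios
from .bold import BoldRun, estimate_brain_mask
from .dual_regression import dual_regress, permutation_group_test
from .group_ica import concatenate, fit_group_ica, match_rsn
from .phantom import generate_cohort, generate_normative_cohort
from .pipeline import (
    StudyConfig,
    _group_gm_mask,
    _substream,
    random_exclusion_rerun,
    run_qc,
    run_study,
)

__all__ = [
    "highpass_gain",
    "qc_detection_summary",
    "recovery_summary",
    "null_fwe_rate",
    "mechanism_summary",
    "csf_contrast_summary",
]


def highpass_gain(period_seconds: float, cutoff_seconds: float = 100.0,
                  tr_seconds: float = 1.8, n_volumes: int = 199) -> float:
    """Empirical amplitude gain of the high-pass filter for a pure
    sinusoid of the given period, measured by projecting the filtered
    series back onto the sinusoid quadrature pair."""
    t = np.arange(n_volumes) * tr_seconds
    series = 100.0 + np.sin(2 * np.pi * t / period_seconds)
    run = BoldRun(data=series.reshape(1, 1, 1, -1), tr_seconds=tr_seconds)
    out = preprocess.highpass_filter(run, cutoff_seconds).data.ravel()
    design = np.column_stack([np.sin(2 * np.pi * t / period_seconds),
                              np.cos(2 * np.pi * t / period_seconds)])
    coefs, *_ = np.linalg.lstsq(design, out - out.mean(), rcond=None)
    return float(np.hypot(*coefs))


def qc_detection_summary(seed: int = 0, n_normative: int = 60) -> dict:
    """QC on the 20-clean + 5-striped cohort: detection counts and the
    flagged-vs-retained mean-tSNR Mann-Whitney comparison."""
    spec = scenarios.qc_detection_spec(seed=seed)
    cohort = generate_cohort(spec)
    normative = generate_normative_cohort(spec, n_normative)
    result = run_qc(cohort, normative, StudyConfig(seed=seed))
    truth = set(scenarios.STRIPE_SUBJECTS)
    flagged = set(result.flagged)
    return {
        "n_true_artifacts": len(truth),
        "true_positives": len(truth & flagged),
        "false_positives": len(flagged - truth),
        "tsnr_p": result.tsnr_pvalue,
        "n_subjects": len(cohort.runs),
    }


def _preprocess_and_mask(cohort, config: StudyConfig, mask):
    masked = []
    for run in cohort.runs:
        pre = preprocess.drop_initial_volumes(run, config.n_drop)
        pre = preprocess.highpass_filter(pre, config.highpass_seconds)
        pre = preprocess.smooth_gaussian(pre, config.fwhm_mm)
        masked.append(preprocess.apply_gm_mask(pre, mask))
    return masked


def recovery_summary(seed: int = 0) -> dict:
    """Fit k=3 group ICA on the three-network cohort; report the worst
    template-map spatial correlation and the worst across-subject
    correlation between stage-B coefficients and true amplitudes."""
    spec = scenarios.recovery_spec(seed=seed)
    cohort = generate_cohort(spec)
    config = StudyConfig(seed=seed, k_components=3)
    mask = _group_gm_mask(cohort, cohort.subject_ids,
                          cohort.runs[0].grid_shape, config.gm_majority)
    masked = _preprocess_and_mask(cohort, config, mask)
    decomp = fit_group_ica(concatenate(masked), 3,
                           seed=_substream(seed, 1))
    templates = cohort.ground_truth["network_maps"]
    matches = match_rsn(decomp, templates)
    spatial_rs = [abs(m.correlation) for m in matches]

    betas = cohort.ground_truth["betas"]
    i, j, k = decomp.voxel_index.T
    subject_maps = {mr.run.subject_id: dual_regress(mr, decomp.spatial_maps)
                    for mr in masked}
    beta_rs = []
    for m in matches:
        if not m.matched:
            beta_rs.append(0.0)
            continue
        net_vox = templates[m.template_name][i, j, k] > 0
        coefs = [subject_maps[sid].values[m.component_id][net_vox].mean()
                 for sid in cohort.subject_ids]
        truth = [betas[sid][m.template_name] for sid in cohort.subject_ids]
        beta_rs.append(abs(float(np.corrcoef(coefs, truth)[0, 1])))
    return {
        "min_spatial_r": float(min(spatial_rs)),
        "min_beta_r": float(min(beta_rs)),
        "n_subjects": len(cohort.runs),
    }


def null_fwe_rate(seed: int = 0, n_reps: int = 200, n_perm: int = 199) -> dict:
    """Family-wise false-positive fraction of the permutation test over
    seeded exchangeable-group phantom repetitions (no deficit, no
    artifacts); dual regression against the true network maps."""
    hits = 0
    for rep in range(n_reps):
        spec = scenarios.null_spec(seed=_substream(seed, 4, rep))
        cohort = generate_cohort(spec)
        gt_maps = cohort.ground_truth["network_maps"]
        gm = cohort.ground_truth["compartments"] == 3
        names = sorted(gt_maps)
        g1, g2 = [], []
        for run in cohort.runs:
            pre = preprocess.drop_initial_volumes(run, 3)
            pre = preprocess.highpass_filter(pre, 100.0)
            mr = preprocess.apply_gm_mask(pre, gm)
            i, j, k = mr.voxel_index.T
            maps = np.stack([gt_maps[n][i, j, k] for n in names])
            sm = dual_regress(mr, maps)
            (g1 if run.group == "control" else g2).append(sm.values[0])
        stat = permutation_group_test(np.stack(g1), np.stack(g2),
                                      n_perm=n_perm,
                                      seed=_substream(seed, 5, rep))
        hits += bool((stat.p_fwe < 0.05).any())
    return {"fwe_rate": hits / n_reps, "n_reps": n_reps}


def mechanism_summary(seed: int = 0, n_normative: int = 60,
                      n_perm: int = 2000) -> dict:
    """The central before/after comparison: significant deficit-network
    voxels in the gmICA arm with all subjects, after CV-QC exclusion,
    and after a size-matched random exclusion."""
    spec = scenarios.mechanism_spec(seed=seed)
    cohort = generate_cohort(spec)
    normative = generate_normative_cohort(spec, n_normative)
    config = StudyConfig(seed=seed, k_components=3, n_permutations=n_perm,
                         arms=("gmica_before", "gmica_after"))
    result = run_study(cohort, normative, config)
    before = result.arms["gmica_before"].network_stats["dmn"].get("n_voxels", 0)
    after = result.arms["gmica_after"].network_stats["dmn"].get("n_voxels", 0)
    n_con = sum(1 for s in result.qc.flagged if
                cohort.groups[s] == "control")
    n_pat = sum(1 for s in result.qc.flagged if
                cohort.groups[s] == "patient")
    random_arm = random_exclusion_rerun(
        cohort, config, {"control": n_con, "patient": n_pat},
        seed=_substream(seed, 6))
    random_count = random_arm.network_stats["dmn"].get("n_voxels", 0)
    return {
        "sig_voxels_before_qc": int(before),
        "sig_voxels_after_qc": int(after),
        "sig_voxels_random_exclusion": int(random_count),
        "n_flagged": n_con + n_pat,
        "n_subjects": len(cohort.runs),
    }


def csf_contrast_summary(seed: int = 0, k: int = 4) -> dict:
    """Maximal |correlation| between any ICA component time course and
    the injected CSF pulsation regressor, under whole-brain vs
    gray-matter-restricted ICA with matched seeds."""
    spec = scenarios.csf_contrast_spec(seed=seed)
    cohort = generate_cohort(spec)
    config = StudyConfig(seed=seed, k_components=k)

    def max_corr(use_gm: bool) -> float:
        if use_gm:
            mask = _group_gm_mask(cohort, cohort.subject_ids,
                                  cohort.runs[0].grid_shape,
                                  config.gm_majority)
        else:
            mask = np.logical_and.reduce(
                [estimate_brain_mask(r) for r in cohort.runs])
        masked = _preprocess_and_mask(cohort, config, mask)
        decomp = fit_group_ica(concatenate(masked), k,
                               seed=_substream(seed, 1))
        regressor = np.concatenate([
            cohort.ground_truth["csf_timecourses"][mr.run.subject_id][
                config.n_drop:]
            for mr in masked
        ])
        return max(abs(float(np.corrcoef(regressor, decomp.mixing[:, c])[0, 1]))
                   for c in range(decomp.k))

    return {
        "max_csf_corr_wbica": max_corr(False),
        "max_csf_corr_gmica": max_corr(True),
        "n_subjects": len(cohort.runs),
    }
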