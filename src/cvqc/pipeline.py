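"""End-to-end study orchestration.

Implements the four-arm design: whole-brain ICA (wbICA) and gray-matter
ICA (gmICA), each run both before and after CV-map quality control, plus
a random-exclusion control that removes the same number of subjects per
group without regard to the QC flags.  QC is computed once; "after"
arms drop flagged subjects.  All randomness flows from a single study
seed through named substreams so QC flags, ICA initialisation and
permutation tests are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess, qc
from .bold import GMMask, estimate_brain_mask
from .dual_regression import (
    GroupStatMap,
    bonferroni_adjust,
    difference_map_stats,
    dual_regress,
    permutation_group_test,
)
from .group_ica import (
    ICADecomposition,
    concatenate,
    fit_group_ica,
    threshold_map,
)
from .phantom import PhantomCohort

__all__ = ["StudyConfig", "ArmResult", "StudyResult", "QCResult",
           "run_qc", "run_arm", "run_study", "random_exclusion_rerun",
           "write_report", "ALL_ARMS"]

ALL_ARMS = ("wbica_before", "wbica_after", "gmica_before", "gmica_after")


@dataclass(frozen=True)
class StudyConfig:
    """Tunable study parameters (defaults follow the reference design:
    3 dropped volumes, 100-s high-pass, 5 mm FWHM smoothing, voxelwise
    permutation inference at alpha 0.05)."""

    n_drop: int = 3
    highpass_seconds: float = 100.0
    fwhm_mm: float = 5.0
    k_components: int = 3
    n_permutations: int = 2000
    alpha: float = 0.05
    arms: tuple[str, ...] = ALL_ARMS
    r_min: float = 0.2
    gm_majority: float = 0.5  # fraction of subjects a voxel needs to enter the group GM mask
    stripe_threshold: float | None = None  # None -> normative median + 5 MAD
    defect_threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100 for inference arms")
        for arm in self.arms:
            if arm not in ALL_ARMS:
                raise ValueError(f"unknown arm {arm!r}")


@dataclass
class QCResult:
    """QC report plus the reference and thresholds used to produce it."""

    report: pd.DataFrame
    thresholds: dict[str, float]
    reference: qc.NormativeReference
    tsnr_u: float | None
    tsnr_pvalue: float | None

    @property
    def flagged(self) -> dict[str, str]:
        rows = self.report[self.report["flag"]]
        return dict(zip(rows["subject_id"], rows["reason"]))


@dataclass
class ArmResult:
    name: str
    excluded: dict[str, str]  # subject_id -> machine-readable reason
    group_sizes: dict[str, int]
    matches: dict[str, list[tuple[int, float]]]  # template -> [(component, r)]
    network_stats: dict[str, dict]  # template -> difference-map summary
    stat_maps: dict[str, GroupStatMap] = field(default_factory=dict)
    decomposition: ICADecomposition | None = None


@dataclass
class StudyResult:
    qc: QCResult
    arms: dict[str, ArmResult]
    config: StudyConfig


def _substream(seed: int, *key: int) -> int:
    """Deterministic named substream seed below 2**31."""
    return int(np.random.SeedSequence((seed, *key)).generate_state(1)[0] % (2**31 - 1))


def _qc_preprocess(run, config: StudyConfig):
    run = preprocess.drop_initial_volumes(run, config.n_drop)
    return preprocess.highpass_filter(run, config.highpass_seconds)


def run_qc(cohort: PhantomCohort, normative_cohort: PhantomCohort,
           config: StudyConfig) -> QCResult:
    """Score every study run against the normative CV reference.

    CV maps are computed after volume dropping and high-pass filtering
    but before smoothing (so slice-localised artifacts stay sharp) and
    before any GM masking.  Flagging thresholds default to
    median + 5 MAD of the normative cohort's own score distributions.
    """
    norm_pre = [_qc_preprocess(r, config) for r in normative_cohort.runs]
    norm_cv = [qc.compute_cv_map(r) for r in norm_pre]
    reference = qc.build_normative_reference(norm_cv)

    def score_one(pre_run, cv_map, ref):
        brain = estimate_brain_mask(pre_run)
        valid = brain & cv_map.valid_mask & ref.valid_mask
        z = qc.deviation_zmap(cv_map, ref)
        tsnr = qc.compute_tsnr_map(pre_run)
        return {
            "subject_id": pre_run.subject_id,
            "group": pre_run.group,
            "mean_tsnr": qc.mean_tsnr(tsnr, brain),
            "stripe_score": qc.stripe_score(z, valid),
            "defect_score": qc.defect_score(z, valid),
        }

    # normative subjects are scored against leave-one-out references so
    # their score distribution matches the out-of-sample study scoring
    norm_rows = []
    for idx, (pre_run, cv_map) in enumerate(zip(norm_pre, norm_cv)):
        loo_ref = qc.build_normative_reference(
            [m for j, m in enumerate(norm_cv) if j != idx]
        )
        norm_rows.append(score_one(pre_run, cv_map, loo_ref))
    norm_scores = pd.DataFrame(norm_rows)
    auto = qc.score_thresholds(norm_scores["stripe_score"].to_numpy(),
                               norm_scores["defect_score"].to_numpy())
    thresholds = {
        "stripe": config.stripe_threshold if config.stripe_threshold is not None
        else auto["stripe"],
        "defect": config.defect_threshold if config.defect_threshold is not None
        else auto["defect"],
    }

    study_pre = [_qc_preprocess(r, config) for r in cohort.runs]
    study_scores = pd.DataFrame(
        [score_one(r, qc.compute_cv_map(r), reference) for r in study_pre]
    )
    report = qc.flag_runs(study_scores, thresholds)

    flagged = report[report["flag"]]["mean_tsnr"].to_numpy()
    retained = report[~report["flag"]]["mean_tsnr"].to_numpy()
    if flagged.size and retained.size:
        u, p = qc.mann_whitney_u(flagged, retained)
    else:
        u, p = None, None
    return QCResult(report=report, thresholds=thresholds, reference=reference,
                    tsnr_u=u, tsnr_pvalue=p)


def _group_gm_mask(cohort: PhantomCohort, subject_ids: list[str],
                   grid_shape, majority: float) -> np.ndarray:
    """Group gray-matter mask: voxels present in at least ``majority`` of
    the included subjects' binarised GM maps (individual atrophy still
    expresses itself through each subject's own signal)."""
    votes = np.zeros(grid_shape, dtype=float)
    for sid in subject_ids:
        mask = GMMask.from_partial_volume(cohort.gm_maps[sid], subject_id=sid)
        mask = preprocess.resample_mask_to_bold(mask, tuple(grid_shape))
        votes += mask.binary
    return votes >= majority * len(subject_ids)


def _template_matches(decomp: ICADecomposition, templates: dict[str, np.ndarray],
                      r_min: float) -> dict[str, list[tuple[int, float]]]:
    """All components correlating with each template at |r| >= r_min,
    strongest first (duplicate components are kept for Bonferroni)."""
    i, j, k = decomp.voxel_index.T
    out: dict[str, list[tuple[int, float]]] = {}
    for name, tpl in templates.items():
        tpl = np.asarray(tpl, dtype=float)
        vec = tpl[i, j, k] if tpl.ndim == 3 else tpl
        if vec.std() == 0:
            out[name] = []
            continue
        rs = [
            (c, float(np.corrcoef(vec, comp)[0, 1]))
            for c, comp in enumerate(decomp.spatial_maps)
            if comp.std() > 0
        ]
        hits = [(c, r) for c, r in rs if abs(r) >= r_min]
        hits.sort(key=lambda cr: -abs(cr[1]))
        out[name] = hits
    return out


def run_arm(
    cohort: PhantomCohort,
    config: StudyConfig,
    name: str,
    excluded: dict[str, str],
    templates: dict[str, np.ndarray],
) -> ArmResult:
    """One analysis arm end-to-end: preprocess -> concatenate -> group
    ICA -> template matching -> dual regression -> permutation test."""
    use_gm = name.startswith("gmica")
    included = [r for r in cohort.runs if r.subject_id not in excluded]
    if len(included) < 4:
        raise ValueError(f"arm {name!r} has too few subjects after exclusion")
    grid_shape = included[0].grid_shape

    if use_gm:
        shared_mask = _group_gm_mask(cohort, [r.subject_id for r in included],
                                     grid_shape, config.gm_majority)
    else:
        shared_mask = np.logical_and.reduce(
            [estimate_brain_mask(r) for r in included]
        )

    masked_runs = []
    for run in included:
        pre = preprocess.drop_initial_volumes(run, config.n_drop)
        pre = preprocess.highpass_filter(pre, config.highpass_seconds)
        pre = preprocess.smooth_gaussian(pre, config.fwhm_mm)
        masked_runs.append(preprocess.apply_gm_mask(pre, shared_mask))

    matrix = concatenate(masked_runs)
    ica_seed = _substream(config.seed, 1)
    decomp = fit_group_ica(matrix, config.k_components, seed=ica_seed)
    matches = _template_matches(decomp, templates, config.r_min)

    # mixture-model thresholds for the matched (network) components
    for hits in matches.values():
        for comp, _r in hits:
            if comp in decomp.thresholds:
                continue
            active, fit = threshold_map(decomp.spatial_maps[comp])
            decomp.thresholds[comp] = {
                "n_active": int(active.sum()),
                "mixture": fit,
            }

    subject_maps = {
        mr.run.subject_id: dual_regress(mr, decomp.spatial_maps)
        for mr in masked_runs
    }
    groups = {r.subject_id: r.group for r in included}
    controls = [sid for sid in subject_maps if groups[sid] == "control"]
    patients = [sid for sid in subject_maps if groups[sid] == "patient"]

    arm_index = ALL_ARMS.index(name) if name in ALL_ARMS else 9
    network_stats: dict[str, dict] = {}
    stat_maps: dict[str, GroupStatMap] = {}
    vox_vol = float(np.prod(included[0].voxel_size_mm))
    for tname, hits in matches.items():
        if not hits:
            network_stats[tname] = {"n_voxels": 0, "volume_mm3": 0.0,
                                    "unmatched": True}
            continue
        m = len(hits)  # Bonferroni factor over duplicate components
        best_stat = None
        for comp, _r in hits:
            g1 = np.stack([subject_maps[s].values[comp] for s in controls])
            g2 = np.stack([subject_maps[s].values[comp] for s in patients])
            stat = permutation_group_test(
                g1, g2, n_perm=config.n_permutations,
                seed=_substream(config.seed, 2, arm_index, comp),
                contrast="control>patient",
            )
            if m > 1:
                stat.p_fwe = bonferroni_adjust(stat.p_fwe, m)
            if best_stat is None or (stat.p_fwe < config.alpha).sum() > (
                best_stat.p_fwe < config.alpha
            ).sum():
                best_stat = stat
        stat_maps[tname] = best_stat
        summary = difference_map_stats(best_stat, alpha=config.alpha,
                                       voxel_volume_mm3=vox_vol,
                                       voxel_index=decomp.voxel_index)
        summary["n_components_tested"] = m
        network_stats[tname] = summary

    return ArmResult(
        name=name,
        excluded=dict(excluded),
        group_sizes={
            "control": len(controls),
            "patient": len(patients),
        },
        matches=matches,
        network_stats=network_stats,
        stat_maps=stat_maps,
        decomposition=decomp,
    )


def run_study(
    cohort: PhantomCohort,
    normative_cohort: PhantomCohort,
    config: StudyConfig,
    templates: dict[str, np.ndarray] | None = None,
) -> StudyResult:
    """Run QC once, then every requested arm.

    "before" arms use all subjects; "after" arms drop CV-flagged
    subjects.  Templates default to the cohort's ground-truth network
    maps (the phantom stand-in for canonical network templates).
    """
    if templates is None:
        templates = cohort.ground_truth["network_maps"]
    qc_result = run_qc(cohort, normative_cohort, config)
    flagged = qc_result.flagged
    arms: dict[str, ArmResult] = {}
    for arm in config.arms:
        excluded = flagged if arm.endswith("_after") else {}
        try:
            arms[arm] = run_arm(cohort, config, arm, excluded, templates)
        except Exception as exc:  # keep other arms alive on stage failure
            arms[arm] = ArmResult(
                name=arm, excluded=dict(excluded), group_sizes={},
                matches={}, network_stats={"error": {"message": str(exc)}},
            )
    return StudyResult(qc=qc_result, arms=arms, config=config)


def random_exclusion_rerun(
    cohort: PhantomCohort,
    config: StudyConfig,
    n_exclude_per_group: dict[str, int],
    seed: int,
    templates: dict[str, np.ndarray] | None = None,
) -> ArmResult:
    """Control analysis: restore any CV-flagged subjects and instead
    drop a seeded random draw of the given size per group, then rerun
    the gmICA arm."""
    if templates is None:
        templates = cohort.ground_truth["network_maps"]
    groups: dict[str, list[str]] = {}
    for run in cohort.runs:
        groups.setdefault(run.group, []).append(run.subject_id)
    rng = np.random.default_rng(seed)
    excluded: dict[str, str] = {}
    for group, n_excl in n_exclude_per_group.items():
        members = groups.get(group, [])
        if n_excl >= len(members):
            raise ValueError(f"cannot exclude {n_excl} of {len(members)} "
                             f"{group} subjects")
        for sid in rng.choice(members, size=n_excl, replace=False):
            excluded[str(sid)] = "random"
    return run_arm(cohort, config, "gmica_before", excluded, templates)


def _format_summary(name: str, summary: dict) -> str:
    if summary.get("unmatched"):
        return f"    {name}: template unmatched (no component above r_min)"
    if "message" in summary:
        return f"    {name}: ERROR {summary['message']}"
    if summary["n_voxels"] == 0:
        return f"    {name}: no significant voxels"
    return (
        f"    {name}: voxels={summary['n_voxels']} "
        f"volume={summary['volume_mm3']:.0f}mm3 peak={summary['peak']} "
        f"t mean={summary['t_mean']:.2f} sd={summary['t_sd']:.2f} "
        f"min={summary['t_min']:.2f} max={summary['t_max']:.2f}"
    )


def write_report(result: StudyResult,
                 extra_arms: dict[str, ArmResult] | None = None) -> str:
    """Human-readable study report: QC table, per-arm network tables and
    a cross-arm comparison of significant-voxel counts."""
    lines = ["# Study report", "", "## Quality control", ""]
    lines.append(result.qc.report.to_string(index=False,
                                            float_format=lambda v: f"{v:.4f}"))
    lines.append("")
    lines.append(f"thresholds: stripe={result.qc.thresholds['stripe']:.4f} "
                 f"defect={result.qc.thresholds['defect']:.4f}")
    if result.qc.tsnr_pvalue is not None:
        lines.append(
            f"mean tSNR, flagged vs retained (Mann-Whitney): U={result.qc.tsnr_u:.1f} "
            f"p={result.qc.tsnr_pvalue:.4f}"
        )
    all_arms = dict(result.arms)
    if extra_arms:
        all_arms.update(extra_arms)
    lines += ["", "## Arms", ""]
    for name, arm in all_arms.items():
        sizes = ", ".join(f"{g}={n}" for g, n in arm.group_sizes.items())
        lines.append(f"  {name} ({sizes})")
        if arm.excluded:
            excl = ", ".join(f"{s}:{r}" for s, r in sorted(arm.excluded.items()))
            lines.append(f"    excluded: {excl}")
        for tname, summary in arm.network_stats.items():
            lines.append(_format_summary(tname, summary))
        lines.append("")
    lines.append("## Cross-arm comparison (significant voxels per network)")
    for name, arm in all_arms.items():
        counts = {t: s.get("n_voxels", 0) for t, s in arm.network_stats.items()
                  if "message" not in s}
        lines.append(f"  {name}: " + ", ".join(f"{t}={c}" for t, c in counts.items()))
    return "\n".join(lines) + "\n"
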