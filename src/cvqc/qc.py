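"""Coefficient-of-variation quality control for BOLD runs.

The central idea: a single 3D map of the voxelwise coefficient of
variation, CV = sigma(X) / mean(X), summarises the temporal dispersion
of a whole 4D run and exposes technical artifacts (stripe-like
slice-direction offsets, widespread signal defects) that are hard to
see in the raw series or in motion parameters.  Single-subject CV maps
are compared against a normative reference (voxelwise mean and SD CV
over a large healthy cohort); runs whose deviation maps show slice-wise
or widespread excursions are flagged and excluded before group analysis.

tSNR = mean(X) / sigma(X) is the reciprocal quantity; flagged runs are
expected to show lower mean tSNR than retained runs, which is checked
with a Mann-Whitney U test.

Both maps use the sample standard deviation (divisor t - 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import scipy.stats

from .bold import BoldRun

__all__ = [
    "CVMap",
    "TSNRMap",
    "NormativeReference",
    "compute_cv_map",
    "compute_tsnr_map",
    "mean_tsnr",
    "build_normative_reference",
    "deviation_zmap",
    "stripe_score",
    "defect_score",
    "score_thresholds",
    "flag_runs",
    "mann_whitney_u",
]

#: relative floor applied to the run's median absolute intensity
DEFAULT_FLOOR_REL = 1e-6
#: |z| above which a voxel counts toward the widespread-defect score
DEFAULT_Z_THRESH = 3.0
#: flagging thresholds default to median + MAD_FACTOR * MAD of the
#: normative cohort's score distribution
MAD_FACTOR = 5.0


@dataclass
class CVMap:
    """Voxelwise sigma/mean map (dimensionless) with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    subject_id: str = "sub-00"


@dataclass
class TSNRMap:
    """Voxelwise mean/sigma map (dimensionless) with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    subject_id: str = "sub-00"


@dataclass
class NormativeReference:
    """Voxelwise mean and SD of CV over a normative cohort."""

    mean_cv: np.ndarray
    sd_cv: np.ndarray
    n_subjects: int
    valid_mask: np.ndarray


def _default_floor(run: BoldRun) -> float:
    med = float(np.median(np.abs(run.data)))
    if med == 0:
        med = float(np.mean(np.abs(run.data))) or 1.0
    return DEFAULT_FLOOR_REL * med


def compute_cv_map(run: BoldRun, mean_floor: float | None = None) -> CVMap:
    """CV = sample SD / mean per voxel; voxels with mean below
    ``mean_floor`` (default 1e-6 x median intensity) are zeroed and
    marked invalid so background voxels cannot blow up the map."""
    if run.n_volumes < 2:
        raise ValueError("CV needs at least 2 time points")
    if mean_floor is None:
        mean_floor = _default_floor(run)
    if mean_floor <= 0:
        raise ValueError("mean_floor must be positive")
    mean = run.data.mean(axis=-1)
    sd = run.data.std(axis=-1, ddof=1)
    valid = mean >= mean_floor
    values = np.zeros_like(mean)
    np.divide(sd, mean, out=values, where=valid)
    values[~valid] = 0.0
    return CVMap(values=values, valid_mask=valid, subject_id=run.subject_id)


def compute_tsnr_map(run: BoldRun, sd_floor: float | None = None) -> TSNRMap:
    """tSNR = mean / sample SD per voxel; constant (sub-floor SD) or
    non-positive-mean voxels are marked invalid rather than infinite."""
    if run.n_volumes < 2:
        raise ValueError("tSNR needs at least 2 time points")
    if sd_floor is None:
        sd_floor = _default_floor(run)
    if sd_floor <= 0:
        raise ValueError("sd_floor must be positive")
    mean = run.data.mean(axis=-1)
    sd = run.data.std(axis=-1, ddof=1)
    valid = (sd >= sd_floor) & (mean >= 0)
    values = np.zeros_like(mean)
    np.divide(mean, sd, out=values, where=valid)
    values[~valid] = 0.0
    return TSNRMap(values=values, valid_mask=valid, subject_id=run.subject_id)


def mean_tsnr(tsnr: TSNRMap, brain_mask: np.ndarray) -> float:
    """Arithmetic mean tSNR over brain_mask intersected with the map's
    validity mask (the analogue of averaging within a standard-space
    brain mask)."""
    joint = np.asarray(brain_mask, dtype=bool) & tsnr.valid_mask
    if not joint.any():
        raise ValueError("brain mask does not overlap the valid tSNR voxels")
    return float(tsnr.values[joint].mean())


def build_normative_reference(cv_maps: list[CVMap]) -> NormativeReference:
    """Merge single-subject CV maps into voxelwise mean and sample-SD
    reference maps; validity is the intersection of subject masks."""
    if len(cv_maps) < 2:
        raise ValueError("need >= 2 CV maps for a normative reference")
    shape = cv_maps[0].values.shape
    if any(m.values.shape != shape for m in cv_maps):
        raise ValueError("CV maps are not on the same grid")
    stack = np.stack([m.values for m in cv_maps])
    valid = np.logical_and.reduce([m.valid_mask for m in cv_maps])
    return NormativeReference(
        mean_cv=stack.mean(axis=0),
        sd_cv=stack.std(axis=0, ddof=1),
        n_subjects=len(cv_maps),
        valid_mask=valid,
    )


def deviation_zmap(
    cv: CVMap, ref: NormativeReference, sd_floor: float = 1e-6
) -> np.ndarray:
    """Voxelwise z score of a subject CV map against the reference:
    z = (CV - mean_cv) / max(sd_cv, sd_floor) on the joint valid mask,
    0 elsewhere."""
    if cv.values.shape != ref.mean_cv.shape:
        raise ValueError("subject map and reference are not on the same grid")
    joint = cv.valid_mask & ref.valid_mask
    denom = np.maximum(ref.sd_cv, sd_floor)
    z = np.zeros_like(cv.values)
    np.divide(cv.values - ref.mean_cv, denom, out=z, where=joint)
    z[~joint] = 0.0
    return z


def stripe_score(zmap: np.ndarray, valid_mask: np.ndarray | None = None) -> float:
    """Slice-wise deviation score, high when one or a few slices deviate
    en bloc: max over slices of (mean |z| within slice) minus the median
    over slices of the same quantity.  Invariant to global shifts of |z|.
    Slices run along the last (slowest) axis.

    Slices holding fewer than half the median per-slice valid voxel
    count (near-empty edge slices, where a mean over a handful of voxels
    is dominated by sampling noise) are left out of both the max and the
    median.
    """
    zmap = np.asarray(zmap)
    if zmap.ndim != 3 or zmap.shape[2] < 3:
        raise ValueError("stripe score needs a 3D map with >= 3 slices")
    if valid_mask is None:
        valid_mask = np.ones(zmap.shape, dtype=bool)
    counts = valid_mask.sum(axis=(0, 1))
    occupied = counts >= max(1.0, 0.5 * np.median(counts))
    if occupied.sum() < 3:
        occupied = counts >= 1
    if occupied.sum() < 3:
        raise ValueError("stripe score needs >= 3 non-empty slices")
    per_slice = np.array([
        np.abs(zmap[:, :, s][valid_mask[:, :, s]]).mean()
        for s in np.flatnonzero(occupied)
    ])
    return float(per_slice.max() - np.median(per_slice))


def defect_score(
    zmap: np.ndarray,
    valid_mask: np.ndarray | None = None,
    z_thresh: float = DEFAULT_Z_THRESH,
) -> float:
    """Fraction of valid voxels with |z| above ``z_thresh``; high for
    widespread signal defects that lift the whole deviation map."""
    zmap = np.asarray(zmap)
    if valid_mask is None:
        valid_mask = np.ones(zmap.shape, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if not valid_mask.any():
        raise ValueError("defect score needs a non-empty valid mask")
    return float((np.abs(zmap[valid_mask]) > z_thresh).mean())


def score_thresholds(
    stripe_scores: np.ndarray, defect_scores: np.ndarray, factor: float = MAD_FACTOR
) -> dict[str, float]:
    """Robust flagging thresholds from a clean (normative) cohort's score
    distributions: median + factor x MAD per score."""

    def thr(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        return float(med + factor * mad)

    return {"stripe": thr(stripe_scores), "defect": thr(defect_scores)}


def flag_runs(scores: pd.DataFrame, thresholds: dict[str, float]) -> pd.DataFrame:
    """Turn per-run scores into a QC report.

    ``scores`` needs columns subject_id, mean_tsnr, stripe_score,
    defect_score.  A run is flagged iff its stripe or defect score
    exceeds the corresponding threshold; the reason column records which.
    """
    required = {"subject_id", "mean_tsnr", "stripe_score", "defect_score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"missing score columns: {sorted(missing)}")
    for key in ("stripe", "defect"):
        if key not in thresholds:
            raise ValueError(f"missing threshold {key!r}")
    report = scores.copy()
    stripe_hit = report["stripe_score"] > thresholds["stripe"]
    defect_hit = report["defect_score"] > thresholds["defect"]
    report["flag"] = stripe_hit | defect_hit
    reasons = []
    for s_hit, d_hit in zip(stripe_hit, defect_hit):
        r = []
        if s_hit:
            r.append("cv_stripe")
        if d_hit:
            r.append("cv_defect")
        reasons.append("+".join(r))
    report["reason"] = reasons
    report.attrs["thresholds"] = dict(thresholds)
    return report


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a, ties counted half."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For combined n <= 12 the p value is computed by exhaustive
    enumeration of all group assignments of the pooled values (exact
    even with ties); otherwise the normal approximation with tie
    correction is used.  Returns (U of sample_a, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    n_a, n_b = a.size, b.size
    if n_a + n_b <= 12:
        pooled = np.concatenate([a, b])
        center = n_a * n_b / 2.0
        dev_obs = abs(u_obs - center)
        total = comb(n_a + n_b, n_a)
        hits = 0
        idx = np.arange(n_a + n_b)
        for combo in itertools.combinations(idx, n_a):
            mask = np.zeros(n_a + n_b, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - center) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    if np.all(np.concatenate([a, b]) == a.flat[0]):
        return u_obs, 1.0
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic")
    return u_obs, float(min(1.0, res.pvalue))
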