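"""Dual regression and permutation-based two-group voxelwise inference.

Stage A regresses each subject's 4D data on the group spatial maps to
obtain subject-specific component time courses (variance-normalised);
stage B regresses each voxel's time series on those time courses to
obtain subject-specific spatial maps.  Group differences are then
tested voxelwise with a two-sample t statistic whose family-wise error
is controlled by max-statistic permutation of group labels, with
Bonferroni correction available for duplicate-network components.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .bold import MaskedRun

__all__ = [
    "SubjectTimecourses",
    "SubjectSpatialMap",
    "GroupStatMap",
    "stage_a",
    "stage_b",
    "dual_regress",
    "permutation_group_test",
    "bonferroni_adjust",
    "difference_map_stats",
]


@dataclass
class SubjectTimecourses:
    """(timepoints x K) component time courses for one subject; each
    column has unit sample variance after normalisation."""

    values: np.ndarray
    subject_id: str


@dataclass
class SubjectSpatialMap:
    """(K x voxels) regression-coefficient maps for one subject."""

    values: np.ndarray
    subject_id: str
    voxel_index: np.ndarray


@dataclass
class GroupStatMap:
    """Voxelwise two-sample t map with FWE-corrected permutation p."""

    tmap: np.ndarray
    p_fwe: np.ndarray
    n_permutations: int
    contrast: str
    exhaustive: bool = False


def _check_design_rank(design: np.ndarray, what: str) -> None:
    k = design.shape[1]
    if np.linalg.matrix_rank(design) < k:
        # report the most collinear pair to aid debugging
        c = np.corrcoef(design.T)
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(c)), c.shape)
        raise ValueError(
            f"rank-deficient {what}: columns {i} and {j} are collinear "
            f"(|r| = {abs(c[i, j]):.4f})"
        )


def stage_a(run: MaskedRun, group_maps: np.ndarray) -> SubjectTimecourses:
    """Regress each volume's voxel vector on the K group maps.

    Maps are demeaned over voxels and the data demeaned per voxel over
    time before the fit; the recovered time courses are then scaled to
    unit sample variance (variance normalisation).
    """
    maps = np.asarray(group_maps, dtype=float)
    if maps.ndim != 2:
        raise ValueError("group_maps must be (K, voxels)")
    k, n_vox = maps.shape
    data = run.matrix().astype(np.float64)  # (t, voxels)
    if n_vox != data.shape[1]:
        raise ValueError("map voxel set does not match the run voxel set")
    if k >= data.shape[0]:
        raise ValueError("need more timepoints than components")
    design = (maps - maps.mean(axis=1, keepdims=True)).T  # (voxels, K)
    _check_design_rank(design, "spatial map set")
    data = data - data.mean(axis=0, keepdims=True)
    tcs, *_ = np.linalg.lstsq(design, data.T, rcond=None)  # (K, t)
    tcs = tcs.T  # (t, K)
    sd = tcs.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate (constant) recovered time course")
    return SubjectTimecourses(values=tcs / sd, subject_id=run.run.subject_id)


def stage_b(run: MaskedRun, tcs: SubjectTimecourses) -> SubjectSpatialMap:
    """Regress each voxel's time series on the K normalised time courses
    (with an intercept); the coefficients form the subject's maps."""
    t_mat = np.asarray(tcs.values, dtype=float)
    data = run.matrix().astype(np.float64)  # (t, voxels)
    if t_mat.shape[0] != data.shape[0]:
        raise ValueError("time-course length does not match the run")
    _check_design_rank(t_mat, "time-course matrix")
    design = np.column_stack([np.ones(t_mat.shape[0]), t_mat])
    coefs, *_ = np.linalg.lstsq(design, data, rcond=None)
    return SubjectSpatialMap(
        values=coefs[1:, :],  # drop intercept
        subject_id=run.run.subject_id,
        voxel_index=run.voxel_index.copy(),
    )


def dual_regress(run: MaskedRun, group_maps: np.ndarray) -> SubjectSpatialMap:
    """Convenience: stage A then stage B for one subject."""
    return stage_b(run, stage_a(run, group_maps))


def _tstats(data: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column.

    ``data`` is (subjects x voxels); ``member`` a boolean matrix
    (n_perm x subjects) selecting group 1 per permutation.  Returns
    (n_perm x voxels) t values; zero-variance voxels with equal means
    get t = 0.
    """
    member = member.astype(np.float64)
    n = data.shape[0]
    n1 = member.sum(axis=1, keepdims=True)
    n2 = n - n1
    s1 = member @ data
    s2 = data.sum(axis=0, keepdims=True) - s1
    sq = data**2
    q1 = member @ sq
    q2 = sq.sum(axis=0, keepdims=True) - q1
    m1, m2 = s1 / n1, s2 / n2
    v1 = (q1 - n1 * m1**2) / (n1 - 1)
    v2 = (q2 - n2 * m2**2) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n - 2)
    sp2 = np.maximum(sp2, 0.0)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[(denom == 0) & (diff == 0)] = 0.0
    t[(denom == 0) & (diff != 0)] = np.sign(diff[(denom == 0) & (diff != 0)]) * np.inf
    return t


def permutation_group_test(
    maps_group1: np.ndarray,
    maps_group2: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    contrast: str = "group1>group2",
    force_monte_carlo: bool = False,
) -> GroupStatMap:
    """Voxelwise two-sample t with max-statistic FWE correction.

    The null is built by permuting group labels ``n_perm`` times (or by
    exhaustive enumeration of label assignments when their total count
    is <= n_perm) and recording the maximum |t| over voxels in each
    permutation.  For random permutations
    ``p_fwe(v) = (1 + #{max >= |t_obs(v)|}) / (n_perm + 1)``; for the
    exhaustive null the plain fraction over all assignments is used
    (the observed labelling is one of them).  Ties count as exceeding
    (conservative).
    """
    g1 = np.atleast_2d(np.asarray(maps_group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(maps_group2, dtype=float))
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 subjects")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is low; p values will be coarse")
    data = np.vstack([g1, g2])
    n = n1 + n2

    obs_member = np.zeros((1, n), dtype=bool)
    obs_member[0, :n1] = True
    t_obs = _tstats(data, obs_member)[0]

    total = comb(n, n1)
    exhaustive = (total <= n_perm) and not force_monte_carlo
    if exhaustive:
        import itertools

        member = np.zeros((total, n), dtype=bool)
        for row, combo in enumerate(itertools.combinations(range(n), n1)):
            member[row, list(combo)] = True
    else:
        rng = np.random.default_rng(seed)
        member = np.zeros((n_perm, n), dtype=bool)
        for row in range(n_perm):
            member[row, rng.permutation(n)[:n1]] = True

    # chunk to bound memory on large permutation counts
    max_null = np.empty(member.shape[0])
    chunk = max(1, int(2e7 // max(1, data.shape[1])))
    for start in range(0, member.shape[0], chunk):
        t_null = _tstats(data, member[start : start + chunk])
        max_null[start : start + chunk] = np.abs(t_null).max(axis=1)

    abs_obs = np.abs(t_obs)
    exceed = (max_null[:, None] >= abs_obs[None, :]).sum(axis=0)
    if exhaustive:
        p = exceed / total
        n_used = total
    else:
        p = (1.0 + exceed) / (n_perm + 1.0)
        n_used = n_perm
    return GroupStatMap(
        tmap=t_obs, p_fwe=p, n_permutations=n_used, contrast=contrast,
        exhaustive=exhaustive,
    )


def bonferroni_adjust(p_values, m: int):
    """Bonferroni over ``m`` tests: p_adj = min(1, p * m).

    ``p_values`` may be the per-test p values themselves or a voxelwise
    p map shared by each of the ``m`` duplicate-component tests.
    """
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)


def difference_map_stats(
    stat: GroupStatMap,
    alpha: float = 0.05,
    voxel_volume_mm3: float = 64.0,
    voxel_index: np.ndarray | None = None,
) -> dict:
    """Summary of the significant difference map in the conventional
    table layout: voxel count, volume, peak location, and mean/SD/min/
    max of t over significant voxels.  Peak coordinates are voxel
    indices (through ``voxel_index`` when given)."""
    sig = stat.p_fwe < alpha
    out = {
        "n_voxels": int(sig.sum()),
        "volume_mm3": float(sig.sum() * voxel_volume_mm3),
        "peak": None,
        "t_mean": None,
        "t_sd": None,
        "t_min": None,
        "t_max": None,
    }
    if not sig.any():
        return out
    tv = stat.tmap[sig]
    peak_flat = int(np.flatnonzero(sig)[np.argmax(np.abs(tv))])
    if voxel_index is not None:
        out["peak"] = tuple(int(c) for c in np.asarray(voxel_index)[peak_flat])
    else:
        out["peak"] = (peak_flat,)
    out.update(
        t_mean=float(tv.mean()),
        t_sd=float(tv.std(ddof=1)) if tv.size > 1 else 0.0,
        t_min=float(tv.min()),
        t_max=float(tv.max()),
    )
    return out
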