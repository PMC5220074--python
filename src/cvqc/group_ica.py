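"""Temporal-concatenation group spatial ICA.

Subjects' (demeaned, per-voxel variance-normalised) time series are
stacked along time and decomposed into K spatial sources that are
maximally non-Gaussian over voxels, after PCA reduction to K dimensions
(FastICA with the log-cosh contrast and symmetric decorrelation).  The
resulting z-scored component maps are thresholded with a Gaussian/gamma
mixture model: a central Gaussian absorbs the null background and a
positive-tail gamma (optionally also a negative-tail gamma) models
activation; a voxel is kept when the posterior probability of the
activation class exceeds 0.5, weighting false positives and false
negatives equally.  Components are matched to named network templates
by spatial correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .bold import MaskedRun

__all__ = [
    "DataMatrix",
    "ICADecomposition",
    "RSNMatch",
    "MixtureFit",
    "concatenate",
    "fit_group_ica",
    "threshold_map",
    "match_rsn",
]


@dataclass
class DataMatrix:
    """(total timepoints x voxels) stack with subject bookkeeping."""

    values: np.ndarray
    subject_boundaries: list[tuple[int, int]]
    subject_ids: list[str]
    voxel_index: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class ICADecomposition:
    """K z-scored spatial maps plus concatenated mixing time courses.

    ``mixing @ spatial_maps`` reconstructs (up to the removed row means)
    the K-dimensional principal subspace of the input matrix.
    """

    spatial_maps: np.ndarray  # (K, voxels), zero mean / unit variance each
    mixing: np.ndarray  # (total timepoints, K)
    k: int
    seed: int
    voxel_index: np.ndarray
    subject_boundaries: list[tuple[int, int]]
    row_means: np.ndarray  # per-row mean removed before decomposition
    thresholds: dict = field(default_factory=dict)


@dataclass
class RSNMatch:
    """Best-correlated component for one named network template."""

    template_name: str
    component_id: int | None
    correlation: float

    @property
    def matched(self) -> bool:
        return self.component_id is not None


@dataclass
class MixtureFit:
    """Fitted Gaussian/gamma mixture for one spatial map."""

    weights: np.ndarray
    gauss_mean: float
    gauss_sd: float
    gamma_pos: tuple[float, float] | None  # (shape, scale)
    gamma_neg: tuple[float, float] | None
    converged: bool
    n_iter: int


def concatenate(masked_runs: list[MaskedRun]) -> DataMatrix:
    """Stack subjects along time after within-subject per-voxel
    demeaning and variance normalisation (unit sample SD; voxels with
    zero variance are left at zero)."""
    if not masked_runs:
        raise ValueError("no runs to concatenate")
    ref_index = masked_runs[0].voxel_index
    blocks, boundaries, ids = [], [], []
    row = 0
    for mr in masked_runs:
        if mr.voxel_index.shape != ref_index.shape or not np.array_equal(
            mr.voxel_index, ref_index
        ):
            raise ValueError(
                f"voxel set of {mr.run.subject_id!r} differs from the first run"
            )
        mat = mr.matrix().astype(np.float64)  # (t, voxels)
        mat -= mat.mean(axis=0, keepdims=True)
        sd = mat.std(axis=0, ddof=1)
        np.divide(mat, sd, out=mat, where=sd > 0)
        mat[:, sd == 0] = 0.0
        blocks.append(mat)
        boundaries.append((row, row + mat.shape[0]))
        ids.append(mr.run.subject_id)
        row += mat.shape[0]
    return DataMatrix(
        values=np.vstack(blocks),
        subject_boundaries=boundaries,
        subject_ids=ids,
        voxel_index=ref_index.copy(),
    )


def fit_group_ica(
    matrix: DataMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ICADecomposition:
    """PCA-reduce to ``k`` dimensions, then spatial FastICA (log-cosh
    contrast, symmetric decorrelation).  The sign of each component is
    fixed so its spatial skewness is non-negative, which makes the
    decomposition reproducible across seeds up to component order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(matrix.n_rows, matrix.n_voxels):
        raise ValueError("k exceeds the rank bound min(rows, voxels)")

    # voxels as samples, timepoints as features -> spatial ICA
    x = matrix.values.T  # (voxels, rows)
    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(x)  # (voxels, k)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"group ICA did not converge in {max_iter} iterations"
            ) from exc

    mixing = ica.mixing_  # (rows, k)
    row_means = ica.mean_.copy()  # (rows,)

    maps = sources.T  # (k, voxels)
    # z-score over voxels; rescale mixing so mixing @ maps is unchanged
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise RuntimeError("degenerate (constant) ICA source map")
    # sources are zero-mean over voxels by construction; mu is numerically 0
    maps = (maps - mu) / sd
    mixing = mixing * sd.T

    skew = scipy.stats.skew(maps, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    maps *= flip[:, None]
    mixing *= flip[None, :]

    return ICADecomposition(
        spatial_maps=maps,
        mixing=mixing,
        k=k,
        seed=seed,
        voxel_index=matrix.voxel_index.copy(),
        subject_boundaries=list(matrix.subject_boundaries),
        row_means=row_means,
    )


def _gauss_gamma_em(
    z: np.ndarray,
    include_negative: bool,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, MixtureFit]:
    """EM for a central Gaussian + tail gamma mixture on a z-scored map.

    The gamma M-step uses moment matching (shape = m^2/v, scale = v/m)
    on responsibility-weighted tail values, which is robust at the small
    activation fractions typical of component maps.
    """
    eps = 1e-300
    n_comp = 3 if include_negative else 2
    w = np.array([0.95, 0.05, 0.0][:n_comp])
    if include_negative:
        w = np.array([0.90, 0.05, 0.05])
    mu, sd = float(np.median(z)), float(z.std())
    shape_p, scale_p = 3.0, 1.0
    shape_n, scale_n = 3.0, 1.0

    def dens():
        d = np.zeros((n_comp, z.size))
        d[0] = scipy.stats.norm.pdf(z, mu, max(sd, 1e-6))
        d[1] = np.where(z > 0, scipy.stats.gamma.pdf(z, shape_p, scale=scale_p), 0.0)
        if include_negative:
            d[2] = np.where(z < 0, scipy.stats.gamma.pdf(-z, shape_n, scale=scale_n), 0.0)
        return d

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = dens()
        num = w[:, None] * d + eps
        resp = num / num.sum(axis=0, keepdims=True)
        ll = float(np.log(num.sum(axis=0)).sum())

        w = resp.mean(axis=1)
        r0 = resp[0]
        mu = float((r0 * z).sum() / r0.sum())
        sd = float(np.sqrt((r0 * (z - mu) ** 2).sum() / r0.sum()))
        for comp, sign in ((1, 1.0),) + (((2, -1.0),) if include_negative else ()):
            r = resp[comp]
            x = sign * z
            mass = r[x > 0].sum()
            if mass < 1e-8:
                w[comp] = 0.0
                continue
            m = float((r[x > 0] * x[x > 0]).sum() / mass)
            v = float((r[x > 0] * (x[x > 0] - m) ** 2).sum() / mass)
            v = max(v, 1e-12)
            if comp == 1:
                shape_p, scale_p = max(m * m / v, 0.1), max(v / m, 1e-6)
            else:
                shape_n, scale_n = max(m * m / v, 0.1), max(v / m, 1e-6)
        w = w / w.sum()
        if abs(ll - prev_ll) < tol * (1 + abs(prev_ll)):
            converged = True
            break
        prev_ll = ll

    d = dens()
    num = w[:, None] * d + eps
    resp = num / num.sum(axis=0, keepdims=True)
    fit = MixtureFit(
        weights=w,
        gauss_mean=mu,
        gauss_sd=sd,
        gamma_pos=(shape_p, scale_p) if w[1] > 0 else None,
        gamma_neg=(shape_n, scale_n) if include_negative and w[2] > 0 else None,
        converged=converged,
        n_iter=it,
    )
    return resp, fit


def threshold_map(
    zmap: np.ndarray,
    include_negative: bool = False,
    posterior_threshold: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[np.ndarray, MixtureFit | None]:
    """Threshold a z-scored spatial map via a Gaussian/gamma mixture.

    Returns (active boolean array, fitted mixture).  A voxel is active
    when the posterior probability of the (positive-tail) activation
    class exceeds ``posterior_threshold`` — equal weighting of false
    positives and false negatives at 0.5.  If EM fails to converge, the
    conventional |z| > 2.3 cut is used instead and the mixture is None.
    """
    z = np.asarray(zmap, dtype=float).ravel()
    if z.size < 100:
        raise ValueError("mixture thresholding needs >= 100 voxels")
    if np.ptp(z) == 0:
        raise ValueError("constant map: no distribution to fit")
    resp, fit = _gauss_gamma_em(z, include_negative, max_iter, tol)
    if not fit.converged:
        warnings.warn(
            "Gaussian/gamma EM did not converge; falling back to |z| > 2.3",
            RuntimeWarning,
        )
        return (np.abs(np.asarray(zmap)) > 2.3), None
    if fit.weights[1] < 1e-4:
        active = np.zeros(z.size, dtype=bool)
    else:
        active = resp[1] > posterior_threshold
    return active.reshape(np.asarray(zmap).shape), fit


def match_rsn(
    decomp: ICADecomposition,
    templates: dict[str, np.ndarray],
    r_min: float = 0.2,
) -> list[RSNMatch]:
    """Match each named template to the component with maximal spatial
    Pearson correlation (ties broken by lower component index); matches
    with |r| below ``r_min`` are reported as unmatched.

    Templates may be 1D vectors over the decomposition's voxel set or 3D
    grids (sampled through the voxel index).
    """
    matches = []
    i, j, kk = decomp.voxel_index.T
    for name, tpl in templates.items():
        tpl = np.asarray(tpl, dtype=float)
        vec = tpl[i, j, kk] if tpl.ndim == 3 else tpl
        if vec.shape[0] != decomp.spatial_maps.shape[1]:
            raise ValueError(f"template {name!r} does not match the voxel set")
        if vec.std() == 0:
            matches.append(RSNMatch(name, None, 0.0))
            continue
        rs = np.array([
            float(np.corrcoef(vec, comp)[0, 1]) if comp.std() > 0 else 0.0
            for comp in decomp.spatial_maps
        ])
        best = int(np.argmax(np.abs(rs)))
        if abs(rs[best]) < r_min:
            matches.append(RSNMatch(name, None, float(rs[best])))
        else:
            matches.append(RSNMatch(name, best, float(rs[best])))
    return matches
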