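"""Minimal BOLD preprocessing on pre-aligned data.

Order of operations in the pipeline: drop initial volumes -> temporal
high-pass -> (CV maps are computed here, before smoothing, so that
slice-localised artifacts are not blurred away) -> spatial smoothing ->
gray-matter masking.

The high-pass filter is a Gaussian-weighted running-line (local linear)
detrend with sigma = cutoff / (2 TR) volumes, the classic fMRI drift
remover; it is characterised by its measured gain curve, not by
coefficient-level compatibility with any particular toolbox.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .bold import BoldRun, GMMask, MaskedRun

__all__ = [
    "drop_initial_volumes",
    "highpass_filter",
    "smooth_gaussian",
    "resample_mask_to_bold",
    "apply_gm_mask",
    "FWHM_TO_SIGMA",
]

#: 1 / (2 sqrt(2 ln 2)); multiply an FWHM by this to get a Gaussian sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def drop_initial_volumes(run: BoldRun, n_drop: int) -> BoldRun:
    """Remove the first ``n_drop`` volumes (T1 saturation transients)."""
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if n_drop >= run.n_volumes:
        raise ValueError(f"cannot drop {n_drop} of {run.n_volumes} volumes")
    if n_drop == 0:
        return run.with_data(run.data.copy())
    return run.with_data(run.data[..., n_drop:].copy())


def _running_line_trend(series: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-weighted local linear fit along the last axis.

    At each time point t the series is fit by a + b (s - t) with weights
    exp(-(s-t)^2 / 2 sigma^2); the trend is the local intercept a.  Near
    the edges the kernel is truncated and the normal equations adapt, so
    the slope term keeps slow edge trends from leaking through.
    """
    n = series.shape[-1]
    radius = min(n - 1, int(np.ceil(4.0 * sigma)))
    u = np.arange(-radius, radius + 1, dtype=np.float64)
    w = np.exp(-(u**2) / (2.0 * sigma**2))
    k0, k1, k2 = w, w * u, w * u * u

    ones = np.ones(n)
    opts = dict(mode="constant", cval=0.0)
    s0 = ndimage.correlate1d(ones, k0, **opts)
    s1 = ndimage.correlate1d(ones, k1, **opts)
    s2 = ndimage.correlate1d(ones, k2, **opts)

    flat = series.reshape(-1, n)
    m0 = ndimage.correlate1d(flat, k0, axis=-1, **opts)
    m1 = ndimage.correlate1d(flat, k1, axis=-1, **opts)
    det = s0 * s2 - s1 * s1
    trend = (s2 * m0 - s1 * m1) / det
    return trend.reshape(series.shape)


def highpass_filter(run: BoldRun, cutoff_seconds: float = 100.0) -> BoldRun:
    """Remove fluctuations slower than ``cutoff_seconds`` per voxel via a
    local-Gaussian-weighted running-line detrend (sigma = cutoff / 2 TR
    volumes); the voxel temporal mean is re-added after filtering."""
    if cutoff_seconds <= 2.0 * run.tr_seconds:
        raise ValueError("cutoff must exceed 2 x TR")
    sigma = cutoff_seconds / (2.0 * run.tr_seconds)
    trend = _running_line_trend(run.data, sigma)
    resid = run.data - trend
    # recenter the filtered fluctuation at the original voxel mean
    mean = run.data.mean(axis=-1, keepdims=True)
    return run.with_data(resid - resid.mean(axis=-1, keepdims=True) + mean)


def smooth_gaussian(
    run: BoldRun, fwhm_mm: float = 5.0, voxel_size_mm=None
) -> BoldRun:
    """Convolve each volume with an isotropic Gaussian of the given FWHM
    (zero-padding boundary).  ``voxel_size_mm`` may be a scalar or a
    3-vector; by default it is taken from the run's affine."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if voxel_size_mm is None:
        voxel_size_mm = run.voxel_size_mm
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    if np.any(vox <= 0):
        raise ValueError("voxel sizes must be positive")
    if fwhm_mm == 0:
        return run.with_data(run.data.copy())
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / vox
    smoothed = ndimage.gaussian_filter(
        run.data, sigma=(*sigma_vox, 0.0), mode="constant", cval=0.0
    )
    return run.with_data(smoothed)


def resample_mask_to_bold(
    mask: GMMask, bold_shape: tuple[int, int, int], threshold: float = 0.5
) -> GMMask:
    """Bring a partial-volume map onto the (coarser) BOLD grid by block
    averaging; the binary mask is re-derived as resampled value >
    threshold.  Grids must be identical or related by integer factors."""
    src = mask.partial_volume
    if tuple(src.shape) == tuple(bold_shape):
        return GMMask(partial_volume=src.copy(), binary=src > threshold,
                      subject_id=mask.subject_id)
    factors = []
    for s, b in zip(src.shape, bold_shape):
        if b == 0 or s % b != 0:
            raise ValueError(
                f"mask grid {src.shape} is not an integer multiple of "
                f"BOLD grid {tuple(bold_shape)}"
            )
        factors.append(s // b)
    fx, fy, fz = factors
    bx, by, bz = bold_shape
    blocks = src.reshape(bx, fx, by, fy, bz, fz)
    pv = blocks.mean(axis=(1, 3, 5))
    return GMMask(partial_volume=pv, binary=pv > threshold,
                  subject_id=mask.subject_id)


def apply_gm_mask(run: BoldRun, mask: GMMask | np.ndarray) -> MaskedRun:
    """Restrict a run to gray-matter voxels.

    Non-GM voxels are zeroed in the returned 4D data and excluded from
    the voxel-index map, so downstream matrix views contain GM only.
    """
    binary = mask if isinstance(mask, np.ndarray) else mask.binary
    binary = np.asarray(binary, dtype=bool)
    if binary.shape != run.grid_shape:
        raise ValueError("mask grid does not match the BOLD grid")
    if not binary.any():
        raise ValueError("mask is empty")
    data = np.where(binary[..., None], run.data, 0.0)
    voxel_index = np.argwhere(binary)
    return MaskedRun(run=run.with_data(data), voxel_index=voxel_index)
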