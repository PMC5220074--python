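"""Core in-memory containers for BOLD runs and tissue masks.

Conventions
-----------
4D data are stored ``(x, y, z, t)`` with the slice (slowest acquisition)
axis along ``z``.  All intensities are in arbitrary scanner units.  Grids
are assumed pre-aligned across subjects: the affine carries voxel size
only, no cross-subject registration is performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["BoldRun", "GMMask", "MaskedRun", "estimate_brain_mask"]


def _default_affine(voxel_size_mm: float = 4.0) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class BoldRun:
    """One subject's 4D BOLD series plus grid metadata.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel time series in scanner units.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    subject_id : str
        Unique subject identifier.
    group : str
        Categorical group label, e.g. ``"control"`` or ``"patient"``.
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine; defaults to a 4 mm isotropic grid.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = "sub-00"
    group: str = "control"
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (x,y,z,t) data, got ndim={self.data.ndim}")
        if self.data.shape[-1] < 2:
            raise ValueError("a BOLD run needs at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray) -> "BoldRun":
        """Return a copy of this run with new data and identical metadata."""
        return replace(self, data=data)


@dataclass
class GMMask:
    """Gray-matter mask: a partial-volume map plus its binarised form."""

    partial_volume: np.ndarray
    binary: np.ndarray
    subject_id: str = "sub-00"

    def __post_init__(self) -> None:
        self.partial_volume = np.asarray(self.partial_volume, dtype=np.float64)
        self.binary = np.asarray(self.binary, dtype=bool)
        if self.partial_volume.ndim != 3:
            raise ValueError("partial_volume must be 3D")
        pv = self.partial_volume
        if pv.min() < 0 or pv.max() > 1:
            raise ValueError("partial-volume values must lie in [0, 1]")
        if np.any(self.binary & (pv <= 0)):
            raise ValueError("binary mask must be a subset of partial_volume > 0")

    @classmethod
    def from_partial_volume(
        cls, pv: np.ndarray, subject_id: str = "sub-00", threshold: float = 0.5
    ) -> "GMMask":
        pv = np.asarray(pv, dtype=np.float64)
        return cls(partial_volume=pv, binary=pv > threshold, subject_id=subject_id)


@dataclass
class MaskedRun:
    """A BOLD run restricted to a voxel set, with the index map retained.

    ``voxel_index`` has shape ``(n_voxels, 3)`` and lists the (x, y, z)
    coordinates of the retained voxels, in the order used by
    :meth:`matrix`.  It is the bridge that lets 2D (time x voxel)
    matrices re-project deterministically to the 3D grid.
    """

    run: BoldRun
    voxel_index: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.voxel_index.ndim != 2 or self.voxel_index.shape[1] != 3:
            raise ValueError("voxel_index must have shape (n_voxels, 3)")

    @property
    def n_voxels(self) -> int:
        return self.voxel_index.shape[0]

    def matrix(self) -> np.ndarray:
        """Return the (timepoints x voxels) data matrix over the voxel set."""
        i, j, k = self.voxel_index.T
        return self.run.data[i, j, k, :].T

    def project(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Re-project a per-voxel vector onto the 3D grid."""
        values = np.asarray(values)
        out = np.full(self.run.grid_shape, fill, dtype=values.dtype)
        i, j, k = self.voxel_index.T
        out[i, j, k] = values
        return out


def estimate_brain_mask(run: BoldRun, rel_threshold: float = 0.25) -> np.ndarray:
    """Data-driven brain mask: voxels whose temporal mean exceeds a
    fraction of the robust (99th percentile) peak intensity.

    Phantom and scanner backgrounds sit near zero while brain tissue sits
    near the baseline level, so a low relative threshold separates them.
    """
    mean_vol = run.data.mean(axis=-1)
    peak = np.percentile(mean_vol, 99)
    if peak <= 0:
        raise ValueError("cannot estimate a brain mask from non-positive data")
    return mean_vol > rel_threshold * peak
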