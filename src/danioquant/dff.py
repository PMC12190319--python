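"""Per-voxel dF/F activity maps from slow whole-brain fluorescence series.

Spontaneous neural activity in GCaMP-expressing larvae is recorded at a low
frame rate (0.5 Hz for 5 min in the motivating experiments).  Because GCaMP
expression level varies between fish, each voxel is normalised to its own
baseline: the minimum fluorescence over the recording.  The activity
readout is the largest fractional excursion above that baseline,

    dF/F = 100 * (max_t F - min_t F) / min_t F   [%]

and the summary statistic is the mean dF/F within a mask covering cellular
brain regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelTimeSeries",
    "DFFMap",
    "smooth_series",
    "dff_map",
    "mask_mean_dff",
]


@dataclass
class VoxelTimeSeries:
    """Fluorescence series on a 2-D (widefield) or 3-D voxel grid.

    ``data`` has shape ``(*grid, n_frames)``: time is the last axis.
    """

    data: np.ndarray
    frame_rate_hz: float
    subject_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (x, y, t) or (x, y, z, t)")
        if self.data.shape[-1] < 2:
            raise ValueError("need at least 2 frames")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class DFFMap:
    """Per-voxel percent change over minimum baseline.

    ``values`` is NaN at voxels whose baseline fell at or below the floor
    (the min-baseline formula is unstable near zero); those voxels are
    excluded from all summaries.
    """

    values: np.ndarray  # percent
    baseline: np.ndarray
    floor: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def smooth_series(series: VoxelTimeSeries, sigma_vox: float = 2.0) -> VoxelTimeSeries:
    """Spatial Gaussian smoothing applied frame by frame.

    ``sigma_vox`` is in voxels and applies to the spatial axes only;
    sigma 0 returns the data unchanged.
    """
    if sigma_vox < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_vox == 0:
        data = series.data.copy()
    else:
        sigma = (sigma_vox,) * (series.data.ndim - 1) + (0.0,)
        data = ndimage.gaussian_filter(series.data, sigma=sigma)
        np.clip(data, 0.0, None, out=data)
    return VoxelTimeSeries(
        data=data,
        frame_rate_hz=series.frame_rate_hz,
        subject_id=series.subject_id,
        genotype=series.genotype,
    )


def dff_map(series: VoxelTimeSeries, baseline_floor: float | None = None) -> DFFMap:
    """Min-baseline dF/F in percent, per voxel.

    The baseline F0 is each voxel's minimum over time; dF/F is
    ``100 * (max - F0) / F0``.  Voxels with F0 at or below
    ``baseline_floor`` are marked invalid (NaN).  The default floor is 1%
    of the series' robust (99.9th percentile) maximum, guarding against
    division by near-zero baselines outside the brain.
    """
    f0 = series.data.min(axis=-1)
    fmax = series.data.max(axis=-1)
    if baseline_floor is None:
        baseline_floor = 0.01 * float(np.percentile(series.data, 99.9))
    valid = f0 > baseline_floor
    if not valid.any():
        raise ValueError("all voxels below the baseline floor")
    values = np.full(f0.shape, np.nan)
    values[valid] = 100.0 * (fmax[valid] - f0[valid]) / f0[valid]
    return DFFMap(values=values, baseline=f0, floor=float(baseline_floor))


def mask_mean_dff(dff: DFFMap, mask: np.ndarray) -> float:
    """Mean dF/F (%) over valid voxels inside a boolean mask."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != dff.values.shape:
        raise ValueError("mask shape must match map shape")
    sel = mask & dff.valid
    if not sel.any():
        raise ValueError("mask does not overlap any valid voxels")
    return float(dff.values[sel].mean())
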