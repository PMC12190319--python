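"""Voxel-based morphometry statistics on registered brain volumes.

After elastic registration of each subject's brain to a reference, the log
Jacobian determinant (LJD) of the transformation records, per voxel, how
much local tissue had to contract (LJD < 0) or dilate (LJD > 0) to match
the reference.  This module consumes such registered maps — LJD channels
and fluorescence channels resampled to the reference grid — and provides:

* ``log_jacobian``: LJD computation from a displacement field;
* ``mask_volume``: subject-space volumetry of a reference-space mask by
  integrating exp(LJD), optionally normalised to whole-brain volume;
* ``voxelwise_group_stat`` / ``permutation_cluster``: two-group voxelwise
  Welch t maps with family-wise cluster significance calibrated by
  permutation of group labels (null statistic = maximum supra-threshold
  cluster extent);
* ``symmetrize``: conservative bilateral symmetrization of p maps
  (greater p at each mirrored voxel pair);
* ``voxelwise_anova``: per-voxel two-way ANOVA (group + cohort) for
  combining independent cohorts;
* ``region_intensity_summary``: in-mask channel intensity group contrast.

Sign convention throughout: negative LJD means the subject is locally
smaller than the reference.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

__all__ = [
    "LJDMap",
    "ChannelMap",
    "ClusterResult",
    "MaskVolumeResult",
    "RegionIntensitySummary",
    "log_jacobian",
    "mask_volume",
    "voxelwise_group_stat",
    "permutation_cluster",
    "symmetrize",
    "voxelwise_anova",
    "region_intensity_summary",
    "save_volume_nifti",
    "load_volume_nifti",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LJDMap:
    """Per-voxel log Jacobian determinant of a subject-to-reference warp."""

    values: np.ndarray  # dimensionless; negative = contraction
    voxel_size_um: tuple[float, float, float]
    subject_id: str = ""
    genotype: str = ""
    cohort_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))


@dataclass
class ChannelMap:
    """A registered per-voxel intensity map (tuba, gad1b or the LJD itself)."""

    values: np.ndarray
    channel: str
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    genotype: str = ""
    cohort_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class ClusterResult:
    """Voxelwise statistics with permutation-calibrated significant clusters.

    ``p_map`` holds the nominal per-voxel p only inside clusters that
    survived the family-wise test; NaN elsewhere.  ``cluster_table`` has one
    row per supra-threshold cluster (significant or not) with its extent,
    peak statistic and family-wise corrected p.
    """

    stat_map: np.ndarray
    p_map: np.ndarray
    cluster_labels: np.ndarray  # 0 outside significant clusters
    cluster_table: pd.DataFrame
    forming_threshold_p: float
    cluster_alpha: float
    n_permutations: int
    seed: int | None
    exhaustive: bool
    null_max_sizes: np.ndarray = field(repr=False, default=None)


@dataclass
class MaskVolumeResult:
    """Subject-space volume of a reference-space mask."""

    subject_id: str
    mask_name: str
    absolute_volume_um3: float
    percent_of_brain: float


@dataclass
class RegionIntensitySummary:
    """Group contrast of mean in-mask channel intensity."""

    per_subject: pd.DataFrame  # subject_id, group, mean_intensity
    group_means: dict
    reference_group: str
    other_group: str
    percent_difference: float  # 100 * (1 - other/reference)
    ci95: tuple[float, float]


# ---------------------------------------------------------------------------
# log Jacobian determinant
# ---------------------------------------------------------------------------

def log_jacobian(
    displacement: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    **meta,
) -> LJDMap:
    """Log Jacobian determinant of a dense displacement field.

    Parameters
    ----------
    displacement
        Displacement vectors u(x) in physical units (µm), shape
        ``(nx, ny, nz, 3)``; the warp is x -> x + u(x).
    voxel_size_um
        Grid spacing, used for the finite differences.

    Returns
    -------
    LJDMap with ``ln det(I + grad u)`` per voxel, computed with central
    differences (one-sided at the borders).  Voxels where the local
    Jacobian is non-invertible (det <= 0) are flagged NaN and excluded
    from downstream statistics.
    """
    u = np.asarray(displacement, dtype=float)
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ValueError("displacement must have shape (nx, ny, nz, 3)")
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field must be finite")
    grid = u.shape[:3]
    jac = np.empty(grid + (3, 3))
    for i in range(3):  # component
        grads = np.gradient(u[..., i], *voxel_size_um, edge_order=1)
        for j in range(3):  # direction
            jac[..., i, j] = grads[j]
        jac[..., i, i] += 1.0
    det = np.linalg.det(jac)
    values = np.full(grid, np.nan)
    ok = det > 0
    values[ok] = np.log(det[ok])
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} voxel(s) with non-invertible local Jacobian flagged NaN")
    return LJDMap(values=values, voxel_size_um=tuple(voxel_size_um), **meta)


# ---------------------------------------------------------------------------
# volumetry
# ---------------------------------------------------------------------------

def mask_volume(
    subject: LJDMap | np.ndarray,
    mask: np.ndarray,
    brain_mask: np.ndarray,
    mask_name: str = "mask",
    voxel_size_um: tuple[float, float, float] | None = None,
) -> MaskVolumeResult:
    """Subject-space volume of a reference-space mask.

    For an ``LJDMap`` input the subject volume of the mask is
    ``sum_mask exp(LJD) * voxel_volume`` — each reference voxel contributes
    the local subject-space volume it maps from.  For a binary
    segmentation array the volume is a plain voxel count times voxel
    volume (``voxel_size_um`` required).  ``percent_of_brain`` normalises
    by the whole-brain volume computed the same way.
    """
    mask = np.asarray(mask).astype(bool)
    brain_mask = np.asarray(brain_mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if isinstance(subject, LJDMap):
        vals = subject.values
        if vals.shape != mask.shape:
            raise ValueError("mask shape must match map grid")
        voxvol = subject.voxel_volume_um3
        factor = np.exp(np.nan_to_num(vals, nan=0.0))
        mask_vol = float(factor[mask].sum()) * voxvol
        brain_vol = float(factor[brain_mask].sum()) * voxvol
        subject_id = subject.subject_id
    else:
        seg = np.asarray(subject).astype(bool)
        if voxel_size_um is None:
            raise ValueError("voxel_size_um required for segmentation input")
        voxvol = float(np.prod(voxel_size_um))
        mask_vol = float((seg & mask).sum()) * voxvol
        brain_vol = float((seg & brain_mask).sum()) * voxvol
        subject_id = ""
    if brain_vol <= 0:
        raise ValueError("brain mask has zero volume")
    return MaskVolumeResult(
        subject_id=subject_id,
        mask_name=mask_name,
        absolute_volume_um3=mask_vol,
        percent_of_brain=100.0 * mask_vol / brain_vol,
    )


# ---------------------------------------------------------------------------
# voxelwise two-group statistics
# ---------------------------------------------------------------------------

def _stack_two_groups(
    maps: Sequence[ChannelMap | LJDMap],
    groups: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if len(maps) != len(groups):
        raise ValueError("one group label per map required")
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}")
    data = np.stack([np.asarray(m.values, dtype=float) for m in maps])
    is_a = np.array([g == labels[0] for g in groups])
    return data, is_a, labels


def _welch_t(data: np.ndarray, is_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t and two-sided p over axis 0 split by ``is_a``.

    ``data`` is (n_subjects, *grid).  Voxels with zero variance in both
    groups get NaN.
    """
    a, b = data[is_a], data[~is_a]
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * special.stdtr(df, -np.abs(t))
    bad = ~np.isfinite(t)
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)
    return t, p


def voxelwise_group_stat(
    maps: Sequence[ChannelMap | LJDMap],
    groups: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel unequal-variance (Welch) two-sample t and nominal p.

    Positive t means the first group (alphabetically first label) is
    larger.  Voxels with zero variance in both groups are NaN.
    """
    data, is_a, _ = _stack_two_groups(maps, groups)
    if is_a.sum() < 2 or (~is_a).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    return _welch_t(data, is_a)


def _label_clusters(mask: np.ndarray) -> tuple[np.ndarray, int]:
    # full connectivity: 26-neighbourhood in 3-D, 8 in 2-D
    structure = np.ones((3,) * mask.ndim, dtype=bool)
    return ndimage.label(mask, structure=structure)


def _max_cluster_size(p: np.ndarray, forming_p: float) -> int:
    labels, n = _label_clusters(np.nan_to_num(p, nan=1.0) < forming_p)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def permutation_cluster(
    maps: Sequence[ChannelMap | LJDMap],
    groups: Sequence[str],
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    forming_threshold_p: float = 0.01,
    seed: int | None = None,
    min_cluster_size: int = 1,
) -> ClusterResult:
    """Two-group cluster inference with permutation family-wise calibration.

    Candidate clusters are connected components (full 26-connectivity) of
    voxels with nominal Welch-t p below ``forming_threshold_p``.  Group
    labels are permuted ``n_perm`` times and the maximum supra-threshold
    cluster extent recorded each time; a cluster is significant when its
    extent is extreme relative to this null at level ``cluster_alpha``
    (Monte-Carlo p ``(1 + b) / (m + 1)``).  When fewer than ``n_perm``
    distinct label arrangements exist the null is enumerated exhaustively
    instead (noted in the result).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    data, is_a, labels2 = _stack_two_groups(maps, groups)
    na = int(is_a.sum())
    nb = int((~is_a).sum())
    if na < 3 or nb < 3:
        raise ValueError("need at least 3 subjects per group")
    n = na + nb
    flat = data.reshape(n, -1)
    grid = data.shape[1:]

    t_obs, p_obs = _welch_t(flat, is_a)
    forming = np.nan_to_num(p_obs, nan=1.0) < forming_threshold_p
    obs_labels, n_clusters = _label_clusters(forming.reshape(grid))
    sizes = np.bincount(obs_labels.ravel())[1:] if n_clusters else np.array([], int)

    n_arrangements = math.comb(n, na)
    exhaustive = n_perm >= n_arrangements
    if exhaustive:
        warnings.warn(
            f"only {n_arrangements} label arrangements for {na}+{nb} subjects; "
            "enumerating the null exhaustively"
        )
        assignments = [
            np.isin(np.arange(n), idx)
            for idx in itertools.combinations(range(n), na)
        ]
    else:
        rng = np.random.default_rng(seed)
        assignments = []
        for _ in range(n_perm):
            perm = rng.permutation(n)
            assignments.append(np.isin(np.arange(n), perm[:na]))

    null_max = np.empty(len(assignments), dtype=int)
    for k, assign in enumerate(assignments):
        _, p_perm = _welch_t(flat, assign)
        null_max[k] = _max_cluster_size(p_perm.reshape(grid), forming_threshold_p)

    rows = []
    significant = np.zeros(n_clusters + 1, dtype=bool)
    t_grid = t_obs.reshape(grid)
    for cid in range(1, n_clusters + 1):
        size = int(sizes[cid - 1])
        if exhaustive:
            p_fwe = float(np.mean(null_max >= size))
        else:
            p_fwe = (1.0 + float(np.sum(null_max >= size))) / (len(null_max) + 1.0)
        sig = p_fwe <= cluster_alpha and size >= min_cluster_size
        significant[cid] = sig
        in_cluster = obs_labels == cid
        peak = float(np.nanmax(np.abs(t_grid[in_cluster])))
        rows.append(
            {"cluster_id": cid, "size_vox": size, "peak_abs_t": peak,
             "p_fwe": p_fwe, "significant": sig}
        )

    sig_labels = np.where(significant[obs_labels], obs_labels, 0)
    p_map = np.where(sig_labels > 0, p_obs.reshape(grid), np.nan)
    table = pd.DataFrame(
        rows, columns=["cluster_id", "size_vox", "peak_abs_t", "p_fwe", "significant"]
    )
    return ClusterResult(
        stat_map=t_grid,
        p_map=p_map,
        cluster_labels=sig_labels,
        cluster_table=table,
        forming_threshold_p=forming_threshold_p,
        cluster_alpha=cluster_alpha,
        n_permutations=len(assignments),
        seed=seed,
        exhaustive=exhaustive,
        null_max_sizes=null_max,
    )


# ---------------------------------------------------------------------------
# symmetrization
# ---------------------------------------------------------------------------

def symmetrize(
    p_map: np.ndarray,
    axis: int = 0,
    center: float | None = None,
) -> np.ndarray:
    """Conservative bilateral symmetrization of a p map.

    Each voxel is replaced by the greater of its own p and the p at its
    mirror position across the midsagittal plane (``axis``, mirror plane at
    coordinate ``center``; default the grid midpoint ``(N - 1) / 2``, which
    for even extents mirrors between voxel centers).  NaNs propagate as the
    greater value so an invalid voxel never lends significance to its
    mirror.  Idempotent by construction.
    """
    p = np.asarray(p_map, dtype=float)
    n = p.shape[axis]
    if center is None:
        center = (n - 1) / 2.0
    idx = np.arange(n)
    mirror = np.round(2.0 * center - idx).astype(int)
    if mirror.min() < 0 or mirror.max() >= n:
        raise ValueError(
            f"mirror plane at {center} maps voxels outside the grid "
            f"(axis length {n}); set `center` consistently with the grid"
        )
    mirrored = np.take(p, mirror, axis=axis)
    return np.maximum(p, mirrored)  # NaN propagates: invalid voxels stay invalid


# ---------------------------------------------------------------------------
# two-cohort voxelwise ANOVA
# ---------------------------------------------------------------------------

def voxelwise_anova(
    maps: Sequence[ChannelMap | LJDMap],
    groups: Sequence[str],
    cohorts: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel two-way ANOVA (group + cohort): F and p for the group effect.

    Fits the additive linear model ``value ~ group + cohort`` at each voxel
    and tests the group effect against the cohort-only reduced model, so a
    constant intensity offset between cohorts is absorbed by the blocking
    factor.  Requires at least two cohorts and two groups with every
    group x cohort cell occupied.
    """
    if len(maps) != len(groups) or len(maps) != len(cohorts):
        raise ValueError("groups and cohorts must label every map")
    glabels = sorted(set(groups))
    clabels = sorted(set(cohorts))
    if len(clabels) < 2:
        raise ValueError(
            "need at least two cohorts; for a single cohort use voxelwise_group_stat"
        )
    if len(glabels) < 2:
        raise ValueError("need at least two groups")
    for g in glabels:
        for c in clabels:
            if not any(gi == g and ci == c for gi, ci in zip(groups, cohorts)):
                raise ValueError(f"empty design cell: group {g!r} in cohort {c!r}")

    n = len(maps)
    flat = np.stack([np.asarray(m.values, dtype=float).ravel() for m in maps])
    grid = np.asarray(maps[0].values).shape

    def design(with_group: bool) -> np.ndarray:
        cols = [np.ones(n)]
        if with_group:
            cols += [[1.0 if g == lab else 0.0 for g in groups] for lab in glabels[1:]]
        cols += [[1.0 if c == lab else 0.0 for c in cohorts] for lab in clabels[1:]]
        return np.column_stack(cols)

    def rss(X: np.ndarray) -> np.ndarray:
        # residual sum of squares per voxel via the hat matrix (n is small)
        H = X @ np.linalg.pinv(X)
        resid = flat - H @ flat
        return (resid**2).sum(axis=0)

    X_full = design(True)
    X_red = design(False)
    df1 = len(glabels) - 1
    df2 = n - X_full.shape[1]
    if df2 <= 0:
        raise ValueError("not enough subjects for the two-way model")
    rss_full = rss(X_full)
    rss_red = rss(X_red)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    valid = np.isfinite(F) & (rss_full > 0)
    F = np.where(valid, F, np.nan)
    p = np.where(valid, stats.f.sf(np.where(valid, F, 0.0), df1, df2), np.nan)
    return F.reshape(grid), p.reshape(grid)


# ---------------------------------------------------------------------------
# region intensity contrast
# ---------------------------------------------------------------------------

def region_intensity_summary(
    maps: Sequence[ChannelMap],
    mask: np.ndarray,
    groups: Sequence[str],
    reference_group: str | None = None,
) -> RegionIntensitySummary:
    """Group contrast of mean in-mask intensity.

    Computes each subject's mean intensity inside ``mask``, the group
    means, and the percent difference ``100 * (1 - other / reference)`` —
    positive when the non-reference group (e.g. mutant) is dimmer.  A 95%
    CI for the percent difference is obtained by the delta method on the
    ratio of group means.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    data, is_a, labels = _stack_two_groups(maps, groups)
    if reference_group is None:
        reference_group = labels[0]
    if reference_group not in labels:
        raise ValueError(f"reference group {reference_group!r} not among {labels}")
    other_group = labels[1] if reference_group == labels[0] else labels[0]
    per_subj = np.array([m.values[mask].mean() for m in maps])
    df = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in maps],
            "group": list(groups),
            "mean_intensity": per_subj,
        }
    )
    ref = per_subj[np.array(groups) == reference_group]
    oth = per_subj[np.array(groups) == other_group]
    mu_r, mu_o = ref.mean(), oth.mean()
    pct = 100.0 * (1.0 - mu_o / mu_r)
    # delta-method variance of the mean ratio
    var_r = ref.var(ddof=1) / len(ref) if len(ref) > 1 else 0.0
    var_o = oth.var(ddof=1) / len(oth) if len(oth) > 1 else 0.0
    se_ratio = math.sqrt(var_o / mu_r**2 + mu_o**2 * var_r / mu_r**4)
    half = 100.0 * 1.96 * se_ratio
    return RegionIntensitySummary(
        per_subject=df,
        group_means={g: float(per_subj[np.array(groups) == g].mean()) for g in labels},
        reference_group=reference_group,
        other_group=other_group,
        percent_difference=float(pct),
        ci95=(float(pct - half), float(pct + half)),
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_volume_nifti(
    values: np.ndarray,
    path: str | Path,
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a 3-D array as NIfTI with voxel size in the affine (µm)."""
    import nibabel as nib

    affine = np.diag(list(voxel_size_um) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def load_volume_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3-D NIfTI; returns (array, voxel size from the header)."""
    import nibabel as nib

    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), zooms
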