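"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs to this package come from high-speed cardiac video, 10 Hz
locomotor tracking, registered confocal volumes and slow GCaMP recordings.
None of those are required for testing: this module generates each input
class with a known, programmable ground truth so recovery can be asserted
exactly.

* Cardiac traces: quasi-periodic dual-chamber pulse trains with a
  programmable atrial rate, atrioventricular conduction ratio (1:1, 2:1 or
  probabilistic intermediate n:1), an optional mid-recording regime
  switch, and additive Gaussian imaging noise.
* Locomotor tracks: immobility broken by Poisson-timed swim bouts, plus
  rare high-displacement seizure-like bursts at a per-group rate.
* Volumetric cohorts: smooth random log-Jacobian and channel-intensity
  fields on a reference grid with ellipsoidal brain/region masks and
  planted per-region volumetric or intensity effects.
* GCaMP series: baseline plus exponentially decaying transients.

All generators are deterministic under a fixed seed; cohort members get
seeds derived from the master seed and a stable hash of their identity, so
any subject can be regenerated in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cardio import (
    CLASS_BLOCK,
    CLASS_INTERMEDIATE,
    CLASS_MATCHED,
    DualChamberTrace,
)
from .dff import VoxelTimeSeries
from .morpho import ChannelMap, LJDMap

__all__ = [
    "CardiacSimParams",
    "TrackSimParams",
    "VolumeSimParams",
    "GcampSimParams",
    "LarvaRecordings",
    "VolumeCohort",
    "simulate_cardiac_trace",
    "simulate_av_cohort",
    "simulate_tracks",
    "simulate_volumes",
    "simulate_gcamp",
    "derive_seed",
    "ellipsoid_mask",
]


def derive_seed(master_seed: int, *identity) -> int:
    """Reproducible per-subject seed: master seed + stable hash of identity.

    Uses CRC32 of the repr of the identity tuple, so cohorts are
    reproducible piecewise regardless of generation order.
    """
    h = zlib.crc32(repr(identity).encode())
    return int((int(master_seed) + h) % (2**31 - 1))


def true_av_class(ratio: float) -> str:
    """Ground-truth conduction class implied by a planted ratio."""
    if abs(ratio - 1.0) < 1e-9:
        return CLASS_MATCHED
    if abs(ratio - 2.0) < 1e-9:
        return CLASS_BLOCK
    return CLASS_INTERMEDIATE


# ---------------------------------------------------------------------------
# cardiac traces
# ---------------------------------------------------------------------------

@dataclass
class CardiacSimParams:
    """Parameters of one synthetic dual-chamber cardiac recording.

    ``conduction_ratio`` is the mean number of atrial beats per ventricular
    beat: 1 = matched rhythm, 2 = 2:1 block, non-integer values produce an
    intermediate n:1 rhythm through probabilistic conduction (each atrial
    beat conducts with probability 1/ratio).  ``noise_sd`` is the standard
    deviation of the additive Gaussian noise as a fraction of the pulse
    amplitude.  If ``switch_time_s`` is set, the conduction ratio changes
    to ``switch_ratio`` mid-recording.
    """

    atrial_rate_bpm: float
    conduction_ratio: float = 1.0
    duration_s: float = 30.0
    sample_rate_hz: float = 100.0
    noise_sd: float = 0.0
    switch_time_s: float | None = None
    switch_ratio: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.atrial_rate_bpm <= 0:
            raise ValueError("atrial_rate_bpm must be positive")
        if self.conduction_ratio < 1.0:
            raise ValueError("conduction_ratio must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.duration_s * self.sample_rate_hz < 256:
            raise ValueError("trace must have at least 256 samples")
        if self.duration_s < 60.0 / self.atrial_rate_bpm:
            raise ValueError("duration too short for a single beat")
        if (self.switch_time_s is None) != (self.switch_ratio is None):
            raise ValueError("switch_time_s and switch_ratio must be set together")
        if self.switch_ratio is not None and self.switch_ratio < 1.0:
            raise ValueError("switch_ratio must be >= 1")


def _pulse_train(
    n_samples: int,
    sample_rate_hz: float,
    beat_times_s: np.ndarray,
    width_s: float,
) -> np.ndarray:
    """Sum of unit-amplitude raised-cosine (Hann) pulses centred on beats."""
    t = np.arange(n_samples) / sample_rate_hz
    x = np.zeros(n_samples)
    half = width_s / 2.0
    for bt in beat_times_s:
        lo = max(0, int(np.ceil((bt - half) * sample_rate_hz)))
        hi = min(n_samples, int(np.floor((bt + half) * sample_rate_hz)) + 1)
        if hi <= lo:
            continue
        tt = t[lo:hi] - bt
        x[lo:hi] += 0.5 * (1.0 + np.cos(np.pi * tt / half))
    return x


def simulate_cardiac_trace(
    params: CardiacSimParams,
    subject_id: str = "",
    recording_id: str = "",
) -> DualChamberTrace:
    """Generate a dual-chamber trace with a planted conduction regime.

    The atrium beats strictly periodically at ``atrial_rate_bpm``; each
    beat is a smooth raised-cosine intensity pulse (only beat timing, not
    pulse shape, is analysed downstream).  Conduction to the ventricle is
    deterministic for integer ratios (every k-th atrial beat) and Bernoulli
    with probability 1/ratio otherwise, so the long-run atrial:ventricular
    beat-count ratio equals ``conduction_ratio``.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate_hz
    n = int(round(params.duration_s * fs))
    period = 60.0 / params.atrial_rate_bpm
    atrial_beats = np.arange(period / 2.0, params.duration_s, period)

    conducted = np.zeros(len(atrial_beats), dtype=bool)

    def conduct(idx: np.ndarray, ratio: float) -> np.ndarray:
        if abs(ratio - round(ratio)) < 1e-9:
            k = int(round(ratio))
            out = np.zeros(len(idx), dtype=bool)
            out[::k] = True
            return out
        return rng.random(len(idx)) < (1.0 / ratio)

    if params.switch_time_s is None:
        conducted[:] = conduct(np.arange(len(atrial_beats)), params.conduction_ratio)
    else:
        pre = atrial_beats < params.switch_time_s
        conducted[pre] = conduct(np.flatnonzero(pre), params.conduction_ratio)
        conducted[~pre] = conduct(np.flatnonzero(~pre), params.switch_ratio)

    width = 0.4 * period
    atrium = _pulse_train(n, fs, atrial_beats, width)
    # ventricular contraction follows atrial activation after a short
    # AV delay; the delay only shifts phase and is irrelevant downstream
    av_delay = min(0.05, period / 4.0)
    ventricle = _pulse_train(n, fs, atrial_beats[conducted] + av_delay, width)
    if params.noise_sd > 0:
        atrium = atrium + rng.normal(0.0, params.noise_sd, n)
        ventricle = ventricle + rng.normal(0.0, params.noise_sd, n)
    return DualChamberTrace(
        time_s=np.arange(n) / fs,
        atrium=atrium,
        ventricle=ventricle,
        sample_rate_hz=fs,
        subject_id=subject_id,
        recording_id=recording_id,
    )


@dataclass
class LarvaRecordings:
    """Ground-truth-labelled recordings of one larva."""

    subject_id: str
    traces: list[DualChamberTrace]
    true_ratios: list[float]
    true_classes: list[str]

    @property
    def true_switched(self) -> bool:
        return len(set(self.true_classes)) > 1


def simulate_av_cohort(
    cohort_spec: Sequence[CardiacSimParams | Sequence[CardiacSimParams]],
    recordings_per_larva: int = 1,
    master_seed: int = 0,
) -> list[LarvaRecordings]:
    """Simulate a cohort of larvae with ground-truth conduction labels.

    Each element of ``cohort_spec`` describes one larva: either a single
    ``CardiacSimParams`` reused for every recording, or a sequence of one
    params object per recording (to plant larvae whose conduction regime
    differs between recordings).  Per-recording seeds are derived from
    ``master_seed`` and the (larva index, recording index) identity, so the
    ``seed`` field of the spec entries is ignored.
    """
    if recordings_per_larva not in (1, 2):
        raise ValueError("recordings_per_larva must be 1 or 2")
    if len(cohort_spec) == 0:
        raise ValueError("empty cohort spec")
    cohort = []
    for i, spec in enumerate(cohort_spec):
        if isinstance(spec, CardiacSimParams):
            per_rec = [spec] * recordings_per_larva
        else:
            per_rec = list(spec)
            if len(per_rec) != recordings_per_larva:
                raise ValueError(
                    f"larva {i}: expected {recordings_per_larva} params, got {len(per_rec)}"
                )
        subject_id = f"larva{i:03d}"
        traces, ratios, classes = [], [], []
        for r, p in enumerate(per_rec):
            seeded = CardiacSimParams(
                atrial_rate_bpm=p.atrial_rate_bpm,
                conduction_ratio=p.conduction_ratio,
                duration_s=p.duration_s,
                sample_rate_hz=p.sample_rate_hz,
                noise_sd=p.noise_sd,
                switch_time_s=p.switch_time_s,
                switch_ratio=p.switch_ratio,
                seed=derive_seed(master_seed, "cardiac", i, r),
            )
            traces.append(
                simulate_cardiac_trace(seeded, subject_id=subject_id, recording_id=f"R{r + 1}")
            )
            ratios.append(p.conduction_ratio)
            classes.append(true_av_class(p.conduction_ratio))
        cohort.append(
            LarvaRecordings(
                subject_id=subject_id,
                traces=traces,
                true_ratios=ratios,
                true_classes=classes,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# locomotor tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSimParams:
    """Parameters of a synthetic tracking experiment.

    Baseline locomotion is a Poisson bout process (``bout_rate_hz`` bouts/s
    while recording); each bout displaces the larva by a draw from the
    baseline distribution spread over ~0.3 s.  Seizure-like bursts occur at
    ``seizure_burst_rate_per_min`` (scalar, or a mapping from
    (genotype, treatment) to rate) and displace by a draw from the burst
    distribution — which must sit strictly above the baseline distribution,
    otherwise planted ground truth would be ill-defined — spread over one
    1-second window.  Displacement distributions are (location, scale) of a
    normal truncated at zero, in mm.
    """

    n_larvae_per_group: int = 10
    group_labels: Sequence[tuple[str, str]] = (("wt", "vehicle"),)
    phase_durations_s: tuple[float, float] = (900.0, 900.0)
    sample_rate_hz: float = 10.0
    arena_mm: float = 7.0
    bout_rate_hz: float = 0.2
    bout_displacement_mm: tuple[float, float] = (1.0, 0.3)
    seizure_burst_rate_per_min: float | Mapping[tuple[str, str], float] = 0.02
    seizure_displacement_mm: tuple[float, float] = (12.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_larvae_per_group < 1:
            raise ValueError("need at least one larva per group")
        if min(self.phase_durations_s) <= 0:
            raise ValueError("phase durations must be positive")
        if self.arena_mm <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("arena_mm and sample_rate_hz must be positive")
        if self.bout_rate_hz < 0:
            raise ValueError("bout_rate_hz must be non-negative")
        if self.seizure_displacement_mm[0] <= self.bout_displacement_mm[0]:
            raise ValueError(
                "seizure displacement distribution must sit strictly above "
                "the baseline bout distribution"
            )

    def burst_rate(self, genotype: str, treatment: str) -> float:
        if isinstance(self.seizure_burst_rate_per_min, Mapping):
            return float(self.seizure_burst_rate_per_min.get((genotype, treatment), 0.0))
        return float(self.seizure_burst_rate_per_min)


def _fold(x: np.ndarray, arena: float) -> np.ndarray:
    """Reflect coordinates into [0, arena] (triangle wave)."""
    period = 2.0 * arena
    m = np.mod(x, period)
    return np.where(m > arena, period - m, m)


def simulate_tracks(
    params: TrackSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-larva position tracks plus ground-truth burst bookkeeping.

    Returns
    -------
    tracks
        Long table: larva_id, time_s, x_mm, y_mm, genotype, treatment,
        phase.  Positions stay inside the square arena (reflecting walls).
    ground_truth
        One row per larva per phase: n_planted_bursts and the burst window
        indices (as a list), for recovery tests.
    """
    fs = params.sample_rate_hz
    frames_per_window = int(round(fs))
    track_rows: list[pd.DataFrame] = []
    truth_rows = []
    for genotype, treatment in params.group_labels:
        rate_per_min = params.burst_rate(genotype, treatment)
        for j in range(params.n_larvae_per_group):
            larva_id = f"{genotype}_{treatment}_{j:03d}"
            rng = np.random.default_rng(
                derive_seed(params.seed, "track", genotype, treatment, j)
            )
            t_offset = 0.0
            current = rng.uniform(0.3 * params.arena_mm, 0.7 * params.arena_mm, 2)
            for phase, dur in zip(("light", "dark"), params.phase_durations_s):
                n = int(round(dur * fs))
                n_windows = n // frames_per_window
                steps = np.zeros((n, 2))

                n_bouts = rng.poisson(params.bout_rate_hz * dur)
                bout_starts = rng.integers(0, max(1, n - 3), size=n_bouts)
                loc, scale = params.bout_displacement_mm
                for s in bout_starts:
                    disp = max(0.0, rng.normal(loc, scale))
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    step = (disp / 3.0) * np.array([np.cos(theta), np.sin(theta)])
                    steps[s:s + 3] += step

                n_bursts = rng.poisson(rate_per_min * dur / 60.0)
                n_bursts = min(n_bursts, n_windows)
                burst_windows = rng.choice(n_windows, size=n_bursts, replace=False)
                bloc, bscale = params.seizure_displacement_mm
                for w in burst_windows:
                    disp = max(0.0, rng.normal(bloc, bscale))
                    thetas = rng.uniform(0.0, 2.0 * np.pi, frames_per_window)
                    steps[w * frames_per_window:(w + 1) * frames_per_window] += (
                        disp / frames_per_window
                    ) * np.column_stack([np.cos(thetas), np.sin(thetas)])

                pos = _fold(current + np.cumsum(steps, axis=0), params.arena_mm)
                current = pos[-1]
                track_rows.append(
                    pd.DataFrame(
                        {
                            "larva_id": larva_id,
                            "time_s": t_offset + np.arange(n) / fs,
                            "x_mm": pos[:, 0],
                            "y_mm": pos[:, 1],
                            "genotype": genotype,
                            "treatment": treatment,
                            "phase": phase,
                        }
                    )
                )
                truth_rows.append(
                    {
                        "larva_id": larva_id,
                        "genotype": genotype,
                        "treatment": treatment,
                        "phase": phase,
                        "n_planted_bursts": int(n_bursts),
                        "burst_windows": sorted(int(w) for w in burst_windows),
                    }
                )
                t_offset += dur
    tracks = pd.concat(track_rows, ignore_index=True)
    return tracks, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# volumetric cohorts
# ---------------------------------------------------------------------------

def ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    center_vox: tuple[float, float, float],
    semi_axes_vox: tuple[float, float, float],
) -> np.ndarray:
    """Boolean ellipsoid on a voxel grid (inclusive boundary)."""
    idx = np.indices(grid_shape, dtype=float)
    q = sum(
        ((idx[d] - center_vox[d]) / semi_axes_vox[d]) ** 2 for d in range(3)
    )
    return q <= 1.0


def _default_masks(grid_shape: tuple[int, int, int]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    nx, ny, nz = grid_shape
    c = (nx / 2.0 - 0.5, ny / 2.0 - 0.5, nz / 2.0 - 0.5)
    brain = ellipsoid_mask(grid_shape, c, (0.42 * nx, 0.36 * ny, 0.38 * nz))
    regions = {
        # small midline region near the back of the brain (MHB-like)
        "MHB": ellipsoid_mask(
            grid_shape, (0.72 * nx, c[1], c[2]), (0.09 * nx, 0.10 * ny, 0.16 * nz)
        ),
        # small anterior region (subpallium-like)
        "subpallium": ellipsoid_mask(
            grid_shape, (0.28 * nx, c[1], c[2]), (0.09 * nx, 0.10 * ny, 0.16 * nz)
        ),
        # large central region standing in for cell-body-rich territory
        "cellular": ellipsoid_mask(
            grid_shape, c, (0.30 * nx, 0.26 * ny, 0.28 * nz)
        ),
    }
    regions = {k: (m & brain) for k, m in regions.items()}
    return brain, regions


@dataclass
class VolumeSimParams:
    """Parameters of a synthetic registered-volume cohort.

    ``planted_contraction`` maps group -> {region -> volumetric factor f}:
    inside that region the subject's LJD is the constant ln f (plus noise),
    so the region's subject-space volume integrates to f times its
    reference volume.  The pseudo-region name ``"brain"`` plants a
    whole-brain factor.  ``planted_intensity_scale`` maps group ->
    {(channel, region) -> factor} applied multiplicatively to the baseline
    channel intensity inside that region.  Noise fields are Gaussian white
    noise smoothed with ``field_smoothness_vox`` and rescaled to standard
    deviation ``noise_sd``.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_um: tuple[float, float, float] = (2.0, 2.0, 4.0)
    n_subjects_per_group: int = 10
    group_labels: Sequence[str] = ("wt", "mut")
    planted_contraction: Mapping[str, Mapping[str, float]] = dc_field(default_factory=dict)
    planted_intensity_scale: Mapping[str, Mapping[tuple[str, str], float]] = dc_field(
        default_factory=dict
    )
    channels: Sequence[str] = ("tuba", "gad1b")
    baseline_intensity: float = 100.0
    field_smoothness_vox: float = 1.5
    noise_sd: float = 0.0
    region_masks: Mapping[str, np.ndarray] | None = None
    brain_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.noise_sd < 0 or self.field_smoothness_vox <= 0:
            raise ValueError("invalid noise/smoothness parameters")
        for per_region in self.planted_contraction.values():
            for f in per_region.values():
                if f <= 0:
                    raise ValueError("planted scale factors must be positive")


@dataclass
class SubjectVolumes:
    subject_id: str
    group: str
    ljd: LJDMap
    channels: dict[str, ChannelMap]


@dataclass
class VolumeCohort:
    subjects: list[SubjectVolumes]
    brain_mask: np.ndarray
    region_masks: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]

    def group(self, label: str) -> list[SubjectVolumes]:
        return [s for s in self.subjects if s.group == label]


def _smooth_noise(rng: np.random.Generator, shape, smoothness: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    from scipy import ndimage

    raw = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness)
    return raw * (sd / raw.std())


def simulate_volumes(params: VolumeSimParams) -> VolumeCohort:
    """Generate a registered cohort of LJD maps and channel volumes.

    Each subject's LJD is a smooth zero-mean random field plus, inside each
    region with planted factor f for its group, the constant ln f — so at
    zero noise the region-integrated exp(LJD) equals f times the region's
    reference volume exactly.  Channel volumes are the baseline intensity
    inside the brain mask, scaled by any planted intensity factor within
    its region, plus smooth noise.
    """
    if params.brain_mask is not None:
        brain = np.asarray(params.brain_mask).astype(bool)
        regions = {
            k: np.asarray(v).astype(bool) for k, v in (params.region_masks or {}).items()
        }
    else:
        brain, regions = _default_masks(params.grid_shape)
        if params.region_masks is not None:
            regions.update(
                {k: np.asarray(v).astype(bool) for k, v in params.region_masks.items()}
            )
    for name, m in regions.items():
        if m.shape != brain.shape:
            raise ValueError(f"region {name!r} shape mismatch")
        if np.any(m & ~brain):
            raise ValueError(f"region {name!r} extends outside the brain mask")

    def region_of(name: str) -> np.ndarray:
        if name == "brain":
            return brain
        if name not in regions:
            raise ValueError(f"unknown region {name!r}")
        return regions[name]

    subjects = []
    for group in params.group_labels:
        contraction = params.planted_contraction.get(group, {})
        intensity = params.planted_intensity_scale.get(group, {})
        for j in range(params.n_subjects_per_group):
            sid = f"{group}_{j:03d}"
            rng = np.random.default_rng(derive_seed(params.seed, "volume", group, j))
            ljd = _smooth_noise(
                rng, params.grid_shape, params.field_smoothness_vox, params.noise_sd
            )
            for region_name, factor in contraction.items():
                ljd[region_of(region_name)] += np.log(factor)
            chans = {}
            for ch in params.channels:
                vals = np.where(brain, params.baseline_intensity, 0.0)
                for (chan, region_name), factor in intensity.items():
                    if chan == ch:
                        m = region_of(region_name)
                        vals = np.where(m, vals * factor, vals)
                vals = vals + _smooth_noise(
                    rng, params.grid_shape, params.field_smoothness_vox, params.noise_sd
                )
                chans[ch] = ChannelMap(
                    values=vals, channel=ch, voxel_size_um=params.voxel_size_um,
                    subject_id=sid, genotype=group,
                )
            subjects.append(
                SubjectVolumes(
                    subject_id=sid,
                    group=group,
                    ljd=LJDMap(
                        values=ljd, voxel_size_um=params.voxel_size_um,
                        subject_id=sid, genotype=group,
                    ),
                    channels=chans,
                )
            )
    return VolumeCohort(
        subjects=subjects,
        brain_mask=brain,
        region_masks=regions,
        voxel_size_um=params.voxel_size_um,
    )


# ---------------------------------------------------------------------------
# GCaMP series
# ---------------------------------------------------------------------------

@dataclass
class GcampSimParams:
    """Parameters of a synthetic slow fluorescence recording.

    Per-voxel series are ``baseline_level`` plus transient events with peak
    amplitude ``event_amplitude_frac * baseline_level`` and exponential
    decay, plus Gaussian noise (absolute intensity units).  ``event_rate``
    is the expected number of events per voxel per minute.  The default
    150 frames at 0.5 Hz mimic a 5-minute recording.
    """

    grid_shape: tuple[int, ...] = (16, 16)
    n_frames: int = 150
    frame_rate_hz: float = 0.5
    baseline_level: float = 100.0
    event_amplitude_frac: float = 0.5
    event_rate: float = 0.2  # events / voxel / min
    event_decay_s: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2 or self.frame_rate_hz <= 0:
            raise ValueError("need >= 2 frames and a positive frame rate")
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")
        if min(self.event_amplitude_frac, self.event_rate, self.noise_sd) < 0:
            raise ValueError("amplitudes, rates and noise must be non-negative")


def simulate_gcamp(
    params: GcampSimParams, subject_id: str = "", genotype: str = ""
) -> tuple[VoxelTimeSeries, np.ndarray]:
    """Generate a voxel fluorescence series with planted calcium transients.

    Events rise instantaneously to their full amplitude on their onset
    frame and decay exponentially, so at zero noise a voxel's planted
    peak amplitude is exactly recovered by min-baseline dF/F.

    Returns the series together with the planted per-voxel event count
    (ground truth for recovery tests).
    """
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.grid_shape)
    nt = params.n_frames
    duration_min = nt / params.frame_rate_hz / 60.0
    data = np.full(shape + (nt,), float(params.baseline_level))
    amp = params.event_amplitude_frac * params.baseline_level
    frames = np.arange(nt)
    decay_frames = params.event_decay_s * params.frame_rate_hz
    n_vox = int(np.prod(shape))
    flat = data.reshape(n_vox, nt)
    n_events = rng.poisson(params.event_rate * duration_min, size=n_vox)
    for v in np.flatnonzero(n_events):
        onsets = rng.integers(0, nt, size=n_events[v])
        for t0 in onsets:
            flat[v, t0:] += amp * np.exp(-(frames[t0:] - t0) / decay_frames)
    if params.noise_sd > 0:
        flat += rng.normal(0.0, params.noise_sd, flat.shape)
        np.clip(flat, 0.0, None, out=flat)
    series = VoxelTimeSeries(
        data=flat.reshape(shape + (nt,)),
        frame_rate_hz=params.frame_rate_hz,
        subject_id=subject_id,
        genotype=genotype,
    )
    return series, n_events.reshape(shape)


# ---------------------------------------------------------------------------
# on-disk interchange
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: Sequence[LarvaRecordings], out_dir: str | Path) -> None:
    """Write each recording as CSV plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for larva in cohort:
        for trace, ratio, cls in zip(larva.traces, larva.true_ratios, larva.true_classes):
            name = f"{larva.subject_id}_{trace.recording_id}.csv"
            trace.to_frame().to_csv(out / name, index=False)
            meta.append(
                {
                    "file": name,
                    "subject_id": larva.subject_id,
                    "recording_id": trace.recording_id,
                    "true_ratio": ratio,
                    "true_class": cls,
                }
            )
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=1))
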