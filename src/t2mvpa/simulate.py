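"""Synthetic cohorts with known ground truth.

Real acquisitions of this kind are not publicly deposited, so validation
rests on simulated cohorts that possess the statistical structure the
analysis assumes: a common voxel grid; a brain with left/right striatal
ROIs; per-subject 4D series built from a static anatomical baseline, a
subject-specific spatial "anatomy" component, a weak global in-ROI shift
proportional to the subject's learning score, a zero-mean multi-voxel
pattern also proportional to the score, and fresh Gaussian noise at every
timepoint.  Tissue partial-volume maps vary smoothly around a common
template so that consensus thresholding produces all four label outcomes.

Generative model for subject ``s`` at timepoint ``t`` (inside the brain)::

    v(s, t) = baseline
              + global_gain * y_s * 1_ROI
              + signal_gain * y_s * W          # zero-sum pattern, RMS 1
              + eta_s                           # spatial, fixed over t
              + eps_{s,t}                       # temporal, fresh each t

``W`` is nonzero only in the configured signal subregion and sums to zero
there, so the pattern carries no spatial-mean information: the spatial-mean
analysis sees only the ``global_gain`` component while the pattern analysis
sees both.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .preprocess import (EpiSeries, ROIMask, TissuePartialVolumes,
                         split_roi_coronal)

__all__ = ["RoiBox", "CohortConfig", "GroundTruth", "Cohort",
           "generate_cohort", "generate_tissue_maps", "DEFAULT_BLOCK_SCHEDULE",
           "COMPACT_BLOCK_SCHEDULE", "compact_config"]


class ConfigError(ValueError):
    """A cohort configuration violates an invariant."""


# Paper-style acquisition at TR = 2 s: seven 46-second passive-watching
# blocks interleaved with six 4-minute active blocks (odd-ball, Space
# Fortress, Space Fortress + odd-ball).  23 + 120 volumes respectively.
DEFAULT_BLOCK_SCHEDULE: tuple[tuple[str, int], ...] = (
    ("PW", 23), ("OB", 120), ("PW", 23), ("SF", 120), ("PW", 23),
    ("SO", 120), ("PW", 23), ("SO", 120), ("PW", 23), ("SF", 120),
    ("PW", 23), ("OB", 120), ("PW", 23),
)

GAME_PLAY_BLOCKS = ("SF", "SO")

# Scaled-down schedule for multi-seed simulation suites: same 13-block
# structure, 3 volumes per passive and 16 per active block.
COMPACT_BLOCK_SCHEDULE: tuple[tuple[str, int], ...] = tuple(
    (tag, 3 if tag == "PW" else 16)
    for tag, _ in DEFAULT_BLOCK_SCHEDULE)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned subregion of the grid, half-open voxel ranges."""

    name: str
    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    def mask(self, grid_shape) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m[self.x[0]:self.x[1], self.y[0]:self.y[1], self.z[0]:self.z[1]] = True
        return m


def _default_rois() -> tuple[RoiBox, ...]:
    # x runs left -> right: the left dorsal striatum sits at low x.
    return (
        RoiBox("dorsal_striatum_left", (3, 7), (4, 12), (4, 8)),
        RoiBox("dorsal_striatum_right", (9, 13), (4, 12), (4, 8)),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Intensities are in arbitrary scanner units (brain baseline 100);
    scores in game points.  ``signal_gain`` and ``global_gain`` are in
    intensity units per score point.  Defaults emulate the acquisition
    and cohort of the motivating study: 34 subjects, a 16 x 16 x 12 grid
    at EPI resolution (3.4375 x 3.4375 x 4 mm), the 13-block schedule with
    two SF and two SO game-play blocks (480 volumes), and effect sizes
    calibrated so the pattern analysis attains prediction accuracy in the
    reported range (r around 0.8) while the spatial-mean analysis attains
    roughly r around 0.5.
    """

    n_subjects: int = 34
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size: tuple[float, float, float] = (3.4375, 3.4375, 4.0)
    block_schedule: tuple[tuple[str, int], ...] = DEFAULT_BLOCK_SCHEDULE
    roi_boxes: tuple[RoiBox, ...] = field(default_factory=_default_rois)
    signal_roi: str = "dorsal_striatum_left"
    signal_portion: Literal["all", "anterior", "posterior"] = "all"
    baseline: float = 100.0
    signal_gain: float = 2.5e-4
    global_gain: float = 6.0e-5
    noise_sd_temporal: float = 5.0
    noise_sd_spatial: float = 1.0
    score_mean: float = 1500.0
    score_sd: float = 1000.0
    initial_score_mean: float = 1000.0
    initial_score_sd: float = 800.0
    tissue_jitter: float = 1.0
    seed: int = 0

    @property
    def n_timepoints(self) -> int:
        return sum(n for _, n in self.block_schedule)

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ConfigError(
                f"invariant 'n_subjects >= 4' violated (got {self.n_subjects})")
        if len(self.grid_shape) != 3 or any(g < 4 for g in self.grid_shape):
            raise ConfigError(
                f"invariant 'grid dimensions >= 4' violated (got {self.grid_shape})")
        if not self.block_schedule:
            raise ConfigError("invariant 'nonempty block schedule' violated")
        if any(n <= 0 for _, n in self.block_schedule):
            raise ConfigError(
                "invariant 'positive per-block timepoint counts' violated")
        for name, sd in (("noise_sd_temporal", self.noise_sd_temporal),
                         ("noise_sd_spatial", self.noise_sd_spatial),
                         ("score_sd", self.score_sd),
                         ("initial_score_sd", self.initial_score_sd)):
            if sd < 0:
                raise ConfigError(f"invariant '{name} >= 0' violated (got {sd})")
        names = [b.name for b in self.roi_boxes]
        if len(set(names)) != len(names):
            raise ConfigError("invariant 'unique ROI names' violated")
        if self.signal_roi not in names:
            raise ConfigError(
                f"invariant 'signal_roi among roi_boxes' violated "
                f"(got {self.signal_roi!r}, have {names})")
        for box in self.roi_boxes:
            for ax, (lo, hi) in enumerate((box.x, box.y, box.z)):
                if not (0 <= lo < hi <= self.grid_shape[ax]):
                    raise ConfigError(
                        f"invariant 'ROI box inside grid' violated for "
                        f"{box.name!r} on axis {ax}")

    def block_labels(self) -> np.ndarray:
        return np.concatenate(
            [np.full(n, tag) for tag, n in self.block_schedule])


@dataclass
class GroundTruth:
    """Generative quantities to recover: weight map, scores, covariates."""

    true_weight_map: np.ndarray
    true_scores: np.ndarray
    covariates: pd.DataFrame
    signal_mask: np.ndarray


@dataclass
class Cohort:
    """A generated cohort: series, masks, tissue maps, scores, truth."""

    config: CohortConfig
    subjects: list[EpiSeries]
    masks: dict[str, ROIMask]
    tissue: list[TissuePartialVolumes]
    scores: pd.DataFrame
    truth: GroundTruth


def compact_config(**overrides) -> CohortConfig:
    """Scaled-down study conditions for multi-seed simulation suites.

    Same grid, cohort size and effect sizes as the default config, but a
    shorter block schedule (64 instead of 480 averaged game-play volumes)
    with the temporal noise SD reduced from 5 to 2 so the noise level of
    the time-averaged volumes matches the full-length schedule
    (5/sqrt(480) = 0.23 vs 2/sqrt(64) = 0.25 intensity units).  The
    operating characteristics of the analysis are therefore preserved at
    a fraction of the simulation cost.
    """
    base = dict(block_schedule=COMPACT_BLOCK_SCHEDULE, noise_sd_temporal=2.0)
    base.update(overrides)
    return CohortConfig(**base)


def _brain_mask(grid_shape) -> np.ndarray:
    """Inscribed ellipsoid standing in for the brain."""
    nx, ny, nz = grid_shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    x, y, z = np.ogrid[:nx, :ny, :nz]
    r2 = (((x - cx) / (nx / 2)) ** 2 + ((y - cy) / (ny / 2)) ** 2
          + ((z - cz) / (nz / 2)) ** 2)
    return r2 <= 1.0


def _normalized_radius(grid_shape) -> np.ndarray:
    nx, ny, nz = grid_shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    x, y, z = np.ogrid[:nx, :ny, :nz]
    return np.sqrt(((x - cx) / (nx / 2)) ** 2 + ((y - cy) / (ny / 2)) ** 2
                   + ((z - cz) / (nz / 2)) ** 2)


def generate_tissue_maps(config: CohortConfig, seed: int
                         ) -> list[TissuePartialVolumes]:
    """Per-subject WM/GM/CSF partial-volume maps around a common template.

    The template places white matter in the deep core, gray matter in a
    shell near the cortical surface, CSF in a small central "ventricle"
    compartment, and an ambiguous WM/GM transition band where no consensus
    fraction exceeds 50 %.  Subject maps add a smooth random field to the
    class logits before the softmax, so fractions stay in [0, 1] and sum
    to at most 1 by construction.
    """
    config.validate()
    shape = config.grid_shape
    r = _normalized_radius(shape)
    brain = _brain_mask(shape)
    # class logits: background, WM, GM, CSF
    l_bg = np.where(brain, -6.0, 8.0)
    l_wm = 3.0 - 14.0 * np.maximum(r - 0.45, 0.0)
    l_gm = 3.0 - 14.0 * np.abs(r - 0.82)
    l_csf = np.full(shape, -5.0)
    nx, ny, nz = shape
    vx = slice(nx // 2 - 1, nx // 2 + 1)
    vy = slice(ny // 2 - 1, ny // 2 + 2)
    vz = slice(nz // 2, nz // 2 + 2)
    l_csf[vx, vy, vz] = 6.0
    template = np.stack([l_bg, l_wm, l_gm, l_csf])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    maps = []
    for _ in range(config.n_subjects):
        jitter = np.stack([
            gaussian_filter(rng.standard_normal(shape), sigma=1.5) * 4.0
            for _ in range(4)]) * config.tissue_jitter
        logits = template + jitter
        ex = np.exp(logits - logits.max(axis=0))
        frac = ex / ex.sum(axis=0)
        maps.append(TissuePartialVolumes(wm=frac[1], gm=frac[2], csf=frac[3]))
    return maps


def _signal_mask(config: CohortConfig, masks: dict[str, ROIMask]) -> np.ndarray:
    roi = masks[config.signal_roi]
    if config.signal_portion == "all":
        return roi.data
    ant, post = split_roi_coronal(roi)
    return ant.data if config.signal_portion == "anterior" else post.data


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort, deterministic given the seed."""
    config.validate()
    shape = config.grid_shape
    brain = _brain_mask(shape)
    masks = {"brain": ROIMask(brain, "brain")}
    for box in config.roi_boxes:
        m = box.mask(shape) & brain
        if not m.any():
            raise ConfigError(
                f"invariant 'ROI overlaps brain' violated for {box.name!r}")
        masks[box.name] = ROIMask(m, box.name)
    roi_union = np.zeros(shape, dtype=bool)
    for box in config.roi_boxes:
        roi_union |= masks[box.name].data

    ss = np.random.SeedSequence(config.seed)
    s_scores, s_weights, s_tissue, s_cov, s_noise = ss.spawn(5)
    rng_scores = np.random.default_rng(s_scores)
    rng_weights = np.random.default_rng(s_weights)
    rng_cov = np.random.default_rng(s_cov)

    sig_mask = _signal_mask(config, masks)
    k = int(sig_mask.sum())
    w = rng_weights.standard_normal(k)
    w -= w.mean()
    rms = np.sqrt((w ** 2).mean())
    if rms > 0:
        w /= rms
    weight_map = np.zeros(shape)
    weight_map[sig_mask] = w

    n = config.n_subjects
    y = config.score_mean + config.score_sd * rng_scores.standard_normal(n)
    s1 = (config.initial_score_mean
          + config.initial_score_sd * rng_scores.standard_normal(n))
    s2 = s1 + y
    voxel_vol = float(np.prod(config.voxel_size))
    roi_volume = (masks[config.signal_roi].n_voxels * voxel_vol
                  * (1.0 + 0.1 * rng_cov.standard_normal(n)))

    props = np.array([0.3, 0.2, 0.3, 0.2])  # control, velocity, speed, points
    sub_names = ["control", "velocity", "speed", "points"]
    rows = {}
    for sess, totals in (("s1", s1), ("s2", s2)):
        e = rng_cov.normal(0.0, 50.0, size=(n, 4))
        e -= e.mean(axis=1, keepdims=True)
        subs = totals[:, None] * props[None, :] + e
        for j, nm in enumerate(sub_names):
            rows[f"{nm}_{sess}"] = subs[:, j]

    subject_ids = [f"s{i + 1:02d}" for i in range(n)]
    labels = config.block_labels()
    t_total = labels.shape[0]
    subjects = []
    base = np.where(brain, config.baseline, 0.0)
    child_seeds = s_noise.spawn(n)
    for i in range(n):
        rng_i = np.random.default_rng(child_seeds[i])
        static = base.copy()
        static += config.global_gain * y[i] * roi_union
        static += config.signal_gain * y[i] * weight_map
        if config.noise_sd_spatial > 0:
            static += np.where(
                brain, config.noise_sd_spatial * rng_i.standard_normal(shape), 0.0)
        series = np.repeat(static[..., None].astype(np.float32), t_total, axis=3)
        if config.noise_sd_temporal > 0:
            noise = rng_i.standard_normal(
                size=shape + (t_total,), dtype=np.float32)
            noise *= np.float32(config.noise_sd_temporal)
            noise *= brain[..., None]
            series += noise
        subjects.append(EpiSeries(subject_ids[i], series,
                                  config.voxel_size, labels))

    scores = pd.DataFrame({
        "subject_id": subject_ids,
        "score_s1": s1,
        "score_s2": s2,
        **rows,
        "score_improvement": s2 - s1,
        "roi_volume": roi_volume,
        "initial_score": s1,
    })
    truth = GroundTruth(
        true_weight_map=weight_map,
        true_scores=y,
        covariates=scores[["subject_id", "roi_volume", "initial_score"]].copy(),
        signal_mask=sig_mask,
    )
    tissue = generate_tissue_maps(config, seed=int(s_tissue.generate_state(1)[0] % (2 ** 31)))
    return Cohort(config, subjects, masks, tissue, scores, truth)
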