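"""From raw 4D series to ROI feature vectors.

The analysis consumes one volume per subject: every EPI volume is divided
by its within-brain mean (compensating scanner drift and between-run gain
differences), the normalized volumes from the selected task blocks are
averaged over time, and the in-ROI intensities of that average become the
subject's feature vector.  The module also holds the consensus tissue
segmentation (>50 % averaged partial volume) and the coronal
anterior/posterior ROI split.

Coordinate convention (documented, not inferred): 0-based voxel indices,
axis order (x, y, z), +y anterior, +x left-to-right.  Features are ordered
by C-order scan of the ROI voxels (x fastest-varying last).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "EpiSeries", "BrainVolume", "ROIMask", "TissuePartialVolumes",
    "TissueLabels", "TissueClass", "FeatureMatrix", "TemporalAverage",
    "normalize_volume", "temporal_average", "extract_features",
    "consensus_segmentation", "split_roi_coronal", "subsample_volume",
]


class GridMismatchError(ValueError):
    """Volumes/masks that should share a grid do not."""


@dataclass
class EpiSeries:
    """A subject's 4D T2*-weighted series on the common grid.

    ``data`` has axes (x, y, z, t); ``block_labels`` tags each timepoint
    with its acquisition block (e.g. PW/OB/SF/SO).
    """

    subject_id: str
    data: np.ndarray
    voxel_size: tuple[float, float, float]
    block_labels: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.block_labels = np.asarray(self.block_labels)
        if self.data.ndim != 4:
            raise ValueError(f"series data must be 4D, got {self.data.ndim}D")
        if self.block_labels.shape[0] != self.data.shape[3]:
            raise ValueError(
                f"{len(self.block_labels)} block labels for "
                f"{self.data.shape[3]} timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite intensities in series {self.subject_id}")


@dataclass
class BrainVolume:
    """A single 3D intensity volume on the common grid."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    space_tag: str = "common"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite intensities in volume")


@dataclass
class ROIMask:
    """Boolean region-of-interest mask on the common grid."""

    data: np.ndarray
    name: str = "roi"

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.data.ndim}D")
        if not self.data.any():
            raise ValueError(f"mask {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class TissuePartialVolumes:
    """Per-voxel white-matter / gray-matter / CSF fractions."""

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray

    def __post_init__(self):
        self.wm = np.asarray(self.wm, dtype=float)
        self.gm = np.asarray(self.gm, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        if not (self.wm.shape == self.gm.shape == self.csf.shape):
            raise GridMismatchError("tissue fraction grids differ in shape")
        for name, frac in (("wm", self.wm), ("gm", self.gm), ("csf", self.csf)):
            if frac.min() < -1e-9 or frac.max() > 1 + 1e-9:
                raise ValueError(f"{name} fractions outside [0, 1]")
        if (self.wm + self.gm + self.csf).max() > 1 + 1e-6:
            raise ValueError("tissue fractions sum to more than 1")


class TissueClass(IntEnum):
    UNASSIGNED = 0
    WM = 1
    GM = 2
    CSF = 3


@dataclass
class TissueLabels:
    """Consensus tissue labels; UNASSIGNED voxels are excluded from analysis."""

    data: np.ndarray

    def mask(self, tissue: TissueClass) -> np.ndarray:
        return self.data == int(tissue)


@dataclass
class FeatureMatrix:
    """Subjects x voxels matrix of in-ROI intensities (the SVR inputs x_i)."""

    values: np.ndarray
    voxel_index: np.ndarray      # (k, 3) int grid coordinates per column
    roi_name: str
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.values.shape[1] != self.voxel_index.shape[0]:
            raise ValueError("column count does not match voxel index")


class TemporalAverage(NamedTuple):
    volume: BrainVolume
    n_volumes: int


def normalize_volume(volume: BrainVolume, brain_mask: ROIMask) -> BrainVolume:
    """Divide a volume by its mean intensity inside the brain mask.

    The in-mask mean of the output is exactly 1 (up to float rounding),
    which makes the operation idempotent.
    """
    if volume.data.shape != brain_mask.data.shape:
        raise GridMismatchError("volume and brain mask grids differ")
    mean = volume.data[brain_mask.data].mean()
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(
            f"cannot normalize: in-mask mean is {mean!r} (must be positive)")
    return BrainVolume(volume.data / mean, volume.voxel_size, volume.space_tag)


def temporal_average(series: EpiSeries, include_blocks: Iterable[str],
                     brain_mask: ROIMask) -> TemporalAverage:
    """Normalize each selected volume, then average them over time.

    Only timepoints whose block label is in ``include_blocks`` contribute.
    Each contributing volume is divided by its own in-brain mean first
    (per-volume drift compensation), so the order of included timepoints
    is irrelevant.  Returns the average and the number of volumes used.
    """
    include = set(include_blocks)
    sel = np.isin(series.block_labels, list(include))
    n_used = int(sel.sum())
    if n_used == 0:
        raise ValueError(
            f"no timepoints with blocks {sorted(include)} in series "
            f"{series.subject_id}")
    if series.data.shape[:3] != brain_mask.data.shape:
        raise GridMismatchError(f"series {series.subject_id} grid differs from mask")
    data = np.asarray(series.data[..., sel], dtype=float)
    means = data[brain_mask.data, :].mean(axis=0)
    if np.any(~np.isfinite(means)) or np.any(means <= 0):
        raise ValueError(
            f"non-positive in-brain mean in series {series.subject_id}")
    avg = (data / means).mean(axis=3)
    return TemporalAverage(
        BrainVolume(avg, series.voxel_size, "common"), n_used)


def extract_features(volumes: Sequence[BrainVolume], roi: ROIMask,
                     subject_ids: Sequence[str] | None = None) -> FeatureMatrix:
    """Stack in-ROI intensities of per-subject volumes into subjects x voxels.

    Voxel (column) order is the C-order scan of the ROI; no scaling is
    applied beyond upstream normalization.
    """
    coords = np.argwhere(roi.data)
    rows = []
    ids = list(subject_ids) if subject_ids is not None else [
        f"s{i:02d}" for i in range(len(volumes))]
    for sid, vol in zip(ids, volumes):
        if vol.data.shape != roi.data.shape:
            raise GridMismatchError(
                f"subject {sid}: volume grid {vol.data.shape} does not match "
                f"ROI grid {roi.data.shape}")
        rows.append(vol.data[roi.data])
    return FeatureMatrix(np.vstack(rows), coords, roi.name, ids)


def consensus_segmentation(
        tissue_maps: Sequence[TissuePartialVolumes]) -> TissueLabels:
    """Average partial volumes over subjects; label by the >50 % rule.

    A voxel is accepted as WM, GM or CSF only if that tissue's averaged
    fraction strictly exceeds 0.5; otherwise it is UNASSIGNED and flagged
    for exclusion.  At most one tissue can exceed 0.5 since fractions sum
    to at most 1.
    """
    if len(tissue_maps) == 0:
        raise ValueError("need at least one subject's tissue maps")
    shape = tissue_maps[0].wm.shape
    for tm in tissue_maps:
        if tm.wm.shape != shape:
            raise GridMismatchError("tissue map grids differ between subjects")
    mean_wm = np.mean([tm.wm for tm in tissue_maps], axis=0)
    mean_gm = np.mean([tm.gm for tm in tissue_maps], axis=0)
    mean_csf = np.mean([tm.csf for tm in tissue_maps], axis=0)
    labels = np.full(shape, int(TissueClass.UNASSIGNED), dtype=np.int8)
    labels[mean_wm > 0.5] = int(TissueClass.WM)
    labels[mean_gm > 0.5] = int(TissueClass.GM)
    labels[mean_csf > 0.5] = int(TissueClass.CSF)
    return TissueLabels(labels)


def split_roi_coronal(roi: ROIMask) -> tuple[ROIMask, ROIMask]:
    """Split an ROI with a coronal plane into near-equal halves.

    +y is anterior.  Among all coronal planes the one minimizing
    ``|n_anterior - n_posterior|`` is chosen; ties go to the smaller
    anterior count.  Raises for an ROI confined to a single coronal slice.
    """
    counts = roi.data.sum(axis=(0, 2))
    occupied = np.flatnonzero(counts)
    if occupied.size < 2:
        raise ValueError(
            f"ROI {roi.name!r} spans a single coronal slice; cannot split")
    total = counts.sum()
    best_plane, best_diff, best_ant = None, None, None
    # plane p: anterior = slices with y >= p
    for p in range(occupied[0] + 1, occupied[-1] + 1):
        n_ant = counts[p:].sum()
        n_post = total - n_ant
        if n_ant == 0 or n_post == 0:
            continue
        diff = abs(int(n_ant) - int(n_post))
        if (best_diff is None or diff < best_diff
                or (diff == best_diff and n_ant < best_ant)):
            best_plane, best_diff, best_ant = p, diff, n_ant
    ant = roi.data.copy()
    ant[:, :best_plane, :] = False
    post = roi.data & ~ant
    return (ROIMask(ant, f"{roi.name}_anterior"),
            ROIMask(post, f"{roi.name}_posterior"))


def subsample_volume(hi_res: BrainVolume, target_shape: Sequence[int],
                     target_voxel_size: Sequence[float]) -> BrainVolume:
    """Block-average a volume onto a coarser grid.

    The integer downsampling factor per axis comes from the voxel-size
    ratio; a trailing partial block is averaged over the voxels it
    actually contains, so a constant volume stays constant and nesting
    grids preserve the mean.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if any(s <= 0 for s in target_shape):
        raise ValueError(f"non-positive target dimensions {target_shape}")
    factors = []
    for ax in range(3):
        f = target_voxel_size[ax] / hi_res.voxel_size[ax]
        fi = int(round(f))
        if fi < 1 or abs(f - fi) > 1e-6:
            raise ValueError(
                f"target voxel size must be an integer multiple of the source "
                f"along axis {ax} (ratio {f})")
        if int(np.ceil(hi_res.data.shape[ax] / fi)) != target_shape[ax]:
            raise ValueError(
                f"target shape {target_shape[ax]} inconsistent with factor "
                f"{fi} on axis {ax} (source {hi_res.data.shape[ax]})")
        factors.append(fi)
    out = hi_res.data
    for ax, f in enumerate(factors):
        if f == 1:
            continue
        edges = np.arange(0, out.shape[ax], f)
        sums = np.add.reduceat(out, edges, axis=ax)
        counts = np.diff(np.append(edges, out.shape[ax]))
        shape = [1, 1, 1]
        shape[ax] = len(counts)
        out = sums / counts.reshape(shape)
    return BrainVolume(out, tuple(float(v) for v in target_voxel_size),
                       hi_res.space_tag)
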