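"""Streamline selection, visitation maps and prediction aggregation.

The indirect-disconnection method: impose a binary lesion mask (in common
space) on the tractogram of each normative subject, keep the streamlines
touched by the lesion, voxelize each selection into a visitation map
(distinct damaged streamlines per voxel), and aggregate the per-subject
maps into a voxel-wise mean (the prediction), standard deviation (its
uncertainty) and standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import Tractogram, VolumeGrid, world_to_voxel

__all__ = [
    "SelectionMode",
    "PredictionResult",
    "dilate_mask",
    "select_damaged",
    "visitation_map",
    "aggregate_prediction",
    "resample_streamline",
]


@dataclass(frozen=True)
class SelectionMode:
    """How streamlines count as damaged.

    ``control`` selects a streamline iff at least one of its stored
    coordinates voxelizes into a lesion voxel. ``patient`` additionally
    selects streamlines whose first or last point falls inside the lesion
    dilated by ``dilation_radius_mm`` — streamlines derived from a
    patient's own diffusion data may terminate just short of the lesion
    edge through partial-volume effects.
    """

    mode: str = "control"
    dilation_radius_mm: float = 2.0

    def __post_init__(self):
        if self.mode not in ("control", "patient"):
            raise ValueError(f"mode must be 'control' or 'patient', got {self.mode!r}")
        if self.mode == "patient" and not self.dilation_radius_mm > 0:
            raise ValueError("patient mode requires dilation_radius_mm > 0")


@dataclass
class PredictionResult:
    """Voxel-wise prediction of streamline damage with its uncertainty.

    mean is the prediction (expected damaged-streamline count per voxel),
    sd the across-subject sample standard deviation, se = sd / sqrt(N).
    """

    mean: VolumeGrid
    sd: VolumeGrid
    se: VolumeGrid
    n_subjects: int

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("a prediction requires at least 2 subjects")
        if not (self.mean.same_grid(self.sd) and self.mean.same_grid(self.se)):
            raise ValueError("mean/sd/se must share one grid")

    def total_deviation(self, scale: str = "sd_plus_se") -> np.ndarray:
        """Predicted per-voxel deviation s_v.

        ``sd_plus_se`` returns sqrt(sd^2 + se^2) — the standard deviation of
        (new observation - estimated mean) under independence; ``sd``
        returns the raw across-subject SD.
        """
        if scale == "sd_plus_se":
            return np.sqrt(self.sd.data**2 + self.se.data**2)
        if scale == "sd":
            return self.sd.data.astype(float)
        raise ValueError(f"unknown deviation scale {scale!r}")


def dilate_mask(mask: VolumeGrid, radius_mm: float) -> VolumeGrid:
    """Dilate a binary mask by a Euclidean radius in world mm.

    The output contains exactly the voxels whose center lies within
    ``radius_mm`` of any input voxel center, with distances measured using
    the per-axis voxel spacings from the affine (anisotropic voxels are
    handled; oblique shear is not modelled). Radius 0 is the identity.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be nonnegative")
    data = mask.data.astype(bool)
    if not data.any():
        raise ValueError("cannot dilate an empty mask")
    if radius_mm == 0:
        return VolumeGrid(data.copy(), mask.affine.copy())
    dist = ndimage.distance_transform_edt(~data, sampling=mask.voxel_sizes)
    return VolumeGrid(dist <= radius_mm + 1e-9, mask.affine.copy())


def resample_streamline(points: np.ndarray, max_step_mm: float) -> np.ndarray:
    """Insert points along segments so no step exceeds ``max_step_mm``.

    Optional preprocessing for coarse external tractograms whose inter-point
    step could skip voxels; densely-stepped tractograms do not need it.
    """
    pts = np.asarray(points, dtype=float)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if not np.any(seglen > max_step_mm):
        return pts
    out = [pts[0]]
    for i, L in enumerate(seglen):
        n_sub = max(1, int(np.ceil(L / max_step_mm)))
        for k in range(1, n_sub + 1):
            out.append(pts[i] + (pts[i + 1] - pts[i]) * (k / n_sub))
    return np.asarray(out)


def _streamline_voxels(tractogram: Tractogram, grid: VolumeGrid):
    """Voxel indices of every stored point, flattened, with per-streamline
    offsets. Out-of-grid points keep index -1 (silently ignored downstream)."""
    counts = np.array([len(s) for s in tractogram.streamlines])
    if counts.size == 0:
        return np.empty(0, dtype=np.int64), np.array([0])
    allpts = np.concatenate(tractogram.streamlines, axis=0)
    idx = world_to_voxel(allpts, grid)
    shape = np.asarray(grid.shape)
    inb = np.all((idx >= 0) & (idx < shape), axis=1)
    flat = np.full(len(idx), -1, dtype=np.int64)
    flat[inb] = np.ravel_multi_index(tuple(idx[inb].T), grid.shape)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return flat, offsets


def select_damaged(
    tractogram: Tractogram, lesion: VolumeGrid, mode: SelectionMode | None = None
) -> Tractogram:
    """Select the streamlines damaged by a lesion (ids preserved).

    Control mode: a streamline is damaged iff >= 1 of its coordinates
    voxelizes into a lesion voxel. Patient mode: additionally damaged if
    its first or last stored point voxelizes into the lesion dilated by
    the mode's radius (the perilesional shell including the lesion itself).
    """
    mode = mode or SelectionMode()
    lesion_data = lesion.data.astype(bool)
    if not lesion_data.any():
        raise ValueError("lesion mask is empty")
    flat, offsets = _streamline_voxels(tractogram, lesion)
    lesion_flat = lesion_data.ravel()
    hit = np.zeros(len(flat), dtype=bool)
    ok = flat >= 0
    hit[ok] = lesion_flat[flat[ok]]
    selected = np.add.reduceat(hit, offsets[:-1]) > 0 if len(flat) else np.zeros(0, bool)

    if mode.mode == "patient":
        dil_flat = dilate_mask(lesion, mode.dilation_radius_mm).data.ravel()
        ends = np.stack([offsets[:-1], offsets[1:] - 1], axis=1).ravel()
        end_idx = flat[ends]
        end_hit = np.zeros(len(ends), dtype=bool)
        ok = end_idx >= 0
        end_hit[ok] = dil_flat[end_idx[ok]]
        selected |= end_hit.reshape(-1, 2).any(axis=1)

    return tractogram.subset(np.flatnonzero(selected))


def visitation_map(tractogram: Tractogram, grid: VolumeGrid) -> VolumeGrid:
    """Count distinct streamlines visiting each voxel.

    A streamline contributes at most 1 to a voxel no matter how many of its
    points fall there. An empty tractogram yields an all-zero map.
    """
    counts = np.zeros(int(np.prod(grid.shape)), dtype=np.int32)
    flat, offsets = _streamline_voxels(tractogram, grid)
    for i in range(len(offsets) - 1):
        vox = flat[offsets[i]:offsets[i + 1]]
        vox = np.unique(vox[vox >= 0])
        counts[vox] += 1
    return VolumeGrid(counts.reshape(grid.shape), grid.affine.copy())


def aggregate_prediction(per_subject_maps: list[VolumeGrid]) -> PredictionResult:
    """Voxel-wise mean / sample SD / SE across subjects' visitation maps."""
    if len(per_subject_maps) < 2:
        raise ValueError("need at least 2 per-subject maps")
    ref = per_subject_maps[0]
    for m in per_subject_maps[1:]:
        if not ref.same_grid(m):
            raise ValueError("per-subject maps must share one grid")
    stack = np.stack([m.data.astype(np.float64) for m in per_subject_maps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    return PredictionResult(
        mean=ref.like(mean), sd=ref.like(sd), se=ref.like(sd / np.sqrt(n)),
        n_subjects=n,
    )
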