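"""Volume and tractogram containers plus NIfTI / TCK / TRK input-output.

All streamline coordinates are kept in world millimetres (RAS+) throughout
the package; voxel indices are produced only at voxelization time, using the
voxel-center convention (integer index i sits at the world position given by
``affine @ [i, 1]``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram as _NibTractogram

__all__ = [
    "VolumeGrid",
    "Tractogram",
    "read_volume",
    "write_volume",
    "read_tractogram",
    "write_tractogram",
    "world_to_voxel",
    "voxel_to_world",
    "as_binary_mask",
]


@dataclass
class VolumeGrid:
    """A 3D scalar array with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    affine : ndarray, shape (4, 4)
        Maps integer voxel indices (voxel centers) to world mm. Must be
        invertible.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid sharing this grid's affine."""
        return VolumeGrid(np.asarray(data), self.affine.copy())

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def as_binary_mask(grid: VolumeGrid, name: str = "mask") -> VolumeGrid:
    """Validate that a grid is strictly binary and return it with bool data."""
    vals = np.unique(grid.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} is not binary: values {vals[:10]}")
    return VolumeGrid(grid.data.astype(bool), grid.affine)


@dataclass
class Tractogram:
    """An ordered collection of streamlines in world mm.

    Each streamline is an (n_points, 3) float array with n_points >= 2.
    Integer ids are stable under selection, so a subset tractogram keeps
    the ids its streamlines had in the parent.
    """

    streamlines: list = field(default_factory=list)
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.streamlines = [np.asarray(s, dtype=np.float64) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError("each streamline must be an (n, 3) array")
            if s.shape[0] < 2:
                raise ValueError("each streamline must have >= 2 points")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline contains non-finite coordinates")
        if self.ids is None:
            self.ids = np.arange(len(self.streamlines))
        else:
            self.ids = np.asarray(self.ids, dtype=int)
            if len(self.ids) != len(self.streamlines):
                raise ValueError("ids length must match streamline count")
            if len(np.unique(self.ids)) != len(self.ids):
                raise ValueError("ids must be unique")

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, indices) -> "Tractogram":
        """Positional subset preserving original ids."""
        indices = np.asarray(indices, dtype=int)
        return Tractogram(
            [self.streamlines[i] for i in indices], ids=self.ids[indices]
        )


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(path) -> VolumeGrid:
    """Read a 3D NIfTI volume into a :class:`VolumeGrid`."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D: {path}")
    return VolumeGrid(data, np.asarray(img.affine))


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a grid as NIfTI-1.

    Binary (bool / {0,1}) data is stored as unsigned 8-bit, everything
    else as 32-bit float; the affine is written unchanged.
    """
    data = grid.data
    if data.dtype == bool or (
        np.issubdtype(data.dtype, np.integer) and data.size and
        data.min() >= 0 and data.max() <= 1
    ):
        out = data.astype(np.uint8)
    else:
        out = data.astype(np.float32)
    img = nib.Nifti1Image(out, grid.affine)
    nib.save(img, os.fspath(path))


# ---------------------------------------------------------------------------
# Tractograms (TCK / TRK)
# ---------------------------------------------------------------------------

def read_tractogram(path) -> Tractogram:
    """Read a TCK or TRK file; coordinates are returned in world mm.

    TRK files carry their own voxel-space header which nibabel resolves
    to RAS+ mm on load; TCK files are stored in RAS+ mm natively.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".tck", ".trk"):
        raise ValueError(f"unknown tractogram extension {ext!r} (expected .tck/.trk)")
    tf = nib.streamlines.load(path)
    streamlines = [np.asarray(s, dtype=np.float64) for s in tf.streamlines]
    if not streamlines:
        raise ValueError(f"tractogram file is empty: {path}")
    return Tractogram(streamlines)


def write_tractogram(tractogram: Tractogram, path, reference: VolumeGrid | None = None) -> None:
    """Write streamlines to TCK or TRK (format chosen by extension).

    TRK requires a ``reference`` grid to populate its spatial header.
    """
    path = os.fspath(path)
    if tractogram.n_streamlines == 0:
        raise ValueError("refusing to write an empty tractogram")
    ext = os.path.splitext(path)[1].lower()
    nt = _NibTractogram(
        [s.astype(np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if ext == ".tck":
        nib.streamlines.save(nt, path)
    elif ext == ".trk":
        if reference is None:
            raise ValueError("writing TRK requires a reference VolumeGrid")
        header = {
            "voxel_to_rasmm": reference.affine.astype(np.float32),
            "voxel_sizes": reference.voxel_sizes.astype(np.float32),
            "dimensions": np.asarray(reference.shape, dtype=np.int16),
            "voxel_order": "".join(nib.aff2axcodes(reference.affine)),
        }
        nib.streamlines.save(nt, path, header=header)
    else:
        raise ValueError(f"unknown tractogram extension {ext!r} (expected .tck/.trk)")


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def world_to_voxel(points: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Map world-mm points to integer voxel indices (voxel-center convention).

    Points go through the inverse affine to continuous voxel coordinates and
    are rounded to the nearest integer; half-integer ties round toward +inf
    per axis. No bounds check is applied here — out-of-grid indices are the
    caller's concern.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite point coordinates")
    inv = np.linalg.inv(grid.affine)
    cont = pts @ inv[:3, :3].T + inv[:3, 3]
    idx = np.floor(cont + 0.5).astype(np.int64)
    if np.asarray(points).ndim == 1:
        return idx[0]
    return idx


def voxel_to_world(indices: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Map integer voxel indices to the world-mm positions of voxel centers."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    world = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    if np.asarray(indices).ndim == 1:
        return world[0]
    return world
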