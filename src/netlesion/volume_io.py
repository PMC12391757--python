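"""Volumetric image I/O and geometric conventions.

All volumes live on a :class:`VolumeGrid` — a voxel lattice defined by its
shape and a 4x4 affine mapping 0-based voxel indices to RAS world
coordinates in millimetres.  Every other module assumes the conventions
enforced here: masks are binary uint8 volumes, lesions are resampled with
nearest-neighbour interpolation, and grids must match exactly before any
voxelwise operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "LesionMask",
    "BrainMask",
    "GridMismatchError",
    "load_mask",
    "save_mask",
    "save_volume",
    "resample_mask",
]

BINARIZE_THRESHOLD = 0.5


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel lattice: shape plus affine (voxel index -> world mm, RAS)."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be a positive triple, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        affine = affine.copy()
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(float(v) for v in np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def matches(self, other: "VolumeGrid", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_size_mm: float = 2.0) -> "VolumeGrid":
        """Axis-aligned grid centred on the origin."""
        shape = tuple(int(s) for s in shape)
        aff = np.diag([voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
        return cls(shape=shape, affine=aff)


def _check_binary(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"mask data must be 3D, got {data.ndim}D")
    out = np.zeros(data.shape, dtype=np.uint8)
    out[data > BINARIZE_THRESHOLD] = 1
    return out


@dataclass
class LesionMask:
    """Binary lesion mask for one subject, in template space."""

    subject_id: str
    grid: VolumeGrid
    data: np.ndarray
    allow_empty: bool = False

    def __post_init__(self) -> None:
        self.data = _check_binary(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not self.allow_empty and self.n_voxels == 0:
            raise ValueError(f"lesion mask {self.subject_id!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3


@dataclass
class BrainMask:
    """Binary analysis mask shared by a cohort."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = _check_binary(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError("brain mask shape does not match its grid")
        if self.data.sum() == 0:
            raise ValueError("brain mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def load_mask(
    path: str | Path,
    expected_grid: VolumeGrid | None = None,
    subject_id: str | None = None,
    allow_empty: bool = False,
) -> LesionMask:
    """Load a NIfTI lesion mask, binarizing any value > 0.5 to 1.

    Raises on missing files, non-3D images, or (when ``expected_grid`` is
    given) a grid mismatch — the caller must resample explicitly rather
    than rely on silent reslicing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has shape {data.shape}")
    grid = VolumeGrid(shape=data.shape, affine=np.asarray(img.affine))
    if expected_grid is not None and not grid.matches(expected_grid):
        raise GridMismatchError(
            f"{path} is on a different grid than expected; resample first"
        )
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return LesionMask(subject_id=sid, grid=grid, data=data, allow_empty=allow_empty)


def save_volume(
    path: str | Path, grid: VolumeGrid, data: np.ndarray, dtype=np.float32
) -> Path:
    """Write a volume as NIfTI-1 with the grid's affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data, dtype=dtype)
    if arr.shape != grid.shape:
        raise ValueError("data shape does not match grid")
    img = nib.Nifti1Image(arr, np.asarray(grid.affine))
    nib.save(img, str(path))
    return path


def save_mask(path: str | Path, mask: LesionMask | BrainMask) -> Path:
    return save_volume(path, mask.grid, mask.data, dtype=np.uint8)


def _nearest_index(x: np.ndarray) -> np.ndarray:
    # round-half-down: ties between two voxel centres break toward the
    # lower index, keeping resampling deterministic
    return np.ceil(x - 0.5).astype(np.int64)


def resample_mask(mask: LesionMask, target: VolumeGrid) -> LesionMask:
    """Nearest-neighbour resampling of a binary mask onto ``target``.

    Each target voxel takes the value of the source voxel whose centre is
    nearest to the target voxel's centre in world space (pull scheme);
    target voxels falling outside the source lattice are 0.
    """
    if mask.grid.matches(target):
        return LesionMask(
            subject_id=mask.subject_id,
            grid=target,
            data=mask.data.copy(),
            allow_empty=True,
        )
    tg_idx = np.indices(target.shape).reshape(3, -1).T.astype(float)
    world = target.voxel_to_world(tg_idx)
    src = mask.grid.world_to_voxel(world)
    src_idx = _nearest_index(src)
    valid = np.all((src_idx >= 0) & (src_idx < np.asarray(mask.grid.shape)), axis=1)
    out = np.zeros(target.shape, dtype=np.uint8)
    vi = src_idx[valid]
    out_flat = out.reshape(-1)
    out_flat[np.flatnonzero(valid)] = mask.data[vi[:, 0], vi[:, 1], vi[:, 2]]
    return LesionMask(
        subject_id=mask.subject_id, grid=target, data=out, allow_empty=True
    )
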