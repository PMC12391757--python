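"""Indirect functional disconnection from a normative connectome.

A lesion drawn on a clinical scan carries no functional data of its own.
Its likely remote functional effects are estimated by embedding it in a
normative resting-state dataset: the within-lesion voxel-by-voxel
connectivity matrix is decomposed by PCA, the first component reshapes
the lesion into a weighted seed, and the seed's correlation with every
brain voxel yields a whole-brain disconnectivity map of r values, later
thresholded (default r >= 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import BrainMask, GridMismatchError, LesionMask, VolumeGrid

__all__ = [
    "NormativeConnectome",
    "DisconnectionMap",
    "within_lesion_connectivity",
    "reshape_lesion",
    "seed_disconnectivity_map",
    "threshold_map",
    "functional_disconnection_map",
    "DEFAULT_R_MIN",
]

DEFAULT_R_MIN = 0.2


@dataclass
class NormativeConnectome:
    """Voxel x time array over a brain mask (group-level normative data).

    ``timeseries`` has one row per in-mask voxel, ordered like
    ``np.argwhere(brainmask.data > 0)``; rows are standardized to zero
    mean and unit variance over time on construction.
    """

    grid: VolumeGrid
    brainmask: BrainMask
    timeseries: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timeseries, dtype=np.float64)
        if ts.ndim != 2:
            raise ValueError("timeseries must be 2D (voxels x time)")
        if ts.shape[0] != self.brainmask.n_voxels:
            raise ValueError("one time series per in-mask voxel required")
        if ts.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        sd = ts.std(axis=1)
        if np.any(~np.isfinite(ts)) or np.any(sd == 0):
            raise ValueError("every in-mask voxel needs a finite, non-constant series")
        self.timeseries = (ts - ts.mean(axis=1, keepdims=True)) / sd[:, None]

    @property
    def n_timepoints(self) -> int:
        return self.timeseries.shape[1]

    def flat_index(self) -> np.ndarray:
        """Flat voxel indices (C order) of the rows of ``timeseries``."""
        return np.flatnonzero(self.brainmask.data.reshape(-1) > 0)

    def lesion_rows(self, lesion: LesionMask) -> np.ndarray:
        """Row indices of the lesion voxels that fall inside the mask."""
        if not lesion.grid.matches(self.grid):
            raise GridMismatchError("lesion not on the connectome grid")
        inmask = self.brainmask.data.reshape(-1) > 0
        row_of = np.full(inmask.size, -1, dtype=np.int64)
        row_of[inmask] = np.arange(inmask.sum())
        rows = row_of[(lesion.data.reshape(-1) > 0) & inmask]
        return rows


@dataclass
class DisconnectionMap:
    """Continuous per-subject disconnection volume.

    ``kind='functional'`` holds Pearson r values in [-1, 1];
    ``kind='structural'`` holds visitation probabilities in [0, 1].
    ``threshold_applied`` records the last threshold applied (0 = none).
    """

    subject_id: str
    grid: VolumeGrid
    values: np.ndarray
    kind: str
    threshold_applied: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("map shape does not match grid")
        if self.kind not in ("functional", "structural"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        lo = -1.0 if self.kind == "functional" else 0.0
        if self.values.min() < lo - 1e-9 or self.values.max() > 1.0 + 1e-9:
            raise ValueError(f"{self.kind} map values out of range")


def within_lesion_connectivity(
    lesion: LesionMask, connectome: NormativeConnectome
) -> np.ndarray:
    """Pearson correlation matrix between all pairs of lesion voxels."""
    rows = connectome.lesion_rows(lesion)
    if rows.size == 0:
        raise ValueError("no lesion voxels inside the brain mask")
    ts = connectome.timeseries[rows]  # already z-scored over time
    T = ts.shape[1]
    corr = (ts @ ts.T) / T
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def reshape_lesion(
    lesion: LesionMask,
    conn_matrix: np.ndarray,
    connectome: NormativeConnectome,
) -> np.ndarray:
    """PCA-based reshaping of the lesion into a weighted seed.

    The first principal component of the within-lesion connectivity
    matrix is oriented so its loadings sum to >= 0, negative loadings are
    rectified to 0, and the remainder is normalized to sum 1.  Degenerate
    cases (<= 2 voxels, rank-deficient matrix, all-zero rectification)
    fall back to uniform weights.  Weights are returned per lesion voxel
    inside the brain mask, in ``connectome.lesion_rows`` order.
    """
    n = conn_matrix.shape[0]
    uniform = np.full(n, 1.0 / n)
    if n <= 2:
        return uniform
    try:
        evals, evecs = np.linalg.eigh(conn_matrix)
    except np.linalg.LinAlgError:
        return uniform
    if not np.isfinite(evals[-1]) or evals[-1] <= 1e-10:
        return uniform
    pc1 = evecs[:, -1]
    if pc1.sum() < 0:
        pc1 = -pc1
    w = np.maximum(pc1, 0.0)
    total = w.sum()
    if total <= 1e-12:
        return uniform
    return w / total


def seed_disconnectivity_map(
    seed_weights: np.ndarray,
    lesion: LesionMask,
    connectome: NormativeConnectome,
) -> DisconnectionMap:
    """Correlate the reshaped-lesion seed with every brain voxel.

    The seed series is the weighted mean of the lesion voxels' series;
    the map holds its Pearson correlation with each in-mask voxel
    (unthresholded; 0 outside the mask).
    """
    w = np.asarray(seed_weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("seed weights must sum to 1")
    rows = connectome.lesion_rows(lesion)
    if rows.size != w.size:
        raise ValueError("one weight per in-mask lesion voxel required")
    seed = w @ connectome.timeseries[rows]
    sd = seed.std()
    if sd == 0:
        raise ValueError("constant seed series")
    seed = (seed - seed.mean()) / sd
    T = connectome.n_timepoints
    r = (connectome.timeseries @ seed) / T
    values = np.zeros(connectome.grid.shape)
    values.reshape(-1)[connectome.flat_index()] = np.clip(r, -1.0, 1.0)
    return DisconnectionMap(
        subject_id=lesion.subject_id,
        grid=connectome.grid,
        values=values,
        kind="functional",
    )


def threshold_map(dmap: DisconnectionMap, r_min: float = DEFAULT_R_MIN) -> DisconnectionMap:
    """Zero all values below ``r_min`` (values >= r_min pass)."""
    if not -1.0 <= r_min <= 1.0:
        raise ValueError("r_min must be in [-1, 1]")
    values = np.where(dmap.values < r_min, 0.0, dmap.values)
    return DisconnectionMap(
        subject_id=dmap.subject_id,
        grid=dmap.grid,
        values=values,
        kind=dmap.kind,
        threshold_applied=r_min,
    )


def functional_disconnection_map(
    lesion: LesionMask, connectome: NormativeConnectome
) -> DisconnectionMap:
    """Full per-subject pipeline: within-lesion PCA reshape, seed map."""
    conn = within_lesion_connectivity(lesion, connectome)
    weights = reshape_lesion(lesion, conn, connectome)
    return seed_disconnectivity_map(weights, lesion, connectome)
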