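"""Indirect structural disconnection over a normative tract set.

A tract is "hit" when the lesion covers a voxel with sufficiently high
visitation probability (default >= 0.5).  The subject's structural
disconnection map assigns every voxel the maximum visitation probability
over the hit tracts, keeping the [0, 1] probability scale; the study
threshold keeps values strictly greater than 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .functional_disconnection import DisconnectionMap
from .volume_io import BrainMask, GridMismatchError, LesionMask, VolumeGrid

__all__ = [
    "Tract",
    "TractSet",
    "lesion_tract_hits",
    "structural_disconnectivity_map",
    "threshold_structural",
    "tract_overlap_report",
    "DEFAULT_HIT_MIN",
    "DEFAULT_P_MIN",
]

DEFAULT_HIT_MIN = 0.5
DEFAULT_P_MIN = 0.5


@dataclass
class Tract:
    """One normative bundle: per-voxel visitation probability in [0, 1]."""

    name: str
    visitation: np.ndarray
    endpoints: tuple[BrainMask, BrainMask] | None = None

    def __post_init__(self) -> None:
        self.visitation = np.asarray(self.visitation, dtype=np.float64)
        if self.visitation.min() < 0 or self.visitation.max() > 1:
            raise ValueError(f"tract {self.name!r} visitation outside [0, 1]")
        if not np.any(self.visitation > 0):
            raise ValueError(f"tract {self.name!r} has no visited voxels")


@dataclass
class TractSet:
    tracts: list[Tract]
    grid: VolumeGrid

    def __post_init__(self) -> None:
        for t in self.tracts:
            if t.visitation.shape != self.grid.shape:
                raise ValueError(f"tract {t.name!r} not on the shared grid")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.tracts]


def lesion_tract_hits(
    lesion: LesionMask, tracts: TractSet, hit_min: float = DEFAULT_HIT_MIN
) -> set[str]:
    """Tracts directly connected with the lesion.

    A tract is hit iff the maximum of its visitation over lesion voxels
    is >= ``hit_min``.
    """
    if not lesion.grid.matches(tracts.grid):
        raise GridMismatchError("lesion and tracts are on different grids")
    inside = lesion.data > 0
    hits = set()
    for t in tracts.tracts:
        if inside.any() and t.visitation[inside].max() >= hit_min:
            hits.add(t.name)
    return hits


def structural_disconnectivity_map(
    lesion: LesionMask, tracts: TractSet, hit_min: float = DEFAULT_HIT_MIN
) -> DisconnectionMap:
    """Per-voxel probability that a lesioned bundle passes through.

    Value at voxel v = max over hit tracts of visitation(v); 0 on voxels
    no hit tract visits.  The max (rather than a sum) keeps the [0, 1]
    probability scale the downstream threshold assumes.
    """
    hit = lesion_tract_hits(lesion, tracts, hit_min=hit_min)
    values = np.zeros(tracts.grid.shape)
    for t in tracts.tracts:
        if t.name in hit:
            np.maximum(values, t.visitation, out=values)
    return DisconnectionMap(
        subject_id=lesion.subject_id,
        grid=tracts.grid,
        values=values,
        kind="structural",
    )


def threshold_structural(
    dmap: DisconnectionMap, p_min: float = DEFAULT_P_MIN
) -> DisconnectionMap:
    """Keep values strictly greater than ``p_min`` (0.5 itself is removed:
    'more than 50% of the normative sample')."""
    if not 0.0 <= p_min <= 1.0:
        raise ValueError("p_min must be in [0, 1]")
    values = np.where(dmap.values > p_min, dmap.values, 0.0)
    return DisconnectionMap(
        subject_id=dmap.subject_id,
        grid=dmap.grid,
        values=values,
        kind=dmap.kind,
        threshold_applied=p_min,
    )


def tract_overlap_report(
    significant_mask: np.ndarray,
    tracts: TractSet,
    binarize_at: float = 0.5,
) -> pd.DataFrame:
    """Overlap of a significant-voxel mask with each binarized tract.

    Each tract's visitation is binarized at ``binarize_at``; the report
    gives the intersection voxel count and its fraction of the binarized
    tract size (the involvement of each bundle in the significant
    pattern).
    """
    significant_mask = np.asarray(significant_mask)
    if significant_mask.shape != tracts.grid.shape:
        raise GridMismatchError("mask and tracts are on different grids")
    sig = significant_mask > 0
    rows = []
    for t in tracts.tracts:
        binar = t.visitation >= binarize_at
        size = int(binar.sum())
        count = int((binar & sig).sum())
        rows.append(
            {
                "tract": t.name,
                "voxels": count,
                "fraction": count / size if size else 0.0,
            }
        )
    return pd.DataFrame(rows)
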