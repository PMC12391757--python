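"""Lesion-to-atlas overlap features.

Each lesion is summarised per parcel by two percentages: the share of the
lesion falling inside the parcel (``lesion_pct``, the spatial distribution
of the lesion) and the share of the parcel covered by the lesion
(``parcel_pct``, a volumetric load measure).  A parcel contributes to the
design matrix only if at least 5% of the lesion or 5% of the parcel is
involved; sub-threshold cells are zeroed per subject rather than dropping
the column for the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import GridMismatchError, LesionMask, VolumeGrid

__all__ = [
    "ParcellationAtlas",
    "OverlapFeatures",
    "compute_overlap",
    "apply_exclusion",
    "build_design_matrix",
    "DEFAULT_EXCLUSION_PCT",
]

DEFAULT_EXCLUSION_PCT = 5.0

ATLAS_KINDS = ("vascular", "functional", "structural-wm")


@dataclass
class ParcellationAtlas:
    """Integer-labelled parcellation (0 = background) with parcel names."""

    grid: VolumeGrid
    labels: np.ndarray
    names: dict[int, str]
    kind: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.shape != self.grid.shape:
            raise ValueError("atlas labels shape does not match grid")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be >= 0")
        if self.kind not in ATLAS_KINDS:
            raise ValueError(f"unknown atlas kind {self.kind!r}")
        present = set(np.unique(self.labels)) - {0}
        if not present:
            raise ValueError("atlas has zero parcels")
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"parcels without names: {sorted(missing)}")

    @property
    def parcel_ids(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    def parcel_sizes(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel())
        return {lab: int(counts[lab]) for lab in self.parcel_ids}

    def write_labels_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = [{"label": lab, "name": self.names[lab]} for lab in self.parcel_ids]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path


@dataclass
class OverlapFeatures:
    """Per-parcel overlap percentages for one lesion."""

    subject_id: str
    lesion_pct: dict[int, float]
    parcel_pct: dict[int, float]
    retained: set[int] = field(default_factory=set)


def compute_overlap(lesion: LesionMask, atlas: ParcellationAtlas) -> OverlapFeatures:
    """Dual overlap percentages of a lesion against every atlas parcel.

    For parcel ``L``: lesion_pct = 100 * |lesion ∩ L| / |lesion| and
    parcel_pct = 100 * |lesion ∩ L| / |L|.  An empty lesion yields all-zero
    features with an empty retained set.
    """
    if not lesion.grid.matches(atlas.grid):
        raise GridMismatchError("lesion and atlas are on different grids")
    parcel_ids = atlas.parcel_ids
    sizes = np.bincount(atlas.labels.ravel())
    n_lesion = lesion.n_voxels
    if n_lesion == 0:
        zeros = {lab: 0.0 for lab in parcel_ids}
        return OverlapFeatures(lesion.subject_id, dict(zeros), dict(zeros), set())
    inter = np.bincount(
        atlas.labels[lesion.data > 0].ravel(), minlength=len(sizes)
    )
    lesion_pct = {lab: 100.0 * inter[lab] / n_lesion for lab in parcel_ids}
    parcel_pct = {lab: 100.0 * inter[lab] / sizes[lab] for lab in parcel_ids}
    feats = OverlapFeatures(lesion.subject_id, lesion_pct, parcel_pct, set())
    return apply_exclusion(feats)


def apply_exclusion(
    features: OverlapFeatures, threshold_pct: float = DEFAULT_EXCLUSION_PCT
) -> OverlapFeatures:
    """Retain a parcel iff lesion_pct >= threshold OR parcel_pct >= threshold.

    The boundary is inclusive: an overlap involving exactly 5% of the
    lesion or 5% of the parcel survives the default rule.
    """
    if threshold_pct < 0:
        raise ValueError("exclusion threshold must be non-negative")
    retained = {
        lab
        for lab in features.lesion_pct
        if features.lesion_pct[lab] >= threshold_pct
        or features.parcel_pct[lab] >= threshold_pct
    }
    features.retained = retained
    return features


def build_design_matrix(
    cohort_features: list[OverlapFeatures],
    atlas: ParcellationAtlas,
    value: str = "lesion_pct",
) -> pd.DataFrame:
    """Subjects x parcels table of post-exclusion overlap values.

    Rows are ordered by subject id, columns by ascending parcel label;
    excluded cells are 0 and every atlas parcel keeps its column.  The
    returned frame carries ``attrs['atlas_kind']``.
    """
    if value not in ("lesion_pct", "parcel_pct"):
        raise ValueError("value must be 'lesion_pct' or 'parcel_pct'")
    ids = [f.subject_id for f in cohort_features]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicated subject ids in cohort features")
    parcel_ids = atlas.parcel_ids
    cols = [f"{atlas.kind}_{lab}_{atlas.names[lab]}" for lab in parcel_ids]
    rows = {}
    for f in sorted(cohort_features, key=lambda f: f.subject_id):
        vals = getattr(f, value)
        rows[f.subject_id] = [
            vals.get(lab, 0.0) if lab in f.retained else 0.0 for lab in parcel_ids
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "subject_id"
    df.attrs["atlas_kind"] = atlas.kind
    df.attrs["parcel_ids"] = parcel_ids
    return df


def write_design_matrix(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
    return path


def read_design_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")
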