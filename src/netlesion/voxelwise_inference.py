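"""Voxel-wise correlates of outcome with TFCE permutation inference.

Per-voxel Pearson correlation of a subject-level feature map (binary
lesion, functional or structural disconnection) with the outcome is
converted to a t statistic, enhanced with threshold-free cluster
enhancement (TFCE), and assessed against the max-statistic permutation
distribution, giving family-wise-error-corrected p-values without an
arbitrary cluster-forming threshold.  Positive and negative contrasts
are run separately via sign flips of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .atlas_features import ParcellationAtlas
from .functional_disconnection import DisconnectionMap
from .volume_io import BrainMask, VolumeGrid

__all__ = [
    "StatMap",
    "TfceParams",
    "InferenceResult",
    "voxelwise_statistic",
    "tfce",
    "permutation_fwe",
    "network_outcome_correlation",
    "T_SENTINEL",
    "DEFAULT_MIN_COVERAGE",
]

T_SENTINEL = 1e6  # |t| cap for r = +/-1
DEFAULT_MIN_COVERAGE = 5

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class TfceParams:
    """TFCE enhancement parameters (field-standard E=0.5, H=2,
    26-neighbourhood, 100 integration steps up to the map maximum)."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None  # None -> max statistic / n_steps per map
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class StatMap:
    grid: VolumeGrid
    t_values: np.ndarray
    direction: str  # positive | negative
    analysis_mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValueError("direction must be 'positive' or 'negative'")
        if self.analysis_mask is None:
            self.analysis_mask = np.isfinite(self.t_values) & (self.t_values != 0)


@dataclass
class InferenceResult:
    tfce_observed: np.ndarray
    fwe_p: np.ndarray
    significant: np.ndarray
    n_permutations: int
    alpha: float
    direction: str
    analysis_mask: np.ndarray
    t_observed: np.ndarray
    perm_max: np.ndarray = field(repr=False, default=None)


def _stack_maps(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        arr = maps
    else:
        arr = np.stack(
            [m.values if isinstance(m, DisconnectionMap) else np.asarray(m) for m in maps]
        )
    if arr.ndim != 4:
        raise ValueError("maps must stack to a 4D (subjects x volume) array")
    return arr.astype(np.float64)


class _CorrelationEngine:
    """Centered data matrix over the analysis mask for fast repeated
    correlation of all voxels with a (permuted) outcome vector."""

    def __init__(self, maps, y, mask: BrainMask, min_coverage: int):
        arr = _stack_maps(maps)
        self.y = np.asarray(y, dtype=float)
        n = arr.shape[0]
        if n < 3:
            raise ValueError("need at least 3 subjects")
        if len(self.y) != n:
            raise ValueError("y length must match number of subjects")
        self.shape = arr.shape[1:]
        if self.shape != mask.grid.shape:
            raise ValueError("maps not on the mask grid")
        flat = arr.reshape(n, -1)
        inmask = mask.data.reshape(-1) > 0
        coverage = (flat != 0).sum(axis=0)
        variance = flat.std(axis=0)
        keep = inmask & (coverage >= min_coverage) & (variance > 0)
        self.voxel_index = np.flatnonzero(keep)
        self.n = n
        M = flat[:, self.voxel_index]
        self.Mc = M - M.mean(axis=0)
        self.colnorm = np.sqrt((self.Mc**2).sum(axis=0))
        self.analysis_mask = keep.reshape(self.shape)

    def t_stat(self, y: np.ndarray) -> np.ndarray:
        """t values over the analysis-mask voxels for outcome vector y."""
        yc = y - y.mean()
        ynorm = np.sqrt((yc**2).sum())
        if ynorm == 0:
            return np.zeros(len(self.voxel_index))
        r = (yc @ self.Mc) / (ynorm * self.colnorm)
        r = np.clip(r, -1.0, 1.0)
        denom = 1.0 - r**2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((self.n - 2) / denom)
        t[denom <= 1e-15] = np.sign(r[denom <= 1e-15]) * T_SENTINEL
        return np.clip(t, -T_SENTINEL, T_SENTINEL)

    def embed(self, flat_vals: np.ndarray) -> np.ndarray:
        out = np.zeros(self.shape)
        out.reshape(-1)[self.voxel_index] = flat_vals
        return out


def voxelwise_statistic(
    maps,
    y,
    mask: BrainMask,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    direction: str = "positive",
) -> StatMap:
    """Per-voxel correlation t-map of feature maps against the outcome.

    Voxels outside the brain mask, with zero variance, or with fewer than
    ``min_coverage`` subjects having nonzero values are excluded from the
    analysis mask.  The negative contrast carries sign-flipped t values
    so that downstream enhancement always works on positive statistics.
    """
    eng = _CorrelationEngine(maps, y, mask, min_coverage)
    t = eng.t_stat(eng.y)
    if direction == "negative":
        t = -t
    return StatMap(
        grid=mask.grid,
        t_values=eng.embed(t),
        direction=direction,
        analysis_mask=eng.analysis_mask,
    )


def tfce(stat, params: TfceParams = TfceParams()) -> np.ndarray:
    """Threshold-free cluster enhancement of a (positive) statistic map.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... <= max of
    e_h(v)^E * h^H * dh, where e_h(v) is the voxel count of the connected
    component containing v in the supra-threshold set {t >= h}.  Voxels
    with t <= 0 score 0.
    """
    t = stat.t_values if isinstance(stat, StatMap) else np.asarray(stat, dtype=float)
    pos = np.maximum(t, 0.0)
    out = np.zeros_like(pos)
    tmax = pos.max()
    if tmax <= 0:
        return out
    dh = params.dh if params.dh is not None else tmax / params.n_steps
    structure = _STRUCTURES[params.connectivity]
    # work inside the positive bounding box only
    nz = np.argwhere(pos > 0)
    lo = nz.min(axis=0)
    hi = nz.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = pos[box]
    acc = np.zeros_like(sub)
    n = int(np.floor(tmax / dh + 1e-9))
    for k in range(1, n + 1):
        h = min(k * dh, tmax)  # guard float drift at the top step
        supra = sub >= h
        if not supra.any():
            break
        labels, nlab = ndimage.label(supra, structure=structure)
        sizes = np.bincount(labels.ravel())
        vals = sizes.astype(float) ** params.E * (h**params.H) * dh
        vals[0] = 0.0
        acc += vals[labels]
    out[box] = acc
    return out


def permutation_fwe(
    maps,
    y,
    mask: BrainMask,
    params: TfceParams = TfceParams(),
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    direction: str = "positive",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> InferenceResult:
    """Max-statistic permutation FWE correction of the TFCE map.

    The outcome vector is permuted across subjects ``n_perm`` times;
    each permutation's maximum TFCE over the analysis mask forms the
    null distribution.  fwe_p(v) = (1 + #{perm max >= observed TFCE(v)})
    / (n_perm + 1), so the smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    eng = _CorrelationEngine(maps, y, mask, min_coverage)
    sign = -1.0 if direction == "negative" else 1.0
    t_obs_flat = sign * eng.t_stat(eng.y)
    t_obs = eng.embed(t_obs_flat)
    tfce_obs = tfce(t_obs, params)
    rng = np.random.default_rng(seed)
    perm_max = np.empty(n_perm)
    for b in range(n_perm):
        yp = eng.y[rng.permutation(eng.n)]
        tp = sign * eng.t_stat(yp)
        perm_max[b] = tfce(eng.embed(tp), params).max()
    obs_in_mask = tfce_obs.reshape(-1)[eng.voxel_index]
    sorted_max = np.sort(perm_max)
    n_ge = n_perm - np.searchsorted(sorted_max, obs_in_mask, side="left")
    p_in_mask = (1.0 + n_ge) / (n_perm + 1.0)
    fwe_p = np.ones(eng.shape)
    fwe_p.reshape(-1)[eng.voxel_index] = p_in_mask
    significant = ((fwe_p < alpha) & eng.analysis_mask).astype(np.uint8)
    return InferenceResult(
        tfce_observed=tfce_obs,
        fwe_p=fwe_p,
        significant=significant,
        n_permutations=n_perm,
        alpha=alpha,
        direction=direction,
        analysis_mask=eng.analysis_mask,
        t_observed=t_obs,
        perm_max=perm_max,
    )


def network_outcome_correlation(
    disc_maps: list[DisconnectionMap],
    atlas: ParcellationAtlas,
    y,
) -> pd.DataFrame:
    """Correlation of per-network mean disconnection with the outcome.

    Each subject is summarised per network by the mean map value over the
    network's voxels; the table reports Pearson r, r^2 and the two-sided
    p from the t distribution with n-2 df.  Constant score vectors are
    reported as r = 0 with ``degenerate=True``.
    """
    y = np.asarray(y, dtype=float)
    if len(disc_maps) != len(y):
        raise ValueError("one outcome per map required")
    if len(y) < 3:
        raise ValueError("need at least 3 subjects")
    labels = atlas.labels
    rows = []
    for lab in atlas.parcel_ids:
        sel = labels == lab
        if not sel.any():
            raise ValueError(f"empty network {lab}")
        scores = np.array([m.values[sel].mean() for m in disc_maps])
        if scores.std() == 0 or y.std() == 0:
            rows.append(
                {
                    "network": lab,
                    "name": atlas.names[lab],
                    "r": 0.0,
                    "r2": 0.0,
                    "p": 1.0,
                    "degenerate": True,
                }
            )
            continue
        r, p = stats.pearsonr(scores, y)
        rows.append(
            {
                "network": lab,
                "name": atlas.names[lab],
                "r": float(r),
                "r2": float(r**2),
                "p": float(p),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)
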