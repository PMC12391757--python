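"""Synthetic cohorts with planted, recoverable effect structure.

The generator emulates the ingredients of a lesion-topography study of
anterior-circulation stroke: a template grid with an ellipsoidal brain
mask; a vascular-like atlas of contiguous territories; a functional
network atlas whose systems are distributed over >= 2 disjoint patches
(mimicking resting-state networks); white-matter tract corridors joining
patches of the same network; a normative connectome with block-structured
voxel time series; and a cohort of unilateral, connected lesion blobs
whose 3-month disability (mRS 0-6) is driven by weighted per-parcel
damage plus age/sex/NIHSS covariates plus Gaussian noise.

Because every effect is planted by construction, downstream stages
(overlap features, disconnection maps, Lasso model comparison, voxel-wise
inference) can be tested against a known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas_features import ParcellationAtlas
from .functional_disconnection import NormativeConnectome
from .structural_disconnection import Tract, TractSet
from .volume_io import BrainMask, LesionMask, VolumeGrid, save_mask, save_volume

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "SyntheticDataset",
    "make_brain_mask",
    "make_atlases",
    "make_connectome",
    "make_tracts",
    "make_cohort",
    "generate_dataset",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults emulate the study conditions
    (n = 70 subjects, 7 distributed networks, mRS driven mostly by damage
    to specific functional networks) at a desk-scale grid."""

    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 2.0
    n_networks: int = 7
    n_vascular_territories: int = 10
    n_tracts: int = 8
    n_subjects: int = 70
    n_timepoints: int = 200
    within_network_corr: float = 0.6
    noise_sd: float = 1.0
    # network-atlas parcel id -> weight on the latent outcome
    outcome_weights: dict[int, float] | None = None
    # per-unit effects of (age - 73), sex, (NIHSS - 13.8) on the latent
    covariate_effects: tuple[float, float, float] = (0.04, 0.3, 0.12)
    # admission NIHSS reflects stroke severity: base + gain * damage + noise
    nihss_base: float = 10.0
    nihss_damage_gain: float = 5.0
    nihss_noise_sd: float = 5.0
    lesion_volume_voxels: tuple[int, int] = (40, 250)
    outcome_intercept: float = 0.0
    mrs_cutpoints: tuple[float, ...] = (0.5, 1.5, 2.5, 3.5, 4.5, 5.5)
    prob_left_hemisphere: float = 40.0 / 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.n_timepoints < 2 * self.n_networks:
            raise ValueError("n_timepoints must be >= 2 * n_networks")
        if not 0.0 < self.within_network_corr <= 1.0:
            raise ValueError("within_network_corr must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.mrs_cutpoints) != 6 or list(self.mrs_cutpoints) != sorted(
            self.mrs_cutpoints
        ):
            raise ValueError("mrs_cutpoints must be 6 ascending values")

    def resolved_weights(self) -> dict[int, float]:
        """Default effect structure: damage to the first two networks
        drives disability, the rest are null parcels."""
        if self.outcome_weights is not None:
            return {int(k): float(v) for k, v in self.outcome_weights.items()}
        return {1: 60.0, 2: 44.0}

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), int(stream)])


@dataclass
class SyntheticCohort:
    lesions: list[LesionMask]
    outcomes: pd.DataFrame  # subject_id, mrs, age, sex, nihss
    truth: dict


@dataclass
class SyntheticDataset:
    """Everything a pipeline run needs, generated from one config."""

    config: SyntheticConfig
    grid: VolumeGrid
    brainmask: BrainMask
    atlases: dict[str, ParcellationAtlas]  # keys: vascular, functional, structural-wm
    tracts: TractSet
    connectome: NormativeConnectome
    cohort: SyntheticCohort


# ---------------------------------------------------------------------------
# geometry helpers

def make_brain_mask(config: SyntheticConfig) -> tuple[VolumeGrid, BrainMask]:
    """Ellipsoid occupying ~90% of each axis, the shared analysis mask."""
    grid = VolumeGrid.isotropic(config.grid_shape, config.voxel_size_mm)
    shape = np.asarray(config.grid_shape, dtype=float)
    centre = (shape - 1) / 2.0
    semi = 0.45 * shape
    idx = np.indices(config.grid_shape, dtype=float)
    r2 = sum(((idx[a] - centre[a]) / semi[a]) ** 2 for a in range(3))
    return grid, BrainMask(grid=grid, data=(r2 <= 1.0).astype(np.uint8))


def _farthest_point_seeds(
    coords: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy max-min selection of k well-separated voxels (deterministic
    given the rng); returns (k, 3) voxel coordinates."""
    if len(coords) < k:
        raise ValueError("grid too small to host the requested parcel count")
    first = rng.integers(len(coords))
    chosen = [coords[first]]
    d = np.linalg.norm(coords - chosen[0], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(coords[nxt])
        d = np.minimum(d, np.linalg.norm(coords - chosen[-1], axis=1))
    return np.asarray(chosen, dtype=float)


def _voronoi_labels(
    mask: np.ndarray, seeds: np.ndarray, seed_labels: np.ndarray
) -> np.ndarray:
    """Assign each in-mask voxel the label of its nearest seed.  Cells of a
    Euclidean Voronoi diagram are convex, so inside a convex (ellipsoidal)
    mask every territory is spatially connected."""
    coords = np.argwhere(mask > 0).astype(float)
    d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    out = np.zeros(mask.shape, dtype=np.int32)
    ijk = coords.astype(int)
    out[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = seed_labels[nearest]
    return out


# ---------------------------------------------------------------------------
# atlases and tracts

class _NetworkGeometry:
    """Distributed-network layout: the brain mask is cut into 2n
    equal-volume slabs along the anterior-posterior axis; network k owns
    slabs s and s + n (cyclically phase-shifted by the seed), so every
    network has exactly two disjoint contiguous patches separated by the
    other networks' territory — the distributed-system structure of
    resting-state networks at toy scale."""

    def __init__(self, config: SyntheticConfig, mask: np.ndarray):
        n = config.n_networks
        self.n_slabs = 2 * n
        coords = np.argwhere(mask > 0)
        ys = coords[:, 1]
        # equal-count slab edges along y
        qs = np.quantile(ys, np.linspace(0, 1, self.n_slabs + 1)[1:-1])
        slab_idx = np.searchsorted(qs, ys, side="right")
        self.slab_of = np.full(mask.shape, -1, dtype=np.int32)
        self.slab_of[tuple(coords.T)] = slab_idx
        offset = int(config.rng(11).integers(n))
        self.network_of_slab = np.array(
            [((s + offset) % self.n_slabs) % n + 1 for s in range(self.n_slabs)],
            dtype=np.int32,
        )
        self.labels = np.zeros(mask.shape, dtype=np.int32)
        inm = mask > 0
        self.labels[inm] = self.network_of_slab[self.slab_of[inm]]
        self.mask = mask
        # per-slab mean y (for tract endpoint placement)
        self.slab_mean_y = np.array(
            [ys[slab_idx == s].mean() for s in range(self.n_slabs)]
        )

    def slab_mask(self, s: int) -> np.ndarray:
        return ((self.slab_of == s) & (self.mask > 0)).astype(np.uint8)

    def network_slabs(self, net: int) -> list[int]:
        return [int(s) for s in np.flatnonzero(self.network_of_slab == net)]


def _tract_plan(config: SyntheticConfig) -> list[tuple[int, int]]:
    """(network, route index) per tract; extra tracts beyond n_networks
    are second, laterally offset corridors between the same patches."""
    return [(t % config.n_networks + 1, t // config.n_networks) for t in range(config.n_tracts)]


def _tract_endpoints(
    config: SyntheticConfig, geom: _NetworkGeometry, net: int, route: int
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Endpoint voxel coordinates in each of the network's two slabs,
    laterally offset (scaled to the local ellipse width) so corridors of
    different networks take distinct routes."""
    shape = np.asarray(geom.mask.shape, dtype=float)
    centre = (shape - 1) / 2.0
    semi = 0.45 * shape
    theta = 2.0 * np.pi * (net - 1) / config.n_networks + route * np.pi / config.n_networks
    s1, s2 = geom.network_slabs(net)
    pts = []
    for s in (s1, s2):
        y = geom.slab_mean_y[s]
        w = np.sqrt(max(0.05, 1.0 - ((y - centre[1]) / semi[1]) ** 2))
        p = np.array(
            [
                centre[0] + 0.5 * w * semi[0] * np.cos(theta),
                y,
                centre[2] + 0.5 * w * semi[2] * np.sin(theta),
            ]
        )
        pts.append(p)
    return pts[0], pts[1], (s1, s2)


def make_tracts(
    config: SyntheticConfig, network_atlas: ParcellationAtlas
) -> TractSet:
    """Corridors joining the two patches of each network.

    Visitation falls off as a Gaussian of the distance to the straight
    segment between the patch endpoints (sigma = 1.2 voxels, support
    radius 2.5), with the core path set to probability 1, mimicking
    normative tract visitation maps.  Tract endpoints are the patch
    masks themselves.
    """
    geom = _NetworkGeometry(config, _atlas_mask(network_atlas))
    shape = network_atlas.grid.shape
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    brain = _atlas_mask(network_atlas).reshape(-1) > 0
    tracts: list[Tract] = []
    sigma, radius = 1.2, 2.5
    for t, (net, route) in enumerate(_tract_plan(config)):
        a, b, (s1, s2) = _tract_endpoints(config, geom, net, route)
        d = _dist_to_segment(idx, a, b)
        vis = np.where(d <= radius, np.exp(-((d / sigma) ** 2)), 0.0)
        vis[~brain] = 0.0
        vis3 = vis.reshape(shape)
        # rasterized core path carries probability 1
        n_samp = max(2, int(4 * np.linalg.norm(b - a)))
        core = np.rint(a + np.linspace(0, 1, n_samp)[:, None] * (b - a)).astype(int)
        core = np.clip(core, 0, np.asarray(shape) - 1)
        keep = brain.reshape(shape)[core[:, 0], core[:, 1], core[:, 2]]
        core = core[keep]
        vis3[core[:, 0], core[:, 1], core[:, 2]] = 1.0
        if not np.any(vis3 > 0):
            raise ValueError("tract corridor has no voxels on this grid")
        name = f"tract-{t + 1:02d}_net{net}"
        tracts.append(
            Tract(
                name=name,
                visitation=vis3,
                endpoints=(
                    BrainMask(grid=network_atlas.grid, data=geom.slab_mask(s1)),
                    BrainMask(grid=network_atlas.grid, data=geom.slab_mask(s2)),
                ),
            )
        )
    return TractSet(tracts=tracts, grid=network_atlas.grid)


def _dist_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip((p - a) @ ab / max(float(ab @ ab), 1e-12), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def _atlas_mask(atlas: ParcellationAtlas) -> np.ndarray:
    return (atlas.labels > 0).astype(np.uint8)


def make_atlases(
    config: SyntheticConfig,
) -> tuple[ParcellationAtlas, ParcellationAtlas, ParcellationAtlas]:
    """Vascular-like, network-like and white-matter-tract-like atlases.

    The vascular atlas partitions the brain mask into contiguous Voronoi
    territories; the network atlas partitions the same mask into
    distributed two-patch systems with slab geometry unrelated to the
    vascular seeds, so the two parcellations have mismatched boundaries;
    the wm atlas labels the tract corridors joining same-network patches.
    """
    grid, brainmask = make_brain_mask(config)
    mask = brainmask.data
    coords = np.argwhere(mask > 0).astype(float)

    # vascular: one seed per territory, contiguous Voronoi wedges
    vseeds = _farthest_point_seeds(coords, config.n_vascular_territories, config.rng(10))
    vlabels = _voronoi_labels(
        mask, vseeds, np.arange(1, config.n_vascular_territories + 1, dtype=np.int32)
    )
    vascular = ParcellationAtlas(
        grid=grid,
        labels=vlabels,
        names={i + 1: f"territory_{i + 1:02d}" for i in range(config.n_vascular_territories)},
        kind="vascular",
    )

    # network: distributed two-patch systems
    geom = _NetworkGeometry(config, mask)
    nlabels = geom.labels
    present = set(np.unique(nlabels)) - {0}
    if len(present) != config.n_networks:
        raise ValueError("grid too small to host the requested network count")
    network = ParcellationAtlas(
        grid=grid,
        labels=nlabels,
        names={k: f"network_{k}" for k in range(1, config.n_networks + 1)},
        kind="functional",
    )

    # wm: argmax-visitation label over tract corridors
    tracts = make_tracts(config, network)
    stack = np.stack([t.visitation for t in tracts.tracts])
    best = np.argmax(stack, axis=0)
    peak = np.max(stack, axis=0)
    wlabels = np.where(peak > 0, best + 1, 0).astype(np.int32)
    # guarantee each tract keeps at least its corridor midpoint
    for t_i, tract in enumerate(tracts.tracts):
        if not np.any(wlabels == t_i + 1):
            core = np.argwhere(tract.visitation >= 1.0)
            mid = core[len(core) // 2]
            wlabels[tuple(mid)] = t_i + 1
    wm = ParcellationAtlas(
        grid=grid,
        labels=wlabels,
        names={i + 1: t.name for i, t in enumerate(tracts.tracts)},
        kind="structural-wm",
    )
    return vascular, network, wm


# ---------------------------------------------------------------------------
# connectome

def make_connectome(
    config: SyntheticConfig, network_atlas: ParcellationAtlas
) -> NormativeConnectome:
    """Block-structured voxel time series over the brain mask.

    Each voxel's series is sqrt(c) * latent network signal +
    sqrt(1 - c) * private noise with all signals i.i.d. standard normal
    over time, so the expected correlation is c within a network
    (including across its disjoint patches) and 0 between networks.
    """
    if config.n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    rng = config.rng(20)
    grid = network_atlas.grid
    mask = _atlas_mask(network_atlas)
    labels = network_atlas.labels[mask > 0]
    n_vox = int(mask.sum())
    T = config.n_timepoints
    c = config.within_network_corr
    latent = rng.standard_normal((config.n_networks + 1, T))
    noise = rng.standard_normal((n_vox, T))
    ts = np.sqrt(c) * latent[labels] + np.sqrt(1.0 - c) * noise
    return NormativeConnectome(
        grid=grid, brainmask=BrainMask(grid=grid, data=mask), timeseries=ts
    )


# ---------------------------------------------------------------------------
# cohort

_NEIGH = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_blob(
    allowed: np.ndarray, target: int, rng: np.random.Generator, max_tries: int = 10
) -> np.ndarray | None:
    """Random 6-connected growth from a seed voxel, confined to ``allowed``.

    Seeds are drawn from the anterior 60% of the allowed region (larger
    anterior/middle territory involvement, as in anterior-circulation
    stroke); growth itself may extend anywhere in ``allowed``.
    """
    shape = np.asarray(allowed.shape)
    cand = np.argwhere(allowed > 0)
    anterior = cand[cand[:, 1] >= 0.4 * allowed.shape[1]]
    seeds = anterior if len(anterior) else cand
    for _ in range(max_tries):
        seed = seeds[rng.integers(len(seeds))]
        blob = np.zeros(allowed.shape, dtype=np.uint8)
        blob[tuple(seed)] = 1
        frontier = {tuple(v) for v in seed + _NEIGH}
        frontier = {
            v
            for v in frontier
            if all(0 <= v[a] < shape[a] for a in range(3)) and allowed[v] and not blob[v]
        }
        n = 1
        while n < target and frontier:
            flist = sorted(frontier)
            pick = flist[rng.integers(len(flist))]
            frontier.remove(pick)
            blob[pick] = 1
            n += 1
            for d in _NEIGH:
                v = (pick[0] + d[0], pick[1] + d[1], pick[2] + d[2])
                if (
                    all(0 <= v[a] < shape[a] for a in range(3))
                    and allowed[v]
                    and not blob[v]
                ):
                    frontier.add(v)
        if n >= target:
            return blob
    return None


def make_cohort(
    config: SyntheticConfig,
    atlases: dict[str, ParcellationAtlas] | tuple[ParcellationAtlas, ...],
    tracts: TractSet | None = None,
) -> SyntheticCohort:
    """Unilateral lesion blobs plus outcomes from the planted linear model.

    damage = sum_p w_p * frac(parcel p lesioned);
    NIHSS  = clip(round(base + gain * damage + noise)) — admission severity
             partially reflects network damage, as it does clinically;
    latent = intercept + damage + a*(age-73) + s*sex + h*(NIHSS-13.8)
             + N(0, noise_sd);
    mRS    = latent discretized by the fixed cut-points into {0..6}.
    """
    if isinstance(atlases, dict):
        network = atlases["functional"]
    else:
        network = next(a for a in atlases if a.kind == "functional")
    grid = network.grid
    mask = _atlas_mask(network)
    weights = config.resolved_weights()
    bad = set(weights) - set(network.parcel_ids)
    if bad:
        raise ValueError(f"outcome_weights refer to missing parcels: {sorted(bad)}")
    sizes = network.parcel_sizes()
    rng = config.rng(30)
    nx = grid.shape[0]
    a_eff, s_eff, h_eff = config.covariate_effects
    lo, hi = config.lesion_volume_voxels

    lesions: list[LesionMask] = []
    rows = []
    latents, fracs_all, hemis = [], [], []
    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:03d}"
        left = rng.random() < config.prob_left_hemisphere
        hemi = np.zeros(grid.shape, dtype=np.uint8)
        if left:
            hemi[: nx // 2] = 1
        else:
            hemi[nx // 2 :] = 1
        allowed = (mask & hemi).astype(np.uint8)
        target = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        blob = _grow_blob(allowed, target, rng)
        if blob is None:
            raise RuntimeError(f"lesion blob growth failed for {sid}")
        lesion = LesionMask(subject_id=sid, grid=grid, data=blob)
        lesions.append(lesion)

        inter = np.bincount(network.labels[blob > 0], minlength=max(sizes) + 1)
        fracs = {p: inter[p] / sizes[p] for p in network.parcel_ids}
        damage = sum(w * fracs[p] for p, w in weights.items())
        age = float(np.clip(rng.normal(73.0, 12.0), 35.0, 95.0))
        sex = int(rng.random() < 0.53)
        nihss = int(
            np.clip(
                np.round(
                    config.nihss_base
                    + config.nihss_damage_gain * damage
                    + (rng.normal(0.0, config.nihss_noise_sd) if config.nihss_noise_sd > 0 else 0.0)
                ),
                0,
                42,
            )
        )
        latent = (
            config.outcome_intercept
            + damage
            + a_eff * (age - 73.0)
            + s_eff * sex
            + h_eff * (nihss - 13.8)
            + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
        )
        mrs = int(np.clip(np.searchsorted(config.mrs_cutpoints, latent), 0, 6))
        rows.append(
            {"subject_id": sid, "mrs": mrs, "age": age, "sex": sex, "nihss": nihss}
        )
        latents.append(latent)
        fracs_all.append({int(p): float(f) for p, f in fracs.items()})
        hemis.append("left" if left else "right")

    outcomes = pd.DataFrame(rows).set_index("subject_id")
    truth = {
        "outcome_weights": {int(k): float(v) for k, v in weights.items()},
        "covariate_effects": list(config.covariate_effects),
        "intercept": config.outcome_intercept,
        "mrs_cutpoints": list(config.mrs_cutpoints),
        "noise_sd": config.noise_sd,
        "latent": [float(v) for v in latents],
        "parcel_damage_fraction": fracs_all,
        "hemisphere": hemis,
    }
    return SyntheticCohort(lesions=lesions, outcomes=outcomes, truth=truth)


# ---------------------------------------------------------------------------
# top level + cohort directory round-trip

def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate every input a pipeline run needs, reproducibly from
    (config, seed)."""
    grid, brainmask = make_brain_mask(config)
    vascular, network, wm = make_atlases(config)
    tracts = make_tracts(config, network)
    connectome = make_connectome(config, network)
    cohort = make_cohort(config, {"functional": network}, tracts)
    return SyntheticDataset(
        config=config,
        grid=grid,
        brainmask=brainmask,
        atlases={"vascular": vascular, "functional": network, "structural-wm": wm},
        tracts=tracts,
        connectome=connectome,
        cohort=cohort,
    )


_ATLAS_FILES = {
    "vascular": "atlas_vascular",
    "functional": "atlas_network",
    "structural-wm": "atlas_wm",
}


def write_cohort(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write the full dataset as a cohort directory (NIfTI + TSV + npz)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_mask(outdir / "brainmask.nii.gz", dataset.brainmask)
    for kind, stem in _ATLAS_FILES.items():
        atlas = dataset.atlases[kind]
        save_volume(outdir / f"{stem}.nii.gz", atlas.grid, atlas.labels, dtype=np.int32)
        atlas.write_labels_tsv(outdir / f"{stem}_labels.tsv")
    for lesion in dataset.cohort.lesions:
        save_mask(outdir / "lesions" / f"{lesion.subject_id}.nii.gz", lesion)
    for tract in dataset.tracts.tracts:
        save_volume(
            outdir / "tracts" / f"{tract.name}.nii.gz",
            dataset.grid,
            tract.visitation,
        )
    np.savez_compressed(
        outdir / "connectome.npz", timeseries=dataset.connectome.timeseries
    )
    dataset.cohort.outcomes.to_csv(outdir / "participants.tsv", sep="\t")
    (outdir / "truth.json").write_text(json.dumps(dataset.cohort.truth, indent=1))
    return outdir


def load_cohort(indir: str | Path, config: SyntheticConfig) -> SyntheticDataset:
    """Load a cohort directory written by :func:`write_cohort`."""
    import nibabel as nib

    indir = Path(indir)
    for required in ["participants.tsv", "brainmask.nii.gz", "connectome.npz"]:
        if not (indir / required).exists():
            raise FileNotFoundError(f"cohort directory missing {required}: {indir}")
    bm_img = nib.load(str(indir / "brainmask.nii.gz"))
    grid = VolumeGrid(shape=bm_img.shape, affine=np.asarray(bm_img.affine))
    brainmask = BrainMask(grid=grid, data=np.asanyarray(bm_img.dataobj))
    atlases = {}
    for kind, stem in _ATLAS_FILES.items():
        img = nib.load(str(indir / f"{stem}.nii.gz"))
        tab = pd.read_csv(indir / f"{stem}_labels.tsv", sep="\t")
        atlases[kind] = ParcellationAtlas(
            grid=grid,
            labels=np.asanyarray(img.dataobj).astype(np.int32),
            names=dict(zip(tab["label"].astype(int), tab["name"].astype(str))),
            kind=kind,
        )
    tract_files = sorted((indir / "tracts").glob("*.nii.gz"))
    tracts = []
    for f in tract_files:
        vis = np.asanyarray(nib.load(str(f)).dataobj).astype(float)
        tracts.append(
            Tract(name=f.name.replace(".nii.gz", ""), visitation=vis, endpoints=None)
        )
    tractset = TractSet(tracts=tracts, grid=grid)
    ts = np.load(indir / "connectome.npz")["timeseries"]
    connectome = NormativeConnectome(grid=grid, brainmask=brainmask, timeseries=ts)
    outcomes = pd.read_csv(indir / "participants.tsv", sep="\t").set_index("subject_id")
    lesions = []
    for f in sorted((indir / "lesions").glob("*.nii.gz")):
        img = nib.load(str(f))
        lesions.append(
            LesionMask(
                subject_id=f.name.replace(".nii.gz", ""),
                grid=grid,
                data=np.asanyarray(img.dataobj),
            )
        )
    truth = {}
    if (indir / "truth.json").exists():
        truth = json.loads((indir / "truth.json").read_text())
    cohort = SyntheticCohort(lesions=lesions, outcomes=outcomes, truth=truth)
    return SyntheticDataset(
        config=config,
        grid=grid,
        brainmask=brainmask,
        atlases=atlases,
        tracts=tractset,
        connectome=connectome,
        cohort=cohort,
    )
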