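import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from netlesion.synthetic_data import (
    SyntheticConfig,
    generate_dataset,
    load_cohort,
    make_atlases,
    make_brain_mask,
    make_cohort,
    make_connectome,
    make_tracts,
    write_cohort,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_subjects=2)
        with pytest.raises(ValueError):
            SyntheticConfig(n_networks=7, n_timepoints=10)
        with pytest.raises(ValueError):
            SyntheticConfig(within_network_corr=0.0)

    def test_weights_must_refer_to_existing_parcels(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, outcome_weights={99: 1.0})
        vascular, network, wm = make_atlases(cfg)
        with pytest.raises(ValueError, match="missing parcels"):
            make_cohort(cfg, {"functional": network})


class TestAtlases:
    def test_partition_of_brain_mask(self, tiny_config, tiny_dataset):
        mask = tiny_dataset.brainmask.data > 0
        for kind in ("vascular", "functional"):
            labels = tiny_dataset.atlases[kind].labels
            # exactly one label per in-mask voxel, none outside
            assert (labels[mask] > 0).all()
            assert (labels[~mask] == 0).all()
        assert len(tiny_dataset.atlases["vascular"].parcel_ids) == 4
        assert len(tiny_dataset.atlases["functional"].parcel_ids) == 3
        assert len(tiny_dataset.atlases["structural-wm"].parcel_ids) == 3

    def test_vascular_territories_contiguous(self, tiny_dataset):
        atlas = tiny_dataset.atlases["vascular"]
        for lab in atlas.parcel_ids:
            _, n = ndimage.label(atlas.labels == lab)
            assert n == 1

    def test_networks_distributed_in_disjoint_patches(self, tiny_dataset):
        atlas = tiny_dataset.atlases["functional"]
        struct = ndimage.generate_binary_structure(3, 3)
        for lab in atlas.parcel_ids:
            _, n = ndimage.label(atlas.labels == lab, structure=struct)
            assert n >= 2  # each network has >= 2 spatially separate patches

    def test_deterministic_given_seed(self, tiny_config):
        a1 = make_atlases(tiny_config)
        a2 = make_atlases(tiny_config)
        for x, y in zip(a1, a2):
            np.testing.assert_array_equal(x.labels, y.labels)

    def test_too_small_grid_raises(self):
        cfg = SyntheticConfig(
            grid_shape=(4, 4, 4), n_networks=7, n_vascular_territories=40,
            n_subjects=3, n_timepoints=20,
        )
        with pytest.raises(ValueError):
            make_atlases(cfg)


class TestConnectome:
    def test_block_correlation_structure(self):
        # Monte-Carlo check of the generative formula at long T
        cfg = SyntheticConfig(
            grid_shape=(12, 14, 12), n_networks=3, n_vascular_territories=4,
            n_tracts=3, n_subjects=3, n_timepoints=2000, within_network_corr=0.6,
            seed=11,
        )
        _, network, _ = make_atlases(cfg)
        conn = make_connectome(cfg, network)
        labels = network.labels[network.labels > 0]
        rng = np.random.default_rng(0)
        idx = rng.choice(len(labels), 150, replace=False)
        C = np.corrcoef(conn.timeseries[idx])
        iu = np.triu_indices(len(idx), 1)
        same = (labels[idx][:, None] == labels[idx][None, :])[iu]
        assert abs(C[iu][same].mean() - 0.6) < 0.05
        assert abs(C[iu][~same].mean()) < 0.05

    def test_perfect_correlation_limit(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, within_network_corr=1.0)
        _, network, _ = make_atlases(cfg)
        conn = make_connectome(cfg, network)
        labels = network.labels[network.labels > 0]
        rows = np.flatnonzero(labels == labels[0])[:5]
        C = np.corrcoef(conn.timeseries[rows])
        np.testing.assert_allclose(C, 1.0, atol=1e-10)

    def test_cross_patch_correlation_matches_within_network(self):
        # two disjoint patches of one network are as correlated as one patch
        cfg = SyntheticConfig(
            grid_shape=(12, 14, 12), n_networks=3, n_vascular_territories=4,
            n_tracts=3, n_subjects=3, n_timepoints=2000, seed=13,
        )
        _, network, _ = make_atlases(cfg)
        conn = make_connectome(cfg, network)
        struct = ndimage.generate_binary_structure(3, 3)
        comp, n = ndimage.label(network.labels == 1, structure=struct)
        assert n >= 2
        flat_rows = np.full(network.grid.shape, -1, dtype=int)
        flat_rows[network.labels > 0] = np.arange((network.labels > 0).sum())
        r1 = flat_rows[comp == 1][:20]
        r2 = flat_rows[comp == 2][:20]
        z1 = conn.timeseries[r1]
        z2 = conn.timeseries[r2]
        cross = (z1 @ z2.T) / conn.n_timepoints
        assert abs(cross.mean() - cfg.within_network_corr) < 0.05


class TestTracts:
    def test_visitation_range_and_endpoints(self, tiny_config, tiny_dataset):
        tracts = tiny_dataset.tracts
        assert len(tracts.tracts) == tiny_config.n_tracts
        net = tiny_dataset.atlases["functional"]
        for t in tracts.tracts:
            vis = t.visitation[t.visitation > 0]
            assert vis.min() > 0 and vis.max() <= 1.0
            assert np.isclose(t.visitation.max(), 1.0)
            # endpoint masks intersect the brain parcellation
            for ep in t.endpoints:
                assert (ep.data & (net.labels > 0)).sum() > 0

    def test_reproducible(self, tiny_config):
        _, network, _ = make_atlases(tiny_config)
        t1 = make_tracts(tiny_config, network)
        t2 = make_tracts(tiny_config, network)
        for a, b in zip(t1.tracts, t2.tracts):
            np.testing.assert_array_equal(a.visitation, b.visitation)


class TestCohort:
    def test_lesions_connected_unilateral_in_mask(self, tiny_dataset):
        mask = tiny_dataset.brainmask.data
        nx = tiny_dataset.grid.shape[0]
        struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        for lesion in tiny_dataset.cohort.lesions:
            assert (lesion.data <= mask).all()
            _, n = ndimage.label(lesion.data, structure=struct)
            assert n == 1
            left = lesion.data[: nx // 2].sum()
            right = lesion.data[nx // 2 :].sum()
            assert (left == 0) != (right == 0)  # exactly one hemisphere

    def test_outcome_bounds_and_matching(self, tiny_dataset):
        out = tiny_dataset.cohort.outcomes
        assert out["mrs"].between(0, 6).all()
        assert set(out.index) == {l.subject_id for l in tiny_dataset.cohort.lesions}

    def test_degenerate_outcome_all_equal(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config, outcome_weights={}, noise_sd=0.0,
            covariate_effects=(0.0, 0.0, 0.0), nihss_damage_gain=0.0,
        )
        _, network, _ = make_atlases(cfg)
        cohort = make_cohort(cfg, {"functional": network})
        assert cohort.outcomes["mrs"].nunique() == 1

    def test_mrs_monotone_in_planted_parcel_damage(self, tiny_config):
        cfg = dataclasses.replace(
            tiny_config, outcome_weights={1: 10.0}, noise_sd=0.0,
            covariate_effects=(0.0, 0.0, 0.0), nihss_damage_gain=0.0,
            n_subjects=20,
        )
        _, network, _ = make_atlases(cfg)
        cohort = make_cohort(cfg, {"functional": network})
        frac = np.array([d["1"] if "1" in d else d[1] for d in cohort.truth["parcel_damage_fraction"]])
        mrs = cohort.outcomes["mrs"].to_numpy()
        order = np.argsort(frac)
        assert (np.diff(mrs[order]) >= 0).all()

    def test_reproducible_from_seed(self, tiny_config):
        d1 = generate_dataset(tiny_config)
        d2 = generate_dataset(tiny_config)
        for l1, l2 in zip(d1.cohort.lesions, d2.cohort.lesions):
            np.testing.assert_array_equal(l1.data, l2.data)
        assert d1.cohort.outcomes.equals(d2.cohort.outcomes)


class TestCohortDirectory:
    def test_write_load_roundtrip(self, tiny_config, tiny_dataset, tmp_path):
        write_cohort(tiny_dataset, tmp_path / "cohort")
        back = load_cohort(tmp_path / "cohort", tiny_config)
        assert len(back.cohort.lesions) == tiny_config.n_subjects
        np.testing.assert_array_equal(
            back.atlases["functional"].labels, tiny_dataset.atlases["functional"].labels
        )
        np.testing.assert_allclose(
            back.connectome.timeseries, tiny_dataset.connectome.timeseries, atol=1e-12
        )
        pd_out = back.cohort.outcomes
        assert pd_out["mrs"].equals(tiny_dataset.cohort.outcomes["mrs"])

    def test_missing_participants_raises(self, tiny_config, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FileNotFoundError, match="participants.tsv"):
            load_cohort(tmp_path / "empty", tiny_config)
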