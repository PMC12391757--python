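import numpy as np
import pytest

from netlesion.atlas_features import (
    OverlapFeatures,
    ParcellationAtlas,
    apply_exclusion,
    build_design_matrix,
    compute_overlap,
)
from netlesion.volume_io import GridMismatchError, LesionMask, VolumeGrid


def brute_force_overlap(lesion_data, labels):
    """Per-voxel counting oracle for the dual overlap percentages."""
    lesion_pct, parcel_pct = {}, {}
    n_lesion = int(lesion_data.sum())
    for lab in sorted(set(labels.ravel()) - {0}):
        inter = size = 0
        for idx in np.ndindex(labels.shape):
            if labels[idx] == lab:
                size += 1
                if lesion_data[idx]:
                    inter += 1
        lesion_pct[lab] = 100.0 * inter / n_lesion if n_lesion else 0.0
        parcel_pct[lab] = 100.0 * inter / size
    return lesion_pct, parcel_pct


def _atlas(grid, labels, kind="vascular"):
    names = {int(v): f"p{int(v)}" for v in np.unique(labels) if v != 0}
    return ParcellationAtlas(grid=grid, labels=labels.astype(np.int32), names=names, kind=kind)


class TestComputeOverlap:
    def test_worked_example_two_parcels(self):
        # lesion of 10 voxels: 6 in parcel A (|A|=100), 4 in parcel B (|B|=20)
        grid = VolumeGrid.isotropic((5, 5, 5), 1.0)
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels.reshape(-1)[:100] = 1
        labels.reshape(-1)[100:120] = 2
        lesion = np.zeros((5, 5, 5))
        lesion.reshape(-1)[:6] = 1
        lesion.reshape(-1)[100:104] = 1
        f = compute_overlap(LesionMask("s", grid, lesion), _atlas(grid, labels))
        assert f.lesion_pct == {1: 60.0, 2: 40.0}
        assert f.parcel_pct == {1: 6.0, 2: 20.0}

    def test_lesion_identical_to_parcel(self, grid8):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[:2] = 1
        labels[2:4] = 2
        lesion = (labels == 1).astype(float)
        f = compute_overlap(LesionMask("s", grid8, lesion), _atlas(grid8, labels))
        assert f.lesion_pct[1] == 100.0 and f.parcel_pct[1] == 100.0
        assert f.lesion_pct[2] == 0.0 and f.parcel_pct[2] == 0.0

    def test_empty_lesion_all_zero(self, grid8):
        labels = np.ones((8, 8, 8), dtype=np.int32)
        lesion = LesionMask("s", grid8, np.zeros((8, 8, 8)), allow_empty=True)
        f = compute_overlap(lesion, _atlas(grid8, labels))
        assert all(v == 0.0 for v in f.lesion_pct.values())
        assert f.retained == set()

    def test_grid_mismatch(self, grid8):
        other = VolumeGrid.isotropic((8, 8, 8), 2.0)
        labels = np.ones((8, 8, 8), dtype=np.int32)
        lesion = LesionMask("s", other, np.ones((8, 8, 8)))
        with pytest.raises(GridMismatchError):
            compute_overlap(lesion, _atlas(grid8, labels))

    def test_matches_counting_oracle(self, grid8, rng):
        labels = rng.integers(0, 4, size=(8, 8, 8)).astype(np.int32)
        labels[0, 0, 0] = 1  # ensure parcels exist
        lesion = (rng.random((8, 8, 8)) > 0.8).astype(float)
        lesion[1, 1, 1] = 1
        f = compute_overlap(LesionMask("s", grid8, lesion), _atlas(grid8, labels))
        lp, pp = brute_force_overlap(lesion, labels)
        assert f.lesion_pct == pytest.approx(lp)
        assert f.parcel_pct == pytest.approx(pp)

    def test_lesion_pct_sums_to_at_most_100(self, grid8, rng):
        labels = rng.integers(0, 3, size=(8, 8, 8)).astype(np.int32)
        labels[0, 0, 0] = 1
        lesion = (rng.random((8, 8, 8)) > 0.5).astype(float)
        f = compute_overlap(LesionMask("s", grid8, lesion), _atlas(grid8, labels))
        assert sum(f.lesion_pct.values()) <= 100.0 + 1e-9


class TestExclusionRule:
    @pytest.mark.parametrize(
        "lesion_pct,parcel_pct,kept",
        [
            (3.0, 2.0, False),   # both below 5% -> excluded
            (3.0, 7.0, True),    # OR rule: parcel share saves it
            (7.0, 3.0, True),
            (5.0, 0.0, True),    # boundary inclusive: 'at least 5%'
            (0.0, 5.0, True),
            (4.999, 4.999, False),
        ],
    )
    def test_or_rule_with_inclusive_boundary(self, lesion_pct, parcel_pct, kept):
        f = OverlapFeatures("s", {1: lesion_pct}, {1: parcel_pct})
        apply_exclusion(f)
        assert (1 in f.retained) is kept

    def test_negative_threshold_rejected(self):
        f = OverlapFeatures("s", {1: 1.0}, {1: 1.0})
        with pytest.raises(ValueError):
            apply_exclusion(f, -1.0)


class TestDesignMatrix:
    def test_values_and_shape(self, grid8):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[:3] = 1
        labels[3:5] = 2
        labels[5:] = 3
        atlas = _atlas(grid8, labels)
        l1 = (labels == 1).astype(float)  # entirely in parcel 1
        l2 = np.zeros((8, 8, 8))
        l2[3, :, :] = 1  # one slab of parcel 2
        feats = [
            compute_overlap(LesionMask("sub-b", grid8, l2), atlas),
            compute_overlap(LesionMask("sub-a", grid8, l1), atlas),
        ]
        X = build_design_matrix(feats, atlas)
        assert X.shape == (2, 3)
        assert list(X.index) == ["sub-a", "sub-b"]  # sorted by subject id
        assert X.loc["sub-a"].tolist() == [100.0, 0.0, 0.0]
        assert X.loc["sub-b"].tolist() == [0.0, 100.0, 0.0]

    def test_empty_lesion_gives_zero_row(self, grid8):
        labels = np.ones((8, 8, 8), dtype=np.int32)
        atlas = _atlas(grid8, labels)
        f = compute_overlap(
            LesionMask("s", grid8, np.zeros((8, 8, 8)), allow_empty=True), atlas
        )
        X = build_design_matrix([f], atlas)
        assert (X.to_numpy() == 0).all()

    def test_columns_survive_exclusion(self, grid8):
        # exclusion zeroes cells, never drops columns
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[:4] = 1
        labels[4:] = 2
        atlas = _atlas(grid8, labels)
        lesion = np.zeros((8, 8, 8))
        lesion[0, 0, 0] = 1  # 100% of lesion in parcel 1, nothing in 2
        f = compute_overlap(LesionMask("s", grid8, lesion), atlas)
        X = build_design_matrix([f], atlas)
        assert X.shape[1] == len(atlas.parcel_ids)

    def test_duplicate_subject_ids_rejected(self, grid8):
        labels = np.ones((8, 8, 8), dtype=np.int32)
        atlas = _atlas(grid8, labels)
        lesion = np.zeros((8, 8, 8))
        lesion[0, 0, 0] = 1
        f = compute_overlap(LesionMask("s", grid8, lesion), atlas)
        with pytest.raises(ValueError, match="duplicated"):
            build_design_matrix([f, f], atlas)


class TestExclusionRuleProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        lesion_pct=st.floats(0.0, 100.0),
        parcel_pct=st.floats(0.0, 100.0),
        threshold=st.floats(0.0, 50.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_retention_is_exactly_the_or_rule(self, lesion_pct, parcel_pct, threshold):
        f = OverlapFeatures("s", {1: lesion_pct}, {1: parcel_pct})
        apply_exclusion(f, threshold)
        assert (1 in f.retained) == (lesion_pct >= threshold or parcel_pct >= threshold)


class TestOverlapProperties:
    def test_translation_equivariance(self, grid8, rng):
        labels = rng.integers(0, 3, size=(8, 8, 8)).astype(np.int32)
        labels[:2, :2, :2] = 1
        lesion = np.zeros((8, 8, 8))
        lesion[1:3, 1:3, 1:3] = 1
        f0 = compute_overlap(LesionMask("s", grid8, lesion), _atlas(grid8, labels))
        shift = (2, 1, 3)
        f1 = compute_overlap(
            LesionMask("s", grid8, np.roll(lesion, shift, axis=(0, 1, 2))),
            _atlas(grid8, np.roll(labels, shift, axis=(0, 1, 2))),
        )
        assert f0.lesion_pct == pytest.approx(f1.lesion_pct)
        assert f0.parcel_pct == pytest.approx(f1.parcel_pct)

    def test_parcel_split_additivity(self, grid8, rng):
        # splitting a parcel in two makes the halves' lesion_pct sum to the whole
        labels = np.ones((8, 8, 8), dtype=np.int32)
        split = labels.copy()
        split[4:] = 2
        lesion = (rng.random((8, 8, 8)) > 0.6).astype(float)
        lesion[0, 0, 0] = 1
        m = LesionMask("s", grid8, lesion)
        whole = compute_overlap(m, _atlas(grid8, labels))
        halves = compute_overlap(m, _atlas(grid8, split))
        assert halves.lesion_pct[1] + halves.lesion_pct[2] == pytest.approx(
            whole.lesion_pct[1]
        )
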