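import numpy as np
import pytest

from t2mvpa.preprocess import (BrainVolume, EpiSeries, ROIMask, TissueClass,
                               TissuePartialVolumes, consensus_segmentation,
                               extract_features, normalize_volume,
                               split_roi_coronal, subsample_volume,
                               temporal_average)
from t2mvpa.simulate import DEFAULT_BLOCK_SCHEDULE, CohortConfig

VS = (1.0, 1.0, 1.0)


def vol(data):
    return BrainVolume(np.asarray(data, dtype=float), VS)


def full_mask(shape, name="brain"):
    return ROIMask(np.ones(shape, dtype=bool), name)


class TestNormalize:
    def test_constant_volume_becomes_one(self):
        v = vol(np.full((4, 4, 4), 7.0))
        out = normalize_volume(v, full_mask((4, 4, 4)))
        assert np.allclose(out.data, 1.0)

    def test_two_voxel_hand_example(self):
        data = np.zeros((2, 1, 1))
        data[:, 0, 0] = [2.0, 4.0]
        out = normalize_volume(vol(data), full_mask((2, 1, 1)))
        assert np.allclose(out.data[:, 0, 0], [2 / 3, 4 / 3])
        assert out.data.mean() == pytest.approx(1.0)

    def test_idempotence(self, rng):
        data = rng.uniform(1, 2, size=(5, 5, 4))
        mask = full_mask((5, 5, 4))
        once = normalize_volume(vol(data), mask)
        twice = normalize_volume(once, mask)
        assert np.allclose(twice.data, once.data)
        assert once.data[mask.data].mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        v = vol(np.full((3, 3, 3), -1.0))
        with pytest.raises(ValueError, match="mean"):
            normalize_volume(v, full_mask((3, 3, 3)))


def make_series(data, labels):
    return EpiSeries("s01", np.asarray(data, dtype=float), VS,
                     np.asarray(labels))


class TestTemporalAverage:
    def test_constant_series_equals_single_normalized_volume(self, rng):
        frame = rng.uniform(1, 2, size=(4, 4, 3))
        series = make_series(np.repeat(frame[..., None], 5, axis=3),
                             ["A"] * 5)
        mask = full_mask((4, 4, 3))
        avg = temporal_average(series, {"A"}, mask)
        single = normalize_volume(vol(frame), mask)
        assert np.allclose(avg.volume.data, single.data)
        assert avg.n_volumes == 5

    def test_default_schedule_game_play_gives_480_volumes(self, rng):
        cfg = CohortConfig()
        labels = cfg.block_labels()
        data = rng.uniform(1, 2, size=(4, 4, 4, labels.size))
        series = make_series(data, labels)
        avg = temporal_average(series, {"SF", "SO"}, full_mask((4, 4, 4)))
        assert avg.n_volumes == 480

    def test_oddball_selection_uses_only_ob_timepoints(self, rng):
        labels = CohortConfig().block_labels()
        data = rng.uniform(1, 2, size=(4, 4, 4, labels.size))
        series = make_series(data, labels)
        avg = temporal_average(series, {"OB"}, full_mask((4, 4, 4)))
        assert avg.n_volumes == 2 * 120

    def test_order_invariance(self, rng):
        labels = np.array(["A", "B", "A", "B", "A"])
        data = rng.uniform(1, 2, size=(3, 3, 3, 5))
        mask = full_mask((3, 3, 3))
        base = temporal_average(make_series(data, labels), {"A"}, mask)
        perm = np.array([4, 2, 0, 1, 3])
        shuffled = temporal_average(
            make_series(data[..., perm], labels[perm]), {"A"}, mask)
        assert np.allclose(base.volume.data, shuffled.volume.data)

    def test_empty_selection_rejected(self, rng):
        series = make_series(rng.uniform(1, 2, size=(3, 3, 3, 4)),
                             ["A"] * 4)
        with pytest.raises(ValueError, match="no timepoints"):
            temporal_average(series, {"Z"}, full_mask((3, 3, 3)))


class TestExtractFeatures:
    def test_shape_and_voxel_order(self, rng):
        shape = (4, 4, 3)
        mask_data = rng.random(shape) > 0.5
        mask_data[0, 0, 0] = True
        roi = ROIMask(mask_data, "roi")
        vols = [vol(rng.normal(size=shape)) for _ in range(5)]
        fm = extract_features(vols, roi)
        assert fm.values.shape == (5, roi.n_voxels)
        # column order is the C-order scan of the ROI
        coords = np.argwhere(mask_data)
        assert np.array_equal(fm.voxel_index, coords)
        for j, (x, y, z) in enumerate(coords[:10]):
            assert fm.values[2, j] == vols[2].data[x, y, z]

    def test_single_voxel_roi(self, rng):
        shape = (3, 3, 3)
        m = np.zeros(shape, dtype=bool)
        m[1, 2, 0] = True
        vols = [vol(rng.normal(size=shape)) for _ in range(3)]
        fm = extract_features(vols, ROIMask(m, "one"))
        assert np.allclose(fm.values[:, 0], [v.data[1, 2, 0] for v in vols])

    def test_subject_order_contract(self, rng):
        shape = (3, 3, 3)
        vols = [vol(rng.normal(size=shape)) for _ in range(4)]
        roi = full_mask(shape, "roi")
        base = extract_features(vols, roi, ["a", "b", "c", "d"])
        perm = [2, 0, 3, 1]
        permed = extract_features([vols[i] for i in perm], roi,
                                  [base.subject_ids[i] for i in perm])
        assert np.allclose(permed.values, base.values[perm])

    def test_grid_mismatch_names_subject(self, rng):
        vols = [vol(rng.normal(size=(3, 3, 3))),
                vol(rng.normal(size=(4, 3, 3)))]
        with pytest.raises(ValueError, match="bad_subj"):
            extract_features(vols, full_mask((3, 3, 3)), ["ok", "bad_subj"])


def tpv(wm, gm, csf, shape=(1, 1, 1)):
    mk = lambda v: np.full(shape, float(v))
    return TissuePartialVolumes(mk(wm), mk(gm), mk(csf))


class TestConsensusSegmentation:
    def test_majority_rule(self):
        labels = consensus_segmentation([tpv(0.6, 0.3, 0.1)])
        assert labels.data[0, 0, 0] == TissueClass.WM

    def test_strict_threshold_boundary(self):
        labels = consensus_segmentation([tpv(0.5, 0.4, 0.1)])
        assert labels.data[0, 0, 0] == TissueClass.UNASSIGNED

    def test_averaging_across_subjects(self):
        # WM fractions 0.9 and 0.2 average to 0.55 -> consensus WM
        labels = consensus_segmentation([tpv(0.9, 0.0, 0.0),
                                         tpv(0.2, 0.0, 0.0)])
        assert labels.data[0, 0, 0] == TissueClass.WM

    def test_labels_partition_and_respect_threshold(self, rng):
        shape = (6, 6, 4)
        maps = []
        for _ in range(5):
            raw = rng.dirichlet([1.0, 1.0, 1.0, 0.8], size=shape)
            maps.append(TissuePartialVolumes(raw[..., 0], raw[..., 1],
                                             raw[..., 2]))
        labels = consensus_segmentation(maps)
        mean = {TissueClass.WM: np.mean([m.wm for m in maps], axis=0),
                TissueClass.GM: np.mean([m.gm for m in maps], axis=0),
                TissueClass.CSF: np.mean([m.csf for m in maps], axis=0)}
        for tissue, frac in mean.items():
            assert np.all(frac[labels.data == tissue] > 0.5)
        unassigned = labels.data == TissueClass.UNASSIGNED
        stacked = np.stack(list(mean.values()))
        assert np.all(stacked[:, unassigned] <= 0.5)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            tpv(0.8, 0.8, 0.0)


class TestSplitRoiCoronal:
    def test_symmetric_roi_splits_equally(self):
        m = np.zeros((4, 6, 4), dtype=bool)
        m[1:3, 1:5, 1:3] = True
        ant, post = split_roi_coronal(ROIMask(m, "roi"))
        assert ant.n_voxels == post.n_voxels
        assert not np.any(ant.data & post.data)
        assert np.array_equal(ant.data | post.data, m)

    def test_single_column_splits_five_five(self):
        m = np.zeros((1, 10, 1), dtype=bool)
        m[0, :, 0] = True
        ant, post = split_roi_coronal(ROIMask(m, "col"))
        assert ant.n_voxels == post.n_voxels == 5
        # +y is anterior: the anterior mask holds the larger y indices
        assert ant.data[0, 9, 0] and post.data[0, 0, 0]

    def test_uneven_slices_brute_force_example(self):
        # slice populations 1,1,5 anterior-to-posterior: best split keeps
        # the two sparse anterior slices together (|2-5| beats |1-6|)
        m = np.zeros((5, 3, 1), dtype=bool)
        m[0:5, 0, 0] = True      # y=0, most posterior, 5 voxels
        m[0, 1, 0] = True
        m[0, 2, 0] = True
        ant, post = split_roi_coronal(ROIMask(m, "roi"))
        assert ant.n_voxels == 2 and post.n_voxels == 5

    def test_single_slice_unsplittable(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[:, 1, :] = True
        with pytest.raises(ValueError, match="single coronal slice"):
            split_roi_coronal(ROIMask(m, "thin"))


class TestSubsample:
    def test_constant_volume_stays_constant(self):
        v = BrainVolume(np.full((8, 8, 8), 3.0), (1.0, 1.0, 1.0))
        out = subsample_volume(v, (4, 4, 4), (2.0, 2.0, 2.0))
        assert np.allclose(out.data, 3.0)
        assert out.voxel_size == (2.0, 2.0, 2.0)

    def test_block_mean_hand_example(self):
        v = BrainVolume(np.arange(1, 9, dtype=float).reshape(2, 2, 2),
                        (1.0, 1.0, 1.0))
        out = subsample_volume(v, (1, 1, 1), (2.0, 2.0, 2.0))
        assert out.data[0, 0, 0] == pytest.approx(4.5)

    def test_identity_grid(self, rng):
        data = rng.normal(size=(4, 5, 6))
        v = BrainVolume(data, (1.0, 1.0, 1.0))
        out = subsample_volume(v, (4, 5, 6), (1.0, 1.0, 1.0))
        assert np.array_equal(out.data, data)

    def test_mean_preserved_on_nesting_grids(self, rng):
        data = rng.normal(size=(8, 6, 4))
        v = BrainVolume(data, (1.0, 1.0, 1.0))
        out = subsample_volume(v, (4, 3, 2), (2.0, 2.0, 2.0))
        assert out.data.mean() == pytest.approx(data.mean())

    def test_bad_target_rejected(self):
        v = BrainVolume(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            subsample_volume(v, (0, 2, 2), (2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            subsample_volume(v, (3, 2, 2), (1.5, 2.0, 2.0))
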