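"""Focal Tversky loss, vote-tile geometry, majority voting and segmentation."""

import numpy as np
import pytest

from itmt.agreement import dice
from itmt.segmentation import (
    FilterBankSegmenter,
    OracleSegmenter,
    SegmentationConfig,
    TverskyParams,
    VoteGrid,
    fit_toy_segmenter,
    focal_tversky_loss,
    majority_vote,
    make_vote_tiles,
    segment_muscles,
    split_left_right,
)
from skimage.transform import resize


class TestFocalTversky:
    def test_perfect_prediction_near_zero(self):
        truth = np.zeros((16, 16))
        truth[4:8, 4:8] = 1
        assert focal_tversky_loss(truth, truth) < 1e-6

    def test_all_background_prediction_near_one(self):
        truth = np.zeros((16, 16))
        truth[4:8, 4:8] = 1
        assert focal_tversky_loss(np.zeros_like(truth), truth) > 0.99

    def test_reduces_to_soft_dice_at_symmetric_params(self):
        # algebraic identity: alpha=beta=0.5, gamma=1 -> 1 - soft Dice
        rng = np.random.default_rng(0)
        params = TverskyParams(alpha=0.5, beta=0.5, gamma=1.0)
        for _ in range(50):
            p = rng.uniform(size=(12, 12))
            t = (rng.uniform(size=(12, 12)) < 0.3).astype(float)
            eps = 1e-6
            soft_dice = (2 * (p * t).sum() + 2 * eps) / (p.sum() + t.sum() + 2 * eps)
            assert focal_tversky_loss(p, t, params) == pytest.approx(1 - soft_dice, abs=1e-9)

    def test_nonincreasing_towards_truth(self):
        rng = np.random.default_rng(1)
        t = (rng.uniform(size=(10, 10)) < 0.4).astype(float)
        p0 = rng.uniform(size=(10, 10))
        prev = np.inf
        for lam in np.linspace(0, 1, 11):
            loss = focal_tversky_loss((1 - lam) * p0 + lam * t, t)
            assert loss <= prev + 1e-12
            prev = loss

    def test_bounded_and_guards(self):
        t = np.ones((4, 4))
        assert 0.0 <= focal_tversky_loss(np.full((4, 4), 0.5), t) <= 1.0
        with pytest.raises(ValueError):
            focal_tversky_loss(np.zeros((3, 3)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            TverskyParams(gamma=0.0)


class TestVoteTiles:
    def test_zero_shift_covers_four_times(self):
        layout = make_vote_tiles((10, 90, 10, 90), 100, (100, 100), shift=0)
        cov = layout.coverage((100, 100))
        assert np.all(cov[10:90, 10:90] == 4)

    def test_maximal_shift_coverage_counted_exhaustively(self):
        # tile 80, roi 64: admissible shift up to (80-64)/2 = 8 < 80/8=10
        layout = make_vote_tiles((18, 82, 18, 82), 80, (100, 100), shift=8)
        cov = layout.coverage((100, 100))
        assert cov[18:82, 18:82].min() >= 3

    def test_unsatisfiable_geometry_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            make_vote_tiles((10, 90, 10, 90), 60, (100, 100), shift=7)

    def test_oversized_shift_rejected(self):
        with pytest.raises(ValueError, match="shift"):
            make_vote_tiles((40, 60, 40, 60), 64, (100, 100), shift=20)


class TestMajorityVote:
    def test_vote_rules(self):
        pos = np.array([[3, 2, 4, 0]])
        tot = np.full((1, 4), 4)
        out = majority_vote(VoteGrid(pos, tot))
        np.testing.assert_array_equal(out.data, [[1, 0, 1, 0]])  # ties negative

    def test_unanimous_equals_single_prediction(self):
        rng = np.random.default_rng(2)
        single = (rng.uniform(size=(8, 8)) < 0.5).astype(np.int32)
        grid = VoteGrid(single * 4, np.full((8, 8), 4))
        np.testing.assert_array_equal(majority_vote(grid).data, single.astype(bool))

    def test_insufficient_votes_rejected(self):
        grid = VoteGrid(np.ones((4, 4), int), np.full((4, 4), 2))
        with pytest.raises(ValueError, match="3 votes"):
            majority_vote(grid, roi=(0, 4, 0, 4))

    def test_invariant_to_tile_order(self):
        # accumulating the same tile predictions in any order gives one grid
        rng = np.random.default_rng(3)
        preds = [(rng.uniform(size=(20, 20)) < 0.5).astype(np.int32) for _ in range(4)]
        ref = None
        for order in ([0, 1, 2, 3], [3, 1, 0, 2]):
            pos = np.zeros((20, 20), np.int32)
            for k in order:
                pos += preds[k]
            out = majority_vote(VoteGrid(pos, np.full((20, 20), 4)))
            if ref is None:
                ref = out.data
            np.testing.assert_array_equal(out.data, ref)


class TestSplitLeftRight:
    def test_two_blobs_one_per_side(self):
        mask = np.zeros((256, 64), bool)
        mask[40:60, 20:40] = True
        mask[190:210, 20:40] = True
        low, high = split_left_right(mask)
        assert low[40:60].any() and not low[190:210].any()
        assert high[190:210].any() and not high[40:60].any()

    def test_single_blob_one_side_empty(self):
        mask = np.zeros((100, 50), bool)
        mask[10:20, 10:20] = True
        low, high = split_left_right(mask)
        assert low.any() and not high.any()

    def test_mirror_swaps_sides_exactly(self):
        rng = np.random.default_rng(4)
        mask = np.zeros((64, 32), bool)
        mask[5:15, 10:20] = rng.uniform(size=(10, 10)) < 0.7
        mask[50:60, 5:15] = rng.uniform(size=(10, 10)) < 0.7
        low, high = split_left_right(mask)
        m_low, m_high = split_left_right(mask[::-1])
        np.testing.assert_array_equal(m_low, high[::-1])
        np.testing.assert_array_equal(m_high, low[::-1])

    def test_radiological_convention_swaps_labels(self):
        mask = np.zeros((100, 50), bool)
        mask[10:20, 10:20] = True
        left_n, right_n = split_left_right(mask, radiological=False)
        left_r, right_r = split_left_right(mask, radiological=True)
        np.testing.assert_array_equal(left_n, right_r)
        np.testing.assert_array_equal(right_n, left_r)


def phantom_slice_and_truth(phantom, dz=0):
    z = phantom["z0"] + dz
    img = phantom["vol"].data[:, :, z]
    truth = (phantom["left"].data[:, :, z] | phantom["right"].data[:, :, z])
    return img, truth


class TestSegmentMuscles:
    @pytest.fixture()
    def oracle_setup(self, preprocessed_phantom):
        img, truth = phantom_slice_and_truth(preprocessed_phantom)
        S = 512
        prob = resize(truth.astype(float), (S, S), order=0, preserve_range=True)
        return img, truth, prob

    def test_oracle_probabilities_give_dice_one(self, oracle_setup, preprocessed_phantom):
        img, truth, prob = oracle_setup
        sides = segment_muscles(img, OracleSegmenter(prob))
        pred = sides.left.data | sides.right.data
        assert dice(pred, truth) == pytest.approx(1.0, abs=0.02)
        assert sides.flags == []

    def test_voting_denoises_flipped_probabilities(self, oracle_setup):
        img, truth, prob = oracle_setup
        sides = segment_muscles(img, OracleSegmenter(prob, noise_flip_frac=0.10, seed=5))
        pred = sides.left.data | sides.right.data
        assert dice(pred, truth) >= 0.95

    def test_erased_muscles_flagged_not_raised(self, preprocessed_phantom):
        img, _ = phantom_slice_and_truth(preprocessed_phantom)
        sides = segment_muscles(img, OracleSegmenter(np.zeros((512, 512))))
        assert sides.left is None and sides.right is None
        assert set(sides.flags) == {"left_missing", "right_missing"}

    def test_mask_export_nifti_and_overlay(self, oracle_setup, tmp_path):
        from itmt.imaging_io import load_volume
        from itmt.segmentation import save_mask_nifti, save_overlay_png

        img, truth, prob = oracle_setup
        sides = segment_muscles(img, OracleSegmenter(prob))
        nii = tmp_path / "left.nii.gz"
        save_mask_nifti(sides.left, nii)
        back = load_volume(nii)
        np.testing.assert_array_equal(back.data[:, :, 0] > 0.5, sides.left.data)
        png = tmp_path / "overlay.png"
        save_overlay_png(img, sides, png)
        assert png.stat().st_size > 0

    def test_mirror_equivariance_with_mirrored_oracle(self, oracle_setup):
        img, truth, prob = oracle_setup
        straight = segment_muscles(img, OracleSegmenter(prob))
        mirrored = segment_muscles(img[::-1], OracleSegmenter(prob[::-1]))
        np.testing.assert_array_equal(mirrored.left.data, straight.right.data[::-1])
        np.testing.assert_array_equal(mirrored.right.data, straight.left.data[::-1])


class TestToySegmenterTraining:
    def test_overfits_phantom_slices(self, toy_models):
        _, seg = toy_models
        assert seg.train_dice_ >= 0.8

    def test_loss_mostly_decreasing(self, toy_models):
        _, seg = toy_models
        loss = np.asarray(seg.loss_curve_)
        assert loss[-1] < loss[0]
        # smoothed curve decreases in >= 80% of steps
        kernel = np.ones(3) / 3
        smooth = np.convolve(loss, kernel, mode="valid")
        frac_down = np.mean(np.diff(smooth) < 0)
        assert frac_down >= 0.8

    def test_zero_epoch_training_leaves_init(self, preprocessed_phantom):
        img, truth = phantom_slice_and_truth(preprocessed_phantom)
        imgs, masks = [img] * 8, [truth] * 8
        a = FilterBankSegmenter(input_size=128, epochs=0, seed=9)
        a.fit(imgs, masks)
        b = FilterBankSegmenter(input_size=128, epochs=0, seed=9)
        b.fit(imgs, masks)
        np.testing.assert_array_equal(a.weights_, b.weights_)
        assert len(a.loss_curve_) == 0

    def test_too_few_pairs_rejected(self, preprocessed_phantom):
        img, truth = phantom_slice_and_truth(preprocessed_phantom)
        with pytest.raises(ValueError, match=">= 8"):
            fit_toy_segmenter(FilterBankSegmenter(), [img] * 4, [truth] * 4)

    def test_save_load_roundtrip(self, toy_models, tmp_path):
        _, seg = toy_models
        path = tmp_path / "seg.npz"
        seg.save(path)
        back = FilterBankSegmenter.load(path)
        rng = np.random.default_rng(6)
        img = rng.uniform(size=(128, 128))
        np.testing.assert_allclose(back.predict_probs(img), seg.predict_probs(img))
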