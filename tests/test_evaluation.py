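"""DICE, correlation sampling, VOI statistics and bias atlases."""
import numpy as np
import pandas as pd
import pytest

from sinusmrac.evaluation import (
    bias_atlas,
    bone_masks_for_dice,
    dice,
    sample_correlations,
    sinus_subvolume,
    voi_mean_mu,
    voi_rel_diff,
)
from sinusmrac.mumap import MuMap, TissueLabel, assign_mu
from sinusmrac.volume_io import GridMismatchError, VolumeGrid


def grid(data, spacing=(2.0, 2.0, 2.0)):
    return VolumeGrid(np.asarray(data, dtype=float), spacing)


class TestDice:
    def test_identical_nonempty(self):
        m = grid(np.eye(4)[None].repeat(4, 0)[:, :4, :4])
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4)); a[0] = 1
        b = np.zeros((4, 4, 4)); b[2] = 1
        assert dice(grid(a), grid(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4)); a[0, 0, :4] = 1
        b = np.zeros((4, 4, 4)); b[0, 0, 2:4] = 1; b[1, 1, :2] = 1
        assert dice(grid(a), grid(b)) == 0.5  # 2*2 / (4+4)

    def test_both_empty_is_perfect_agreement(self):
        z = grid(np.zeros((3, 3, 3)))
        assert dice(z, z) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = grid((rng.random((6, 6, 6)) < 0.4).astype(float))
        b = grid((rng.random((6, 6, 6)) < 0.4).astype(float))
        assert dice(a, b) == dice(b, a)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            dice(grid(np.zeros((3, 3, 3))), grid(np.zeros((4, 4, 4))))


class TestBoneMasks:
    def make_mumap(self, mu_values):
        mu = grid(mu_values)
        labels = mu.like(np.full(mu.shape, int(TissueLabel.CT_DERIVED), np.int16))
        return MuMap(mu, labels)

    def test_class_values_split_at_threshold(self):
        mu = np.full((2, 2, 2), 0.100)
        mu[0, 0, 0] = 0.151
        ct = grid(np.zeros((2, 2, 2)))
        _, mrac_mask = bone_masks_for_dice(ct, self.make_mumap(mu))
        assert mrac_mask.data[0, 0, 0] == 1       # bone class is in
        assert mrac_mask.data[1, 1, 1] == 0       # bulk 0.100 stays out

    def test_ct_threshold_is_strict(self):
        ct_vals = np.full((2, 2, 2), 157.0)
        ct_vals[0, 0, 0] = 157.1
        ct_mask, _ = bone_masks_for_dice(grid(ct_vals), self.make_mumap(np.zeros((2, 2, 2))))
        assert ct_mask.data[0, 0, 0] == 1
        assert ct_mask.data.sum() == 1            # exactly 157 is excluded

    def test_all_soft_head_gives_empty_masks(self):
        ct = grid(np.zeros((3, 3, 3)))
        masks = bone_masks_for_dice(ct, self.make_mumap(np.full((3, 3, 3), 0.096)))
        assert masks[0].data.sum() == 0 and masks[1].data.sum() == 0


class TestSinusSubvolume:
    def test_default_range_measures_42_mm(self):
        v = grid(np.zeros((96, 96, 96)))
        sub = sinus_subvolume(v)
        assert sub.shape[2] == 21
        assert sub.shape[2] * sub.spacing[2] == pytest.approx(42.0)  # 4.2 cm

    def test_single_slice(self):
        v = grid(np.arange(4 * 4 * 6, dtype=float).reshape(4, 4, 6))
        sub = sinus_subvolume(v, (3, 3))
        np.testing.assert_array_equal(sub.data[..., 0], v.data[..., 2])

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            sinus_subvolume(grid(np.zeros((4, 4, 96))), (70, 50))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sinus_subvolume(grid(np.zeros((4, 4, 40))), (50, 70))


class TestSampleCorrelations:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.a = grid(rng.random((12, 12, 12)))
        self.mask = grid(np.ones((12, 12, 12)))

    def test_identical_volumes_give_r_one(self):
        rs = sample_correlations(self.a, self.a, self.mask, n_vox=50, n_reps=10)
        np.testing.assert_allclose(rs, 1.0)

    def test_negative_affine_gives_r_minus_one(self):
        b = self.a.like(-self.a.data + 0.5)
        rs = sample_correlations(self.a, b, self.mask, n_vox=50, n_reps=10)
        np.testing.assert_allclose(rs, -1.0)

    def test_seeded_determinism_and_bounds(self):
        b = self.a.like(self.a.data + np.random.default_rng(2).normal(0, 0.3, self.a.shape))
        r1 = sample_correlations(self.a, b, self.mask, n_vox=40, n_reps=20, seed=5)
        r2 = sample_correlations(self.a, b, self.mask, n_vox=40, n_reps=20, seed=5)
        np.testing.assert_array_equal(r1, r2)
        assert np.all(r1 >= -1) and np.all(r1 <= 1)

    def test_constant_side_yields_nan(self):
        b = self.a.like(np.full(self.a.shape, 0.1))
        rs = sample_correlations(self.a, b, self.mask, n_vox=30, n_reps=5)
        assert np.isnan(rs).all()

    def test_small_mask_rejected(self):
        tiny = self.mask.like(np.zeros(self.mask.shape))
        with pytest.raises(ValueError, match="need"):
            sample_correlations(self.a, self.a, tiny, n_vox=10)

    def test_spread_narrows_with_larger_draws(self):
        rng = np.random.default_rng(3)
        b = self.a.like(self.a.data + rng.normal(0, 0.5, self.a.shape))
        iqr = []
        for n_vox in (20, 200):
            rs = sample_correlations(self.a, b, self.mask, n_vox=n_vox,
                                     n_reps=60, seed=1)
            iqr.append(np.subtract(*np.percentile(rs, [75, 25])))
        assert iqr[1] < iqr[0]


class TestVoiMeanMu:
    def test_uniform_region(self):
        mu = grid(np.full((4, 4, 4), 0.100))
        voi = mu.like(np.ones((4, 4, 4)))
        assert voi_mean_mu(mu, voi) == pytest.approx(0.100)

    def test_half_air_half_soft(self):
        data = np.zeros((2, 2, 2))
        data[1] = 0.096
        mu = grid(data)
        assert voi_mean_mu(mu, mu.like(np.ones((2, 2, 2)))) == pytest.approx(0.048)

    def test_accepts_mumap(self):
        labels = VolumeGrid(np.full((2, 2, 2), int(TissueLabel.BULK_SINUS)), (2, 2, 2))
        m = assign_mu(labels)
        assert voi_mean_mu(m, m.mu.like(np.ones((2, 2, 2)))) == pytest.approx(0.100)

    def test_empty_voi_rejected(self):
        mu = grid(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            voi_mean_mu(mu, mu.like(np.zeros((2, 2, 2))))


class TestVoiRelDiff:
    def setup_method(self):
        rng = np.random.default_rng(4)
        self.pet = grid(rng.uniform(1, 5, (10, 10, 10)))
        labels = np.zeros((10, 10, 10), int)
        labels[:5] = 1
        labels[5:, :5] = 2
        labels[5:, 5:] = 3
        self.labels = self.pet.like(labels.astype(float))
        gm = np.ones((10, 10, 10))
        gm[labels == 3] = 0.1   # VOI 3 entirely below the GM threshold
        self.gm = self.pet.like(gm)

    def test_identical_inputs_give_zero_rows(self):
        df = voi_rel_diff(self.pet, self.pet, self.labels, self.gm)
        assert set(df["voi"]) == {1, 2}
        np.testing.assert_allclose(df["rel_diff"], 0.0)

    def test_scaling_shifts_every_row_exactly(self):
        scaled = self.pet.like(self.pet.data * 1.05)
        df = voi_rel_diff(scaled, self.pet, self.labels, self.gm)
        np.testing.assert_allclose(df["rel_diff"], 0.05)

    def test_subthreshold_voi_absent(self):
        df = voi_rel_diff(self.pet, self.pet, self.labels, self.gm)
        assert 3 not in set(df["voi"])

    def test_zero_reference_yields_nan_sentinel(self):
        zero_ref = self.pet.like(np.zeros(self.pet.shape))
        df = voi_rel_diff(self.pet, zero_ref, self.labels, self.gm)
        assert df["rel_diff"].isna().all()


class TestBiasAtlas:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.ref = grid(rng.uniform(1, 2, (8, 8, 8)))
        mask = np.zeros((8, 8, 8))
        mask[2:6, 2:6, 2:6] = 1
        self.mask = self.ref.like(mask)

    def test_identical_pair_is_zero_inside_mask(self):
        atlas = bias_atlas([(self.ref, self.ref)], self.mask)
        inside = self.mask.data > 0
        np.testing.assert_allclose(atlas.data[inside], 0.0)
        assert np.isnan(atlas.data[~inside]).all()

    def test_opposite_biases_cancel(self):
        up = self.ref.like(self.ref.data * 1.1)
        down = self.ref.like(self.ref.data * 0.9)
        atlas = bias_atlas([(up, self.ref), (down, self.ref)], self.mask)
        inside = self.mask.data > 0
        np.testing.assert_allclose(atlas.data[inside], 0.0, atol=1e-12)

    def test_uniform_two_percent_bias(self):
        up = self.ref.like(self.ref.data * 1.02)
        atlas = bias_atlas([(up, self.ref)], self.mask)
        inside = self.mask.data > 0
        np.testing.assert_allclose(atlas.data[inside], 0.02, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            bias_atlas([], self.mask)
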