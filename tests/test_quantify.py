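"""Flat-field, background correction, masking and the f/b statistic."""

import numpy as np
import pytest

from qlisa.quantify import (
    EmptyMaskError,
    ImagePair,
    background_correct,
    binarize_epi,
    measure_band,
    measure_fov,
    pseudo_flat_field,
    rfu_per_bead_area,
)
from qlisa.simulate import render_fov


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestPseudoFlatField:
    @pytest.mark.parametrize("method", ["polynomial", "gaussian"])
    def test_uniform_image_is_fixed_point(self, method):
        img = np.full((64, 80), 37.0)
        out = pseudo_flat_field(img, method=method)
        np.testing.assert_allclose(out, img, rtol=1e-9)

    def test_linear_gradient_removed(self):
        # uniform scene under a 0.5 -> 1.5 multiplicative ramp
        base = np.full((100, 120), 200.0)
        ramp = np.linspace(0.5, 1.5, 120)[None, :]
        out = pseudo_flat_field(base * ramp)
        assert np.max(np.abs(out / 200.0 - 1.0)) < 0.02

    def test_gaussian_method_removes_gradient_in_interior(self):
        base = np.full((120, 120), 200.0)
        ramp = np.linspace(0.8, 1.2, 120)[None, :]
        out = pseudo_flat_field(base * ramp, method="gaussian")
        interior = out[30:-30, 30:-30]
        assert np.max(np.abs(interior / 200.0 - 1.0)) < 0.05

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(10, 20, (50, 60))
        np.testing.assert_array_equal(
            pseudo_flat_field(img), pseudo_flat_field(img)
        )

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError):
            pseudo_flat_field(np.zeros((10, 10)))

    def test_mean_preserved(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(100, 300, (80, 80))
        out = pseudo_flat_field(img)
        assert out.mean() == pytest.approx(img.mean(), rel=1e-9)


class TestBackgroundCorrect:
    def test_constant_image_goes_to_zero(self):
        img = np.full((40, 40), 7.0)
        np.testing.assert_array_equal(background_correct(img), np.zeros_like(img))

    def test_disk_over_constant_background(self):
        img = np.full((60, 60), 3.0)
        disk = _disk_mask(img.shape, 30, 30, 8)
        img[disk] += 10.0
        out = background_correct(img, mask=disk)
        np.testing.assert_allclose(out[disk], 10.0)
        np.testing.assert_allclose(out[~disk], 0.0)

    def test_zero_background_unchanged(self):
        img = np.zeros((40, 40))
        img[10:20, 10:20] = 5.0
        mask = img > 0
        np.testing.assert_array_equal(background_correct(img, mask=mask), img)

    def test_full_mask_rejected(self):
        with pytest.raises(ValueError):
            background_correct(np.ones((5, 5)), mask=np.ones((5, 5), bool))


class TestBinarizeEpi:
    def test_recovers_ground_truth_mask(self, clean_small_config):
        pair, truth = render_fov(
            clean_small_config, "GFAP", {"GFAP": 1000.0}, seed=5
        )
        mask = binarize_epi(pseudo_flat_field(pair.epi))
        # agreement within a 1-px boundary band around each bead
        disagree = mask ^ truth.mask
        boundary_budget = int(2 * np.pi * truth.radii_px.sum() * 1.5) + 10
        assert disagree.sum() <= boundary_budget

    def test_constant_image_warns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize_epi(np.full((32, 32), 5.0))
        assert not mask.any()

    def test_inverted_polarity_selects_complement(self, clean_small_config):
        pair, truth = render_fov(
            clean_small_config, "GFAP", {"GFAP": 1000.0}, seed=5
        )
        corrected = pseudo_flat_field(pair.epi)
        wrong = binarize_epi(corrected, polarity="beads_bright")
        overlap = (wrong & truth.mask).sum() / max(truth.mask.sum(), 1)
        assert overlap < 0.05


class TestRfuPerBeadArea:
    def test_uniform_signal_identity(self):
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:15] = True  # 100 px
        fluor = np.where(mask, 5.0, 0.0)
        stats = rfu_per_bead_area(mask, {"ch": fluor})
        assert stats.b == 100
        assert stats.f["ch"] == pytest.approx(500.0)
        assert stats.rfu_per_bead_area["ch"] == pytest.approx(5.0)

    def test_off_mask_debris_exactly_ignored(self):
        mask = np.zeros((40, 40), bool)
        mask[5:15, 5:15] = True
        fluor = np.where(mask, 5.0, 0.0)
        with_debris = fluor.copy()
        with_debris[25:32, 25:32] = 1000.0  # 49-px debris blob off mask
        clean = rfu_per_bead_area(mask, {"ch": fluor})
        dirty = rfu_per_bead_area(mask, {"ch": with_debris})
        assert dirty.rfu_per_bead_area["ch"] == clean.rfu_per_bead_area["ch"]

    def test_empty_mask_raises_not_nan(self):
        with pytest.raises(EmptyMaskError):
            rfu_per_bead_area(np.zeros((10, 10), bool), {"ch": np.ones((10, 10))})

    def test_matches_naive_double_loop(self, rng):
        mask = rng.random((12, 14)) > 0.6
        fluor = rng.uniform(0, 100, (12, 14))
        stats = rfu_per_bead_area(mask, {"ch": fluor})
        b, f = 0, 0.0
        for i in range(12):
            for j in range(14):
                if mask[i, j]:
                    b += 1
                    f += fluor[i, j]
        assert stats.b == b
        assert stats.f["ch"] == f

    def test_scale_equivariance(self, rng):
        mask = rng.random((20, 20)) > 0.7
        fluor = np.where(mask, rng.uniform(1, 50, (20, 20)), 0.0)
        base = rfu_per_bead_area(mask, {"ch": fluor}).rfu_per_bead_area["ch"]
        scaled = rfu_per_bead_area(mask, {"ch": 7.5 * fluor}).rfu_per_bead_area["ch"]
        assert scaled == pytest.approx(7.5 * base, rel=1e-12)


class TestMeasureFovAndBand:
    def test_statistic_close_to_ground_truth(self, small_config):
        pair, truth = render_fov(small_config, "GFAP", {"GFAP": 1000.0}, seed=9)
        stats = measure_fov(pair)
        assert stats.rfu_per_bead_area["Qdot585"] == pytest.approx(
            truth.true_rfu_per_bead_area["Qdot585"], rel=0.05
        )

    def test_identical_fovs_have_zero_sem(self, clean_small_config):
        pair, _ = render_fov(clean_small_config, "GFAP", {"GFAP": 500.0}, seed=3)
        bm = measure_band([pair, pair, pair])
        assert bm.sem["Qdot585"] == 0.0

    def test_control_equal_to_measurement_subtracts_to_zero(self, clean_small_config):
        pair, _ = render_fov(clean_small_config, "GFAP", {"GFAP": 500.0}, seed=3)
        bm = measure_band([pair], control_fovs=[pair])
        assert bm.control_subtracted["Qdot585"] == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_channels_rejected(self):
        a = ImagePair(np.ones((8, 8)), {"x": np.ones((8, 8))})
        b = ImagePair(np.ones((8, 8)), {"y": np.ones((8, 8))})
        with pytest.raises(ValueError, match="channel"):
            measure_band([a, b])

    def test_illumination_gradient_changes_statistic_little(self, small_config):
        from qlisa.simulate import SimConfig

        flat = SimConfig.from_dict({**small_config.to_dict(), "illumination": {}})
        pair_g, _ = render_fov(small_config, "GFAP", {"GFAP": 1000.0}, seed=21)
        pair_f, _ = render_fov(flat, "GFAP", {"GFAP": 1000.0}, seed=21)
        v_g = measure_fov(pair_g).rfu_per_bead_area["Qdot585"]
        v_f = measure_fov(pair_f).rfu_per_bead_area["Qdot585"]
        assert abs(v_g / v_f - 1.0) < 0.03
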