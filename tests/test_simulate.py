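"""The generative model: diameters, binding response, rendering, runs."""

import numpy as np
import pytest

from qlisa.device import BeadSpec
from qlisa.simulate import (
    BindingModel,
    SimConfig,
    default_two_plex_config,
    mean_response,
    render_fov,
    render_sizing_projection,
    sample_bead_diameters,
    simulate_multiplex_run,
    simulate_standard_curve_run,
)


class TestSampleBeadDiameters:
    def test_zero_cv_is_constant(self):
        d = sample_bead_diameters(BeadSpec("b", 2.8, 0.0), 5, seed=0)
        np.testing.assert_array_equal(d, np.full(5, 2.8))

    def test_large_sample_mean(self):
        d = sample_bead_diameters(BeadSpec("b", 4.5, 0.05), 10_000, seed=1)
        assert d.mean() == pytest.approx(4.5, rel=0.01)
        assert np.all(np.abs(d - 4.5) <= 3 * 0.05 * 4.5 + 1e-12)

    def test_same_seed_reproduces(self):
        spec = BeadSpec("b", 2.8, 0.03)
        np.testing.assert_array_equal(
            sample_bead_diameters(spec, 100, seed=7),
            sample_bead_diameters(spec, 100, seed=7),
        )


class TestMeanResponse:
    def test_baseline_at_zero(self):
        m = BindingModel(baseline=12.0)
        assert mean_response(0.0, m) == 12.0

    def test_half_saturation(self):
        m = BindingModel(response_max=100.0, k_half=500.0, baseline=10.0, hill=1.0)
        assert mean_response(500.0, m) == pytest.approx(60.0)

    def test_ten_k_half(self):
        m = BindingModel(response_max=110.0, k_half=100.0, baseline=0.0, hill=1.0)
        assert mean_response(1000.0, m) == pytest.approx(100.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            mean_response(-1.0, BindingModel())

    def test_monotone_non_decreasing(self):
        m = BindingModel(hill=1.7)
        cs = np.logspace(-1, 5, 30)
        vals = [mean_response(c, m) for c in cs]
        assert np.all(np.diff(vals) >= 0)


class TestRenderFov:
    def test_degenerate_render_exact_intensity(self):
        # one bead, no noise/debris/illumination: fluorescence inside the
        # disk equals response * crossover gain exactly
        cfg = SimConfig(
            image_shape=(64, 64),
            bead_specs=(BeadSpec("A", 2.8, 0.0, "chA"),),
            channels=("chA",),
            crossover={"chA": {"chA": 1.0}},
            autofluorescence={},
            beads_per_fov=1,
            epi_noise_sd=0.0,
            fluor_noise_sd=0.0,
            fluor_background=0.0,
            bead_brightness_cv=0.0,
            fov_effect_cv=0.0,
            replicate_effect_cv=0.0,
            debris_per_fov=0.0,
            illumination={},
            carryover_fraction=0.0,
        )
        pair, truth = render_fov(cfg, "A", {"A": 2000.0}, seed=0)
        expected = mean_response(2000.0, cfg.binding_model)
        interior = truth.mask & (pair.fluor["chA"] > 0)
        # interior pixels (full coverage) carry exactly the mean response
        vals = pair.fluor["chA"][truth.mask]
        assert np.max(vals) == pytest.approx(expected, rel=1e-12)
        assert truth.true_rfu_per_bead_area["chA"] == pytest.approx(expected)

    def test_fixed_seed_bit_identical(self, small_config):
        p1, t1 = render_fov(small_config, "GFAP", {"GFAP": 500.0}, seed=11)
        p2, t2 = render_fov(small_config, "GFAP", {"GFAP": 500.0}, seed=11)
        np.testing.assert_array_equal(p1.epi, p2.epi)
        for ch in p1.fluor:
            np.testing.assert_array_equal(p1.fluor[ch], p2.fluor[ch])
        np.testing.assert_array_equal(t1.mask, t2.mask)

    def test_true_band_value_increases_with_concentration(self, clean_small_config):
        values = []
        for conc in (0.0, 100.0, 1000.0, 10000.0):
            _, truth = render_fov(
                clean_small_config, "GFAP", {"GFAP": conc}, seed=4
            )
            values.append(truth.true_rfu_per_bead_area["Qdot585"])
        assert np.all(np.diff(values) > 0)

    def test_mask_area_matches_disk_areas(self, clean_small_config):
        _, truth = render_fov(clean_small_config, "GFAP", {"GFAP": 0.0}, seed=8)
        analytic = np.pi * (truth.radii_px**2).sum()
        # ±1 px per bead boundary pixel budget
        budget = 2 * np.pi * truth.radii_px.sum() + len(truth.radii_px)
        assert abs(truth.mask.sum() - analytic) <= budget

    def test_own_channel_dominates(self):
        cfg = default_two_plex_config(seed=0, image_shape=(160, 200), beads_per_fov=25)
        for band in ("IL-6", "GFAP"):
            _, truth = render_fov(
                cfg, band, {"IL-6": 25000.0, "GFAP": 10000.0}, seed=6
            )
            own = cfg.spec_for(band).fluor_channel
            others = [c for c in cfg.channels if c != own]
            for other in others:
                assert (
                    truth.true_rfu_per_bead_area[own]
                    > truth.true_rfu_per_bead_area[other]
                )

    def test_zero_carryover_means_pure_band(self):
        cfg = default_two_plex_config(
            seed=0, image_shape=(160, 200), beads_per_fov=20, carryover_fraction=0.0
        )
        _, truth = render_fov(cfg, "IL-6", {"IL-6": 0.0, "GFAP": 0.0}, seed=2)
        assert set(truth.bead_labels) == {"IL-6"}

    def test_overfull_fov_raises(self):
        cfg = SimConfig(
            image_shape=(48, 48),
            bead_specs=(BeadSpec("A", 2.8, 0.0, "chA"),),
            channels=("chA",),
            crossover={"chA": {"chA": 1.0}},
            autofluorescence={},
            beads_per_fov=500,
            debris_per_fov=0.0,
        )
        with pytest.raises(RuntimeError, match="place"):
            render_fov(cfg, "A", {"A": 0.0}, seed=0)


class TestRuns:
    def test_curve_run_measurement_count(self, small_config):
        out = list(
            simulate_standard_curve_run(
                (10000.0, 5000.0, 1000.0, 500.0, 100.0, 0.0),
                replicates=3,
                config=small_config,
                n_blanks=10,
            )
        )
        assert len(out) == 6 * 3 + 10
        blanks = [m for m in out if m.is_blank]
        assert len(blanks) == 10
        assert all(m.concentration == 0.0 for m in blanks)
        assert all(len(m.fovs) == small_config.n_fov for m in out)

    def test_single_measurement_run(self, small_config):
        out = list(
            simulate_standard_curve_run(
                (500.0,), replicates=1, config=small_config, n_blanks=0
            )
        )
        assert len(out) == 1

    def test_multiplex_bands_in_diameter_order(self):
        cfg = default_two_plex_config(seed=1, image_shape=(160, 200), beads_per_fov=20)
        bands = [
            band
            for band, _, _ in simulate_multiplex_run(
                {"IL-6": 25000.0, "GFAP": 10000.0}, cfg, n_fov=1
            )
        ]
        assert bands == ["IL-6", "GFAP"]

    def test_multiplex_missing_analyte_rejected(self):
        cfg = default_two_plex_config(seed=1, image_shape=(160, 200))
        with pytest.raises(ValueError, match="missing"):
            list(simulate_multiplex_run({"IL-6": 100.0}, cfg))

    def test_all_blank_multiplex_sits_at_baseline(self):
        cfg = default_two_plex_config(
            seed=1,
            image_shape=(160, 200),
            beads_per_fov=20,
            fov_effect_cv=0.0,
            replicate_effect_cv=0.0,
            bead_brightness_cv=0.0,
        )
        for band, meas, _ in simulate_multiplex_run(
            {"IL-6": 0.0, "GFAP": 0.0}, cfg, with_controls=False, n_fov=1
        ):
            own = cfg.spec_for(band).fluor_channel
            truth = meas.truths[0]
            base = cfg.binding_model.baseline
            # own-channel true value = baseline (+ autofluorescence terms
            # contributed by carryover beads only)
            assert truth.true_rfu_per_bead_area[own] <= base * 1.2 + 1e-9
            assert truth.true_rfu_per_bead_area[own] >= base * 0.8


class TestSizingProjection:
    def test_diameters_match_request(self):
        proj, d = render_sizing_projection(
            BeadSpec("b", 2.8, 0.0), 10, seed=0, pixel_size_um=0.1
        )
        np.testing.assert_array_equal(d, np.full(10, 2.8))
        assert proj.max() > 0
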