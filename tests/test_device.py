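"""Channel geometry, trapping and lubrication-flow model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from qlisa.device import (
    BeadSpec,
    ChannelProfile,
    LayoutError,
    TrapStatus,
    band_position,
    capacity,
    design_check,
    flow_rate,
    height_at,
    hydraulic_resistance,
    plan_layout,
    resistance_quadrature_oracle,
)


class TestHeightAt:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 7.583), (20000.0, 2.077), (10000.0, 4.830)],
    )
    def test_linear_profile(self, two_plex_profile, x, expected):
        assert height_at(two_plex_profile, x) == pytest.approx(expected)

    def test_out_of_range_raises(self, two_plex_profile):
        with pytest.raises(ValueError):
            height_at(two_plex_profile, -1.0)
        with pytest.raises(ValueError):
            height_at(two_plex_profile, 20001.0)

    def test_measured_profile_interpolates(self):
        samples = ((0.0, 6.0), (5000.0, 5.0), (20000.0, 2.0))
        p = ChannelProfile(20000, 3000, 6.0, 2.0, kind="measured", samples=samples)
        assert height_at(p, 2500.0) == pytest.approx(5.5)
        assert height_at(p, 12500.0) == pytest.approx(3.5)

    def test_measured_profile_must_be_monotone(self):
        with pytest.raises(ValueError, match="non-increasing"):
            ChannelProfile(
                20000, 3000, 6.0, 2.0, kind="measured",
                samples=((0.0, 6.0), (5000.0, 6.5), (20000.0, 2.0)),
            )


class TestBandPosition:
    def test_trapped_bead_position(self, two_plex_profile):
        # bisection on height_at as an independent inversion oracle
        x, status = band_position(two_plex_profile, 4.5)
        assert status is TrapStatus.TRAPPED
        oracle = optimize.brentq(
            lambda t: height_at(two_plex_profile, t) - 4.5, 0, 20000, xtol=1e-10
        )
        assert x == pytest.approx(oracle, abs=1e-6)
        assert x == pytest.approx(11199, abs=1.0)

    def test_small_bead_passes_through(self, two_plex_profile):
        pos, status = band_position(two_plex_profile, 1.0)
        assert status is TrapStatus.PASSES_THROUGH
        assert pos is None

    def test_inlet_sized_bead_excluded(self, two_plex_profile):
        pos, status = band_position(two_plex_profile, 7.583)
        assert status is TrapStatus.EXCLUDED_AT_INLET
        assert pos == 0.0

    @given(d=st.floats(2.078, 7.582))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_round_trip_height_of_position_is_diameter(self, d):
        p = ChannelProfile(20000.0, 3000.0, 7.583, 2.077)
        x, status = band_position(p, d)
        assert status is TrapStatus.TRAPPED
        assert abs(height_at(p, x) - d) < 1e-9

    @given(
        d1=st.floats(2.1, 7.5),
        d2=st.floats(2.1, 7.5),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_smaller_diameter_traps_further_downstream(self, d1, d2):
        p = ChannelProfile(20000.0, 3000.0, 7.583, 2.077)
        if abs(d1 - d2) < 1e-6:
            return
        lo, hi = sorted((d1, d2))
        x_small, _ = band_position(p, lo)
        x_large, _ = band_position(p, hi)
        assert x_small > x_large


class TestPlanLayout:
    def test_two_bead_panel_feasible(self, two_plex_profile):
        beads = [BeadSpec("IL-6", 4.5), BeadSpec("GFAP", 2.8)]
        layout = plan_layout(two_plex_profile, beads)
        positions = [p.position_um for p in layout.placements]
        assert positions[0] == pytest.approx(11199, abs=1.0)
        assert positions[1] == pytest.approx(17372, abs=2.0)
        (_, _, sep), = layout.separations_um
        assert sep == pytest.approx(6173, abs=3.0)
        assert layout.feasible

    def test_single_bead_no_separations(self, two_plex_profile):
        layout = plan_layout(two_plex_profile, [BeadSpec("GFAP", 2.8)])
        assert layout.separations_um == []
        assert layout.feasible

    def test_duplicate_diameters_rejected(self, two_plex_profile):
        beads = [BeadSpec("A", 4.5), BeadSpec("B", 4.5)]
        with pytest.raises(LayoutError, match="duplicate"):
            plan_layout(two_plex_profile, beads)

    def test_untrapped_bead_flagged(self, two_plex_profile):
        layout = plan_layout(
            two_plex_profile, [BeadSpec("IL-6", 4.5), BeadSpec("IL-8", 1.0)]
        )
        assert not layout.feasible
        assert any("passes through" in v for v in layout.violations)


class TestCapacity:
    @pytest.mark.parametrize(
        "length, bw, sep, expected",
        [(20000, 500, 500, 20), (1000, 500, 500, 1), (20000, 500, 1500, 10)],
    )
    def test_band_count(self, length, bw, sep, expected):
        assert capacity(length, bw, sep) == expected

    def test_non_positive_arguments_rejected(self):
        with pytest.raises(ValueError):
            capacity(0, 500, 500)
        with pytest.raises(ValueError):
            capacity(20000, -1, 500)

    @given(
        bw=st.floats(100, 2000),
        sep=st.floats(100, 2000),
        extra=st.floats(0, 1000),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_capacity_non_increasing_in_spacing(self, bw, sep, extra):
        base = capacity(20000.0, bw, sep)
        assert capacity(20000.0, bw + extra, sep) <= base
        assert capacity(20000.0, bw, sep + extra) <= base


class TestFlowRate:
    def test_uniform_limit_matches_plane_poiseuille(self):
        # uniform channel: closed form reduces to w h^3 dP / (12 mu L)
        h = 2.0
        p = ChannelProfile(20000.0, 3000.0, h, h)
        q = flow_rate(p, 1e4, 1e-3)
        w, L = 3000e-6, 20000e-6
        expected = w * (h * 1e-6) ** 3 * 1e4 / (12 * 1e-3 * L) * 1e9 * 60
        assert q == pytest.approx(expected, rel=1e-12)

    def test_linear_in_pressure(self, two_plex_profile):
        q1 = flow_rate(two_plex_profile, 1e4, 1e-3)
        q2 = flow_rate(two_plex_profile, 2e4, 1e-3)
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_closed_form_matches_quadrature(self, two_plex_profile):
        r = hydraulic_resistance(two_plex_profile, 1e-3)
        oracle = resistance_quadrature_oracle(two_plex_profile, 1e-3)
        assert r == pytest.approx(oracle, rel=1e-9)

    @given(
        hi=st.floats(3.0, 8.0),
        ho=st.floats(1.0, 2.5),
        L=st.floats(5000.0, 30000.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_quadrature_equivalence_random_geometries(self, hi, ho, L):
        p = ChannelProfile(L, 3000.0, hi, ho)
        r = hydraulic_resistance(p, 1e-3)
        oracle = resistance_quadrature_oracle(p, 1e-3)
        assert r == pytest.approx(oracle, rel=1e-9)

    def test_measured_profile_resistance_matches_quadrature(self):
        samples = ((0.0, 7.0), (4000.0, 5.5), (12000.0, 3.0), (20000.0, 2.0))
        p = ChannelProfile(
            20000.0, 3000.0, 7.0, 2.0, kind="measured", samples=samples
        )
        r = hydraulic_resistance(p, 1e-3)
        oracle = resistance_quadrature_oracle(p, 1e-3)
        assert r == pytest.approx(oracle, rel=1e-9)

    def test_outlet_dominates_flow_sensitivity(self):
        # |dlnQ/dln h_o| > |dlnQ/dln h_i| across the geometry range
        for ho in np.linspace(1.0, 2.5, 6):
            for hi in np.linspace(3.0, 8.0, 6):
                def q(hi_, ho_):
                    return flow_rate(
                        ChannelProfile(20000.0, 3000.0, hi_, ho_), 1e4, 1e-3
                    )
                eps = 1e-4
                d_ho = (np.log(q(hi, ho * (1 + eps))) - np.log(q(hi, ho))) / eps
                d_hi = (np.log(q(hi * (1 + eps), ho)) - np.log(q(hi, ho))) / eps
                assert abs(d_ho) > abs(d_hi)


class TestDesignCheck:
    @pytest.mark.parametrize(
        "outlet, n_violations",
        [(0.963, 1), (2.077, 0), (1.5, 0)],
    )
    def test_outlet_height_rule(self, outlet, n_violations):
        p = ChannelProfile(20000.0, 3000.0, 6.342, outlet)
        assert len(design_check(p)) == n_violations
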