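"""Vessel, pit and stomatal trait computations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hydrotrait import anatomy
from hydrotrait.exceptions import InputError

diam_lists = st.lists(st.floats(1.0, 200.0), min_size=1, max_size=30)


class TestHydraulicDiameter:
    @pytest.mark.parametrize(
        "diams, expected",
        [
            ([10, 10, 10], 10.0),
            ([10, 20], ((10**4 + 20**4) / 2) ** 0.25),  # ~17.07
            ([42.5], 42.5),
        ],
    )
    def test_examples(self, diams, expected):
        assert anatomy.hydraulic_diameter(diams) == pytest.approx(expected, rel=1e-12)

    @given(diam_lists)
    def test_power_mean_inequality(self, diams):
        dh = anatomy.hydraulic_diameter(diams)
        assert dh >= np.mean(diams) - 1e-9

    @given(st.floats(1.0, 200.0), st.integers(1, 20))
    def test_identical_vessels(self, d, n):
        assert anatomy.hydraulic_diameter([d] * n) == pytest.approx(d, rel=1e-12)

    def test_empty_raises(self):
        with pytest.raises(InputError):
            anatomy.hydraulic_diameter([])


class TestVesselFrequencyAndConductivity:
    @pytest.mark.parametrize(
        "n, area, expected",
        [(50, 0.5, 100.0), (13, 0.22, 13 / 0.22)],  # 0.22 mm^2 is the 20x field
    )
    def test_vessel_frequency(self, n, area, expected):
        sec = anatomy.VesselSection(vessel_diameters=[10.0] * n, image_area=area)
        assert anatomy.vessel_frequency(sec) == pytest.approx(expected)

    def test_zero_area_raises(self):
        with pytest.raises(InputError):
            anatomy.VesselSection(vessel_diameters=[10.0], image_area=0.0)

    def test_kth_reference_value(self):
        # prefactor pi*rho/(128*eta) ~ 2.445e10; x 1e8 m^-2 x (2e-5 m)^4
        k = anatomy.theoretical_conductivity(100.0, 20.0)
        expected = math.pi * 998.2 / (128 * 1.002e-9) * 1e8 * (2e-5) ** 4
        assert k == pytest.approx(expected, rel=1e-12)
        assert k == pytest.approx(0.3912, rel=1e-3)

    def test_kth_zero_vf(self):
        assert anatomy.theoretical_conductivity(0.0, 20.0) == 0.0

    def test_kth_quartic_law(self):
        k1 = anatomy.theoretical_conductivity(100.0, 15.0)
        k2 = anatomy.theoretical_conductivity(100.0, 30.0)
        assert k2 / k1 == pytest.approx(16.0, rel=1e-12)
        assert anatomy.theoretical_conductivity(200.0, 15.0) / k1 == pytest.approx(2.0)

    def test_kth_nonpositive_dh_raises(self):
        with pytest.raises(InputError):
            anatomy.theoretical_conductivity(100.0, 0.0)

    @given(diam_lists, st.floats(0.05, 5.0))
    def test_kth_equals_per_vessel_poiseuille_sum(self, diams, area):
        """K_th from (VF, D_h) equals the brute-force per-vessel sum.

        (pi rho / 128 eta) * sum(d^4) / area is the Hagen-Poiseuille sum
        over individual vessels; with D_h and VF from the same section the
        two routes are algebraically identical.
        """
        sec = anatomy.VesselSection(vessel_diameters=diams, image_area=area)
        dh = anatomy.hydraulic_diameter(sec)
        vf = anatomy.vessel_frequency(sec)
        k = anatomy.theoretical_conductivity(vf, dh)
        const = anatomy.PhysicalConstants()
        d_m = np.asarray(diams) * 1e-6
        area_m2 = area * 1e-6
        brute = const.poiseuille_prefactor * np.sum(d_m**4) / area_m2
        assert k == pytest.approx(brute, rel=1e-9)


class TestPits:
    def _pits(self, scale=1.0, counts=((10, 200.0), (5, 100.0))):
        s = scale
        return anatomy.PitMorphology(
            d_pml=np.array([4.0, 5.0]) * s, d_pms=np.array([2.0, 5.0]) * s,
            d_pal=np.array([4.0, 2.0]) * s, d_pas=np.array([2.0, 2.0]) * s,
            a_pit=np.array([8.0, 20.0]) * s**2, a_pa=np.array([6.0, 3.0]) * s**2,
            pit_counts=[(n, a * s**2) for n, a in counts],
        )

    def test_circular_pits_unit_ratios(self):
        pits = anatomy.PitMorphology(
            d_pml=[3.0], d_pms=[3.0], d_pal=[1.0], d_pas=[1.0],
            a_pit=[7.0], a_pa=[0.8], pit_counts=[(1, 10.0)],
        )
        s = anatomy.pit_summary(pits)
        assert s.r_pa == 1.0 and s.r_pit == 1.0

    def test_ratio_and_pooled_density(self):
        s = anatomy.pit_summary(self._pits())
        assert s.r_pa == pytest.approx((2.0 + 1.0) / 2)   # per-pit mean of 4/2 and 2/2
        assert s.r_pit == pytest.approx((2.0 + 1.0) / 2)
        assert s.d_p == pytest.approx(15 / 300.0)          # pooled 0.05 um^-2

    def test_ratio_of_means_mode(self):
        s = anatomy.pit_summary(self._pits(), ratio_mode="mean_diameter")
        assert s.r_pa == pytest.approx(np.mean([4, 2]) / np.mean([2, 2]))

    @given(st.floats(0.1, 10.0))
    def test_unit_rescaling(self, scale):
        """Ratios are invariant to length rescaling; areas scale as scale^2."""
        base = anatomy.pit_summary(self._pits(1.0))
        scaled = anatomy.pit_summary(self._pits(scale))
        assert scaled.r_pa == pytest.approx(base.r_pa, rel=1e-9)
        assert scaled.r_pit == pytest.approx(base.r_pit, rel=1e-9)
        assert scaled.a_pit == pytest.approx(base.a_pit * scale**2, rel=1e-9)
        assert scaled.d_p == pytest.approx(base.d_p / scale**2, rel=1e-9)

    def test_invalid_axis_order_raises(self):
        with pytest.raises(InputError):
            anatomy.PitMorphology(
                d_pml=[2.0], d_pms=[3.0], d_pal=[1.0], d_pas=[1.0],
                a_pit=[7.0], a_pa=[0.8],
            )


class TestStomata:
    def _field(self, centroids, w=1000.0, h=1000.0, areas=()):
        return anatomy.StomatalField(
            centroids=centroids, field_width=w, field_height=h, stomatal_areas=areas
        )

    def test_empty_field(self):
        res = anatomy.stomatal_traits(self._field([]))
        assert res.d_s == 0.0
        assert not res.s_s_defined and math.isnan(res.s_s)

    def test_border_counting_rule(self):
        """Interior + top/left-border stomata count; bottom/right discarded."""
        rng = np.random.default_rng(0)
        interior = rng.uniform(50, 950, size=(50, 2))
        top_left = [(0.5, 400), (0.2, 600), (300, 0.4), (700, 0.1)]   # 4 kept
        bottom_right = [(999.8, 300), (500, 999.9), (999.9, 999.9)]   # 3 dropped
        field = self._field(np.vstack([interior, top_left, bottom_right]))
        res = anatomy.stomatal_traits(field, border_tol=1.0)
        assert res.n_counted == 54
        assert res.d_s == pytest.approx(54.0)  # 1 mm^2 field

    def test_density_scales_with_area(self):
        pts = [(100, 100), (200, 200), (300, 300)]
        d_full = anatomy.stomatal_traits(self._field(pts, 1000, 1000)).d_s
        d_half = anatomy.stomatal_traits(self._field(pts, 1000, 500)).d_s
        assert d_half == pytest.approx(2 * d_full)

    @given(st.lists(st.tuples(st.floats(10, 990), st.floats(10, 990)), min_size=1, max_size=40))
    def test_interior_points_match_naive_count(self, pts):
        """Away from all borders the inclusion rule is irrelevant."""
        res = anatomy.stomatal_traits(self._field(pts), border_tol=1.0)
        assert res.n_counted == len(pts)

    def test_stomatal_size_mean(self):
        res = anatomy.stomatal_traits(self._field([(500, 500)], areas=[400.0, 600.0]))
        assert res.s_s == pytest.approx(500.0)


class TestPacking:
    @pytest.mark.parametrize(
        "a_pit, d_p, expected",
        [
            (10.0, 0.1, 1.0),
            (13.29, 0.045, 13.29 * 0.045),    # ~0.598, leaf-scale means
            (174.74, 0.004, 174.74 * 0.004),  # ~0.699, gymnosperm-scale means
        ],
    )
    def test_coverage_fraction(self, a_pit, d_p, expected):
        assert anatomy.packing_position(a_pit, d_p) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_raises(self):
        with pytest.raises(InputError):
            anatomy.packing_position(0.0, 0.1)


class TestEquivalentDiameter:
    def test_area_preserving(self):
        d = anatomy.equivalent_circular_diameter(16.0, 4.0)
        assert d == pytest.approx(8.0)
        # ellipse area pi/4*a*b equals circle area pi/4*d^2
        assert math.pi / 4 * 16 * 4 == pytest.approx(math.pi / 4 * d**2)
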