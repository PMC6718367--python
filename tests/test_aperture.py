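"""Aperture polygons, region metrics and field classification."""

import numpy as np
import pytest
from shapely.geometry import box as shapely_box

from headscatter import (AperturePolygon, JawSetting, MLCBank, classify_category,
                         exposed_mlc_area, mlc_polygon, scatter_interface,
                         split_by_interface)
from headscatter.campaign import cross_bank
from headscatter.geometry import Rect

from conftest import (edge_sum_perimeter, random_aperture, segment_clip_fp_split,
                      shoelace_area)


class TestBank:
    def test_default_millennium_bank_geometry(self):
        bank = MLCBank.retracted()
        assert bank.n_pairs == 60
        assert bank.edges[0] == -20.0 and bank.edges[-1] == 20.0
        widths = np.diff(bank.edges)
        assert np.sum(widths == 0.5) == 40 and np.sum(widths == 1.0) == 20

    def test_square_bank_only_opens_covered_pairs(self):
        bank = MLCBank.square(8.0)
        open_pairs = bank.is_open()
        centers = 0.5 * (bank.edges[:-1] + bank.edges[1:])
        assert np.array_equal(open_pairs, np.abs(centers) < 4.0)

    def test_invalid_tips_rejected(self):
        with pytest.raises(ValueError):
            MLCBank(left=np.full(60, 1.0), right=np.full(60, -1.0))


class TestMlcPolygon:
    def test_full_open_square(self):
        bank = MLCBank(left=np.full(60, -5.0), right=np.full(60, 5.0))
        poly = mlc_polygon(bank, JawSetting.square(10.0), plane_dist=100.0)
        assert poly.area == pytest.approx(100.0, rel=1e-12)
        assert poly.perimeter == pytest.approx(40.0, rel=1e-12)

    def test_all_closed_is_zero_area(self):
        bank = MLCBank(left=np.zeros(60), right=np.zeros(60))
        poly = mlc_polygon(bank, JawSetting.square(10.0))
        assert poly.is_empty and poly.area == 0.0

    def test_cross_shape_matches_shoelace_oracle(self):
        poly = mlc_polygon(cross_bank(15.0), JawSetting.square(15.0))
        # plus-shape: 15 cm span, 5 cm arms -> area 125 cm^2, perimeter 60 cm
        assert poly.area == pytest.approx(125.0, rel=1e-12)
        assert poly.perimeter == pytest.approx(60.0, rel=1e-12)
        assert poly.area == pytest.approx(shoelace_area(poly.geom), rel=1e-12)
        assert poly.perimeter == pytest.approx(edge_sum_perimeter(poly.geom), rel=1e-12)

    def test_projection_scales_metrics(self):
        poly = mlc_polygon(MLCBank.square(8.0), JawSetting.square(12.0))
        scaled = poly.projected(51.0)
        assert scaled.perimeter == pytest.approx(poly.perimeter * 0.51, rel=1e-12)
        assert scaled.area == pytest.approx(poly.area * 0.51 ** 2, rel=1e-12)


class TestExposedArea:
    def test_retracted_and_identical_fields_expose_nothing(self):
        jaw = JawSetting.square(20.0)
        assert exposed_mlc_area(jaw, mlc_polygon(None, jaw)) == 0.0
        full = mlc_polygon(MLCBank.square(20.0), jaw)
        assert exposed_mlc_area(jaw, full) == pytest.approx(0.0, abs=1e-9)

    def test_hand_value_at_mid_mlc_plane(self):
        jaw = JawSetting.square(20.0)
        poly = mlc_polygon(MLCBank.square(10.0), jaw, plane_dist=51.0)
        ma = exposed_mlc_area(jaw, poly)
        assert ma == pytest.approx((400 - 100) * 0.51 ** 2, rel=1e-12)  # 78.03

    def test_violated_containment_raises(self):
        big = AperturePolygon(shapely_box(-20, -20, 20, 20), 100.0)
        with pytest.raises(ValueError):
            exposed_mlc_area(JawSetting.square(10.0), big)


class TestSplitByInterface:
    def test_aperture_strictly_inside_interface(self, geom):
        jaw = JawSetting.square(20.0)
        iface = scatter_interface(geom, jaw.rect())
        poly = mlc_polygon(MLCBank.square(4.0), jaw, plane_dist=geom.smd)
        m = split_by_interface(poly, jaw, iface, geom)
        assert m.fp_in == pytest.approx(poly.perimeter, rel=1e-12)
        assert m.fp_out == pytest.approx(0.0, abs=1e-12)

    def test_aperture_equal_to_interface_ties_inward(self, geom):
        iface = Rect(-2.0, 2.0, -2.0, 2.0, 51.0)
        poly = AperturePolygon(shapely_box(-2, -2, 2, 2), 51.0)
        m = split_by_interface(poly, JawSetting.square(20.0), iface, geom)
        assert m.fp_in == pytest.approx(m.rp, rel=1e-12)
        assert m.fp_out == pytest.approx(0.0, abs=1e-12)
        assert m.ma_in == pytest.approx(0.0, abs=1e-12)

    def test_plane_mismatch_rejected(self, geom):
        poly = AperturePolygon(shapely_box(-2, -2, 2, 2), 100.0)
        with pytest.raises(ValueError):
            split_by_interface(poly, JawSetting.square(20.0),
                               Rect(-2, 2, -2, 2, 51.0), geom)

    def test_random_apertures_match_clip_oracles(self, geom):
        rng = np.random.default_rng(2024)
        jaw = JawSetting.square(40.0)  # covers every generated aperture at 51 cm
        for _ in range(60):
            poly = random_aperture(rng)
            iface = Rect(rng.uniform(-4, -0.5), rng.uniform(0.5, 4),
                         rng.uniform(-4, -0.5), rng.uniform(0.5, 4), poly.plane_dist)
            m = split_by_interface(poly, jaw, iface, geom)
            fp_in, fp_out = segment_clip_fp_split(poly.geom, iface)
            assert m.fp_in == pytest.approx(fp_in, rel=1e-9, abs=1e-9)
            assert m.fp_out == pytest.approx(fp_out, rel=1e-9, abs=1e-9)
            # conservation against independent totals
            assert m.fp_in + m.fp_out == pytest.approx(
                edge_sum_perimeter(poly.geom), rel=1e-9)
            assert m.ma_in + m.ma_out == pytest.approx(
                jaw.area * (poly.plane_dist / geom.sad) ** 2 - shoelace_area(poly.geom),
                rel=1e-9)


class TestClassification:
    def test_no_bank_and_strictly_retracted_are_category_1(self, geom):
        jaw = JawSetting.square(10.0)
        iface = scatter_interface(geom, jaw.rect())
        assert classify_category(jaw, None, iface, geom) == 1
        assert classify_category(jaw, MLCBank.retracted(), iface, geom) == 1

    def test_leaves_in_bev_outside_interface_are_category_2(self, geom):
        jaw = JawSetting.square(20.0)
        iface = scatter_interface(geom, jaw.rect())
        assert classify_category(jaw, MLCBank.square(16.0), iface, geom) == 2

    def test_mlc_square_equal_to_jaw_is_category_2(self, geom):
        # tips parked exactly at the jaw edge still expose their rounded ends
        jaw = JawSetting.square(20.0)
        iface = scatter_interface(geom, jaw.rect())
        assert classify_category(jaw, MLCBank.square(20.0), iface, geom) == 2

    def test_aperture_reaching_interface_is_category_3(self, geom):
        jaw = JawSetting.square(20.0)
        iface = scatter_interface(geom, jaw.rect())
        assert classify_category(jaw, MLCBank.square(6.0), iface, geom) == 3
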