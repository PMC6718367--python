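"""MLC scatter source: line/area factors, AP-ratio model, Sc_MLC and fitting."""

import numpy as np
import pytest

from headscatter import (FieldSpec, FitError, JawSetting, MLCBank,
                         MLCSourceModel, ModelValidityError, es_area, es_line,
                         params_from_apratio, reference_field, sc_breakdown,
                         sc_dsm, sc_mlc, sc_total)
from headscatter import defaults
from headscatter.campaign import CampaignDesign, simulate_campaign
from headscatter.mlc_source import QuadCoeff, field_metrics, fit_mlc_params


class TestLineSource:
    def test_equal_perimeters_collapse_to_unity(self):
        assert es_line(23.5, 23.5, 0.016, 0.797) == 1.0

    def test_zero_amplitude(self):
        assert es_line(31.0, 12.0, 0.0, 0.9) == 1.0

    def test_published_twenty_by_twenty_value(self):
        # a, b from the 20x20 out column; FP 30 cm, RP 23.54 cm at mid-MLC
        assert es_line(30.0, 23.54, 0.016, 0.797) == pytest.approx(1.04229, abs=5e-5)

    def test_zero_fp_keeps_printed_form(self):
        assert es_line(0.0, 10.0, 0.02, 0.8) == pytest.approx(
            1.0 - 0.02 * 10.0 ** 0.8, rel=1e-12)


class TestAreaSource:
    def test_zero_argument_and_wide_sigma_limits(self):
        assert es_area(0.0, 45.9) == 1.0
        assert es_area(123.0, 1e9) == pytest.approx(1.0, abs=1e-12)

    def test_published_twenty_by_twenty_value(self):
        assert es_area(50.0, 45.942) == pytest.approx(0.98823, abs=1e-5)

    def test_exceeds_unity_when_area_below_reference(self):
        assert es_area(-30.0, 45.942) > 1.0


class TestAPRatioModel:
    def test_quadratic_constant_term_at_zero(self):
        c = QuadCoeff(*defaults.PUBLISHED_APRATIO_COEFFS["a_out"])
        assert c(0.0) == 0.015

    @pytest.mark.parametrize("apratio,expected", [(5.0, 0.016), (7.5, 0.017)])
    def test_published_a_out_consistent_with_per_jaw_table(self, apratio, expected):
        c = QuadCoeff(*defaults.PUBLISHED_APRATIO_COEFFS["a_out"])
        assert round(c(apratio), 3) == expected

    def test_published_sigma_quadratics_are_invalid(self):
        # the printed sigma coefficients go negative inside the fitted range
        model = defaults.published_apratio_model()
        with pytest.raises(ModelValidityError):
            model.evaluate(5.0)

    def test_table_interpolation_reproduces_anchors(self):
        model = defaults.published_anchored_apratio_model()
        for side, truth in defaults.PUBLISHED_PER_JAW_PARAMS.items():
            got = model.evaluate(side / 4.0)
            assert got.as_array() == pytest.approx(truth.as_array(), rel=1e-9)

    def test_warns_outside_fitted_range(self):
        model = defaults.published_anchored_apratio_model()
        with pytest.warns(UserWarning, match="outside the fitted range"):
            model.evaluate(8.5)

    def test_region_selector(self):
        model = defaults.published_anchored_apratio_model()
        assert params_from_apratio(5.0, "out", model) == model.evaluate(5.0).out_triple
        assert params_from_apratio(5.0, "in", model) == model.evaluate(5.0).in_triple
        with pytest.raises(ValueError):
            params_from_apratio(5.0, "sideways", model)


class TestScMlc:
    def test_category_1_short_circuit_is_exact(self, geom):
        fs = FieldSpec(jaw=JawSetting.square(10.0), bank=MLCBank.retracted())
        metrics, category = field_metrics(fs, geom)
        assert category == 1
        p = defaults.PUBLISHED_PER_JAW_PARAMS[10.0]
        comp = sc_mlc(metrics, p.out_triple, p.in_triple, category=category)
        assert comp.sc_mlc == 1.0

    def test_neutral_metrics_give_unity(self, geom):
        from headscatter import RegionMetrics
        m = RegionMetrics(fp_in=23.5, fp_out=23.5, ma_in=2.3409, ma_out=34.6,
                          rp=23.5, ra_in=2.3409, ra_out=34.6, plane_dist=51.0)
        p = defaults.PUBLISHED_PER_JAW_PARAMS[20.0]
        comp = sc_mlc(m, p.out_triple, p.in_triple)
        assert comp.sc_mlc == pytest.approx(1.0, rel=1e-12)

    def test_jaw20_mlc10_matches_hand_evaluation(self, geom):
        # step-by-step scalar evaluation on the aperture-model metrics, frozen
        fs = FieldSpec(jaw=JawSetting.square(20.0), bank=MLCBank.square(10.0))
        metrics, category = field_metrics(fs, geom)
        assert category == 3
        assert metrics.fp_in == pytest.approx(20.4, rel=1e-9)
        assert metrics.fp_out == 0.0
        assert metrics.ma_in == pytest.approx(8.62793316, rel=1e-9)
        assert metrics.ma_out == pytest.approx(69.40206684, rel=1e-9)
        p = defaults.PUBLISHED_PER_JAW_PARAMS[20.0]
        comp = sc_mlc(metrics, p.out_triple, p.in_triple, category=category)
        assert comp.sc_mlc == pytest.approx(0.79239372, abs=1e-7)

    def test_zero_fp_identity_switch(self, geom):
        fs = FieldSpec(jaw=JawSetting.square(20.0), bank=MLCBank.square(10.0))
        metrics, category = field_metrics(fs, geom)
        p = defaults.PUBLISHED_PER_JAW_PARAMS[20.0]
        default_comp = sc_mlc(metrics, p.out_triple, p.in_triple, category=category)
        forced = sc_mlc(metrics, p.out_triple, p.in_triple, category=category,
                        zero_fp_identity=True)
        # fp_out = 0 here: the switch replaces 1 - a_out RP^b_out by 1
        assert forced.sc_line > default_comp.sc_line
        assert forced.sc_area == default_comp.sc_area

    def test_small_steps_as_leaf_tip_crosses_interface(self, geom, mlc_truth):
        """Sc_MLC moves in segment-scale steps, not jumps, as one leaf tip
        sweeps across the interface edge."""
        jaw = JawSetting.square(20.0)
        values = []
        for tip in np.linspace(5.0, 6.6, 33):
            bank = MLCBank.square(8.0)
            i = np.argmin(np.abs(0.5 * (bank.edges[:-1] + bank.edges[1:])))
            bank.right[i] = tip  # one protruding leaf
            fs = FieldSpec(jaw=jaw, bank=bank)
            metrics, category = field_metrics(fs, geom)
            p = mlc_truth.resolve(jaw)
            values.append(sc_mlc(metrics, p.out_triple, p.in_triple,
                                 category=category).sc_mlc)
        steps = np.abs(np.diff(values))
        # the instant the 0.5 cm tip segment switches region, es_line_out moves
        # by ~ a_out b_out FP_out^(b-1) x (segment length at mid-MLC) ~ 5e-3;
        # everywhere else the sweep is smooth.  No order-unity jumps.
        assert steps.max() < 1e-2


class TestScTotal:
    def test_reference_field_is_exactly_one(self, geom, dsm_truth, mlc_truth):
        assert sc_total(reference_field(), dsm_truth, mlc_truth, geom) == 1.0

    def test_retracted_mlc_reduces_to_dsm(self, geom, dsm_truth, mlc_truth):
        for side in (6, 15, 30):
            fs = FieldSpec(jaw=JawSetting.square(side), bank=MLCBank.retracted())
            assert sc_total(fs, dsm_truth, mlc_truth, geom) == pytest.approx(
                sc_dsm(fs, dsm_truth, geom), rel=1e-12)

    def test_total_is_product_of_factors(self, geom, dsm_truth, mlc_truth):
        fs = FieldSpec(jaw=JawSetting.square(20.0), bank=MLCBank.square(12.0))
        bd = sc_breakdown(fs, dsm_truth, mlc_truth, geom)
        assert bd.sc == pytest.approx(bd.sc_dsm * bd.sc_line * bd.sc_area, rel=1e-12)

    def test_per_jaw_params_take_precedence_over_apratio_model(self, geom, dsm_truth):
        full = defaults.published_source_model()
        interp_only = MLCSourceModel(per_jaw={},
                                     apratio_model=full.apratio_model)
        fs = FieldSpec(jaw=JawSetting.square(20.0), bank=MLCBank.square(8.0))
        # anchored jaws resolve identically either way (interpolation is exact
        # at the anchors); an unseen jaw must use the interpolation
        assert sc_total(fs, dsm_truth, full, geom) == pytest.approx(
            sc_total(fs, dsm_truth, interp_only, geom), rel=1e-9)
        fs15 = FieldSpec(jaw=JawSetting.square(15.0), bank=MLCBank.square(8.0))
        assert full.resolve(fs15.jaw) == interp_only.resolve(fs15.jaw)


class TestFitMlc:
    def test_campaign_without_mlc_fields_rejected(self, geom, dsm_truth, mlc_truth):
        design = CampaignDesign(include_mlc_squares=False, include_irregular=False,
                                noise_sd=0.0)
        table = simulate_campaign(design, dsm_truth, mlc_truth, geom, seed=0)
        with pytest.raises(FitError):
            fit_mlc_params(table, dsm_truth, geom)

    def test_single_category_series_rejected(self, geom, dsm_truth, mlc_truth):
        # squares 4..8 in a 20 cm jaw all sit inside the interface (category 3)
        design = CampaignDesign(include_jaw_fields=False, include_irregular=False,
                                mlc_series_jaws=(20,), mlc_square_sides=(4, 5, 6, 7, 8),
                                noise_sd=0.0)
        table = simulate_campaign(design, dsm_truth, mlc_truth, geom, seed=0)
        with pytest.raises(FitError, match="categories 2 and 3"):
            fit_mlc_params(table, dsm_truth, geom)

    def test_noise_free_single_jaw_recovery(self, geom, dsm_truth, mlc_truth):
        design = CampaignDesign(include_jaw_fields=False, include_irregular=False,
                                mlc_series_jaws=(20,), noise_sd=0.0)
        table = simulate_campaign(design, dsm_truth, mlc_truth, geom, seed=0)
        result = fit_mlc_params(table, dsm_truth, geom)
        fit = result.per_jaw_fits[(20.0, 20.0)]
        truth = defaults.PUBLISHED_PER_JAW_PARAMS[20.0]
        assert fit.converged
        assert fit.params.as_array() == pytest.approx(truth.as_array(), rel=1e-6)
        # fewer than three jaw settings: no AP-ratio interpolation
        assert result.model.apratio_model is None
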