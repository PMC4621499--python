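"""Dissociation curve, oxygen contents, Fick extraction, per-mass scaling,
and the composed per-subject pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retflow import (
    AnalysisConfig,
    OxygenModelParams,
    SubjectRecord,
    VesselMeasurement,
    WallLossParams,
    analyze_subject,
    extraction,
    oxygen_content,
    per_100g,
    perfused_mass_fraction,
    po2_to_saturation,
    saturation_to_po2,
    vessel_flow,
)
from retflow.errors import DataQualityWarning


class TestDissociationCurve:
    def test_half_saturation_at_p50(self):
        assert saturation_to_po2(0.5) == pytest.approx(26.8, rel=1e-12)
        assert po2_to_saturation(26.8) == pytest.approx(0.5, rel=1e-12)

    def test_inverse_hill_hand_value(self):
        # P50 * (s/(1-s))^(1/n) at s=0.68, n=2.7
        expected = 26.8 * (0.68 / 0.32) ** (1 / 2.7)
        assert saturation_to_po2(0.68) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(35.43, abs=0.005)

    def test_round_trip_tight(self):
        for s in np.linspace(0.01, 0.99, 197):
            assert po2_to_saturation(saturation_to_po2(s)) == pytest.approx(
                s, abs=1e-9
            )

    def test_strictly_increasing(self):
        grid = np.linspace(0.005, 0.995, 500)
        po2 = [saturation_to_po2(s) for s in grid]
        assert np.all(np.diff(po2) > 0)

    @pytest.mark.parametrize("s", [0.0, 1.0, 1.1, -0.1])
    def test_domain_errors_at_curve_asymptotes(self, s):
        with pytest.raises(ValueError):
            saturation_to_po2(s)

    def test_custom_hill_exponent(self):
        params = OxygenModelParams(hill_exponent=2.0)
        assert saturation_to_po2(0.8, params) == pytest.approx(26.8 * 2.0, rel=1e-12)


class TestOxygenContent:
    def test_baseline_arterial_hand_value(self):
        # 1.35*Hb*s + (0.003/100)*PO2
        expected = 1.35 * 0.138 * 0.953 + 3e-5 * 95
        assert oxygen_content(0.953, 95, 0.138) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1804, abs=5e-5)

    def test_hyperoxic_arterial_hand_value(self):
        assert oxygen_content(0.994, 300, 0.138) == pytest.approx(0.194, abs=5e-4)

    def test_no_oxygen(self):
        assert oxygen_content(0.0, 0.0, 0.138) == 0.0

    def test_linear_in_each_argument(self):
        c0 = oxygen_content(0.4, 50, 0.1)
        assert oxygen_content(0.8, 50, 0.1) - c0 == pytest.approx(
            1.35 * 0.1 * 0.4, rel=1e-9
        )
        assert oxygen_content(0.4, 100, 0.1) - c0 == pytest.approx(3e-5 * 50, rel=1e-9)


class TestExtractionAndNormalization:
    def test_fick_product_hand_value(self):
        assert extraction(44.3, 0.1804, 0.1277) == pytest.approx(2.33, abs=0.005)

    def test_zero_when_contents_equal_and_linear_in_flow(self):
        assert extraction(30.0, 0.15, 0.15) == 0.0
        assert extraction(20.0, 0.18, 0.13) == pytest.approx(
            2 * extraction(10.0, 0.18, 0.13), rel=1e-12
        )

    def test_negative_extraction_warns_never_clamps(self):
        with pytest.warns(DataQualityWarning, match="negative"):
            assert extraction(10.0, 0.12, 0.13) == pytest.approx(-0.1)

    def test_per_100g_hand_value(self):
        # 0.88 ul/min over half of 326 mg, rescaled to 100 g
        assert per_100g(0.88) == pytest.approx(0.88e-3 / (0.326 * 0.5) * 100, rel=1e-12)
        assert round(per_100g(0.88), 2) == 0.54

    def test_per_100g_inverse_in_perfused_fraction(self):
        half = per_100g(1.0, OxygenModelParams(perfused_fraction=0.5))
        quarter = per_100g(1.0, OxygenModelParams(perfused_fraction=0.25))
        assert quarter == pytest.approx(2 * half, rel=1e-12)
        assert per_100g(0.0) == 0.0

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            per_100g(1.0, OxygenModelParams(retina_mass_mg=0.0))

    def test_perfused_mass_fraction(self):
        assert perfused_mass_fraction(0.43, 0.11) == pytest.approx(0.4927, rel=1e-12)
        assert perfused_mass_fraction(1.0, 0.0) == 1.0
        assert perfused_mass_fraction(0.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            perfused_mass_fraction(1.2, 0.1)


def _two_vessel_record(sat_a=0.953, sat_v=0.680, hb=0.138, pao2=95.0):
    vessels = [
        VesselMeasurement(
            vessel_id="a1", vessel_type="artery", mean_velocity_mm_s=15.0,
            diameter_um=100.0, distance_to_onh_um=0.0, measured_saturation=sat_a,
            diameter_source="oct",
        ),
        VesselMeasurement(
            vessel_id="v1", vessel_type="vein", mean_velocity_mm_s=15.0,
            diameter_um=100.0, distance_to_onh_um=0.0, measured_saturation=sat_v,
            diameter_source="oct",
        ),
    ]
    return SubjectRecord(
        subject_id="two", condition="baseline", vessels=vessels,
        hb_g_ml=hb, pao2_mmhg=pao2,
    )


class TestAnalyzeSubject:
    def test_two_vessel_closed_form(self):
        """With no wall flux, one artery and one vein of equal flow, the
        whole pipeline collapses to a hand-computable Fick calculation."""
        record = _two_vessel_record()
        config = AnalysisConfig(wall_loss=WallLossParams(wall_flux_ml_per_cm2_min=0.0))
        res = analyze_subject(record, config)
        q = vessel_flow(15.0, 100.0)
        po2_v = 26.8 * (0.680 / 0.320) ** (1 / 2.7)
        c_a = 1.35 * 0.138 * 0.953 + 3e-5 * 95.0
        c_v = 1.35 * 0.138 * 0.680 + 3e-5 * po2_v
        assert res.hemodynamics.q_total_ul_min == pytest.approx(q, rel=1e-12)
        assert res.oximetry.sat_cra == 0.953
        assert res.oximetry.sat_crv == 0.680
        assert res.ext_o2_ul_min == pytest.approx(q * (c_a - c_v), rel=1e-12)

    def test_zero_flux_reduces_to_pure_fick(self):
        """With j=0 the corrected saturations equal the measured ones even at
        a nonzero measurement distance."""
        record = _two_vessel_record()
        far = [
            VesselMeasurement(
                vessel_id=v.vessel_id, vessel_type=v.vessel_type,
                mean_velocity_mm_s=v.mean_velocity_mm_s, diameter_um=v.diameter_um,
                distance_to_onh_um=2500.0, measured_saturation=v.measured_saturation,
                diameter_source="oct",
            )
            for v in record.vessels
        ]
        record_far = SubjectRecord(
            subject_id="two", condition="baseline", vessels=far,
            hb_g_ml=record.hb_g_ml, pao2_mmhg=record.pao2_mmhg,
        )
        config = AnalysisConfig(wall_loss=WallLossParams(wall_flux_ml_per_cm2_min=0.0))
        res = analyze_subject(record_far, config)
        assert res.oximetry.corrected_saturation["a1"] == 0.953
        assert res.oximetry.corrected_saturation["v1"] == 0.680

    def test_wall_correction_moves_arteries_up_veins_down(self):
        record = _two_vessel_record()
        far = [
            VesselMeasurement(
                vessel_id=v.vessel_id, vessel_type=v.vessel_type,
                mean_velocity_mm_s=v.mean_velocity_mm_s, diameter_um=v.diameter_um,
                distance_to_onh_um=2500.0, measured_saturation=v.measured_saturation,
                diameter_source="oct",
            )
            for v in record.vessels
        ]
        record = SubjectRecord(
            subject_id="two", condition="baseline", vessels=far,
            hb_g_ml=record.hb_g_ml, pao2_mmhg=record.pao2_mmhg,
        )
        res = analyze_subject(record)
        assert res.oximetry.corrected_saturation["a1"] > 0.953
        assert res.oximetry.corrected_saturation["v1"] < 0.680

    def test_duplicating_every_vessel_at_half_flow_is_invariant(self):
        """Splitting each vessel into two of equal saturation with conserved
        flow leaves every pipeline output unchanged."""
        record = _two_vessel_record()
        halved = []
        for v in record.vessels:
            for suffix in ("_1", "_2"):
                halved.append(
                    VesselMeasurement(
                        vessel_id=v.vessel_id + suffix, vessel_type=v.vessel_type,
                        mean_velocity_mm_s=v.mean_velocity_mm_s,
                        diameter_um=v.diameter_um / np.sqrt(2),  # half the area
                        distance_to_onh_um=v.distance_to_onh_um,
                        measured_saturation=v.measured_saturation,
                        diameter_source="oct",
                    )
                )
        split = SubjectRecord(
            subject_id="two", condition="baseline", vessels=halved,
            hb_g_ml=record.hb_g_ml, pao2_mmhg=record.pao2_mmhg,
        )
        config = AnalysisConfig(wall_loss=WallLossParams(wall_flux_ml_per_cm2_min=0.0))
        res0 = analyze_subject(record, config)
        res1 = analyze_subject(split, config)
        assert res1.hemodynamics.q_total_ul_min == pytest.approx(
            res0.hemodynamics.q_total_ul_min, rel=1e-12
        )
        assert res1.ext_o2_ul_min == pytest.approx(res0.ext_o2_ul_min, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        sat_a=st.floats(0.90, 0.99), sat_v=st.floats(0.5, 0.8),
        hb=st.floats(0.11, 0.17), pao2=st.floats(70, 110),
    )
    def test_uniform_venous_saturation_matches_single_vessel(self, sat_a, sat_v, hb, pao2):
        """When all veins share one saturation, flow weighting is irrelevant
        and the result matches the two-vessel closed form."""
        record = _two_vessel_record(sat_a, sat_v, hb, pao2)
        config = AnalysisConfig(wall_loss=WallLossParams(wall_flux_ml_per_cm2_min=0.0))
        res = analyze_subject(record, config)
        po2_v = 26.8 * (sat_v / (1 - sat_v)) ** (1 / 2.7)
        c_a = 1.35 * hb * sat_a + 3e-5 * pao2
        c_v = 1.35 * hb * sat_v + 3e-5 * po2_v
        assert res.ext_o2_ul_min == pytest.approx(
            res.hemodynamics.q_total_ul_min * (c_a - c_v), rel=1e-10
        )

    def test_out_of_band_hemoglobin_warns(self):
        with pytest.warns(DataQualityWarning, match="hemoglobin"):
            _two_vessel_record(hb=0.03)
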