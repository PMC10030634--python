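"""Model variants: convection terms, prediction decomposition, nesting."""
import numpy as np
import pytest

from beeheat import (
    DEFAULT_CONSTANTS,
    DEFAULT_SURFACE,
    VARIANTS,
    CoefficientSet,
    VariantMismatchError,
    VisitRecord,
    body_mean_temperature,
    conductance_estimate,
    convection_per_part,
    convection_simple,
    convection_three_compartment,
    load_preset,
    predict_metabolism,
)


def record(T_hd=35.0, T_th=38.0, T_ab=30.0, T_a=25.0, G=50.0, **kw):
    return VisitRecord(T_hd=T_hd, T_th=T_th, T_ab=T_ab, T_a=T_a, G=G, **kw)


def isothermal(T=25.0, G=0.0):
    return VisitRecord(T_hd=T, T_th=T, T_ab=T, T_a=T, G=G)


class TestConvection:
    def test_simple_vanishes_at_ambient(self):
        assert convection_simple(isothermal(), h_b=12.14393) == pytest.approx(0.0)

    def test_simple_hand_value(self):
        # h_b * A_b * 10 degC with the published simple-model coefficient
        rec = record(T_hd=35.0, T_th=35.0, T_ab=35.0, T_a=25.0)
        assert convection_simple(rec, h_b=12.14393)[0] == pytest.approx(
            0.01987961341, rel=1e-9
        )

    def test_simple_antisymmetry(self):
        hot = record(T_hd=35, T_th=35, T_ab=35, T_a=25)
        cold = record(T_hd=15, T_th=15, T_ab=15, T_a=25)
        assert convection_simple(hot, 5.0)[0] == pytest.approx(
            -convection_simple(cold, 5.0)[0], rel=1e-12
        )

    @pytest.mark.parametrize("preset", ["table2a", "table2b"])
    def test_per_part_vanishes_at_ambient(self, preset):
        value = convection_per_part(isothermal(), load_preset(preset))
        assert value[0] == pytest.approx(0.0, abs=1e-15)

    def test_per_part_thorax_term_hand_value(self):
        # only the thorax deviates from ambient: the head and abdomen
        # terms vanish and E_cv reduces to (a_hth + b_hth*T_a)*A_th*10
        rec = record(T_hd=25.0, T_th=35.0, T_ab=25.0, T_a=25.0)
        coeffs = load_preset("table2a")
        expected = (26.88355 + 5.26661 * 25.0) * DEFAULT_SURFACE.A_th * 10.0
        assert convection_per_part(rec, coeffs)[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0758, abs=5e-5)

    @pytest.mark.parametrize("preset", ["table3a", "table3b"])
    def test_three_compartment_vanishes_at_ambient(self, preset):
        value = convection_three_compartment(isothermal(), load_preset(preset))
        assert value[0] == pytest.approx(0.0, abs=1e-15)

    def test_three_compartment_hand_value(self):
        # T_a=25, T_th-T_hd=5, T_th-T_a=10, T_th-T_ab=12
        rec = record(T_hd=30.0, T_th=35.0, T_ab=23.0, T_a=25.0)
        c = load_preset("table3b")
        expected = (
            (c["a_hthhd"] + c["b_hthhd"] * 25.0) * 5.0
            + (c["a_hth"] + c["b_hth"] * 25.0) * DEFAULT_SURFACE.A_th * 10.0
            + c["h_thab"] * 12.0
        )
        assert convection_three_compartment(rec, c)[0] == pytest.approx(expected, rel=1e-12)

    def test_nesting_reduced_variants(self):
        rec = record()
        full = load_preset("table2b").values | {"a_hab": -22.66916, "b_hab": 0.0}
        del full["h_ab"]
        nested = CoefficientSet("per_part", full)
        assert convection_per_part(rec, nested)[0] == pytest.approx(
            convection_per_part(rec, load_preset("table2b"))[0], rel=1e-14
        )
        full3 = load_preset("table3b").values | {"a_hthab": 0.00195, "b_hthab": 0.0}
        del full3["h_thab"]
        nested3 = CoefficientSet("three_compartment", full3)
        assert convection_three_compartment(rec, nested3)[0] == pytest.approx(
            convection_three_compartment(rec, load_preset("table3b"))[0], rel=1e-14
        )

    def test_variant_dispatch_is_strict(self):
        with pytest.raises(VariantMismatchError):
            convection_per_part(record(), load_preset("table3a"))
        with pytest.raises(VariantMismatchError):
            convection_three_compartment(record(), load_preset("table2a"))


class TestPrediction:
    @pytest.mark.parametrize("preset", ["table2a", "table2b", "table3a", "table3b"])
    def test_component_decomposition_is_exact(self, small_visits, preset):
        pred = predict_metabolism(small_visits, load_preset(preset))
        reassembled = (
            pred.radiative_loss_term
            - pred.radiative_gain_term
            + pred.convection
            + pred.evaporation_term
        )
        np.testing.assert_array_equal(pred.M, reassembled)

    def test_full_equilibrium_leaves_only_evaporation(self):
        # r_l = r_g = 1, surroundings at body temperature, no sun, all
        # body parts at ambient: radiation and convection cancel exactly
        coeffs = CoefficientSet(
            "simple", {"r_l": 1.0, "r_g": 1.0, "e_lev": 1.82501, "h_b": 12.14393}
        )
        rec = isothermal(T=30.0)
        pred = predict_metabolism(rec, coeffs, T_surround=30.0)
        assert pred.M[0] == pytest.approx(1.82501 * DEFAULT_CONSTANTS.E_ev, rel=1e-12)

    def test_evaporative_term_product(self):
        pred = predict_metabolism(record(), load_preset("table2a"))
        assert pred.evaporation_term[0] == pytest.approx(-0.03444572, rel=1e-9)

    def test_milliwatt_conversion(self):
        pred = predict_metabolism(record(), load_preset("table2b"))
        assert pred.M_mW[0] == pytest.approx(pred.M[0] * 1000.0, rel=1e-15)

    def test_term_by_term_against_hand_assembly(self):
        # independent re-assembly from the hand formulas, table2b
        from beeheat import ir_gain, radiative_loss, solar_gain

        rec = record(T_hd=33.0, T_th=39.5, T_ab=28.0, T_a=22.0, G=400.0)
        c = load_preset("table2b")
        T_b = (33.0 + 39.5 + 28.0) / 3.0
        e_cv = (
            (c["a_hhd"] + c["b_hhd"] * 22.0) * DEFAULT_SURFACE.A_hd * (33.0 - 22.0)
            + (c["a_hth"] + c["b_hth"] * 22.0) * DEFAULT_SURFACE.A_th * (39.5 - 22.0)
            + c["h_ab"] * DEFAULT_SURFACE.A_ab * (28.0 - 22.0)
        )
        expected = (
            c["r_l"] * radiative_loss(T_b, DEFAULT_SURFACE.A_b)
            - c["r_g"] * (ir_gain(22.0, DEFAULT_SURFACE.A_b)
                          + solar_gain(400.0, DEFAULT_SURFACE.A_b))
            + e_cv
            + c["e_lev"] * DEFAULT_CONSTANTS.E_ev
        )
        assert predict_metabolism(rec, c).M[0] == pytest.approx(expected, rel=1e-12)


class TestConductance:
    def test_arithmetic(self):
        assert conductance_estimate(50.0, 35.0, 25.0) == pytest.approx(5.0)
        assert conductance_estimate(0.0, 35.0, 25.0) == 0.0

    def test_reciprocal_in_excess(self):
        assert conductance_estimate(50.0, 30.0, 25.0) == pytest.approx(
            2 * conductance_estimate(50.0, 35.0, 25.0)
        )

    def test_undefined_at_zero_excess_reports_nan(self):
        assert np.isnan(conductance_estimate(50.0, 25.0, 25.0))
        out = conductance_estimate([50.0, 10.0], [25.0, 30.0], [25.0, 25.0])
        assert np.isnan(out[0]) and out[1] == pytest.approx(2.0)


class TestVisitRecord:
    def test_sun_threshold_is_strict(self):
        assert not VisitRecord(35, 38, 30, 25, G=100.0).is_sun
        assert VisitRecord(35, 38, 30, 25, G=100.1).is_sun

    def test_body_mean_is_unweighted(self):
        rec = record(T_hd=30.0, T_th=40.0, T_ab=20.0)
        assert body_mean_temperature(rec)[0] == pytest.approx(30.0)

    def test_variant_schema_enforced(self):
        with pytest.raises(VariantMismatchError):
            CoefficientSet("per_part", {"r_l": 1.0})
        with pytest.raises(VariantMismatchError):
            CoefficientSet("nonsense", {"r_l": 1.0})
        assert set(VARIANTS) == {
            "simple",
            "per_part",
            "per_part_reduced",
            "three_compartment",
            "three_compartment_reduced",
        }
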