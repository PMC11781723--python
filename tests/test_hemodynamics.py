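import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vbpe.anthropometry import Demographics, vessel_length_difference
from vbpe.errors import InputError, ModelDomainError
from vbpe.hemodynamics import (
    FIXED_DIAMETER_M,
    FIXED_LENGTH_M,
    FIXED_WALL_M,
    ModelConstants,
    VesselParameters,
    artery_diameter,
    build_parameters,
    estimate_bp,
    invert_ptt,
    variant_offset_mmhg,
    wall_thickness,
)
from vbpe.transit import TransitTimes

# Cohort-mean demographics: age 40.35 y, height 158.1 cm, weight 63.80 kg.
MEANS = dict(height_cm=158.1, weight_kg=63.80, age_years=40.35)


@pytest.fixture
def mean_demo():
    return Demographics(subject_id="mean", **MEANS)


def _tt(ptt_s, ptt_d=None):
    return TransitTimes(ptt_s=ptt_s, ptt_d=ptt_d or ptt_s, n_pairs_s=9,
                        n_pairs_d=9)


class TestDemographicRegressions:
    def test_diameter_at_cohort_means(self, mean_demo):
        # hand evaluation: -0.258 + 0.029*158.1 + 0.006*40.35 + 0.036*25.524
        assert artery_diameter(mean_demo) == pytest.approx(5.488, abs=1e-3)

    def test_wall_thickness_at_cohort_means(self, mean_demo):
        assert wall_thickness(mean_demo) == pytest.approx(0.5794, abs=1e-3)

    def test_wall_thickness_intercept_limit(self):
        d = Demographics("x", height_cm=170.0, weight_kg=1e-6, age_years=1e-6)
        assert wall_thickness(d) == pytest.approx(0.25, abs=1e-6)

    @given(
        age=st.floats(17.0, 82.0),
        dage=st.floats(0.1, 20.0),
        height=st.floats(140.0, 200.0),
        weight=st.floats(40.0, 120.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_age_and_weight(self, age, dage, height, weight):
        d1 = Demographics("a", height, weight, age)
        d2 = Demographics("a", height, weight, age + dage)
        d3 = Demographics("a", height, weight + 5.0, age)
        assert artery_diameter(d2) > artery_diameter(d1)
        assert artery_diameter(d3) > artery_diameter(d1)
        assert wall_thickness(d2) > wall_thickness(d1)
        assert wall_thickness(d3) > wall_thickness(d1)


class TestBuildParameters:
    def test_fixed_variant_constants(self):
        p = build_parameters("fixed")
        assert (p.length_m, p.diameter_s, p.wall) == (
            FIXED_LENGTH_M, FIXED_DIAMETER_M, FIXED_WALL_M
        )
        assert (p.length_m, p.diameter_s, p.wall) == (0.2, 0.01, 0.001)

    def test_demographic_composition(self, mean_demo):
        g = vessel_length_difference(800.0, 350.0, 250.0, 160.0)  # L = 20 cm
        p = build_parameters("demographic", demo=mean_demo, geometry=g)
        assert p.length_m == pytest.approx(0.20)
        assert p.diameter_s == pytest.approx(5.488, abs=1e-3)
        assert p.wall == pytest.approx(0.5794, abs=1e-3)

    def test_demographic_without_geometry_errors(self, mean_demo):
        with pytest.raises(InputError, match="geometry"):
            build_parameters("demographic", demo=mean_demo)

    def test_constants_default_to_model_values(self):
        c = ModelConstants()
        assert (c.rho, c.e0, c.alpha) == (1060.0, 1005.0, 0.017)


class TestPressureModel:
    @pytest.mark.parametrize("variant", ["fixed", "demographic"])
    @pytest.mark.parametrize("bp", [85.0, 120.0, 202.0])
    def test_round_trip_exact(self, variant, bp, mean_demo):
        if variant == "fixed":
            params = build_parameters("fixed")
        else:
            g = vessel_length_difference(800.0, 350.0, 250.0, 160.0)
            params = build_parameters("demographic", demo=mean_demo, geometry=g)
        tt = _tt(invert_ptt(bp, params, "systolic"),
                 invert_ptt(bp, params, "diastolic"))
        est = estimate_bp(tt, params)
        assert abs(est.sbp_mmhg - bp) < 1e-9
        assert abs(est.dbp_mmhg - bp) < 1e-9

    def test_pwv_elasticity_consistency(self):
        # PWV^2 * rho * D = h * E0 * exp(alpha * BP) for every estimate
        params = build_parameters("fixed")
        c = params.constants
        for bp in (85.0, 120.0, 202.0):
            tt = _tt(invert_ptt(bp, params, "systolic"),
                     invert_ptt(bp, params, "diastolic"))
            est = estimate_bp(tt, params)
            lhs = est.pwv_s**2 * c.rho * params.diameter_s
            rhs = params.wall * c.e0 * math.exp(c.alpha * est.sbp_mmhg)
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_bp_decreases_with_ptt(self):
        params = build_parameters("fixed")
        est1 = estimate_bp(_tt(0.20), params)
        est2 = estimate_bp(_tt(0.25), params)
        assert est2.sbp_mmhg < est1.sbp_mmhg

    def test_doubling_length_adds_two_over_alpha_log2(self):
        params = build_parameters("fixed")
        doubled = VesselParameters(
            variant="fixed", length_m=2 * params.length_m,
            diameter_s=params.diameter_s, diameter_d=params.diameter_d,
            wall=params.wall, constants=params.constants,
        )
        e1 = estimate_bp(_tt(0.22), params).sbp_mmhg
        e2 = estimate_bp(_tt(0.22), doubled).sbp_mmhg
        expected = (2.0 / params.constants.alpha) * math.log(2.0)
        assert e2 - e1 == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_ptt_rejected(self):
        params = build_parameters("fixed")
        with pytest.raises(ModelDomainError, match="PTT"):
            estimate_bp(_tt(0.0), params)

    def test_invert_decreasing_and_linear_in_length(self):
        params = build_parameters("fixed")
        assert invert_ptt(130.0, params) < invert_ptt(110.0, params)
        doubled = VesselParameters(
            variant="fixed", length_m=2 * params.length_m,
            diameter_s=params.diameter_s, diameter_d=params.diameter_d,
            wall=params.wall, constants=params.constants,
        )
        assert invert_ptt(120.0, doubled) == pytest.approx(
            2 * invert_ptt(120.0, params), rel=1e-12
        )

    @pytest.mark.filterwarnings("ignore")
    def test_variant_offset_identity(self, mean_demo):
        g = vessel_length_difference(800.0, 380.0, 720.0, 160.0)
        demo_params = build_parameters("demographic", demo=mean_demo,
                                       geometry=g)
        fixed_params = build_parameters("fixed")
        ptt = invert_ptt(120.0, demo_params)
        bp_demo = estimate_bp(_tt(ptt), demo_params).sbp_mmhg
        bp_fixed = estimate_bp(_tt(ptt), fixed_params).sbp_mmhg
        assert bp_demo - bp_fixed == pytest.approx(
            variant_offset_mmhg(demo_params, fixed_params), rel=1e-9
        )

    def test_estimate_records_pwv_and_snapshot(self):
        params = build_parameters("fixed")
        est = estimate_bp(_tt(0.22, 0.25), params)
        assert est.pwv_s == pytest.approx(params.length_m / 0.22)
        assert est.parameters["E0"] == 1005.0
        assert est.variant == "fixed"
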