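import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isapk import pk_core
from isapk.datatypes import DoseEvent, IndividualParameters, PopulationModel


class TestIndividualParameters:
    @pytest.mark.parametrize("bmi,eta_cl,eta_v,exp_cl,exp_v", [
        (25.0, 0.0, 0.0, 2.3, 523.0),           # reference BMI, typical
        (50.0, 0.0, 0.0, 2.3, 1046.0),          # linear BMI scaling of V
        (25.0, math.log(2), 0.0, 4.6, 523.0),   # exp(ln 2) doubles CL
    ])
    def test_final_model_equations(self, final_model, bmi, eta_cl, eta_v,
                                   exp_cl, exp_v):
        ind = pk_core.individual_parameters(final_model, bmi, eta_cl, eta_v)
        assert ind.cl == pytest.approx(exp_cl)
        assert ind.v == pytest.approx(exp_v)

    def test_nonpositive_bmi_rejected(self, final_model):
        with pytest.raises(ValueError):
            pk_core.individual_parameters(final_model, 0.0)


class TestConcentration:
    def test_single_oral_dose_closed_form(self, typical_individual):
        c = pk_core.concentration(24.0, [DoseEvent(time=0.0, amount=200.0)],
                                  typical_individual)
        assert c == pytest.approx(0.3447, abs=5e-4)

    def test_zero_before_first_dose(self, typical_individual):
        assert pk_core.concentration(
            0.0, [DoseEvent(time=0.0, amount=200.0)], typical_individual) == 0.0

    def test_superposition_of_shifted_doses(self, typical_individual):
        doses = [DoseEvent(time=0.0, amount=200.0),
                 DoseEvent(time=24.0, amount=200.0)]
        both = pk_core.concentration(30.0, doses, typical_individual)
        one = pk_core.concentration(30.0, [doses[0]], typical_individual)
        shifted = pk_core.concentration(6.0, [doses[0]], typical_individual)
        assert both == pytest.approx(one + shifted, rel=1e-12)

    def test_iv_bolus_and_infusion_limit(self, typical_individual):
        bolus = pk_core.concentration(
            10.0, [DoseEvent(time=0.0, amount=200.0, route="intravenous")],
            typical_individual)
        short_inf = pk_core.concentration(
            10.0, [DoseEvent(time=0.0, amount=200.0, route="intravenous",
                             infusion_duration=0.01)], typical_individual)
        assert short_inf == pytest.approx(bolus, rel=1e-3)

    def test_ka_equal_ke_degenerate(self):
        ind = IndividualParameters(cl=2.5 * 500.0, v=500.0, ka=2.5)
        with pytest.raises(ValueError):
            pk_core.concentration(5.0, [DoseEvent(time=0.0, amount=100.0)],
                                  ind)


class TestSteadyState:
    def test_trough_closed_form(self, typical_individual):
        assert pk_core.cmin_ss(200.0, 24.0, typical_individual) == \
            pytest.approx(3.442, abs=1e-3)

    def test_trough_matches_long_run_superposition(self, typical_individual):
        # 20 half-lives of once-daily dosing as a brute-force oracle
        n = int(20 * pk_core.half_life(typical_individual) / 24.0) + 1
        doses = [DoseEvent(time=24.0 * k, amount=200.0) for k in range(n)]
        brute = pk_core.concentration(24.0 * n, doses, typical_individual)
        ss = pk_core.cmin_ss(200.0, 24.0, typical_individual)
        assert brute == pytest.approx(ss, rel=1e-3)

    def test_dose_linearity(self, typical_individual):
        assert pk_core.cmin_ss(400.0, 24.0, typical_individual) == \
            pytest.approx(2 * pk_core.cmin_ss(200.0, 24.0, typical_individual))

    def test_auc_values(self, typical_individual):
        assert pk_core.auc_ss(200.0, typical_individual) == \
            pytest.approx(86.96, abs=5e-3)
        ind = IndividualParameters(cl=2.0, v=500.0, ka=2.5)
        assert pk_core.auc_ss(100.0, ind) == pytest.approx(50.0)

    def test_auc_equals_numeric_integral_over_interval(self, typical_individual):
        n = int(20 * pk_core.half_life(typical_individual) / 24.0) + 1
        doses = [DoseEvent(time=24.0 * k, amount=200.0) for k in range(n)]
        t = np.linspace(24.0 * (n - 1), 24.0 * n, 2001)
        c = pk_core.concentration(t, doses, typical_individual)
        auc_num = np.trapezoid(c, t)
        assert auc_num == pytest.approx(
            pk_core.auc_ss(200.0, typical_individual), rel=5e-3)


class TestTmaxHalfLife:
    def test_tmax_base_model(self):
        ind = IndividualParameters(cl=2.2, v=550.0, ka=2.5)
        assert round(pk_core.tmax(ind), 1) == 2.6

    def test_tmax_matches_profile_argmax(self, typical_individual):
        t = np.linspace(0.01, 12.0, 24000)
        c = pk_core.concentration(
            t, [DoseEvent(time=0.0, amount=200.0)], typical_individual)
        assert t[np.argmax(c)] == pytest.approx(
            pk_core.tmax(typical_individual), abs=0.01)

    def test_tmax_monotone_in_ka(self, typical_individual):
        faster = IndividualParameters(cl=typical_individual.cl,
                                      v=typical_individual.v, ka=5.0)
        assert pk_core.tmax(faster) < pk_core.tmax(typical_individual)

    def test_half_life_values(self, typical_individual):
        assert pk_core.half_life(typical_individual) == \
            pytest.approx(157.6, abs=0.05)
        unit = IndividualParameters(cl=math.log(2) * 300.0, v=300.0, ka=2.5)
        assert pk_core.half_life(unit) == pytest.approx(1.0)

    def test_half_life_scale_invariant(self, typical_individual):
        scaled = IndividualParameters(cl=3 * typical_individual.cl,
                                      v=3 * typical_individual.v, ka=2.5)
        assert pk_core.half_life(scaled) == \
            pytest.approx(pk_core.half_life(typical_individual))


@settings(max_examples=25, deadline=None)
@given(
    cl=st.floats(0.5, 8.0), vscale=st.floats(0.5, 2.0),
    dose=st.floats(50.0, 400.0), t=st.floats(0.5, 400.0),
)
def test_block_evaluation_matches_per_dose_superposition(cl, vscale, dose, t):
    """Geometric-series block sums equal explicit per-dose superposition."""
    v = 523.0 * vscale
    doses = ([DoseEvent(time=24.0 * k, amount=dose, route="intravenous",
                        infusion_duration=1.0) for k in range(3)]
             + [DoseEvent(time=24.0 * k, amount=dose) for k in range(3, 12)])
    ind = IndividualParameters(cl=cl, v=v, ka=2.5)
    ref = pk_core.concentration(t, doses, ind)

    from isapk.poppk_fit import _dose_blocks
    blocks = _dose_blocks(doses)
    B = len(blocks)
    arr = lambda idx: np.array([[b[idx] for b in blocks]], float)
    val = pk_core.concentration_blocks(
        np.array([[t]]), arr(0), arr(1), arr(2), arr(3), arr(4), arr(5),
        np.array([cl]), np.array([v]), 2.5)[0, 0]
    assert val == pytest.approx(ref, rel=1e-9, abs=1e-12)


@settings(max_examples=20, deadline=None)
@given(factor=st.floats(0.25, 4.0))
def test_exposure_metrics_dose_linearity(factor, typical_individual):
    base = pk_core.exposure_metrics(200.0, 24.0, typical_individual)
    scaled = pk_core.exposure_metrics(200.0 * factor, 24.0, typical_individual)
    assert scaled.cmin_ss == pytest.approx(base.cmin_ss * factor, rel=1e-12)
    assert scaled.auc_tau == pytest.approx(base.auc_tau * factor, rel=1e-12)
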