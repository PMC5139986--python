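"""Scalp Windkessel: calibration identities, flow laws, step-response dynamics."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fnirsim.errors import CalibrationError, ModelDomainError
from fnirsim.scalp import (
    ScalpParams,
    calibrate_scalp,
    conductance_from_flow,
    fit_pressure_flow_coefficients,
    scalp_derivatives,
    scalp_flow_flux,
    scalp_flow_pressure,
    scalp_oxygen,
    scalp_state_from_flow,
    scalp_steady_state,
)
from fnirsim.types import SystemicInputs


@pytest.fixture(scope="module")
def scalp():
    params, base = calibrate_scalp()
    return params, base


class TestCalibration:
    def test_default_baseline_volumes(self, scalp):
        params, base = scalp
        assert base.Va == pytest.approx(0.25, abs=1e-12)
        assert base.Vv == pytest.approx(0.75, abs=1e-12)
        assert base.Va + base.Vv == pytest.approx(1.0, abs=1e-12)

    def test_default_compliant_venous_volume(self, scalp):
        params, base = scalp
        assert base.Pv * params.Cv == pytest.approx(0.075, abs=1e-12)

    def test_venous_pressure_is_resistance_share_of_arterial(self, scalp):
        params, base = scalp
        assert base.Pv / params.Pa_n == pytest.approx(params.Rfrac_v, abs=1e-12)

    def test_unit_vratio_splits_volumes_equally(self):
        params, base = calibrate_scalp(ScalpParams(vratio=1.0))
        assert base.Va == pytest.approx(0.5)
        assert base.Vv == pytest.approx(0.5)

    def test_inconsistent_parameters_rejected(self):
        with pytest.raises(CalibrationError, match="Rfrac_v|Volc_frac"):
            calibrate_scalp(ScalpParams(Rfrac_v=1.5))

    def test_baseline_is_steady(self, scalp):
        params, base = scalp
        assert scalp_derivatives(base, params.Pa_n, params.q_n, params) == pytest.approx(
            0.0, abs=1e-12
        )


class TestFlowModels:
    def test_pressure_flow_arithmetic(self):
        p = ScalpParams(lam_Fx=10.0, lam_Fx_p=0.4)
        assert scalp_flow_pressure(100.0, p) == pytest.approx(50.0)

    def test_pressure_flow_degenerate_slope_is_constant(self):
        p = ScalpParams(lam_Fx=5.0, lam_Fx_p=0.0)
        assert scalp_flow_pressure(75.0, p) == scalp_flow_pressure(125.0, p) == 5.0

    def test_fitted_coefficients_give_increasing_flow(self, scalp):
        params, _ = scalp
        assert params.lam_Fx_p > 0
        assert scalp_flow_pressure(125.0, params) > scalp_flow_pressure(100.0, params)

    def test_fit_recovers_slope_from_exact_table(self):
        table = np.column_stack([np.linspace(80, 120, 9), 0.2 + 0.008 * np.linspace(80, 120, 9)])
        lam, lam_p = fit_pressure_flow_coefficients(table, q_n=1.0)
        assert lam == pytest.approx(0.2, abs=1e-12)
        assert lam_p == pytest.approx(0.008, abs=1e-12)

    def test_flux_flow_is_scaling_by_normal_value(self):
        p = ScalpParams(Fy_n=50.0)
        assert scalp_flow_flux(1.0, p) == pytest.approx(50.0)
        assert scalp_flow_flux(1.2, p) == pytest.approx(60.0)

    def test_flux_normal_value_matches_pressure_model_baseline(self, scalp):
        params, _ = scalp
        assert params.Fy_n == pytest.approx(scalp_flow_pressure(params.Pa_n, params), rel=1e-12)

    def test_non_positive_flow_rejected(self):
        p = ScalpParams(lam_Fx=-100.0, lam_Fx_p=0.1)
        with pytest.raises(CalibrationError):
            scalp_flow_pressure(100.0, p)


class TestDynamics:
    def test_steady_state_is_conductance_divider(self, scalp):
        params, _ = scalp
        ss = scalp_steady_state(100.0, 0.12, params)
        assert ss.Pv == pytest.approx(ss.G * 100.0 / (ss.G + params.Gv), rel=1e-12)

    def test_symmetric_divider_halves_pressure(self, scalp):
        params, _ = scalp
        # choose the flow so that the implied G equals Gv
        F = params.Gv * 100.0 / 2.0
        ss = scalp_steady_state(100.0, F, params)
        assert ss.G == pytest.approx(params.Gv, rel=1e-12)
        assert ss.Pv == pytest.approx(50.0, rel=1e-12)

    def test_geometry_relations_hold(self, scalp):
        params, _ = scalp
        st = scalp_state_from_flow(9.0, 110.0, 0.12, params)
        assert st.G / params.G_n == pytest.approx(st.r**4, rel=1e-12)
        assert st.Va / params.Va_n == pytest.approx(st.r**2, rel=1e-12)

    def test_step_response_matches_analytic_exponential(self, scalp):
        """A pressure step relaxes Pv (hence Vv) exponentially with time
        constant Cv/(G+Gv); the trajectory matches the closed form to <1%."""
        params, base = scalp
        Pa1 = 125.0
        F1 = scalp_flow_pressure(Pa1, params)
        G1 = conductance_from_flow(F1, Pa1, params)
        tau = params.Cv / (G1 + params.Gv)
        Pv_inf = G1 * Pa1 / (G1 + params.Gv)

        def rhs(t, y):
            st = scalp_state_from_flow(y[0], Pa1, F1, params)
            return [scalp_derivatives(st, Pa1, F1, params)]

        t_eval = np.linspace(0.0, 5.0 * tau, 200)
        sol = solve_ivp(rhs, (0.0, 5.0 * tau), [base.Pv], t_eval=t_eval,
                        rtol=1e-10, atol=1e-12)
        analytic = Pv_inf + (base.Pv - Pv_inf) * np.exp(-t_eval / tau)
        # compare venous volumes (the NIRS-relevant quantity)
        vv_num = params.Vv_nc + sol.y[0] * params.Cv
        vv_ana = params.Vv_nc + analytic * params.Cv
        assert np.max(np.abs(vv_num - vv_ana) / np.abs(vv_ana - vv_ana[-1] + 1e-12).max()) < 0.01

    def test_flow_exceeding_venous_capacity_rejected(self, scalp):
        params, _ = scalp
        with pytest.raises(ModelDomainError):
            conductance_from_flow(params.Gv * 100.0 + 0.1, 100.0, params)

    def test_same_direction_hb_changes_without_saturation_change(self, scalp):
        """With fixed saturations, scalp dHbO2 and dHHb always move together:
        the compartment cannot produce opposing changes."""
        params, base = scalp
        sa, sv = 96.0, params.SvO2_n
        for F in (0.08, 0.11, 0.125):
            ss = scalp_steady_state(100.0, F, params)
            d_hbo2 = (ss.Va - base.Va) * sa / 100 + (ss.Vv - base.Vv) * sv / 100
            d_hhb = (ss.Va - base.Va) * (1 - sa / 100) + (ss.Vv - base.Vv) * (1 - sv / 100)
            assert d_hbo2 * d_hhb >= 0

    def test_shape_insensitive_to_volume_resistance_fractions(self):
        """Varying Volc_frac and Rfrac_v by +/-50% leaves the normalised
        pressure-step haemoglobin response within a small envelope once the
        sub-sampling-interval venous transient has passed (Pv << Pa)."""
        shapes = []
        t_eval = np.arange(0.0, 61.0, 1.0)
        for volc in (0.05, 0.1, 0.15):
            for rfrac in (0.05, 0.1, 0.15):
                params, base = calibrate_scalp(ScalpParams(Volc_frac=volc, Rfrac_v=rfrac))
                Pa1 = 125.0
                F1 = scalp_flow_pressure(Pa1, params)

                def rhs(t, y):
                    st = scalp_state_from_flow(y[0], Pa1, F1, params)
                    return [scalp_derivatives(st, Pa1, F1, params)]

                sol = solve_ivp(rhs, (0.0, 60.0), [base.Pv], t_eval=t_eval,
                                rtol=1e-9, atol=1e-11)
                states = [scalp_state_from_flow(pv, Pa1, F1, params) for pv in sol.y[0]]
                d_hbo2 = np.array(
                    [(s.Va - base.Va) * 0.96 + (s.Vv - base.Vv) * 0.70 for s in states]
                )
                shapes.append(d_hbo2 / d_hbo2[-1])
        shapes = np.array(shapes)
        spread = np.max(shapes, axis=0) - np.min(shapes, axis=0)
        assert np.max(spread[5:]) < 0.05  # regression envelope, t >= 5 s


class TestOxygen:
    def test_arterial_passthrough_and_fixed_venous(self, scalp):
        params, base = scalp
        sat_a, sat_v = scalp_oxygen(base, 96.0, params)
        assert sat_a == 96.0
        assert sat_v == params.SvO2_n

    def test_saturation_step_is_instantaneous_and_venous_invariant(self, scalp):
        params, base = scalp
        for sa in (90.0, 96.0, 100.0):
            sat_a, sat_v = scalp_oxygen(base, sa, params)
            assert sat_a == sa
            assert sat_v == params.SvO2_n


def test_conditional_independence_of_compartments(scalp):
    """No scalp quantity depends on cerebral state: the scalp response is
    bit-identical when the cerebral parameterisation changes."""
    import dataclasses

    from fnirsim.config import default_config
    from fnirsim.simulation import build_step_protocol, run_simulation

    cfg1 = default_config()
    from fnirsim.cerebral import calibrate_cerebral

    cfg2 = dataclasses.replace(cfg1, cerebral=calibrate_cerebral(targets={}, g_P=0.1))
    tl = build_step_protocol("Pa")
    r1 = run_simulation(tl, cfg1)
    r2 = run_simulation(tl, cfg2)
    # the equations are uncoupled; joint integration only adds error at the
    # solver tolerance (rtol 1e-6 on uM-scale signals)
    assert np.allclose(r1.df["dHbO2_scalp"], r2.df["dHbO2_scalp"], atol=1e-4)
    assert np.allclose(r1.df["dHHb_scalp"], r2.df["dHHb_scalp"], atol=1e-4)
    # ...while the cerebral response did change
    assert not np.array_equal(r1.df["dHbO2_cerebral"], r2.df["dHbO2_cerebral"])
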