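import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from poppk import PKParameters, predict_concentration, steady_state_metrics
from poppk.structural import (
    concentration_batch,
    disposition_constants,
    steady_state_profile,
)

SINGLE_DOSE_TIMES = [1, 2, 4, 6, 8, 12, 24, 48, 72, 96]


def ode_concentration(p, dose_mg, times):
    """High-accuracy ODE integration of the 3-state absorption system."""
    d = disposition_constants(p)

    def rhs(t, y):
        depot, central, peripheral = y
        return [
            -p.ka * depot,
            p.ka * depot - (d["k10"] + d["k12"]) * central + d["k21"] * peripheral,
            d["k12"] * central - d["k21"] * peripheral,
        ]

    times = np.asarray(times, dtype=float)
    shifted = times - p.tlag
    out = np.zeros_like(times)
    pos = shifted > 0
    if pos.any():
        sol = solve_ivp(
            rhs,
            [0.0, shifted[pos].max()],
            [dose_mg, 0.0, 0.0],
            t_eval=np.sort(shifted[pos]),
            rtol=1e-10,
            atol=1e-13,
        )
        order = np.argsort(shifted[pos])
        vals = np.empty_like(sol.t)
        vals[order] = sol.y[1]
        out[pos] = 1000.0 * vals / p.v
    return out


class TestClosedForm:
    def test_zero_before_lag(self, typical_params):
        c = predict_concentration(typical_params, [(0.0, 100.0)], [0.2])
        assert c.concentrations[0] == 0.0

    def test_matches_ode_at_typical_parameters(self, typical_params):
        times = np.array(SINGLE_DOSE_TIMES, dtype=float)
        closed = predict_concentration(typical_params, [(0.0, 100.0)], times)
        ode = ode_concentration(typical_params, 100.0, times)
        np.testing.assert_allclose(closed.concentrations, ode, rtol=1e-6)

    def test_dose_linearity(self, typical_params):
        times = [2.0, 12.0, 48.0]
        c100 = predict_concentration(typical_params, [(0.0, 100.0)], times)
        c900 = predict_concentration(typical_params, [(0.0, 900.0)], times)
        np.testing.assert_allclose(
            c900.concentrations, 9.0 * c100.concentrations, rtol=1e-12
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        ka=st.floats(0.1, 5.0),
        tlag=st.floats(0.0, 2.0),
        v=st.floats(5.0, 100.0),
        v2=st.floats(5.0, 100.0),
        cl=st.floats(0.2, 20.0),
        cl2=st.floats(0.05, 10.0),
    )
    def test_matches_ode_for_random_parameters(self, ka, tlag, v, v2, cl, cl2):
        p = PKParameters(ka=ka, tlag=tlag, v=v, v2=v2, cl=cl, cl2=cl2)
        times = np.array([0.5, 1, 3, 7, 13, 25, 49, 97], dtype=float)
        closed = predict_concentration(p, [(0.0, 300.0)], times).concentrations
        ode = ode_concentration(p, 300.0, times)
        scale = max(ode.max(), 1e-6)
        np.testing.assert_allclose(closed / scale, ode / scale, atol=2e-6)

    def test_multiple_dose_superposition(self, typical_params):
        doses = [(0.0, 100.0), (24.0, 100.0)]
        t = [30.0]
        both = predict_concentration(typical_params, doses, t).concentrations
        first = predict_concentration(typical_params, [doses[0]], t).concentrations
        second = predict_concentration(typical_params, [doses[1]], t).concentrations
        np.testing.assert_allclose(both, first + second, rtol=1e-12)

    def test_batch_agrees_with_scalar_path(self, typical_params):
        p = typical_params
        theta = np.array(
            [[p.ka, p.tlag, p.v, p.v2, p.cl, p.cl2],
             [1.0, 0.1, 30.0, 20.0, 2.0, 1.0]]
        )
        times = np.array([1.0, 6.0, 30.0])
        batch = concentration_batch(theta, [0.0, 24.0], [100.0, 100.0], times)
        for row, pars in zip(batch, theta):
            pk = PKParameters(*pars)
            single = predict_concentration(
                pk, [(0.0, 100.0), (24.0, 100.0)], times
            ).concentrations
            np.testing.assert_allclose(row, single, rtol=1e-12)

    def test_ka_near_alpha_degeneracy_is_finite(self, typical_params):
        d = disposition_constants(typical_params)
        p = PKParameters(ka=float(d["alpha"]), tlag=0.35, v=26.21, v2=26.60,
                         cl=1.07, cl2=0.75)
        c = predict_concentration(p, [(0.0, 100.0)], [1.0, 10.0, 50.0])
        assert np.all(np.isfinite(c.concentrations))
        assert np.all(c.concentrations >= 0)


class TestDispositionConstants:
    def test_k10_quotient(self, typical_params):
        d = disposition_constants(typical_params)
        assert d["k10"] == pytest.approx(1.07 / 26.21, rel=1e-12)
        assert d["k10"] == pytest.approx(0.04082, abs=5e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        v=st.floats(5.0, 100.0),
        v2=st.floats(5.0, 100.0),
        cl=st.floats(0.2, 20.0),
        cl2=st.floats(0.05, 10.0),
    )
    def test_macro_micro_identities(self, v, v2, cl, cl2):
        p = PKParameters(ka=1.0, tlag=0.0, v=v, v2=v2, cl=cl, cl2=cl2)
        d = disposition_constants(p)
        assert d["alpha"] > d["beta"] > 0
        assert d["alpha"] * d["beta"] == pytest.approx(
            d["k10"] * d["k21"], rel=1e-12
        )
        assert d["alpha"] + d["beta"] == pytest.approx(
            d["k10"] + d["k12"] + d["k21"], rel=1e-12
        )

    def test_one_compartment_limit(self):
        # as CL2 -> 0 the surviving macro rate tends to k10 = CL/V and the
        # profile collapses onto the one-compartment oral solution
        p = PKParameters(ka=1.0, tlag=0.0, v=20.0, v2=20.0, cl=2.0, cl2=1e-7)
        d = disposition_constants(p)
        assert d["alpha"] == pytest.approx(d["k10"], rel=1e-5)
        t = np.array([1.0, 5.0, 20.0])
        k = 2.0 / 20.0
        one_cpt = 1000.0 * 100.0 * 1.0 / 20.0 / (1.0 - k) * (
            np.exp(-k * t) - np.exp(-1.0 * t)
        )
        two_cpt = predict_concentration(p, [(0.0, 100.0)], t).concentrations
        np.testing.assert_allclose(two_cpt, one_cpt, rtol=1e-4)


class TestSteadyState:
    def test_auc_is_dose_over_clearance(self, typical_params):
        met = steady_state_metrics(typical_params, 900.0, 24.0)
        assert met.auc_ss == pytest.approx(1000.0 * 900.0 / 1.07, rel=1e-12)
        # and the profile integrates to the same number
        grid = np.linspace(0.0, 24.0, 4001)
        conc = steady_state_profile(typical_params, 900.0, 24.0, grid)
        assert np.trapezoid(conc, grid) == pytest.approx(met.auc_ss, rel=1e-3)

    def test_trough_peak_match_day21_profile(self, typical_params):
        # by day 21 of once-daily dosing the system is near steady state
        met = steady_state_metrics(typical_params, 900.0, 24.0)
        doses = [(0.0, 900.0)] + [(96.0 + 24.0 * i, 900.0) for i in range(21)]
        trough = predict_concentration(typical_params, doses, [600.0])
        assert trough.concentrations[0] == pytest.approx(met.cmin_ss, rel=5e-3)
        fine = np.linspace(576.0, 600.0, 2000)
        peak = predict_concentration(typical_params, doses, fine)
        assert peak.concentrations.max() == pytest.approx(met.cmax_ss, rel=5e-3)

    def test_long_interval_trough_vanishes(self, typical_params):
        met = steady_state_metrics(typical_params, 900.0, 2000.0, grid_step=5.0)
        assert met.cmin_ss < 1e-6 * met.cmax_ss

    def test_cmin_le_cmax(self, typical_params):
        met = steady_state_metrics(typical_params, 300.0, 24.0)
        assert 0 < met.cmin_ss <= met.cmax_ss

    def test_invalid_inputs_rejected(self, typical_params):
        with pytest.raises(ValueError):
            steady_state_metrics(typical_params, -1.0, 24.0)
        with pytest.raises(ValueError):
            steady_state_metrics(typical_params, 900.0, 0.0)
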