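import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

import dapapkpd.pk_model as pk


class TestCovariateCL:
    def test_normalisation_point(self):
        assert pk.covariate_cl(229.3, 0.41, 77.0, 77.0) == pytest.approx(229.3)

    def test_power_function_value(self):
        # direct evaluation: 229.3 * (100/77)^0.41
        assert pk.covariate_cl(229.3, 0.41, 100.0, 77.0) == pytest.approx(
            255.2365, abs=1e-3)

    def test_zero_exponent_ignores_weight(self):
        assert pk.covariate_cl(229.3, 0.0, 49.0, 77.0) == pytest.approx(229.3)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            pk.covariate_cl(229.3, 0.41, 0.0, 77.0)


def _ode_single_dose(t, dose, ka, cl, vf):
    """Independent oracle: integrate the absorption/disposition system."""
    def rhs(_, y):
        a, c = y
        return [-ka * a, ka * a / vf - cl / vf * c]

    sol = solve_ivp(rhs, [0.0, max(t, 1e-9)], [dose, 0.0], rtol=1e-10,
                    atol=1e-12, t_eval=[t])
    return sol.y[1, -1] / 1000.0  # ng/L -> ng/mL


class TestSingleDose:
    def test_zero_at_dose_time(self):
        assert pk.conc_single_dose(0.0, 5e6, 57.4, 229.3, 73.9) == 0.0

    def test_matches_ode_oracle_at_one_day(self):
        got = pk.conc_single_dose(1.0, 5e6, 57.4, 229.3, 73.9)
        want = _ode_single_dose(1.0, 5e6, 57.4, 229.3, 73.9)
        assert got == pytest.approx(want, rel=1e-6)
        assert got == pytest.approx(3.2, abs=0.1)  # trough scale, ng/mL

    @pytest.mark.parametrize("ka,cl,vf", [
        (57.4, 229.3, 73.9), (5.0, 229.3, 73.9), (3.2, 229.3, 73.9),
        (3.103, 229.3, 73.9),  # ka almost equal to the elimination rate
        (0.9, 60.0, 30.0)])
    def test_ode_agreement_across_parameter_grid(self, ka, cl, vf):
        for t in (0.2, 1.0, 2.5):
            got = pk.conc_single_dose(t, 5e6, ka, cl, vf)
            want = _ode_single_dose(t, 5e6, ka, cl, vf)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12)

    def test_equal_rates_limit_is_continuous(self):
        k = 229.3 / 73.9
        exact = pk.conc_single_dose(1.0, 5e6, k, 229.3, 73.9)
        near = pk.conc_single_dose(1.0, 5e6, k * (1 + 1e-7), 229.3, 73.9)
        assert exact == pytest.approx(near, rel=1e-5)

    def test_fully_eliminated_at_long_times(self):
        assert pk.conc_single_dose(1e4, 5e6, 57.4, 229.3, 73.9) < 1e-12


class TestMultipleDosing:
    regimen = pk.Regimen(dose=5e6, interval=1.0, n_doses=365)
    fixed = pk.PKFixedEffects()
    ind = pk.PKIndividual(cl_f=229.3)

    def test_time_zero_only(self):
        reg = pk.Regimen(dose=5e6, n_doses=1)
        assert pk.conc_profile(reg, [0.0], self.ind, self.fixed) == [0.0]

    def test_before_start_is_zero_not_error(self):
        reg = pk.Regimen(dose=5e6, n_doses=10, start_time=5.0)
        out = pk.conc_profile(reg, [0.0, 2.0, 6.5], self.ind, self.fixed)
        assert out[0] == 0.0 and out[1] == 0.0 and out[2] > 0.0

    def test_steady_state_trough_in_reported_band(self):
        """A typical 77 kg patient on 5 mg once daily runs trough levels
        inside the reported 2-5 ng/mL window."""
        c = pk.conc_profile(self.regimen, [60.0], self.ind, self.fixed)[0]
        assert 2.0 < c < 5.0

    def test_thirty_doses_match_accumulation_formula(self):
        reg = pk.Regimen(dose=5e6, n_doses=31)
        got = pk.conc_profile(reg, [30.0], self.ind, self.fixed)[0]
        want = pk.steady_state_trough(5e6, self.fixed.ka, 229.3, self.fixed.v_f)
        assert got == pytest.approx(want, rel=1e-3)

    def test_superposition_linearity_in_dose(self):
        times = [0.5, 10.3, 40.0]
        reg2 = pk.Regimen(dose=1e7, interval=1.0, n_doses=365)
        c1 = pk.conc_profile(self.regimen, times, self.ind, self.fixed)
        c2 = pk.conc_profile(reg2, times, self.ind, self.fixed)
        np.testing.assert_allclose(c2, 2.0 * np.asarray(c1), rtol=1e-12)

    def test_periodic_at_steady_state(self):
        c = pk.conc_profile(self.regimen, [300.0, 301.0, 302.0], self.ind,
                            self.fixed)
        assert abs(c[1] - c[0]) < 1e-9 and abs(c[2] - c[1]) < 1e-9

    def test_average_steady_state_equals_dose_over_clearance(self):
        f = lambda t: pk.conc_profile(self.regimen, [t], self.ind, self.fixed)[0]
        avg, _ = quad(f, 300.0, 301.0, limit=200)
        want = 5e6 / 229.3 / 1000.0  # ng/mL
        assert avg == pytest.approx(want, rel=1e-4)

    def test_weight_blocks_match_per_dose_superposition(self):
        """Clearance re-evaluated per dosing interval equals the explicit
        dose-by-dose sum with the weight in force."""
        wt_t = [0.0, 10.0, 20.0]
        wt = [80.0, 76.0, 72.0]
        reg = pk.Regimen(dose=5e6, n_doses=30)
        got = pk.conc_profile(reg, [25.5], self.ind, self.fixed,
                              weight_times=wt_t, weights=wt)
        want = 0.0
        for d in range(26):  # doses administered before t = 25.5
            w = wt[np.searchsorted(wt_t, d, side="right") - 1]
            cl = pk.covariate_cl(self.fixed.theta_cl, self.fixed.theta_bw, w)
            want += pk.conc_single_dose(25.5 - d, 5e6, self.fixed.ka, cl,
                                        self.fixed.v_f)
        assert got == pytest.approx(want, rel=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(cl=st.floats(100.0, 500.0), t=st.floats(0.0, 50.0),
           n=st.integers(1, 50))
    def test_profile_never_negative(self, cl, t, n):
        reg = pk.Regimen(dose=5e6, n_doses=n)
        ind = pk.PKIndividual(cl_f=cl)
        assert pk.conc_profile(reg, [t], ind, self.fixed)[0] >= 0.0


class TestGuards:
    def test_flipflop_guard_on_fixed_effects(self):
        with pytest.raises(ValueError):
            pk.PKFixedEffects(theta_cl=-1.0)

    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            pk.Regimen(dose=0.0)

    def test_individual_positive_clearance(self):
        with pytest.raises(ValueError):
            pk.PKIndividual(cl_f=0.0)
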