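import numpy as np
import pytest

import dapapkpd.pd_model as pdm
from dapapkpd.pk_model import DoseBlocks, conc_blocks


@pytest.fixture(scope="module")
def fx():
    return pdm.PDFixedEffects()


@pytest.fixture(scope="module")
def daily_conc():
    """Typical once-daily 5 mg concentration profile (120 days)."""
    blocks = DoseBlocks([0.0], [120], [229.3], 5e6, 1.0)
    return lambda t: conc_blocks(np.asarray(t, dtype=float), blocks,
                                 57.4, 73.9)


class TestEffectLink:
    def test_half_maximal_at_ec50(self, fx):
        assert pdm.efc(23.7, 0.034, 23.7, 1.0) == pytest.approx(0.017)

    def test_zero_concentration_no_effect(self, fx):
        assert pdm.efc(0.0, 0.034, 23.7, 1.0) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            pdm.efc(-1.0, 0.034, 23.7)

    def test_scaling_zero_at_floor(self):
        assert pdm.ef(5.0, 0.03) == 0.0

    def test_scaling_identity_at_reference_baseline(self):
        assert pdm.ef(8.0, 0.03) == pytest.approx(0.03)

    def test_scaling_linear_between(self):
        assert pdm.ef(6.5, 0.03) == pytest.approx(0.015)

    def test_below_floor_clipped(self):
        assert pdm.ef(4.0, 0.03) == 0.0


class TestDerivative:
    def test_rest_at_baseline_without_drug(self, fx):
        ind = pdm.PDIndividual(16.1, 6.8)
        assert pdm.hba1c_derivative(6.8, 0.0, ind, fx) == pytest.approx(0.0)

    def test_saturation_limit_arithmetic(self, fx):
        ind = pdm.PDIndividual(16.1, 8.0)
        kout = np.log(2) / 16.1
        want = ind.kin - 0.034 - kout * 8.0
        got = pdm.hba1c_derivative(8.0, 1e12, ind, fx)
        assert got == pytest.approx(want, rel=1e-6)

    def test_no_effect_reduces_to_plain_turnover(self):
        fx0 = pdm.PDFixedEffects(emax=1e-300)
        ind = pdm.PDIndividual(16.1, 7.5)
        got = pdm.hba1c_derivative(7.0, 50.0, ind, fx0)
        assert got == pytest.approx(ind.kin - ind.kout * 7.0, rel=1e-9)


class TestProfile:
    def test_no_drug_invariance(self, fx):
        ind = pdm.PDIndividual(16.1, 6.8)
        h = pdm.hba1c_profile(ind, fx, lambda t: np.zeros_like(
            np.asarray(t, dtype=float)), [0.0, 30.0, 180.0, 365.0])
        np.testing.assert_allclose(h, 6.8, atol=1e-8)

    def test_constant_ec50_converges_to_closed_form_root(self, fx):
        """At C = EC50 from an 8.0% baseline the steady state solves a
        linear equation, ~7.65%."""
        ind = pdm.PDIndividual(16.1, 8.0)
        want = pdm.constant_conc_steady_state(23.7, 8.0, fx)
        assert want == pytest.approx(7.651, abs=5e-3)
        got = pdm.hba1c_profile(ind, fx, lambda t: np.full_like(
            np.asarray(t, dtype=float), 23.7), [600.0])[0]
        assert got == pytest.approx(want, rel=1e-6)

    def test_monotone_decrease_under_constant_concentration(self, fx):
        ind = pdm.PDIndividual(16.1, 8.0)
        t = np.linspace(0, 200, 41)
        h = pdm.hba1c_profile(ind, fx, lambda x: np.full_like(
            np.asarray(x, dtype=float), 23.7), t)
        assert np.all(np.diff(h) < 0)

    def test_floor_never_crossed(self):
        fx_strong = pdm.PDFixedEffects(emax=5.0, ec50=1.0)
        ind = pdm.PDIndividual(5.0, 6.0)
        h = pdm.hba1c_profile(ind, fx_strong, lambda t: np.full_like(
            np.asarray(t, dtype=float), 1e4), np.linspace(0, 400, 30))
        assert np.all(h >= 5.0)

    def test_fast_path_matches_adaptive_solver(self, fx, daily_conc):
        """The exact exponential update and a generic adaptive solver are
        two independent integrations of the same linear ODE."""
        ind = pdm.PDIndividual(16.1, 8.0)
        times = [10.0, 30.0, 60.0, 100.0]
        fast = pdm.hba1c_profile(ind, fx, daily_conc, times, method="fast")
        ode = pdm.hba1c_profile(ind, fx, daily_conc, times, method="ode",
                                rtol=1e-11, atol=1e-12)
        np.testing.assert_allclose(fast, ode, rtol=1e-6)

    def test_fast_path_fractional_times(self, fx, daily_conc):
        ind = pdm.PDIndividual(16.1, 7.0)
        fast = pdm.hba1c_profile(ind, fx, daily_conc, [10.25, 10.75],
                                 method="fast")
        ode = pdm.hba1c_profile(ind, fx, daily_conc, [10.25, 10.75],
                                method="ode", rtol=1e-11, atol=1e-12)
        np.testing.assert_allclose(fast, ode, rtol=1e-6)

    def test_baseline_scaling_mode_differs_but_matches_its_solver(self, fx,
                                                                  daily_conc):
        ind = pdm.PDIndividual(16.1, 6.5)
        t = [20.0, 60.0]
        fast = pdm.hba1c_profile(ind, fx, daily_conc, t, method="fast",
                                 effect_scaling="baseline")
        ode = pdm.hba1c_profile(ind, fx, daily_conc, t, method="ode",
                                effect_scaling="baseline",
                                rtol=1e-11, atol=1e-12)
        np.testing.assert_allclose(fast, ode, rtol=1e-6)


class TestEngine:
    def test_matches_scalar_fast_path(self, fx, daily_conc):
        blocks = DoseBlocks([0.0], [120], [229.3], 5e6, 1.0)
        days = np.array([0, 10, 30, 60, 100])
        eng = pdm.TurnoverEngine([blocks], [days], 57.4, 73.9)
        eng.set_effect(fx.emax, fx.ec50, fx.hill)
        got = eng.trajectories(np.array([np.log(2) / 16.1]), np.array([8.0]))
        ind = pdm.PDIndividual(16.1, 8.0)
        want = pdm.hba1c_profile(ind, fx, daily_conc, days.astype(float))
        np.testing.assert_allclose(got[0], want, rtol=1e-9)

    def test_changing_clearance_blocks_match_ode(self, fx):
        """Weight-driven clearance changes mid-treatment: engine vs the
        adaptive solver on the identical concentration function."""
        blocks = DoseBlocks([0.0, 30.0], [30, 60], [250.0, 210.0], 5e6, 1.0)
        cf = lambda t: conc_blocks(np.asarray(t, dtype=float), blocks,
                                   57.4, 73.9)
        days = np.array([0, 15, 30, 45, 90])
        eng = pdm.TurnoverEngine([blocks], [days], 57.4, 73.9)
        eng.set_effect(fx.emax, fx.ec50, fx.hill)
        got = eng.trajectories(np.array([np.log(2) / 16.1]), np.array([7.2]))
        ind = pdm.PDIndividual(16.1, 7.2)
        want = pdm.hba1c_profile(ind, fx, cf, days.astype(float),
                                 method="ode", rtol=1e-11, atol=1e-12)
        np.testing.assert_allclose(got[0], want, rtol=2e-6)

    def test_dose_monotonicity_pointwise(self, fx):
        """Doubling the dose can only lower HbA1c, subject by subject."""
        rng = np.random.default_rng(3)
        n = 12
        cl = 229.3 * np.exp(rng.normal(0, 0.14, n))
        kout = np.log(2) / (16.1 * np.exp(rng.normal(0, 0.85, n)))
        h0 = rng.uniform(5.8, 8.5, n)
        days = np.arange(0, 366, 15)
        blocks = [DoseBlocks([0.0], [365], [c], 5e6, 1.0) for c in cl]
        eng = pdm.TurnoverEngine(blocks, [days] * n, 57.4, 73.9)
        eng.set_effect(fx.emax, fx.ec50, fx.hill, dose_scale=1.0)
        h5 = eng.trajectories(kout, h0)
        eng.set_effect(fx.emax, fx.ec50, fx.hill, dose_scale=2.0)
        h10 = eng.trajectories(kout, h0)
        assert np.all(h10 <= h5 + 1e-12)

    def test_infinite_dose_reaches_saturated_effect(self, fx):
        blocks = [DoseBlocks([0.0], [365], [229.3], 5e6, 1.0)]
        days = np.array([0, 365])
        eng = pdm.TurnoverEngine(blocks, [days], 57.4, 73.9)
        eng.set_effect(fx.emax, fx.ec50, fx.hill, dose_scale=np.inf)
        got = eng.trajectories(np.array([np.log(2) / 16.1]),
                               np.array([8.0]))[0, 1]
        want = pdm.constant_conc_steady_state(1e15, 8.0, fx)
        assert got == pytest.approx(want, rel=1e-6)


class TestValidation:
    def test_fixed_effects_positivity(self):
        with pytest.raises(ValueError):
            pdm.PDFixedEffects(emax=0.0)

    def test_floor_below_reference(self):
        with pytest.raises(ValueError):
            pdm.PDFixedEffects(floor=9.0)

    def test_kin_kout_relation(self):
        ind = pdm.PDIndividual(16.1, 6.8)
        assert ind.kin == pytest.approx(ind.kout * 6.8)
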