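import json
import math

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss

import dapapkpd.nlme as nlme
from dapapkpd.constants import BW_REF_KG, cv_from_omega2, omega2_from_cv
from dapapkpd.pk_model import KA_FIXED, VF_FIXED


class ToyExpProblem:
    """One-parameter toy: f_ij = a_j * exp(eta_i), additive or proportional
    noise.  Simple enough for the exact marginal likelihood by quadrature."""

    theta_names = ["base"]
    theta_log = [True]

    def __init__(self, y, subject_index, a):
        self.y = np.asarray(y, dtype=float)
        self.subject_index = np.asarray(subject_index, dtype=int)
        self.n_subjects = int(self.subject_index.max()) + 1
        self.subjects = list(range(self.n_subjects))
        self.a = np.asarray(a, dtype=float)

    def predict(self, theta, eta):
        return theta[0] * self.a * np.exp(np.asarray(eta)[self.subject_index])


def quadrature_m2ll(problem, theta, omega2, sigma, kind, n_nodes=41):
    """Independent oracle: adaptive Gauss-Hermite marginal likelihood with
    the envelope centred per subject by a dense mode scan."""
    z, w = hermegauss(n_nodes)
    total = 0.0
    for i in range(problem.n_subjects):
        idx = problem.subject_index == i
        y = problem.y[idx]
        a = problem.a[idx]

        def m2logjoint(eta):
            f = theta[0] * a * math.exp(eta)
            v = sigma ** 2 if kind == "additive" else (sigma * f) ** 2
            return (np.sum((y - f) ** 2 / v + np.log(2 * np.pi * v))
                    + eta ** 2 / omega2 + math.log(2 * math.pi * omega2))

        scan = np.linspace(-6, 6, 2001)
        vals = np.array([m2logjoint(e) for e in scan])
        mode = scan[np.argmin(vals)]
        h = 1e-4
        curv = (m2logjoint(mode + h) - 2 * m2logjoint(mode)
                + m2logjoint(mode - h)) / h ** 2
        s = math.sqrt(2.0 / max(curv, 1e-6))
        nodes = mode + s * z
        logs = np.array([-0.5 * m2logjoint(n) + 0.5 * zz ** 2
                         for n, zz in zip(nodes, z)])
        m = logs.max()
        li = m + math.log(np.sum(w * np.exp(logs - m))) + math.log(s)
        total += -2.0 * li
    return total


def _toy(seed=0, n_subj=6, n_obs=4, omega=0.4, sigma=0.2, kind="additive"):
    rng = np.random.default_rng(seed)
    a = np.tile(np.linspace(0.5, 2.0, n_obs), n_subj)
    si = np.repeat(np.arange(n_subj), n_obs)
    eta = rng.normal(0, omega, n_subj)
    f = 1.3 * a * np.exp(eta[si])
    noise = rng.normal(0, 1, len(f))
    y = f + sigma * noise if kind == "additive" else f * (1 + sigma * noise)
    return ToyExpProblem(np.abs(y), si, a)


class TestObjective:
    def test_wls_limit_without_random_effects(self):
        """omega = 0 collapses the objective to weighted least squares."""
        p = _toy()
        res = nlme.ResidualErrorSpec("additive", sigma_add=0.2)
        got = nlme.foce_objective(p, np.array([1.3]), 0.0, res)
        pred = p.predict(np.array([1.3]), np.zeros(p.n_subjects))
        v = 0.2 ** 2
        want = np.sum((p.y - pred) ** 2 / v + np.log(2 * np.pi * v))
        assert got == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize("kind,sigma", [("additive", 0.2),
                                            ("proportional", 0.15)])
    @pytest.mark.parametrize("theta,omega2", [
        (1.3, 0.16), (0.9, 0.04), (1.8, 0.49)])
    def test_matches_quadrature_oracle_on_toys(self, kind, sigma, theta,
                                               omega2):
        """Laplace-at-the-mode vs 41-node adaptive Gauss-Hermite across a
        parameter grid: within 0.5 units of -2LL."""
        p = _toy(kind=kind)
        spec = (nlme.ResidualErrorSpec("additive", sigma_add=sigma)
                if kind == "additive"
                else nlme.ResidualErrorSpec("proportional", sigma_prop=sigma))
        got = nlme.foce_objective(p, np.array([theta]), omega2, spec)
        want = quadrature_m2ll(p, [theta], omega2, sigma, kind)
        assert got == pytest.approx(want, abs=0.5)

    def test_agq_refinement_tightens_quadrature_agreement(self):
        p = _toy(kind="additive")
        spec = nlme.ResidualErrorSpec("additive", sigma_add=0.2)
        st = nlme.EstimationSettings(agq_nodes=21)
        got = nlme.foce_objective(p, np.array([1.3]), 0.16, spec, settings=st)
        want = quadrature_m2ll(p, [1.3], 0.16, 0.2, "additive")
        assert got == pytest.approx(want, abs=0.05)

    def test_subject_order_exchangeable(self):
        p = _toy(n_subj=5)
        perm = np.array([3, 0, 4, 1, 2])
        p2 = ToyExpProblem(p.y, perm[p.subject_index], p.a)
        res = nlme.ResidualErrorSpec("additive", sigma_add=0.2)
        v1 = nlme.foce_objective(p, np.array([1.3]), 0.1, res)
        v2 = nlme.foce_objective(p2, np.array([1.3]), 0.1, res)
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_duplicated_population_doubles_the_objective(self):
        p = _toy(n_subj=4)
        p2 = ToyExpProblem(np.r_[p.y, p.y],
                           np.r_[p.subject_index, p.subject_index + 4],
                           np.r_[p.a, p.a])
        res = nlme.ResidualErrorSpec("additive", sigma_add=0.2)
        v1 = nlme.foce_objective(p, np.array([1.3]), 0.1, res)
        v2 = nlme.foce_objective(p2, np.array([1.3]), 0.1, res)
        assert v2 == pytest.approx(2 * v1, rel=1e-6)


class TestIndividualParams:
    def test_typical_individual(self):
        assert nlme.individual_params(229.3, 0.0) == pytest.approx(229.3)

    def test_lognormal_multiplication(self):
        assert nlme.individual_params(229.3, 0.1) == pytest.approx(
            253.41, abs=0.01)

    def test_cv_conventions(self):
        spec = nlme.RandomEffectSpec("CL/F", omega2_from_cv(13.9))
        assert spec.reported_cv == pytest.approx(13.9, rel=1e-9)


class TestFit:
    def test_toy_fit_recovers_and_aic_identity_holds(self):
        rng = np.random.default_rng(5)
        n_subj, n_obs = 40, 6
        a = np.tile(np.linspace(0.5, 2.0, n_obs), n_subj)
        si = np.repeat(np.arange(n_subj), n_obs)
        eta = rng.normal(0, 0.3, n_subj)
        y = 1.5 * a * np.exp(eta[si]) + rng.normal(0, 0.1, len(a))
        p = ToyExpProblem(y, si, a)
        res = nlme.fit(p, nlme.ResidualErrorSpec("additive", sigma_add=0.3),
                       [1.0], 0.04,
                       nlme.EstimationSettings(compute_se=False))
        assert res.theta["base"] == pytest.approx(1.5, rel=0.1)
        assert math.sqrt(res.omega2) == pytest.approx(0.3, rel=0.3)
        assert res.n_params == 3
        assert res.aic == pytest.approx(res.minus2ll + 2 * 3)

    def test_omega_zero_truth_estimated_near_boundary(self):
        rng = np.random.default_rng(6)
        n_subj, n_obs = 30, 5
        a = np.tile(np.linspace(0.5, 2.0, n_obs), n_subj)
        si = np.repeat(np.arange(n_subj), n_obs)
        y = 1.5 * a + rng.normal(0, 0.05, len(a))
        p = ToyExpProblem(y, si, a)
        res = nlme.fit(p, nlme.ResidualErrorSpec("additive", sigma_add=0.1),
                       [1.0], 0.04,
                       nlme.EstimationSettings(compute_se=False))
        assert math.sqrt(res.omega2) < 0.05

    def test_fit_result_serialises(self, tmp_path):
        p = _toy()
        res = nlme.fit(p, nlme.ResidualErrorSpec("additive", sigma_add=0.2),
                       [1.0], 0.1,
                       nlme.EstimationSettings(compute_se=False,
                                               outer_maxfev=150))
        path = tmp_path / "fit.json"
        res.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["theta"]["base"] == pytest.approx(res.theta["base"])
        assert payload["aic"] == pytest.approx(res.aic)
        assert len(payload["ebe"]) == p.n_subjects


class TestPKProblem:
    def test_prediction_unit_invariance(self, small_study):
        """Rescaling dose ng -> mg with matching concentration units
        leaves the weighted residuals (and hence estimates) unchanged."""
        _, _, _, table = small_study
        terms = [nlme.CovariateTerm("WT", "power", BW_REF_KG)]
        p = nlme.PopPKProblem(table, KA_FIXED, VF_FIXED, terms)
        theta = np.array([229.3, 0.41])
        eta = np.zeros(p.n_subjects)
        pred = p.predict(theta, eta)
        p2 = nlme.PopPKProblem(table, KA_FIXED, VF_FIXED, terms)
        p2.dose_amt = p.dose_amt / 1e6  # mg
        pred2 = p2.predict(theta, eta)
        np.testing.assert_allclose(pred2 * 1e6, pred, rtol=1e-12)

    def test_ebe_shrinkage_vanishes_with_rich_data(self, reference_params):
        """Empirical Bayes estimates approach the true etas as the
        residual noise shrinks."""
        from dapapkpd.cohort import CohortSpec, generate_study
        from dataclasses import replace

        truth = replace(reference_params, sigma_prop_pk=0.02)
        spec = CohortSpec(n_subjects=25, missingness=0.0)
        _, truth_df, table = generate_study(spec, truth, seed=9)
        terms = [nlme.CovariateTerm("WT", "power", BW_REF_KG)]
        p = nlme.PopPKProblem(table, KA_FIXED, VF_FIXED, terms)
        res = nlme.fit(p, nlme.ResidualErrorSpec("proportional",
                                                 sigma_prop=0.05),
                       [200.0, 0.5], 0.02,
                       nlme.EstimationSettings(compute_se=False))
        true_eta = truth_df.set_index("ID").loc[p.subjects, "ETA_CL"]
        assert np.corrcoef(res.ebe, true_eta)[0, 1] > 0.98


class TestResidualSpec:
    @pytest.mark.parametrize("kwargs", [
        dict(kind="additive"), dict(kind="proportional"),
        dict(kind="combined", sigma_add=0.1),
        dict(kind="nonsense", sigma_add=0.1)])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            nlme.ResidualErrorSpec(**kwargs)

    def test_combined_variance_components(self):
        spec = nlme.ResidualErrorSpec("combined", sigma_add=0.1,
                                      sigma_prop=0.2)
        assert spec.names() == ["sigma_add", "sigma_prop"]
        np.testing.assert_allclose(spec.sigma_vector(), [0.1, 0.2])
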