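"""Approximate-marginal-likelihood estimation for nonlinear mixed-effects
models with a single log-normal random effect per model.

The marginal likelihood of each subject is approximated by a Laplace-type
expansion at the conditional mode of the random effect (first-order
conditional estimation with interaction: the residual variance is evaluated
at the conditional prediction).  For subject *i* with conditional
predictions f_ij(eta) and residual variances v_ij,

    -2LL_i = sum_j [ ln(2 pi v_ij) + (y_ij - f_ij)^2 / v_ij ]
             + eta_hat^2 / omega^2 + ln(omega^2) + ln(kappa_i / 2),

evaluated at the mode eta_hat, where kappa_i is the curvature of the
conditional -2 log joint density at the mode.  With omega = 0 the objective
collapses to extended (variance-weighted) least squares.

Fixed effects, omega and the residual SDs are estimated jointly by a
derivative-free simplex on log-transformed positive parameters; standard
errors come from the central-difference Hessian of the objective at the
optimum and are reported as CV% (100 * SE / estimate).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import study_data as sd
from .constants import cv_from_omega2
from .pd_model import PDFixedEffects, TurnoverEngine
from .pk_model import DoseBlocks, _geom_decay

log = logging.getLogger(__name__)

_BIG = 1e10
_VAR_FLOOR = 1e-12


@dataclass
class RandomEffectSpec:
    """A log-normal inter-individual random effect on one parameter."""

    parameter_name: str
    omega2: float  # variance on the log scale

    def __post_init__(self) -> None:
        if self.omega2 < 0:
            raise ValueError("omega^2 must be non-negative")

    @property
    def reported_cv(self) -> float:
        return cv_from_omega2(self.omega2)


@dataclass
class ResidualErrorSpec:
    """Residual (within-subject) error model."""

    kind: str  # "additive" | "proportional" | "combined"
    sigma_add: float = 0.0   # DV units
    sigma_prop: float = 0.0  # fraction

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual error kind {self.kind!r}")
        if self.kind == "additive" and self.sigma_add <= 0:
            raise ValueError("additive error needs sigma_add > 0")
        if self.kind == "proportional" and self.sigma_prop <= 0:
            raise ValueError("proportional error needs sigma_prop > 0")
        if self.kind == "combined" and (self.sigma_add <= 0
                                        or self.sigma_prop <= 0):
            raise ValueError("combined error needs both components > 0")

    def sigma_vector(self) -> np.ndarray:
        if self.kind == "additive":
            return np.array([self.sigma_add])
        if self.kind == "proportional":
            return np.array([self.sigma_prop])
        return np.array([self.sigma_add, self.sigma_prop])

    def names(self) -> list[str]:
        if self.kind == "additive":
            return ["sigma_add"]
        if self.kind == "proportional":
            return ["sigma_prop"]
        return ["sigma_add", "sigma_prop"]


def individual_params(p_pop, eta):
    """Individual parameter under the log-normal model,
    ``P_i = P_pop * exp(eta_i)``."""
    return np.asarray(p_pop) * np.exp(np.asarray(eta))


def _residual_variance(pred, sigma_vec, kind):
    if kind == "additive":
        v = np.full_like(pred, sigma_vec[0] ** 2)
    elif kind == "proportional":
        v = (sigma_vec[0] * pred) ** 2
    else:
        v = sigma_vec[0] ** 2 + (sigma_vec[1] * pred) ** 2
    return np.maximum(v, _VAR_FLOOR)


@dataclass
class FitResult:
    """Estimates, precision, objective value and empirical Bayes estimates."""

    theta: dict
    theta_cv: dict
    omega2: float
    omega2_cv: float
    sigma: dict
    sigma_cv: dict
    minus2ll: float
    aic: float
    n_params: int
    ebe: np.ndarray
    subjects: list
    residual_kind: str
    convergence: dict = field(default_factory=dict)

    def omega_as_cv(self, convention: str = "lognormal") -> float:
        """IIV magnitude in CV%.  ``lognormal``: 100*sqrt(exp(w^2)-1)
        (the package's reporting convention); ``sd``: 100*sqrt(w^2)."""
        if convention == "lognormal":
            return cv_from_omega2(self.omega2)
        if convention == "sd":
            return 100.0 * math.sqrt(self.omega2)
        raise ValueError(f"unknown convention {convention!r}")

    def eta_for(self, subject_id) -> float:
        return float(self.ebe[self.subjects.index(subject_id)])

    def to_json(self, path=None) -> str:
        payload = {
            "theta": self.theta, "theta_cv_pct": self.theta_cv,
            "omega2": self.omega2, "omega_cv_pct": self.omega_as_cv(),
            "sigma": self.sigma, "sigma_cv_pct": self.sigma_cv,
            "minus2ll": self.minus2ll, "aic": self.aic,
            "n_params": self.n_params, "residual_kind": self.residual_kind,
            "ebe": {str(s): float(e)
                    for s, e in zip(self.subjects, self.ebe)},
            "convergence": self.convergence,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class EstimationSettings:
    inner_tol: float = 1e-7
    inner_maxiter: int = 60
    outer_maxfev: int = 800
    outer_fatol: float = 1e-6
    outer_xatol: float = 1e-5
    compute_se: bool = True
    eta_bound: float = 8.0  # hard clamp on |eta| during the inner search
    #: adaptive Gauss-Hermite nodes refining the Laplace marginal (0 = off,
    #: plain FOCE).  Useful when the random-effect variance is large and
    #: per-subject data sparse, where the Laplace step is least accurate.
    agq_nodes: int = 0


# ---------------------------------------------------------------------------
# objective


def _subject_ell(problem, theta, eta, sigma_vec, kind, omega2):
    """Conditional -2 log joint density per subject (2 pi terms dropped)."""
    pred = problem.predict(theta, eta)
    if pred is None or not np.all(np.isfinite(pred)):
        return None
    v = _residual_variance(pred, sigma_vec, kind)
    res = problem.y - pred
    per_obs = res * res / v + np.log(v)
    ell = np.bincount(problem.subject_index, weights=per_obs,
                      minlength=problem.n_subjects)
    if omega2 > 0:
        ell = ell + eta * eta / omega2
    return ell


def _inner_modes(problem, theta, omega2, sigma_vec, kind, eta0,
                 settings: EstimationSettings):
    """Vectorised damped-Newton search for every subject's conditional mode.

    Returns (eta_hat, ell_at_mode, curvature) or None on failure.
    """
    h = 1e-4
    eta = np.clip(eta0.copy(), -settings.eta_bound, settings.eta_bound)
    ell = _subject_ell(problem, theta, eta, sigma_vec, kind, omega2)
    if ell is None:
        return None
    curv = np.full(problem.n_subjects, 2.0 / max(omega2, 1e-8))
    for _ in range(settings.inner_maxiter):
        ellp = _subject_ell(problem, theta, eta + h, sigma_vec, kind, omega2)
        ellm = _subject_ell(problem, theta, eta - h, sigma_vec, kind, omega2)
        if ellp is None or ellm is None:
            return None
        g = (ellp - ellm) / (2 * h)
        c = (ellp - 2 * ell + ellm) / (h * h)
        curv = np.where(c > 1e-8, c, curv)
        scale = np.maximum(np.abs(ell), 1.0)
        active = np.abs(g) > settings.inner_tol * scale
        if not active.any():
            break
        step = np.where(active, -g / np.maximum(c, 1e-8), 0.0)
        step = np.clip(step, -1.0, 1.0)
        # backtracking on subjects whose objective worsened
        for _bt in range(8):
            eta_new = np.clip(eta + step, -settings.eta_bound,
                              settings.eta_bound)
            ell_new = _subject_ell(problem, theta, eta_new, sigma_vec, kind,
                                   omega2)
            if ell_new is None:
                return None
            worse = ell_new > ell + 1e-12
            if not worse.any():
                break
            step = np.where(worse, step * 0.5, step)
        accept = ell_new <= ell + 1e-12
        eta = np.where(accept, eta_new, eta)
        ell = np.where(accept, ell_new, ell)
    return eta, ell, np.maximum(curv, 1e-8)


def foce_objective(problem, theta, omega2: float, residual: ResidualErrorSpec,
                   eta0=None, settings: EstimationSettings | None = None,
                   return_eta: bool = False):
    """FOCE-I approximation to -2 log marginal likelihood, summed over
    subjects.  ``omega2 = 0`` gives the weighted-least-squares limit."""
    settings = settings or EstimationSettings()
    sigma_vec = residual.sigma_vector()
    kind = residual.kind
    n_obs = len(problem.y)
    if omega2 <= 0:
        eta = np.zeros(problem.n_subjects)
        ell = _subject_ell(problem, theta, eta, sigma_vec, kind, 0.0)
        if ell is None:
            return (_BIG, eta, None) if return_eta else _BIG
        m2ll = float(ell.sum() + n_obs * math.log(2 * math.pi))
        return (m2ll, eta, None) if return_eta else m2ll

    eta0 = np.zeros(problem.n_subjects) if eta0 is None else eta0
    res = _inner_modes(problem, theta, omega2, sigma_vec, kind, eta0, settings)
    if res is None:
        return (_BIG, eta0, None) if return_eta else _BIG
    eta, ell, curv = res
    if settings.agq_nodes and settings.agq_nodes > 1:
        m2ll = _agq_m2ll(problem, theta, eta, curv, omega2, sigma_vec, kind,
                         settings.agq_nodes)
    else:
        m2ll = float(ell.sum() + n_obs * math.log(2 * math.pi)
                     + problem.n_subjects * math.log(omega2)
                     + np.log(curv / 2.0).sum())
    if not np.isfinite(m2ll):
        m2ll = _BIG
    return (m2ll, eta, curv) if return_eta else m2ll


def _agq_m2ll(problem, theta, eta_hat, curv, omega2, sigma_vec, kind, K):
    """Adaptive Gauss-Hermite refinement of the per-subject marginal,
    centred at the conditional modes and scaled by the mode curvature."""
    from numpy.polynomial.hermite_e import hermegauss

    z, w = hermegauss(K)  # probabilists': int g(u) exp(-u^2/2) du ~ sum w g
    s = np.sqrt(2.0 / curv)
    n_i = np.bincount(problem.subject_index, minlength=problem.n_subjects)
    log_terms = np.empty((K, problem.n_subjects))
    for k in range(K):
        ell_k = _subject_ell(problem, theta, eta_hat + s * z[k], sigma_vec,
                             kind, omega2)
        if ell_k is None:
            return _BIG
        log_terms[k] = math.log(w[k]) + 0.5 * z[k] ** 2 - 0.5 * ell_k
    m = log_terms.max(axis=0)
    log_int = m + np.log(np.exp(log_terms - m).sum(axis=0)) + np.log(s)
    m2ll = (n_i * math.log(2 * math.pi)
            + math.log(2 * math.pi * omega2) * np.ones_like(log_int)
            - 2.0 * log_int).sum()
    return float(m2ll)


# ---------------------------------------------------------------------------
# outer optimisation


def _pack(theta, omega2, sigma_vec, theta_log):
    x = [math.log(t) if lg else t for t, lg in zip(theta, theta_log)]
    x.append(0.5 * math.log(omega2))
    x.extend(math.log(s) for s in sigma_vec)
    return np.array(x)


def _unpack(x, n_theta, theta_log, n_sigma):
    theta = np.array([math.exp(v) if lg else v
                      for v, lg in zip(x[:n_theta], theta_log)])
    omega2 = math.exp(2 * x[n_theta])
    sigma_vec = np.exp(x[n_theta + 1: n_theta + 1 + n_sigma])
    return theta, omega2, sigma_vec


def fit(problem, residual: ResidualErrorSpec, start_theta, start_omega2: float,
        settings: EstimationSettings | None = None,
        theta_bounds=None) -> FitResult:
    """Minimise the FOCE-I objective over (theta, omega, sigma).

    Positivity of log-transformed parameters is enforced by construction;
    empirical Bayes estimates are the final conditional modes.
    ``theta_bounds`` (per fixed effect, in natural units) constrain the
    search to a plausibility box; weakly identified parameters can
    otherwise drift along near-flat likelihood ridges.
    """
    settings = settings or EstimationSettings()
    theta0 = np.asarray(start_theta, dtype=float)
    theta_log = problem.theta_log
    n_theta = len(theta0)
    sigma0 = residual.sigma_vector()
    n_sigma = len(sigma0)
    kind = residual.kind

    warm = {"eta": np.zeros(problem.n_subjects)}
    trace = []

    def obj(x):
        theta, omega2, sigma_vec = _unpack(x, n_theta, theta_log, n_sigma)
        spec = _respec(kind, sigma_vec)
        val, eta, _ = foce_objective(problem, theta, omega2, spec,
                                     eta0=warm["eta"], settings=settings,
                                     return_eta=True)
        if val < _BIG:
            warm["eta"] = eta
        trace.append(val)
        return val

    x0 = _pack(theta0, start_omega2, sigma0, theta_log)
    bounds = None
    if theta_bounds is not None:
        bounds = [(math.log(lo) if lg else lo, math.log(hi) if lg else hi)
                  for (lo, hi), lg in zip(theta_bounds, theta_log)]
        bounds += [(-50.0, 50.0)] * (1 + n_sigma)
    opt = minimize(obj, x0, method="Nelder-Mead", bounds=bounds,
                   options={"maxfev": settings.outer_maxfev,
                            "fatol": settings.outer_fatol,
                            "xatol": settings.outer_xatol,
                            "adaptive": True})
    x_hat = opt.x
    theta_hat, omega2_hat, sigma_hat = _unpack(x_hat, n_theta, theta_log,
                                               n_sigma)
    spec_hat = _respec(kind, sigma_hat)
    m2ll, eta_hat, _ = foce_objective(problem, theta_hat, omega2_hat, spec_hat,
                                      eta0=warm["eta"], settings=settings,
                                      return_eta=True)
    n_params = n_theta + 1 + n_sigma
    aic = m2ll + 2 * n_params

    cv_theta = {n: float("nan") for n in problem.theta_names}
    cv_omega = float("nan")
    cv_sigma = {n: float("nan") for n in residual.names()}
    if settings.compute_se:
        ses = _standard_errors(problem, theta_hat, omega2_hat, sigma_hat,
                               kind, warm["eta"], settings)
        if ses is not None:
            vals = np.concatenate([theta_hat, [omega2_hat], sigma_hat])
            cvs = 100.0 * ses / np.abs(vals)
            cv_theta = dict(zip(problem.theta_names, cvs[:n_theta]))
            cv_omega = float(cvs[n_theta])
            cv_sigma = dict(zip(residual.names(), cvs[n_theta + 1:]))

    converged = bool(opt.success) and m2ll < _BIG
    if not converged:
        warnings.warn("outer optimisation did not report convergence; "
                      "partial diagnostics retained")
    return FitResult(
        theta=dict(zip(problem.theta_names, map(float, theta_hat))),
        theta_cv={k: float(v) for k, v in cv_theta.items()},
        omega2=float(omega2_hat), omega2_cv=cv_omega,
        sigma=dict(zip(residual.names(), map(float, sigma_hat))),
        sigma_cv={k: float(v) for k, v in cv_sigma.items()},
        minus2ll=float(m2ll), aic=float(aic), n_params=n_params,
        ebe=eta_hat, subjects=list(problem.subjects),
        residual_kind=kind,
        convergence={"success": converged, "nfev": int(opt.nfev),
                     "message": str(opt.message),
                     "objective_trace_len": len(trace)},
    )


def _respec(kind, sigma_vec):
    if kind == "additive":
        return ResidualErrorSpec("additive", sigma_add=float(sigma_vec[0]))
    if kind == "proportional":
        return ResidualErrorSpec("proportional",
                                 sigma_prop=float(sigma_vec[0]))
    return ResidualErrorSpec("combined", sigma_add=float(sigma_vec[0]),
                             sigma_prop=float(sigma_vec[1]))


def _standard_errors(problem, theta, omega2, sigma_vec, kind, eta, settings):
    """Central-difference Hessian of the objective in the original
    parameter space; covariance = 2 * H^-1 for a -2LL objective."""
    vals = np.concatenate([theta, [omega2], sigma_vec])
    n = len(vals)
    n_theta = len(theta)

    def f(v):
        spec = _respec(kind, v[n_theta + 1:])
        return foce_objective(problem, v[:n_theta], v[n_theta], spec,
                              eta0=eta, settings=settings)

    steps = np.maximum(np.abs(vals) * 1e-3, 1e-8)
    H = np.empty((n, n))
    f0 = f(vals)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(vals + ei) - 2 * f0 + f(vals - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(vals + ei + ej) - f(vals + ei - ej)
                    - f(vals - ei + ej) + f(vals - ei - ej)
                ) / (4 * steps[i] * steps[j])
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(d <= 0):
        return None
    return np.sqrt(d)


# ---------------------------------------------------------------------------
# population PK problem (trough concentrations)


@dataclass
class CovariateTerm:
    """One covariate link on apparent clearance.

    ``power``: (x / ref) ** coef;  ``linear``: 1 + coef * (x / ref - 1);
    ``shift`` (categorical): 1 + coef * x.
    """

    name: str
    form: str = "power"
    ref: float = 1.0
    time_varying: bool = True

    def factor(self, coef, x):
        if self.form == "power":
            return (x / self.ref) ** coef
        if self.form == "linear":
            return 1.0 + coef * (x / self.ref - 1.0)
        if self.form == "shift":
            return 1.0 + coef * x
        raise ValueError(f"unknown covariate form {self.form!r}")


class PopPKProblem:
    """Trough-concentration mixed-effects problem on an event table.

    The random effect acts multiplicatively on CL/F; ka and V/F are fixed.
    Doses are grouped into runs of constant covariate values so that the
    prediction is a closed-form geometric superposition per (observation,
    block) pair.
    """

    def __init__(self, table: sd.EventTable, ka: float, v_f: float,
                 terms: list[CovariateTerm] | None = None,
                 lloq_excluded: bool = True):
        if lloq_excluded:
            table = sd.exclude_blq(table)
        self.lloq = table.lloq if lloq_excluded else None
        self.ka, self.v_f = ka, v_f
        self.terms = terms or []
        self.theta_names = ["theta_cl"] + [
            f"{t.form}_{t.name}" for t in self.terms]
        self.theta_log = [True] + [False] * len(self.terms)

        obs = table.observations(sd.DVID_CONC)
        self.subjects = list(table.df["ID"].unique())
        sub_idx = {s: i for i, s in enumerate(self.subjects)}
        # keep only subjects that have concentration data
        self.subjects = [s for s in self.subjects
                         if (obs["ID"] == s).any()]
        sub_idx = {s: i for i, s in enumerate(self.subjects)}
        self.n_subjects = len(self.subjects)
        obs = obs[obs["ID"].isin(sub_idx)]
        self.y = obs["DV"].to_numpy(dtype=float)
        self.subject_index = obs["ID"].map(sub_idx).to_numpy(dtype=int)
        obs_time = obs["TIME"].to_numpy(dtype=float)
        self.obs_time = obs_time

        # per-subject dose blocks and (obs, block) pair tables
        pair_obs, pair_subj, pair_blk = [], [], []
        pair_m, pair_s = [], []
        block_cov_rows, block_subj = [], []
        self.dose_amt = None
        self._blocks_raw = {}
        for s in self.subjects:
            d = table.doses(s)
            times = d["TIME"].to_numpy(dtype=float)
            amt = d["AMT"].to_numpy(dtype=float)
            if self.dose_amt is None:
                self.dose_amt = float(amt[0])
            cov = np.column_stack([
                d[t.name].to_numpy(dtype=float) if t.time_varying
                else np.full(len(d), float(d[t.name].iloc[0]))
                for t in self.terms]) if self.terms else np.zeros((len(d), 0))
            change = np.flatnonzero(np.r_[True, np.any(
                cov[1:] != cov[:-1], axis=1)]) if len(d) else np.array([0])
            starts = times[change]
            counts = np.diff(np.r_[change, len(times)])
            self._blocks_raw[s] = (starts, counts, cov[change])
            b0 = len(block_subj)
            block_subj.extend([sub_idx[s]] * len(starts))
            block_cov_rows.append(cov[change])
            o_mask = self.subject_index == sub_idx[s]
            for oi in np.flatnonzero(o_mask):
                t = obs_time[oi]
                for b, (st, ct) in enumerate(zip(starts, counts)):
                    m_eff = min(int(math.floor(t - st)) + 1, int(ct))
                    if m_eff < 1:
                        continue
                    pair_obs.append(oi)
                    pair_subj.append(sub_idx[s])
                    pair_m.append(m_eff)
                    pair_s.append(t - st - (m_eff - 1))
                    pair_blk.append(b0 + b)
        self.pair_obs = np.asarray(pair_obs, dtype=int)
        self.pair_subj = np.asarray(pair_subj, dtype=int)
        self.pair_m = np.asarray(pair_m, dtype=float)
        self.pair_s = np.asarray(pair_s, dtype=float)
        self.pair_blk = np.asarray(pair_blk, dtype=int)
        self.block_subj = np.asarray(block_subj, dtype=int)
        self.block_cov = (np.vstack(block_cov_rows)
                          if block_cov_rows else np.zeros((0, 0)))

    # typical clearance per block for a given theta
    def _block_cl(self, theta):
        cl = np.full(len(self.block_subj), theta[0])
        ok = True
        for j, term in enumerate(self.terms):
            fac = term.factor(theta[1 + j], self.block_cov[:, j])
            if np.any(~np.isfinite(fac)) or np.any(fac <= 0):
                ok = False
                break
            cl = cl * fac
        return cl if ok else None

    def predict(self, theta, eta):
        cl_typ = self._block_cl(theta)
        if cl_typ is None:
            return None
        cl = cl_typ * np.exp(np.asarray(eta)[self.block_subj])
        k = cl / self.v_f
        if np.any(k >= self.ka * (1 - 1e-6)):
            return None
        kp = k[self.pair_blk]
        amp = self.dose_amt / self.v_f / 1000.0 * self.ka / (self.ka - kp)
        g_k = _geom_decay(kp, self.pair_s, self.pair_m)
        g_ka = _geom_decay(np.full_like(kp, self.ka), self.pair_s, self.pair_m)
        contrib = amp * (g_k - g_ka)
        return np.bincount(self.pair_obs, weights=contrib, minlength=len(self.y))

    def individual_cl_blocks(self, theta, eta) -> dict:
        """Per-subject DoseBlocks at the given fixed effects and etas
        (used to carry post hoc PK into the sequential PD stage)."""
        out = {}
        for i, s in enumerate(self.subjects):
            starts, counts, cov = self._blocks_raw[s]
            cl = np.full(len(starts), theta[0])
            for j, term in enumerate(self.terms):
                cl = cl * term.factor(theta[1 + j], cov[:, j])
            cl = cl * math.exp(float(np.asarray(eta)[i]))
            out[s] = DoseBlocks(starts, counts, cl, self.dose_amt, 1.0)
        return out


# ---------------------------------------------------------------------------
# population PD problem (HbA1c)


class PopPDProblem:
    """HbA1c turnover mixed-effects problem on fixed individual PK.

    The random effect acts multiplicatively on the HbA1c half-life; each
    subject's concentration function is frozen at the supplied dose blocks
    (typically the post hoc PK parameters) and the baseline H(0) is fixed
    to the subject's observed baseline HbA1c.
    """

    theta_names = ["t_half_hba1c", "emax", "ec50"]
    theta_log = [True, True, True]

    def __init__(self, table: sd.EventTable, cl_blocks: dict, ka: float,
                 v_f: float, fixed_template: PDFixedEffects | None = None,
                 effect_scaling: str = "current"):
        tpl = fixed_template or PDFixedEffects()
        self.hill = tpl.hill
        self.floor, self.ref = tpl.floor, tpl.ref_baseline
        self.effect_scaling = effect_scaling

        obs = table.observations(sd.DVID_HBA1C)
        subjects, h0, excluded = [], [], 0
        for s in table.df["ID"].unique():
            if s not in cl_blocks:
                continue
            o = obs[obs["ID"] == s]
            base = o[o["TIME"] == 0]
            post = o[o["TIME"] > 0]
            if base.empty or post.empty:
                excluded += 1
                continue
            subjects.append(s)
            h0.append(float(base["DV"].iloc[0]))
        if excluded:
            log.warning("%d subject(s) lacking baseline or post-baseline "
                        "HbA1c excluded from the PD fit", excluded)
        self.subjects = subjects
        self.n_subjects = len(subjects)
        self.h0 = np.asarray(h0)
        self.n_excluded = excluded

        sub_idx = {s: i for i, s in enumerate(subjects)}
        y, si, day = [], [], []
        out_days_list = []
        slot = []
        for s in subjects:
            o = obs[(obs["ID"] == s) & (obs["TIME"] > 0)]
            days = np.round(o["TIME"].to_numpy(dtype=float)).astype(int)
            uniq = np.unique(days)
            out_days_list.append(uniq)
            pos = {d: j for j, d in enumerate(uniq)}
            for d, v in zip(days, o["DV"].to_numpy(dtype=float)):
                y.append(v); si.append(sub_idx[s]); slot.append(pos[d])
        self.y = np.asarray(y)
        self.subject_index = np.asarray(si, dtype=int)
        self.obs_slot = np.asarray(slot, dtype=int)
        self.obs_time = np.asarray(
            [d for s in subjects
             for d in np.round(obs[(obs["ID"] == s) & (obs["TIME"] > 0)]
                               ["TIME"].to_numpy(dtype=float)).astype(int)],
            dtype=float)
        self.engine = TurnoverEngine(
            [cl_blocks[s] for s in subjects], out_days_list, ka, v_f,
            floor=self.floor, ref_baseline=self.ref)

    def predict(self, theta, eta):
        t_half, emax, ec50 = theta
        if min(t_half, emax, ec50) <= 0:
            return None
        self.engine.set_effect(emax, ec50, self.hill)
        kout = math.log(2.0) / (t_half * np.exp(np.asarray(eta)))
        H = self.engine.trajectories(kout, self.h0, self.effect_scaling)
        return H[self.subject_index, self.obs_slot]


def fit_sequential_pd(pk_problem: PopPKProblem, pk_fit: FitResult,
                      table: sd.EventTable, start_theta, start_omega2: float,
                      residual: ResidualErrorSpec,
                      settings: EstimationSettings | None = None,
                      fixed_template: PDFixedEffects | None = None,
                      effect_scaling: str = "current", theta_bounds=None):
    """Sequential (IPP) PK->PD fit: freeze each subject's concentration
    function at the post hoc PK parameters, then estimate the PD model on
    the HbA1c observations alone."""
    theta_vec = np.array([pk_fit.theta[n] for n in pk_problem.theta_names])
    blocks = pk_problem.individual_cl_blocks(theta_vec, pk_fit.ebe)
    problem = PopPDProblem(table, blocks, pk_problem.ka, pk_problem.v_f,
                           fixed_template, effect_scaling)
    result = fit(problem, residual, start_theta, start_omega2, settings,
                 theta_bounds=theta_bounds)
    return result, problem
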