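"""Structural pharmacokinetics: one-compartment disposition with first-order
absorption under repeated once-daily oral dosing.

All parameters are apparent (oral) quantities: CL/F in L/day, V/F in L, the
absorption rate constant ka in 1/day.  The absorption rate and apparent
volume cannot be identified from trough-only sampling and are therefore
carried as fixed constants; only the apparent clearance (with a body-weight
power covariate and a log-normal random effect) is estimated.

Body weight may change during treatment.  The clearance is then re-evaluated
per dosing interval using the covariate in force (carried forward from the
most recent visit), and each administered dose contributes an analytic
single-dose curve computed with the clearance at its administration time, so
the multiple-dose profile stays a closed-form superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BW_REF_KG, ML_PER_L

#: Fixed absorption rate constant, 1/day (literature value; not estimable
#: from trough-only data).
KA_FIXED = 57.4
#: Fixed apparent volume of distribution, L.
VF_FIXED = 73.9
#: Reference population apparent clearance at the normalisation weight, L/day.
THETA_CL_REF = 229.3
#: Reference body-weight power exponent on CL/F.
THETA_BW_REF = 0.41

_EQUAL_RATE_RTOL = 1e-9


@dataclass
class PKFixedEffects:
    """Population (typical-value) PK parameters."""

    theta_cl: float = THETA_CL_REF  # L/day at bw_ref
    theta_bw: float = THETA_BW_REF  # dimensionless power exponent
    ka: float = KA_FIXED            # 1/day, fixed
    v_f: float = VF_FIXED           # L, fixed
    bw_ref: float = BW_REF_KG       # kg

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.v_f <= 0 or self.theta_cl <= 0:
            raise ValueError("ka, V/F and theta_cl must be positive")


@dataclass
class PKIndividual:
    """Individual-level PK parameters after covariates and the random effect."""

    cl_f: float           # L/day
    eta_cl: float = 0.0   # log-scale random effect

    def __post_init__(self) -> None:
        if self.cl_f <= 0:
            raise ValueError("individual CL/F must be positive")


@dataclass
class Regimen:
    """Repeated oral dosing schedule."""

    dose: float               # ng per administration
    interval: float = 1.0     # days (once daily)
    n_doses: int = 1
    start_time: float = 0.0   # days

    def __post_init__(self) -> None:
        if self.dose <= 0 or self.interval <= 0 or self.n_doses < 1:
            raise ValueError("dose and interval must be positive, n_doses >= 1")

    def dose_times(self) -> np.ndarray:
        return self.start_time + self.interval * np.arange(self.n_doses)


def covariate_cl(theta_cl: float, theta_bw: float, bw, bw_ref: float = BW_REF_KG):
    """Typical apparent clearance at body weight ``bw``:
    ``theta_cl * (bw / bw_ref) ** theta_bw``."""
    bw = np.asarray(bw, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be positive")
    return theta_cl * (bw / bw_ref) ** theta_bw


def conc_single_dose(t_after_dose, dose: float, ka: float, cl_f: float,
                     v_f: float):
    """Plasma concentration (ng/mL) after a single oral dose.

    ``(dose / v_f) * ka / (ka - k) * (exp(-k t) - exp(-ka t)) / 1000`` with
    ``k = cl_f / v_f``; the equal-rates case ``ka == k`` uses the limiting
    form ``(dose / v_f) * k * t * exp(-k t) / 1000``.
    """
    t = np.asarray(t_after_dose, dtype=float)
    if np.any(t < 0):
        raise ValueError("time after dose must be non-negative")
    k = cl_f / v_f
    scale = dose / v_f / ML_PER_L
    if abs(ka - k) <= _EQUAL_RATE_RTOL * ka:
        out = scale * k * t * np.exp(-k * t)
    else:
        out = scale * ka / (ka - k) * (np.exp(-k * t) - np.exp(-ka * t))
    return out if out.ndim else float(out)


@dataclass
class DoseBlocks:
    """Consecutive once-daily doses grouped into runs of equal clearance.

    ``start[b]`` is the day of the first dose of block ``b``, ``n[b]`` the
    number of doses in the block and ``cl[b]`` the apparent clearance used
    for every dose of the block.
    """

    start: np.ndarray
    n: np.ndarray
    cl: np.ndarray
    dose: float                # ng per administration
    interval: float = 1.0      # days

    def __post_init__(self) -> None:
        self.start = np.atleast_1d(np.asarray(self.start, dtype=float))
        self.n = np.atleast_1d(np.asarray(self.n, dtype=int))
        self.cl = np.atleast_1d(np.asarray(self.cl, dtype=float))


def _geom_decay(r, s, m):
    """``sum_{i=0}^{m-1} exp(-r (s + i*tau))`` with tau folded into r.

    Written with only negative exponents so long blocks cannot overflow.
    """
    er = np.exp(-r)
    with np.errstate(invalid="ignore"):
        ratio = np.where(er < 1.0, (1.0 - er ** m) / (1.0 - er), m)
    return np.exp(-r * s) * ratio


def conc_blocks(times, blocks: DoseBlocks, ka: float, v_f: float):
    """Concentration (ng/mL) at ``times`` from block-structured dosing.

    Closed-form superposition: within a block the dose contributions form a
    geometric series in the elapsed intervals, so evaluation is O(number of
    blocks) per time point regardless of the number of doses.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    tau = blocks.interval
    k = blocks.cl / v_f  # per block

    # (T, B) grids
    dt = t[:, None] - blocks.start[None, :]
    m_eff = np.clip(np.floor(dt / tau) + 1, 0, blocks.n[None, :]).astype(int)
    active = m_eff >= 1
    # time since last counted dose (>= 0); zeroed where no dose was given yet
    s_last = np.where(active, dt - (m_eff - 1) * tau, 0.0)

    out = np.zeros(len(t))
    kb = np.broadcast_to(k[None, :], dt.shape)
    near_equal = np.abs(ka - k) <= _EQUAL_RATE_RTOL * ka
    scale = blocks.dose / v_f / ML_PER_L
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = np.where(near_equal, np.nan, scale * ka / (ka - k))

    g_k = _geom_decay(kb * tau, s_last / tau, m_eff)
    g_ka = _geom_decay(np.full_like(kb, ka * tau), s_last / tau, m_eff)
    contrib = np.where(active, amp[None, :] * (g_k - g_ka), 0.0)

    if np.any(near_equal):  # rare degenerate blocks: sum doses explicitly
        for b in np.flatnonzero(near_equal):
            td = blocks.start[b] + tau * np.arange(blocks.n[b])
            dtb = t[:, None] - td[None, :]
            cb = np.where(dtb >= 0,
                          conc_single_dose(np.clip(dtb, 0, None), blocks.dose,
                                           ka, blocks.cl[b], v_f), 0.0)
            contrib[:, b] = cb.sum(axis=1)

    out = np.nansum(contrib, axis=1)
    return out if np.ndim(times) else float(out[0])


def blocks_from_weights(regimen: Regimen, weight_times, weights,
                        fixed: PKFixedEffects, eta_cl: float = 0.0) -> DoseBlocks:
    """Build dose blocks with clearance re-evaluated per dosing interval.

    ``weights`` are the body weights recorded at ``weight_times`` (carried
    forward between records); doses before the first record use the first
    recorded weight.
    """
    wt_t = np.asarray(weight_times, dtype=float)
    wt = np.asarray(weights, dtype=float)
    order = np.argsort(wt_t, kind="mergesort")
    wt_t, wt = wt_t[order], wt[order]
    dose_t = regimen.dose_times()
    idx = np.clip(np.searchsorted(wt_t, dose_t, side="right") - 1, 0, None)
    w_dose = wt[idx]
    # group consecutive doses with identical weight
    change = np.flatnonzero(np.r_[True, w_dose[1:] != w_dose[:-1]])
    starts = dose_t[change]
    counts = np.diff(np.r_[change, len(dose_t)])
    cl = covariate_cl(fixed.theta_cl, fixed.theta_bw, wt[idx][change],
                      fixed.bw_ref) * np.exp(eta_cl)
    return DoseBlocks(starts, counts, cl, regimen.dose, regimen.interval)


def conc_profile(regimen: Regimen, times, individual: PKIndividual,
                 fixed: PKFixedEffects, weight_times=None, weights=None):
    """Multiple-dose concentration profile for one individual.

    With a weight trajectory supplied, clearance follows the covariate in
    force per dosing interval; otherwise ``individual.cl_f`` applies to
    every dose.  Times before the first dose return 0.
    """
    if weight_times is not None:
        eta = individual.eta_cl
        blocks = blocks_from_weights(regimen, weight_times, weights, fixed, eta)
    else:
        blocks = DoseBlocks(np.array([regimen.start_time]),
                            np.array([regimen.n_doses]),
                            np.array([individual.cl_f]),
                            regimen.dose, regimen.interval)
    return conc_blocks(times, blocks, fixed.ka, fixed.v_f)


def steady_state_trough(dose: float, ka: float, cl_f: float, v_f: float,
                        interval: float = 1.0) -> float:
    """Closed-form steady-state pre-dose (trough) concentration, ng/mL.

    Accumulation-factor expression for first-order absorption at dosing
    interval tau: each exponential term is divided by ``1 - exp(-r tau)``.
    """
    k = cl_f / v_f
    tau = interval
    a = np.exp(-k * tau) / (1.0 - np.exp(-k * tau))
    b = np.exp(-ka * tau) / (1.0 - np.exp(-ka * tau))
    return dose / v_f / ML_PER_L * ka / (ka - k) * (a - b)
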