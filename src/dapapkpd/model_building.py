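"""Stepwise covariate screening on apparent clearance.

Candidates enter one at a time in a greedy forward phase (likelihood-ratio
test at p < 0.01, chi-square with one degree of freedom per added
parameter) and survive a backward-elimination phase only if their deletion
worsens the fit at p < 0.001.  Continuous covariates are normalised by the
subject mean before entering a power (default) or linear link; sex enters
as a proportional shift.  Candidate order is alphabetical so ties resolve
reproducibly; among equally significant candidates the smaller AIC wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import study_data as sd
from .nlme import (CovariateTerm, EstimationSettings, PopPKProblem,
                   ResidualErrorSpec, fit)
from .pk_model import KA_FIXED as _KA, VF_FIXED as _VF

log = logging.getLogger(__name__)

FORWARD_ALPHA = 0.01
BACKWARD_ALPHA = 0.001


@dataclass(frozen=True)
class CovariateCandidate:
    """A covariate-link candidate on CL/F."""

    covariate: str          # column name (WT, AGE, SEX, HT, AST, ALT, GGT, EGFR)
    form: str = "power"     # "power" | "linear"; SEX always uses "shift"
    parameter: str = "CL/F"
    time_varying: bool = True

    def to_term(self, table: sd.EventTable) -> CovariateTerm:
        if self.covariate == "SEX":
            return CovariateTerm("SEX", "shift", 1.0, time_varying=False)
        base = table.df.groupby("ID")[self.covariate].first()
        return CovariateTerm(self.covariate, self.form, float(base.mean()),
                             time_varying=self.time_varying)


def default_candidates() -> list[CovariateCandidate]:
    """The screening set: demographics, hepatic enzymes, renal function."""
    return [CovariateCandidate(c) for c in
            ["AGE", "ALT", "AST", "EGFR", "GGT", "HT", "SEX", "WT"]]


def lrt(minus2ll_reduced: float, minus2ll_full: float, df: int) -> float:
    """Likelihood-ratio p-value for nested fits from the change in -2LL."""
    delta = minus2ll_reduced - minus2ll_full
    if delta < -1e-6 * max(1.0, abs(minus2ll_full)) - 0.1:
        raise ValueError(
            f"nesting violation: full model fits worse by {-delta:.3f}")
    return float(chi2.sf(max(delta, 0.0), df))


def _fit_terms(table, terms, residual, start_cl, start_coefs, start_omega2,
               settings):
    problem = PopPKProblem(table, ka=_KA, v_f=_VF, terms=terms)
    start = np.r_[start_cl, start_coefs]
    return fit(problem, residual, start, start_omega2, settings)


def stepwise_select(table: sd.EventTable,
                    candidates: list[CovariateCandidate] | None = None,
                    residual: ResidualErrorSpec | None = None,
                    start_cl: float = 200.0, start_omega2: float = 0.09,
                    settings: EstimationSettings | None = None):
    """Forward-addition / backward-elimination covariate search.

    Returns ``(final_terms, base_or_final_fit, trace)`` where ``trace`` is
    a dataframe with one row per tested model.
    """
    candidates = sorted(candidates if candidates is not None
                        else default_candidates(),
                        key=lambda c: c.covariate)
    residual = residual or ResidualErrorSpec("proportional", sigma_prop=0.3)
    settings = settings or EstimationSettings(compute_se=False,
                                              outer_maxfev=400)
    rows = []
    included: list[CovariateCandidate] = []
    terms: list[CovariateTerm] = []
    base_fit = _fit_terms(table, [], residual, start_cl, [], start_omega2,
                          settings)
    current_fit = base_fit
    rows.append({"phase": "base", "candidate": "", "minus2ll":
                 base_fit.minus2ll, "delta": 0.0, "df": 0, "p": np.nan,
                 "aic": base_fit.aic, "decision": "start"})

    def fit_with(cands):
        ts = [c.to_term(table) for c in cands]
        coefs = [current_fit.theta.get(f"{t.form}_{t.name}", 0.1) for t in ts]
        return _fit_terms(table, ts, residual,
                          current_fit.theta["theta_cl"], coefs,
                          current_fit.omega2, settings), ts

    # forward
    while True:
        best = None
        for cand in candidates:
            if cand in included:
                continue
            try:
                trial, _ = fit_with(included + [cand])
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("candidate %s skipped: %s", cand.covariate, exc)
                continue
            if trial.minus2ll >= 1e9:
                rows.append({"phase": "forward", "candidate": cand.covariate,
                             "minus2ll": np.nan, "delta": np.nan, "df": 1,
                             "p": np.nan, "aic": np.nan,
                             "decision": "non-convergent"})
                continue
            p = lrt(current_fit.minus2ll, trial.minus2ll, 1)
            rows.append({"phase": "forward", "candidate": cand.covariate,
                         "minus2ll": trial.minus2ll,
                         "delta": current_fit.minus2ll - trial.minus2ll,
                         "df": 1, "p": p, "aic": trial.aic,
                         "decision": "tested"})
            if p < FORWARD_ALPHA:
                key = (p, trial.aic, cand.covariate)
                if best is None or key < best[0]:
                    best = (key, cand, trial)
        if best is None:
            break
        _, cand, trial = best
        included.append(cand)
        current_fit = trial
        rows.append({"phase": "forward", "candidate": cand.covariate,
                     "minus2ll": trial.minus2ll, "delta": np.nan, "df": 1,
                     "p": best[0][0], "aic": trial.aic, "decision": "added"})

    # backward
    changed = True
    while changed and included:
        changed = False
        worst = None
        for cand in included:
            reduced_set = [c for c in included if c is not cand]
            try:
                reduced, _ = fit_with(reduced_set)
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("backward fit without %s failed: %s",
                            cand.covariate, exc)
                continue
            p = lrt(reduced.minus2ll, current_fit.minus2ll, 1)
            rows.append({"phase": "backward", "candidate": cand.covariate,
                         "minus2ll": reduced.minus2ll,
                         "delta": reduced.minus2ll - current_fit.minus2ll,
                         "df": 1, "p": p, "aic": reduced.aic,
                         "decision": "tested"})
            if p >= BACKWARD_ALPHA:  # deletion not significant -> removable
                key = (-p, cand.covariate)
                if worst is None or key < worst[0]:
                    worst = (key, cand, reduced)
        if worst is not None:
            _, cand, reduced = worst
            included.remove(cand)
            current_fit = reduced
            changed = True
            rows.append({"phase": "backward", "candidate": cand.covariate,
                         "minus2ll": reduced.minus2ll, "delta": np.nan,
                         "df": 1, "p": -worst[0][0], "aic": reduced.aic,
                         "decision": "removed"})

    final_terms = [c.to_term(table) for c in included]
    rows.append({"phase": "final", "candidate":
                 "+".join(c.covariate for c in included) or "(base)",
                 "minus2ll": current_fit.minus2ll, "delta": np.nan, "df": 0,
                 "p": np.nan, "aic": current_fit.aic, "decision": "final"})
    return final_terms, current_fit, pd.DataFrame(rows)


def choose_baseline_vs_timevarying_bw(table: sd.EventTable,
                                      residual: ResidualErrorSpec | None = None,
                                      start_cl: float = 200.0,
                                      start_omega2: float = 0.09,
                                      settings: EstimationSettings | None = None
                                      ) -> dict:
    """Compare body weight as a baseline-only vs visit-updated covariate.

    Both encodings have the same parameter count, so the comparison is by
    -2LL / AIC rather than a nested test.
    """
    residual = residual or ResidualErrorSpec("proportional", sigma_prop=0.3)
    settings = settings or EstimationSettings(compute_se=False,
                                              outer_maxfev=400)
    out = {}
    for label, tv in [("baseline", False), ("time_varying", True)]:
        term = CovariateTerm("WT", "power",
                             float(table.df.groupby("ID")["WT"].first().mean()),
                             time_varying=tv)
        res = _fit_terms(table, [term], residual, start_cl, [0.1],
                         start_omega2, settings)
        out[label] = {"minus2ll": res.minus2ll, "aic": res.aic,
                      "theta": res.theta}
    out["selected"] = min(("baseline", "time_varying"),
                          key=lambda k: out[k]["aic"])
    return out
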