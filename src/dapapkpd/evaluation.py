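"""Model qualification: prediction-corrected visual predictive check and
nonparametric bootstrap.

The pc-VPC normalises out typical-prediction differences between subjects
before binning: with a multiplicative residual model each observation (and
each simulated value) is scaled by the ratio of the bin's median typical
prediction to the subject's own typical prediction; with an additive model
the difference is added instead.  Binning follows the visit structure of
the design.  The bootstrap resamples whole subjects with replacement and
refits each replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import study_data as sd
from .nlme import FitResult, _residual_variance

log = logging.getLogger(__name__)

#: Bin edges (days) separating baseline and the nominal visit months
#: 1, 3, 6, 9, 12.
DEFAULT_VISIT_BIN_EDGES = (0.0, 60.5, 137.0, 228.5, 319.5, np.inf)

PERCENTILES = (5.0, 50.0, 95.0)


def prediction_correct(dv, pred_typical, pred_bin_median, error_kind: str):
    """Prediction-corrected observation.

    Proportional (or combined) error: ``dv * bin_median / pred``; additive:
    ``dv + (bin_median - pred)``.  Non-positive typical predictions under
    proportional correction yield NaN with a warning (record dropped).
    """
    dv = np.asarray(dv, dtype=float)
    pred = np.asarray(pred_typical, dtype=float)
    med = np.asarray(pred_bin_median, dtype=float)
    if error_kind == "additive":
        return dv + (med - pred)
    bad = pred <= 0
    if np.any(bad):
        warnings.warn(f"{int(np.sum(bad))} record(s) with non-positive "
                      "typical prediction dropped from the pc-VPC")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, dv * med / pred)
    return out


@dataclass
class VPCResult:
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    n_obs: np.ndarray
    observed: np.ndarray      # (3, n_bins): 5th / 50th / 95th of pc-DV
    simulated: np.ndarray     # (3, n_bins): median across replicates
    sim_ci_lo: np.ndarray     # (3, n_bins): 2.5th percentile across reps
    sim_ci_hi: np.ndarray     # (3, n_bins)
    n_sim: int

    def coverage(self) -> float:
        """Fraction of (percentile, bin) cells whose observed value falls
        inside the simulated 95% CI."""
        ok = (self.observed >= self.sim_ci_lo) & (self.observed <= self.sim_ci_hi)
        return float(np.mean(ok[:, self.n_obs > 0]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in range(len(self.bin_mid)):
            for i, p in enumerate(PERCENTILES):
                rows.append({"bin_mid": self.bin_mid[j], "percentile": p,
                             "observed": self.observed[i, j],
                             "simulated": self.simulated[i, j],
                             "ci_lo": self.sim_ci_lo[i, j],
                             "ci_hi": self.sim_ci_hi[i, j],
                             "n_obs": self.n_obs[j]})
        return pd.DataFrame(rows)


def _binned_percentiles(values, bin_idx, n_bins):
    out = np.full((len(PERCENTILES), n_bins), np.nan)
    for b in range(n_bins):
        v = values[(bin_idx == b) & np.isfinite(values)]
        if len(v):
            out[:, b] = np.percentile(v, PERCENTILES)
    return out


def run_vpc(problem, fit_result: FitResult, n_sim: int = 1000,
            bin_edges=DEFAULT_VISIT_BIN_EDGES, seed=None,
            lloq="auto") -> VPCResult:
    """Prediction-corrected VPC by simulation at the original design.

    ``problem`` is the fitted mixed-effects problem (it carries the design:
    observation times, dose histories, covariates); replicates redraw the
    random effect and residual noise from the fitted variances.  When the
    observed data had below-LLOQ records excluded, simulated values below
    the same limit are dropped too, so both sides of the comparison see
    the identical observation process (``lloq="auto"`` takes the limit
    from the problem; pass ``None`` to disable).
    """
    if n_sim < 100:
        warnings.warn("n_sim < 100: VPC confidence intervals are unstable")
    if lloq == "auto":
        lloq = getattr(problem, "lloq", None)
    rng = np.random.default_rng(seed)
    theta = np.array([fit_result.theta[n] for n in problem.theta_names])
    sigma_vec = np.array([fit_result.sigma[n]
                          for n in _sigma_names(fit_result.residual_kind)])
    kind = fit_result.residual_kind
    omega = np.sqrt(fit_result.omega2)

    edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(edges) - 1
    t = problem.obs_time
    bin_idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                      n_bins - 1)

    pred_typ = problem.predict(theta, np.zeros(problem.n_subjects))
    bin_med = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = bin_idx == b
        if m.any():
            bin_med[b] = np.median(pred_typ[m])
    pc_obs = prediction_correct(problem.y, pred_typ, bin_med[bin_idx], kind)
    observed = _binned_percentiles(pc_obs, bin_idx, n_bins)

    sim_pcts = np.empty((n_sim, len(PERCENTILES), n_bins))
    for r in range(n_sim):
        eta = rng.normal(0.0, omega, problem.n_subjects)
        f = problem.predict(theta, eta)
        v = _residual_variance(f, sigma_vec, kind)
        y = f + np.sqrt(v) * rng.standard_normal(len(f))
        pc = prediction_correct(y, pred_typ, bin_med[bin_idx], kind)
        if lloq is not None:
            pc = np.where(y < lloq, np.nan, pc)  # mimic the M1 exclusion
        sim_pcts[r] = _binned_percentiles(pc, bin_idx, n_bins)

    mids = np.array([np.median(t[bin_idx == b]) if (bin_idx == b).any()
                     else 0.5 * (edges[b] + edges[b + 1])
                     for b in range(n_bins)])
    n_obs = np.bincount(bin_idx, minlength=n_bins)
    return VPCResult(
        bin_edges=edges, bin_mid=mids, n_obs=n_obs, observed=observed,
        simulated=np.nanmedian(sim_pcts, axis=0),
        sim_ci_lo=np.nanpercentile(sim_pcts, 2.5, axis=0),
        sim_ci_hi=np.nanpercentile(sim_pcts, 97.5, axis=0),
        n_sim=n_sim)


def _sigma_names(kind):
    return {"additive": ["sigma_add"], "proportional": ["sigma_prop"],
            "combined": ["sigma_add", "sigma_prop"]}[kind]


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame
    median: pd.Series
    ci_lo: pd.Series   # 2.5th percentile
    ci_hi: pd.Series   # 97.5th percentile
    n_failed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"median": self.median, "ci_2.5": self.ci_lo,
                             "ci_97.5": self.ci_hi})


def resample_subjects(table: sd.EventTable, rng) -> sd.EventTable:
    """A bootstrap replicate dataset: subjects drawn with replacement and
    relabelled so duplicates stay distinct."""
    ids = table.df["ID"].unique()
    chosen = rng.choice(ids, size=len(ids), replace=True)
    frames = []
    for new_id, sid in enumerate(chosen, start=1):
        sub = table.df[table.df["ID"] == sid].copy()
        sub["ID"] = new_id
        frames.append(sub)
    return sd.EventTable(pd.concat(frames, ignore_index=True),
                         lloq=table.lloq)


def run_bootstrap(table: sd.EventTable, fit_fn, n_boot: int = 1000,
                  seed=None) -> BootstrapResult:
    """Nonparametric bootstrap: ``fit_fn(table) -> FitResult`` is applied
    to each subject-resampled replicate; hard failures are excluded and
    counted."""
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for r in range(n_boot):
        rep = resample_subjects(table, rng)
        try:
            res = fit_fn(rep)
        except Exception as exc:
            log.warning("bootstrap replicate %d failed: %s", r, exc)
            n_failed += 1
            continue
        if res is None or not np.isfinite(res.minus2ll) or res.minus2ll >= 1e9:
            n_failed += 1
            continue
        row = dict(res.theta)
        row["omega2"] = res.omega2
        row["omega_cv_pct"] = res.omega_as_cv()
        row.update(res.sigma)
        rows.append(row)
    reps = pd.DataFrame(rows)
    return BootstrapResult(
        replicates=reps,
        median=reps.median(),
        ci_lo=reps.quantile(0.025),
        ci_hi=reps.quantile(0.975),
        n_failed=n_failed)
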