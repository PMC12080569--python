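"""Virtual-patient generator emulating the study's real-world data
structure: 85 Japanese outpatients with type-2 diabetes on once-daily oral
dapagliflozin, trough-only drug sampling and HbA1c at clinic visits about
1, 3, 6, 9 and 12 months after the first dose.

Covariates are drawn from truncated normals matching the published
demographic summaries (body weight 78.1 +/- 13.4 kg in 49-118, baseline
HbA1c 6.8 +/- 0.5 % in 5.6-8.8, ...), with height and weight drawn jointly
given sex (correlation 0.5) so body shapes stay plausible.  Body weight
declines slowly over the year (median -1.5 kg, range -10.8 to +6.0);
weights are recorded at visits and carried forward, which is also how the
true clearance is evaluated, so the generating model is exactly the model
the estimation stage assumes.  eGFR is computed from serum creatinine, age
and sex with the Japanese GFR-estimation equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import study_data as sd
from .constants import LLOQ_NG_ML, NG_PER_MG, omega2_from_cv
from .pd_model import PDFixedEffects, TurnoverEngine
from .pk_model import DoseBlocks, PKFixedEffects, conc_blocks, covariate_cl


def egfr_japanese(scr, age, is_female) -> float:
    """Japanese GFR-estimation equation, mL/min/1.73 m^2:
    ``194 * sCr^-1.094 * age^-0.287 * (0.739 if female)``."""
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("serum creatinine and age must be positive")
    out = 194.0 * scr ** -1.094 * age ** -0.287
    out = out * np.where(np.asarray(is_female, dtype=bool), 0.739, 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated-normal recipe for one covariate."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi and self.sd > 0):
            raise ValueError("invalid truncation recipe")
        if self.hi < self.mean - 6 * self.sd or self.lo > self.mean + 6 * self.sd:
            raise ValueError("truncation range excludes mean +/- 6 SD")

    def draw(self, rng, n: int) -> np.ndarray:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n,
                             random_state=rng)


@dataclass
class CohortSpec:
    """Distributional recipe for the virtual population."""

    n_subjects: int = 85
    dose_mg: float = 5.0
    p_male: float = 61 / 85
    age: TruncatedNormal = TruncatedNormal(59.1, 10.0, 37.0, 75.0)
    weight: TruncatedNormal = TruncatedNormal(78.1, 13.4, 49.0, 118.0)
    height: TruncatedNormal = TruncatedNormal(165.9, 8.1, 148.0, 186.0)
    hba1c0: TruncatedNormal = TruncatedNormal(6.8, 0.5, 5.6, 8.8)
    scr: TruncatedNormal = TruncatedNormal(0.81, 0.23, 0.32, 1.50)
    ast: TruncatedNormal = TruncatedNormal(29.0, 20.0, 12.0, 140.0)
    alt: TruncatedNormal = TruncatedNormal(36.0, 31.0, 10.0, 200.0)
    ggt: TruncatedNormal = TruncatedNormal(48.0, 40.0, 10.0, 300.0)
    #: 12-month body-weight change, kg (slow decline on treatment).
    weight_change: TruncatedNormal = TruncatedNormal(-1.5, 3.0, -10.8, 6.0)
    #: within-sex height-weight correlation
    hw_corr: float = 0.5
    #: sex-specific (height, weight) means; marginals recover the recipe
    #: means at the cohort's sex ratio
    height_mean_by_sex: tuple = (168.9, 158.3)  # (male, female)
    weight_mean_by_sex: tuple = (80.0, 73.3)
    height_sd_within: float = 7.0
    weight_sd_within: float = 13.0
    visit_months: tuple = (1, 3, 6, 9, 12)
    visit_jitter_days: int = 7
    sampling_offset_days: float = 1.0  # trough drawn 24 h after the last dose
    missingness: float = 0.02
    lloq: float = LLOQ_NG_ML

    def nominal_visit_days(self) -> np.ndarray:
        return np.round(np.asarray(self.visit_months) * 365.0 / 12.0).astype(int)


@dataclass
class PopulationParameters:
    """Full population truth: fixed effects, IIV variances and residual SDs."""

    pk: PKFixedEffects
    pd: PDFixedEffects
    omega2_cl: float
    omega2_thalf: float
    sigma_prop_pk: float
    sigma_add_pd: float

    @classmethod
    def reference(cls) -> "PopulationParameters":
        """The final-model estimates of the source study."""
        return cls(pk=PKFixedEffects(), pd=PDFixedEffects(),
                   omega2_cl=omega2_from_cv(13.9),
                   omega2_thalf=omega2_from_cv(103.9),
                   sigma_prop_pk=0.398, sigma_add_pd=0.24)


@dataclass
class VirtualSubject:
    """One virtual patient with true (simulated) individual parameters."""

    sid: int
    sex: int           # 0 male, 1 female
    age: float
    height: float
    weight0: float
    weight_change_12m: float
    hba1c0: float
    scr: float
    ast: float
    alt: float
    ggt: float
    egfr: float
    eta_cl: float
    eta_thalf: float
    visit_days: np.ndarray

    def weights_at(self, days) -> np.ndarray:
        """True (linear-in-time) weight at arbitrary days."""
        return self.weight0 + self.weight_change_12m * np.asarray(days) / 365.0

    @property
    def weight_records(self):
        """(times, weights) as measured: baseline plus each visit."""
        t = np.r_[0, self.visit_days]
        return t, self.weights_at(t)


def _draw_height_weight(spec: CohortSpec, sex: np.ndarray, rng) -> tuple:
    n = len(sex)
    mh = np.where(sex == 0, spec.height_mean_by_sex[0], spec.height_mean_by_sex[1])
    mw = np.where(sex == 0, spec.weight_mean_by_sex[0], spec.weight_mean_by_sex[1])
    r = spec.hw_corr
    chol = np.array([[1.0, 0.0], [r, np.sqrt(1 - r * r)]])
    ht = np.empty(n)
    wt = np.empty(n)
    todo = np.ones(n, dtype=bool)
    for _ in range(200):
        m = int(todo.sum())
        if m == 0:
            break
        z = rng.standard_normal((m, 2)) @ chol.T
        h = mh[todo] + spec.height_sd_within * z[:, 0]
        w = mw[todo] + spec.weight_sd_within * z[:, 1]
        ok = ((h >= spec.height.lo) & (h <= spec.height.hi)
              & (w >= spec.weight.lo) & (w <= spec.weight.hi))
        idx = np.flatnonzero(todo)[ok]
        ht[idx], wt[idx] = h[ok], w[ok]
        todo[idx] = False
    if todo.any():
        raise RuntimeError("height/weight rejection sampling failed")
    return ht, wt


def draw_cohort(spec: CohortSpec, truth: PopulationParameters,
                seed=None):
    """Sample virtual subjects and return them with a truth table.

    The truth table (one row per subject: covariates, etas, true individual
    CL/F at baseline weight and true HbA1c half-life) supports parameter
    recovery testing.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    sex = (rng.random(n) >= spec.p_male).astype(int)  # 1 = female
    ht, wt = _draw_height_weight(spec, sex, rng)
    age = spec.age.draw(rng, n)
    h0 = spec.hba1c0.draw(rng, n)
    scr = spec.scr.draw(rng, n)
    ast = spec.ast.draw(rng, n)
    alt = spec.alt.draw(rng, n)
    ggt = spec.ggt.draw(rng, n)
    dwt = spec.weight_change.draw(rng, n)
    eta_cl = rng.normal(0.0, np.sqrt(truth.omega2_cl), n)
    eta_th = rng.normal(0.0, np.sqrt(truth.omega2_thalf), n)
    nominal = spec.nominal_visit_days()
    jit = rng.integers(-spec.visit_jitter_days, spec.visit_jitter_days + 1,
                       size=(n, len(nominal)))
    visits = nominal[None, :] + jit

    subjects = []
    rows = []
    for i in range(n):
        s = VirtualSubject(
            sid=i + 1, sex=int(sex[i]), age=float(age[i]), height=float(ht[i]),
            weight0=float(wt[i]), weight_change_12m=float(dwt[i]),
            hba1c0=float(h0[i]), scr=float(scr[i]), ast=float(ast[i]),
            alt=float(alt[i]), ggt=float(ggt[i]),
            egfr=float(egfr_japanese(scr[i], age[i], sex[i] == 1)),
            eta_cl=float(eta_cl[i]), eta_thalf=float(eta_th[i]),
            visit_days=visits[i].astype(int),
        )
        subjects.append(s)
        cl0 = covariate_cl(truth.pk.theta_cl, truth.pk.theta_bw, s.weight0,
                           truth.pk.bw_ref) * np.exp(s.eta_cl)
        rows.append({
            "ID": s.sid, "SEX": s.sex, "AGE": s.age, "HT": s.height,
            "WT0": s.weight0, "DWT12": s.weight_change_12m,
            "HBA1C0": s.hba1c0, "SCR": s.scr, "AST": s.ast, "ALT": s.alt,
            "GGT": s.ggt, "EGFR": s.egfr,
            "ETA_CL": s.eta_cl, "ETA_THALF": s.eta_thalf,
            "CL_F_TRUE_BASELINE": float(cl0),
            "T_HALF_TRUE": truth.pd.t_half_hba1c * np.exp(s.eta_thalf),
        })
    return subjects, pd.DataFrame(rows)


def _true_blocks(subject: VirtualSubject, spec: CohortSpec,
                 truth: PopulationParameters) -> DoseBlocks:
    """True dose blocks: clearance from the LOCF visit weights and eta."""
    t_rec, w_rec = subject.weight_records
    last = int(subject.visit_days.max())
    dose_days = np.arange(last)
    idx = np.clip(np.searchsorted(t_rec, dose_days, side="right") - 1, 0, None)
    w_dose = w_rec[idx]
    change = np.flatnonzero(np.r_[True, w_dose[1:] != w_dose[:-1]])
    starts = dose_days[change].astype(float)
    counts = np.diff(np.r_[change, len(dose_days)])
    cl = covariate_cl(truth.pk.theta_cl, truth.pk.theta_bw, w_dose[change],
                      truth.pk.bw_ref) * np.exp(subject.eta_cl)
    return DoseBlocks(starts, counts, cl, spec.dose_mg * NG_PER_MG, 1.0)


def generate_event_table(subjects, spec: CohortSpec,
                         truth: PopulationParameters, seed=None):
    """Build the full longitudinal event table for a drawn cohort.

    Dose rows daily through the last visit; trough concentrations at each
    visit with proportional residual error (flagged when below the LLOQ);
    HbA1c at baseline and each visit with additive error; ~2% of scheduled
    post-baseline observations missing at random.
    """
    rng = np.random.default_rng(seed)
    blocks = [_true_blocks(s, spec, truth) for s in subjects]
    engine = TurnoverEngine(blocks, [np.r_[0, s.visit_days] for s in subjects],
                            truth.pk.ka, truth.pk.v_f,
                            floor=truth.pd.floor,
                            ref_baseline=truth.pd.ref_baseline)
    engine.set_effect(truth.pd.emax, truth.pd.ec50, truth.pd.hill)
    kout = np.array([np.log(2.0) / (truth.pd.t_half_hba1c * np.exp(s.eta_thalf))
                     for s in subjects])
    h0 = np.array([s.hba1c0 for s in subjects])
    H = engine.trajectories(kout, h0)

    frames = []
    for i, s in enumerate(subjects):
        b = blocks[i]
        last = int(s.visit_days.max())
        dose_days = np.arange(last)
        t_rec, w_rec = s.weight_records
        idx = np.clip(np.searchsorted(t_rec, dose_days, side="right") - 1,
                      0, None)

        def cov_cols(n_rows, wt_vals):
            return {"WT": wt_vals, "AGE": s.age, "SEX": s.sex, "HT": s.height,
                    "AST": s.ast, "ALT": s.alt, "GGT": s.ggt, "SCR": s.scr,
                    "EGFR": s.egfr}

        dose_df = pd.DataFrame({
            "ID": s.sid, "TIME": dose_days.astype(float),
            "EVID": sd.EVID_DOSE, "DVID": 0,
            "AMT": spec.dose_mg * NG_PER_MG, "DV": 0.0, "BLQ": 0,
            **cov_cols(last, w_rec[idx])})

        # trough concentrations at visits
        c_true = conc_blocks(s.visit_days.astype(float), b, truth.pk.ka,
                             truth.pk.v_f)
        eps = rng.normal(0.0, 1.0, len(c_true))
        c_obs = np.maximum(c_true * (1.0 + truth.sigma_prop_pk * eps), 0.0)
        keep_pk = rng.random(len(c_obs)) >= spec.missingness
        wt_vis = w_rec[1:]
        pk_df = pd.DataFrame({
            "ID": s.sid, "TIME": s.visit_days.astype(float),
            "EVID": sd.EVID_OBS, "DVID": sd.DVID_CONC, "AMT": 0.0,
            "DV": c_obs, "BLQ": (c_obs < spec.lloq).astype(int),
            **cov_cols(len(c_obs), wt_vis)})[keep_pk]

        # HbA1c at baseline (never missing) and visits.  The baseline row
        # is recorded without residual noise: it defines the turnover
        # model's initial condition, which the estimation stage fixes to
        # the recorded value, so the generating process must treat it as
        # exact for the generator to lie inside the fitted model class.
        h_true = H[i, : len(s.visit_days) + 1]
        h_obs = h_true + rng.normal(0.0, truth.sigma_add_pd,
                                    len(s.visit_days) + 1)
        h_obs[0] = h_true[0]
        h_obs = np.maximum(h_obs, 0.0)
        keep_pd = np.r_[True,
                        rng.random(len(s.visit_days)) >= spec.missingness]
        pd_df = pd.DataFrame({
            "ID": s.sid, "TIME": np.r_[0.0, s.visit_days.astype(float)],
            "EVID": sd.EVID_OBS, "DVID": sd.DVID_HBA1C, "AMT": 0.0,
            "DV": h_obs, "BLQ": 0,
            **cov_cols(len(h_obs), w_rec)})[keep_pd]

        frames.extend([dose_df, pk_df, pd_df])
    df = pd.concat(frames, ignore_index=True)
    return sd.EventTable(df, lloq=spec.lloq)


def generate_study(spec: CohortSpec, truth: PopulationParameters, seed):
    """Convenience: draw a cohort and its event table with one seed."""
    ss = np.random.SeedSequence(seed)
    s_draw, s_obs = ss.spawn(2)
    subjects, truth_df = draw_cohort(spec, truth,
                                     np.random.default_rng(s_draw))
    table = generate_event_table(subjects, spec, truth,
                                 np.random.default_rng(s_obs))
    return subjects, truth_df, table
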