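"""Unit conversions and reference parameter sets.

Time is measured in days throughout the package, dose amounts in ng and
concentrations in ng/mL, so that apparent clearance in L/day and apparent
volume in L combine without hidden factors (1 ng/L = 1e-3 ng/mL).
"""

NG_PER_MG = 1.0e6
ML_PER_L = 1.0e3

#: Lower limit of quantification of the plasma assay, ng/mL.
LLOQ_NG_ML = 0.5

#: Normalisation body weight for the clearance covariate model, kg
#: (the cohort median).
BW_REF_KG = 77.0

#: Lower physiological boundary of HbA1c used by the drug-effect scaling, %.
HBA1C_FLOOR = 5.0

#: Reference baseline HbA1c at which Emax is defined, %.
HBA1C_REF_BASELINE = 8.0


def omega2_from_cv(cv_pct: float) -> float:
    """Log-scale variance of a log-normal random effect from its CV%."""
    import math

    return math.log(1.0 + (cv_pct / 100.0) ** 2)


def cv_from_omega2(omega2: float) -> float:
    """CV% of a log-normal random effect from its log-scale variance."""
    import math

    return 100.0 * math.sqrt(math.exp(omega2) - 1.0)
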