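"""Longitudinal event-table data model shared by all analysis stages.

The dataset dialect is a single flat CSV per cohort, following the NONMEM
convention: one row per dose or observation event with columns

    ID, TIME, EVID, DVID, AMT, DV, BLQ, WT, AGE, SEX, HT, AST, ALT, GGT,
    SCR, EGFR

``EVID`` is 1 for dose rows and 0 for observations; ``DVID`` distinguishes
plasma drug concentration (1, ng/mL) from HbA1c (2, %).  ``TIME`` is days
since the first dose, ``AMT`` is the dose in ng.  Covariate columns carry
the value in force at the row's time (last observation carried forward
between visits).  Observations below the assay's lower limit of
quantification are retained in the file but flagged with ``BLQ = 1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .constants import LLOQ_NG_ML

log = logging.getLogger(__name__)

MANDATORY_COLUMNS = ["ID", "TIME", "EVID", "DVID", "AMT", "DV", "BLQ"]
COVARIATE_COLUMNS = ["WT", "AGE", "SEX", "HT", "AST", "ALT", "GGT", "SCR", "EGFR"]

EVID_DOSE = 1
EVID_OBS = 0
DVID_CONC = 1
DVID_HBA1C = 2


class FormatError(ValueError):
    """Raised when a dataset file does not match the declared dialect."""


class ValidationError(ValueError):
    """Raised when a dataset violates an event-table invariant."""


@dataclass(frozen=True)
class EventRecord:
    """A single dose/observation row, as a typed view onto the table."""

    subject_id: object
    time: float
    event_kind: str  # "dose" | "pk_obs" | "pd_obs"
    amount: float | None = None
    value: float | None = None
    below_lloq: bool | None = None
    covariates: dict = field(default_factory=dict)


@dataclass
class EventTable:
    """Ordered longitudinal records for a cohort.

    Wraps a :class:`pandas.DataFrame` in the dialect above.  Rows are kept
    sorted by (ID, TIME) with dose rows preceding observations at tied
    times.
    """

    df: pd.DataFrame
    lloq: float = LLOQ_NG_ML

    def __post_init__(self) -> None:
        self.df = _normalise(self.df, self.lloq)

    # ---- queries ---------------------------------------------------------
    @property
    def subjects(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return int(self.df["ID"].nunique())

    def counts(self) -> dict:
        """Per-kind record counts: {'dose': ..., 'pk_obs': ..., 'pd_obs': ...}."""
        d = self.df
        return {
            "dose": int((d["EVID"] == EVID_DOSE).sum()),
            "pk_obs": int(((d["EVID"] == EVID_OBS) & (d["DVID"] == DVID_CONC)).sum()),
            "pd_obs": int(((d["EVID"] == EVID_OBS) & (d["DVID"] == DVID_HBA1C)).sum()),
        }

    def subject_counts(self, subject_id) -> dict:
        sub = EventTable(self.df[self.df["ID"] == subject_id].copy(), self.lloq)
        return sub.counts()

    def doses(self, subject_id) -> pd.DataFrame:
        d = self.df
        return d[(d["ID"] == subject_id) & (d["EVID"] == EVID_DOSE)]

    def observations(self, dvid: int) -> pd.DataFrame:
        d = self.df
        return d[(d["EVID"] == EVID_OBS) & (d["DVID"] == dvid)]

    def records(self) -> Iterator[EventRecord]:
        cov_cols = [c for c in COVARIATE_COLUMNS if c in self.df.columns]
        for row in self.df.itertuples(index=False):
            cov = {c: getattr(row, c) for c in cov_cols}
            if row.EVID == EVID_DOSE:
                yield EventRecord(row.ID, row.TIME, "dose", amount=row.AMT,
                                  covariates=cov)
            else:
                kind = "pk_obs" if row.DVID == DVID_CONC else "pd_obs"
                blq = bool(row.BLQ) if kind == "pk_obs" else None
                yield EventRecord(row.ID, row.TIME, kind, value=row.DV,
                                  below_lloq=blq, covariates=cov)

    # ---- io --------------------------------------------------------------
    def write(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)


def _normalise(df: pd.DataFrame, lloq: float) -> pd.DataFrame:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {missing}")
    df = df.copy()
    for c in ["TIME", "AMT", "DV"]:
        df[c] = pd.to_numeric(df[c])
    for c in ["ID", "EVID", "DVID", "BLQ"]:
        if c != "ID":
            df[c] = pd.to_numeric(df[c]).astype(int)

    neg_t = df.index[df["TIME"] < 0]
    if len(neg_t):
        raise ValidationError(f"negative TIME at row {int(neg_t[0])}")
    dose = df["EVID"] == EVID_DOSE
    bad_amt = df.index[dose & ~(df["AMT"] > 0)]
    if len(bad_amt):
        raise ValidationError(f"non-positive AMT on dose row {int(bad_amt[0])}")
    obs = df["EVID"] == EVID_OBS
    bad_dv = df.index[obs & (df["DV"] < 0)]
    if len(bad_dv):
        raise ValidationError(f"negative DV on observation row {int(bad_dv[0])}")

    # re-derive the BLQ flag so it is true iff value < lloq for pk rows
    pk = obs & (df["DVID"] == DVID_CONC)
    df.loc[pk, "BLQ"] = (df.loc[pk, "DV"] < lloq).astype(int)
    df.loc[~pk, "BLQ"] = 0

    # stable sort: time within subject, dose before observation at ties
    df = df.sort_values(["ID", "TIME", "EVID"],
                        ascending=[True, True, False],
                        kind="mergesort").reset_index(drop=True)

    # every subject with observations must have a dose at or before that
    # time, except HbA1c at time 0 (baseline)
    for sid, grp in df.groupby("ID", sort=False):
        has_dose = (grp["EVID"] == EVID_DOSE).any()
        o = grp[grp["EVID"] == EVID_OBS]
        needs_dose = o[~((o["DVID"] == DVID_HBA1C) & (o["TIME"] == 0))]
        if len(needs_dose):
            if not has_dose:
                raise ValidationError(f"subject {sid} has observations but no dose")
            first_dose = grp.loc[grp["EVID"] == EVID_DOSE, "TIME"].min()
            if (needs_dose["TIME"] < first_dose).any():
                raise ValidationError(
                    f"subject {sid} has an observation before the first dose")
    return df


def read_event_table(path, lloq: float = LLOQ_NG_ML) -> EventTable:
    """Read and validate a cohort CSV in the declared dialect.

    Rows with concentration below ``lloq`` are retained but flagged.
    """
    df = pd.read_csv(path)
    return EventTable(df, lloq=lloq)


def write_event_table(table: EventTable, path) -> None:
    table.write(path)


def exclude_blq(table: EventTable) -> EventTable:
    """Drop below-LLOQ concentration rows (M1 handling); log the count.

    Dose and HbA1c rows are untouched.
    """
    d = table.df
    drop = (d["EVID"] == EVID_OBS) & (d["DVID"] == DVID_CONC) & (d["BLQ"] == 1)
    n = int(drop.sum())
    if n:
        log.info("excluding %d below-LLOQ concentration rows", n)
    out = EventTable(d[~drop].reset_index(drop=True), lloq=table.lloq)
    if out.counts()["pk_obs"] == 0 and table.counts()["pk_obs"] > 0:
        warnings.warn("all concentration observations were below the LLOQ")
    return out


def covariate_at(table: EventTable, subject_id, name: str, time: float,
                 interpolation: str = "locf") -> float:
    """Covariate value in force at ``time`` for one subject.

    Last observation carried forward by default (covariates are recorded at
    clinic visits only); a query before the first record returns the
    baseline value with a warning.
    """
    if name not in table.df.columns:
        raise KeyError(f"unknown covariate {name!r}")
    grp = table.df[table.df["ID"] == subject_id]
    grp = grp[np.isfinite(grp[name])]
    if grp.empty:
        raise ValidationError(
            f"subject {subject_id} has no record carrying covariate {name!r}")
    times = grp["TIME"].to_numpy()
    vals = grp[name].to_numpy()
    # keep the value of the last row at each distinct time
    if time < times[0]:
        warnings.warn(
            f"covariate {name} queried at t={time} before the first record; "
            "returning the baseline value")
        return float(vals[0])
    if interpolation == "locf":
        idx = np.searchsorted(times, time, side="right") - 1
        return float(vals[idx])
    if interpolation == "linear":
        return float(np.interp(time, times, vals))
    raise ValueError(f"unknown interpolation rule {interpolation!r}")


def empty_frame(n: int = 0) -> pd.DataFrame:
    """An empty dataframe with the full dialect's columns."""
    cols = MANDATORY_COLUMNS + COVARIATE_COLUMNS
    return pd.DataFrame({c: np.zeros(n) for c in cols})
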