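"""12-month utilization and expenditure aggregation, all-cause and
schizophrenia-related.

Scope rule: a medical claim is schizophrenia-related when any diagnosis
position carries an F20-prefix code; the schizophrenia-related drug bucket
is restricted to oral atypical antipsychotic fills.  Inpatient stays merge
overlapping or day-sharing claims; stay length is inclusive
(discharge - admission + 1), clipped to follow-up.  ED visits collapse to
distinct service dates; outpatient visits count claim rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from . import intervals as iv
from .io import DX_COLS, ClaimsBundle

FOLLOWUP_START = 0
FOLLOWUP_END = 364

ALL_CAUSE = "all_cause"
SCHIZ = "schizophrenia"
SCOPES = (ALL_CAUSE, SCHIZ)


@dataclass
class UtilizationSummary:
    inpatient_visits: int
    ed_visits: int
    outpatient_visits: int
    inpatient_days: Optional[int]  # defined only when inpatient_visits >= 1

    @property
    def any_inpatient(self) -> bool:
        return self.inpatient_visits >= 1

    @property
    def any_ed(self) -> bool:
        return self.ed_visits >= 1

    @property
    def any_outpatient(self) -> bool:
        return self.outpatient_visits >= 1


@dataclass
class ExpenditureSummary:
    inpatient: float
    ed: float
    outpatient: float
    prescription: float  # all outpatient pharmacy, or OAAP-only in schiz scope

    @property
    def total_medical(self) -> float:
        return self.inpatient + self.ed + self.outpatient

    @property
    def total(self) -> float:
        return self.total_medical + self.prescription


def is_schiz_claim(dx_codes: Iterable[str]) -> bool:
    return any(str(c).replace(".", "").upper().startswith("F20") for c in dx_codes)


def build_stays(
    inpatient_claims: Sequence[Tuple[int, int]],
    window: Tuple[int, int] = (FOLLOWUP_START, FOLLOWUP_END),
) -> List[Tuple[int, int]]:
    """Merge overlapping / day-sharing (admission, discharge) claim pairs
    into stays, clipped to the window.  Rows with discharge before
    admission are dropped."""
    valid = [(adm, dis) for adm, dis in inpatient_claims if adm <= dis]
    return iv.clip(iv.normalize(valid, gap=0), *window)


def stay_los(stays: Sequence[Tuple[int, int]]) -> int:
    """Total inclusive length of stay across merged stays."""
    return sum(dis - adm + 1 for adm, dis in stays)


def count_visits(medical: pd.DataFrame, index_date: pd.Timestamp,
                 scope: str = ALL_CAUSE) -> UtilizationSummary:
    """Visit counts for one patient's medical claims in one scope."""
    df = _in_scope(medical, scope)
    days = (pd.to_datetime(df["service_date"]) - index_date).dt.days if len(df) else None

    stays_in: List[Tuple[int, int]] = []
    ed_days: set = set()
    n_outpatient = 0
    for pos, row in enumerate(df.itertuples(index=False)):
        if row.setting == "inpatient":
            adm = (pd.Timestamp(row.admit_date) - index_date).days
            dis = (pd.Timestamp(row.discharge_date) - index_date).days
            if adm <= dis and adm <= FOLLOWUP_END and dis >= FOLLOWUP_START:
                stays_in.append((adm, dis))
        else:
            day = int(days.iloc[pos])
            if not FOLLOWUP_START <= day <= FOLLOWUP_END:
                continue
            if row.setting == "ed":
                ed_days.add(day)
            elif row.setting == "outpatient":
                n_outpatient += 1
    stays = build_stays(stays_in)
    return UtilizationSummary(
        inpatient_visits=len(stays),
        ed_visits=len(ed_days),
        outpatient_visits=n_outpatient,
        inpatient_days=stay_los(stays) if stays else None,
    )


def _in_scope(medical: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == ALL_CAUSE:
        return medical
    if scope == SCHIZ:
        if medical.empty:
            return medical
        mask = medical[DX_COLS].apply(
            lambda col: col.astype(str).str.replace(".", "", regex=False)
            .str.upper().str.startswith("F20")
        ).any(axis=1)
        return medical[mask]
    raise ValueError(f"unknown scope {scope!r}")


def sum_expenditures(
    medical: pd.DataFrame,
    pharmacy: pd.DataFrame,
    index_date: pd.Timestamp,
    scope: str = ALL_CAUSE,
) -> ExpenditureSummary:
    """Paid-amount sums by category within follow-up for one patient.

    Negative paid amounts (reversals) are rejected.  Inpatient claims are
    keyed by admission day, service claims by service day.
    """
    df = _in_scope(medical, scope)
    sums = {"inpatient": 0.0, "ed": 0.0, "outpatient": 0.0}
    for row in df.itertuples(index=False):
        paid = float(row.paid)
        if paid < 0:
            continue
        key_date = row.admit_date if row.setting == "inpatient" else row.service_date
        day = (pd.Timestamp(key_date) - index_date).days
        if FOLLOWUP_START <= day <= FOLLOWUP_END and row.setting in sums:
            sums[row.setting] += paid

    rx = 0.0
    if len(pharmacy):
        for row in pharmacy.itertuples(index=False):
            paid = float(row.paid)
            if paid < 0:
                continue
            if scope == SCHIZ and int(row.is_oaap) != 1:
                continue
            day = (pd.Timestamp(row.fill_date) - index_date).days
            if FOLLOWUP_START <= day <= FOLLOWUP_END:
                rx += paid
    return ExpenditureSummary(
        inpatient=sums["inpatient"], ed=sums["ed"], outpatient=sums["outpatient"],
        prescription=rx,
    )


@dataclass
class CostContrast:
    mean_flagged: Optional[float]
    mean_unflagged: Optional[float]

    @property
    def difference(self) -> Optional[float]:
        if self.mean_flagged is None or self.mean_unflagged is None:
            return None
        return self.mean_flagged - self.mean_unflagged


def cost_contrast(values: Sequence[float], flags: Sequence[bool]) -> CostContrast:
    """Group means of ``values`` by boolean ``flags`` and their difference
    (flagged minus unflagged).  An empty group yields a missing mean and a
    missing difference."""
    if len(values) != len(flags):
        raise ValueError("values and flags must have equal length")
    grp = {True: [], False: []}
    for v, f in zip(values, flags):
        grp[bool(f)].append(float(v))
    mean = lambda xs: (sum(xs) / len(xs)) if xs else None
    return CostContrast(mean_flagged=mean(grp[True]), mean_unflagged=mean(grp[False]))


def hru_tables(bundle: ClaimsBundle, cohort: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient-and-scope utilization and expenditure tables."""
    med_by_pid = dict(iter(bundle.medical.groupby("patient_id"))) if len(bundle.medical) else {}
    pharm_by_pid = dict(iter(bundle.pharmacy.groupby("patient_id"))) if len(bundle.pharmacy) else {}
    empty_med = bundle.medical.iloc[0:0]
    empty_pharm = bundle.pharmacy.iloc[0:0]

    util_rows, exp_rows = [], []
    for rec in cohort.itertuples(index=False):
        pid = rec.patient_id
        index_date = pd.Timestamp(rec.index_date)
        med = med_by_pid.get(pid, empty_med)
        pharm = pharm_by_pid.get(pid, empty_pharm)
        for scope in SCOPES:
            u = count_visits(med, index_date, scope)
            e = sum_expenditures(med, pharm, index_date, scope)
            util_rows.append(
                {
                    "patient_id": pid,
                    "scope": scope,
                    "inpatient_visits": u.inpatient_visits,
                    "ed_visits": u.ed_visits,
                    "outpatient_visits": u.outpatient_visits,
                    "inpatient_days": u.inpatient_days if u.inpatient_days is not None else float("nan"),
                    "any_inpatient": int(u.any_inpatient),
                    "any_ed": int(u.any_ed),
                    "any_outpatient": int(u.any_outpatient),
                }
            )
            exp_rows.append(
                {
                    "patient_id": pid,
                    "scope": scope,
                    "inpatient": round(e.inpatient, 2),
                    "ed": round(e.ed, 2),
                    "outpatient": round(e.outpatient, 2),
                    "prescription": round(e.prescription, 2),
                    "total_medical": round(e.total_medical, 2),
                    "total": round(e.total, 2),
                }
            )
    util_cols = [
        "patient_id", "scope", "inpatient_visits", "ed_visits", "outpatient_visits",
        "inpatient_days", "any_inpatient", "any_ed", "any_outpatient",
    ]
    exp_cols = [
        "patient_id", "scope", "inpatient", "ed", "outpatient",
        "prescription", "total_medical", "total",
    ]
    return (
        pd.DataFrame(util_rows, columns=util_cols),
        pd.DataFrame(exp_rows, columns=exp_cols),
    )
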