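"""Index-event identification and the seven-step inclusion cascade.

Criteria, applied in order, each one logged to the attrition ledger:

1. a paid oral-atypical (OAAP) fill inside the identification window
   (1b. exactly one OAAP product on the index date);
2. no antipsychotic fill of any class during the 182-day baseline;
3. never dual-eligible during the study period;
4. schizophrenia evidence: >= 1 inpatient claim or >= 2 outpatient claims
   carrying an F20-prefix diagnosis during baseline or follow-up
   (claim rows, not distinct dates);
5. age 18-63 at index;
6. enrollment spans jointly covering every day of -182..364 (zero gap);
7. no long-acting-injectable antipsychotic claim at any time.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import intervals as iv
from .io import DX_COLS, ClaimsBundle

BASELINE_START = -182
BASELINE_END = -1
FOLLOWUP_START = 0
FOLLOWUP_END = 364

AGE_MIN = 18
AGE_MAX = 63


@dataclass(frozen=True)
class StudyWindows:
    """Index-anchored baseline and follow-up windows (inclusive day offsets)."""

    baseline: Tuple[int, int] = (BASELINE_START, BASELINE_END)
    followup: Tuple[int, int] = (FOLLOWUP_START, FOLLOWUP_END)

    @property
    def study(self) -> Tuple[int, int]:
        return (self.baseline[0], self.followup[1])


@dataclass(frozen=True)
class IndexEvent:
    patient_id: str
    index_date: dt.date
    index_drugs: Tuple[str, ...]  # distinct OAAP products filled on the index date

    @property
    def single_product(self) -> bool:
        return len(self.index_drugs) == 1

    @property
    def index_drug(self) -> str:
        return self.index_drugs[0]


@dataclass
class AttritionTable:
    """Ordered (criterion label, patients remaining) ledger."""

    rows: List[Tuple[str, int]] = field(default_factory=list)

    def append(self, label: str, n_remaining: int) -> None:
        if self.rows and n_remaining > self.rows[-1][1]:
            raise ValueError(
                f"attrition must be non-increasing: {label} has {n_remaining} "
                f"after {self.rows[-1][1]}"
            )
        self.rows.append((label, int(n_remaining)))

    @property
    def final_count(self) -> int:
        return self.rows[-1][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["criterion", "n_remaining"])


def find_index_event(
    pharmacy: pd.DataFrame,
    window: Tuple[dt.date, dt.date],
) -> Optional[IndexEvent]:
    """First OAAP fill inside the identification window for one patient.

    If several distinct OAAP products share the first date, all are listed
    and the event is flagged non-single-product (excluded later).
    """
    oaap = pharmacy[pharmacy["is_oaap"] == 1]
    if oaap.empty:
        return None
    dates = pd.to_datetime(oaap["fill_date"]).dt.date
    mask = (dates >= window[0]) & (dates <= window[1])
    if not mask.any():
        return None
    in_window = oaap[mask]
    first = min(dates[mask])
    drugs = tuple(sorted(in_window.loc[dates[mask] == first, "drug"].unique()))
    return IndexEvent(
        patient_id=str(pharmacy["patient_id"].iloc[0]), index_date=first, index_drugs=drugs
    )


def schizophrenia_evidence(medical: pd.DataFrame, index_date: dt.date,
                           windows: StudyWindows = StudyWindows()) -> bool:
    """>= 1 inpatient or >= 2 outpatient claim rows with an F20-prefix code
    during baseline or follow-up."""
    if medical.empty:
        return False
    lo, hi = windows.study
    n_inpatient = 0
    n_outpatient = 0
    for row in medical.itertuples(index=False):
        day = (dt.date.fromisoformat(str(row.service_date)) - index_date).days
        if not lo <= day <= hi:
            continue
        if not any(str(getattr(row, c)).replace(".", "").upper().startswith("F20")
                   for c in DX_COLS):
            continue
        if row.setting == "inpatient":
            n_inpatient += 1
        else:
            n_outpatient += 1
    return n_inpatient >= 1 or n_outpatient >= 2


def _age_at(birth: dt.date, on: dt.date) -> int:
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def _continuous_enrollment(spans: pd.DataFrame, index_date: dt.date,
                           windows: StudyWindows) -> bool:
    lo, hi = windows.study
    ivs = []
    for row in spans.itertuples(index=False):
        start = (dt.date.fromisoformat(str(row.span_start)) - index_date).days
        end = (dt.date.fromisoformat(str(row.span_end)) - index_date).days
        if start <= end:
            ivs.append((start, end))
    merged = iv.clip(iv.normalize(ivs), lo, hi)
    return iv.total_days(merged) == hi - lo + 1


def apply_inclusion(
    bundle: ClaimsBundle,
    window: Tuple[dt.date, dt.date],
    windows: StudyWindows = StudyWindows(),
) -> Tuple[pd.DataFrame, AttritionTable]:
    """Apply the seven inclusion criteria; return (cohort, attrition ledger).

    The cohort frame has columns patient_id, index_date, index_drug.
    Missing demographics or enrollment fail the relevant criterion rather
    than raising.
    """
    pharm_by_pid: Dict[str, pd.DataFrame] = (
        dict(iter(bundle.pharmacy.groupby("patient_id"))) if len(bundle.pharmacy) else {}
    )
    med_by_pid: Dict[str, pd.DataFrame] = (
        dict(iter(bundle.medical.groupby("patient_id"))) if len(bundle.medical) else {}
    )
    enroll_by_pid: Dict[str, pd.DataFrame] = (
        dict(iter(bundle.enrollment.groupby("patient_id"))) if len(bundle.enrollment) else {}
    )
    birth_by_pid: Dict[str, str] = dict(
        zip(bundle.patients["patient_id"], bundle.patients["birth_date"])
    )

    all_pids = sorted(
        set(bundle.patients["patient_id"]) | set(pharm_by_pid) | set(med_by_pid)
    )
    attrition = AttritionTable()
    attrition.append("0. patients in source data", len(all_pids))

    events: Dict[str, IndexEvent] = {}
    for pid in all_pids:
        pf = pharm_by_pid.get(pid)
        if pf is None:
            continue
        ev = find_index_event(pf, window)
        if ev is not None:
            events[pid] = ev
    keep = [p for p in all_pids if p in events]
    attrition.append("1. index OAAP fill in identification window", len(keep))

    keep = [p for p in keep if events[p].single_product]
    attrition.append("1b. single OAAP product on index date", len(keep))

    def _day(pid: str, date_str: str) -> int:
        return (dt.date.fromisoformat(str(date_str)) - events[pid].index_date).days

    # 2. AP-free baseline (washout)
    blo, bhi = windows.baseline
    survivors = []
    for pid in keep:
        pf = pharm_by_pid[pid]
        ap = pf[(pf["is_oaap"] == 1) | (pf["is_typical_ap"] == 1) | (pf["is_lai"] == 1)]
        days = [_day(pid, d) for d in ap["fill_date"]]
        if not any(blo <= d <= bhi for d in days):
            survivors.append(pid)
    keep = survivors
    attrition.append("2. no AP fill during 6-month baseline", len(keep))

    # 3. never dual-eligible during the study period
    survivors = []
    slo, shi = windows.study
    for pid in keep:
        spans = enroll_by_pid.get(pid)
        dual = False
        if spans is not None:
            for row in spans.itertuples(index=False):
                if not int(row.dual_eligible):
                    continue
                start = _day(pid, row.span_start)
                end = _day(pid, row.span_end)
                if start <= shi and end >= slo:
                    dual = True
                    break
        if not dual:
            survivors.append(pid)
    keep = survivors
    attrition.append("3. not dual-eligible pre- or post-index", len(keep))

    # 4. schizophrenia evidence
    keep = [
        pid
        for pid in keep
        if schizophrenia_evidence(
            med_by_pid.get(pid, bundle.medical.iloc[0:0]), events[pid].index_date, windows
        )
    ]
    attrition.append("4. schizophrenia diagnosis evidence", len(keep))

    # 5. age 18-63 at index
    survivors = []
    for pid in keep:
        birth = birth_by_pid.get(pid)
        if not isinstance(birth, str) or not birth:
            continue
        age = _age_at(dt.date.fromisoformat(birth), events[pid].index_date)
        if AGE_MIN <= age <= AGE_MAX:
            survivors.append(pid)
    keep = survivors
    attrition.append("5. age 18-63 at index", len(keep))

    # 6. continuous enrollment over the study period
    survivors = []
    for pid in keep:
        spans = enroll_by_pid.get(pid)
        if spans is not None and _continuous_enrollment(spans, events[pid].index_date, windows):
            survivors.append(pid)
    keep = survivors
    attrition.append("6. continuous enrollment pre- and post-index", len(keep))

    # 7. no LAI claim at any time
    keep = [pid for pid in keep if not (pharm_by_pid[pid]["is_lai"] == 1).any()]
    attrition.append("7. no LAI AP claim", len(keep))

    cohort = pd.DataFrame(
        {
            "patient_id": keep,
            "index_date": [events[p].index_date.isoformat() for p in keep],
            "index_drug": [events[p].index_drug for p in keep],
        },
        columns=["patient_id", "index_date", "index_drug"],
    )
    return cohort, attrition
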