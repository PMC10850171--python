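"""Coverage construction, PDC adherence, and switch/augmentation detection.

All day arithmetic is index-anchored: day 0 is the index fill date and the
follow-up window is days 0..364.  Coverage is built with interval algebra
(:mod:`apclaims.intervals`); overlapping same-drug fills are unioned rather
than shifted end-to-end (no stockpiling), so a day in possession of a drug
counts once no matter how many fills or products cover it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from . import intervals as iv

FOLLOWUP_START = 0
FOLLOWUP_END = 364
FOLLOWUP_LEN = 365

PDC_THRESHOLD = 0.8
SWITCH_WINDOW_DAYS = 30
AUGMENT_MIN_OVERLAP = 60


@dataclass(frozen=True)
class Fill:
    """A pharmacy fill in index-anchored days."""

    drug: str
    day: int
    days_supply: int

    def interval(self) -> Tuple[int, int]:
        return (self.day, self.day + self.days_supply - 1)


@dataclass
class CoverageProfile:
    """Per-drug covered-day intervals plus hospital days, clipped to follow-up."""

    patient_id: str
    index_drug: str
    drug_intervals: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    hospital_intervals: List[Tuple[int, int]] = field(default_factory=list)
    n_rejected_fills: int = 0

    def day_set(self, drug: str) -> FrozenSet[int]:
        return frozenset(iv.to_day_set(self.drug_intervals.get(drug, [])))

    def all_drug_intervals(self) -> List[Tuple[int, int]]:
        out: List[Tuple[int, int]] = []
        for ivs in self.drug_intervals.values():
            out.extend(ivs)
        return iv.normalize(out)

    def all_day_set(self) -> FrozenSet[int]:
        return frozenset(iv.to_day_set(self.all_drug_intervals()))

    def hospital_day_set(self) -> FrozenSet[int]:
        return frozenset(iv.to_day_set(self.hospital_intervals))


@dataclass
class ExposureResult:
    patient_id: str
    index_drug: str
    index_medication_days: int
    all_oaap_medication_days: int
    hospital_day_count: int
    pdc_index: float
    pdc_all: float
    adherent_index: bool
    adherent_all: bool
    switched: bool
    switch_day: Optional[int]
    augmented: bool


def build_coverage(
    patient_id: str,
    index_drug: str,
    fills: Iterable[Fill],
    window: Tuple[int, int] = (FOLLOWUP_START, FOLLOWUP_END),
) -> CoverageProfile:
    """Union each drug's fill intervals and clip to the follow-up window.

    A fill on day ``d`` with supply ``s`` covers days ``d..d+s-1``.
    Pre-index fills contribute only their in-window tail.  Fills with a
    non-positive days supply are rejected (counted, not raised).
    """
    profile = CoverageProfile(patient_id=patient_id, index_drug=index_drug)
    by_drug: Dict[str, List[Tuple[int, int]]] = {}
    for f in fills:
        if f.days_supply < 1:
            profile.n_rejected_fills += 1
            continue
        by_drug.setdefault(f.drug, []).append(f.interval())
    for drug, ivs in by_drug.items():
        clipped = iv.clip(iv.normalize(ivs), *window)
        if clipped:
            profile.drug_intervals[drug] = clipped
    return profile


def hospital_days(
    stays: Iterable[Tuple[int, int]],
    window: Tuple[int, int] = (FOLLOWUP_START, FOLLOWUP_END),
) -> List[Tuple[int, int]]:
    """Merged admission..discharge intervals clipped to the window.

    Rows with discharge before admission are dropped.
    """
    valid = [(adm, dis) for adm, dis in stays if adm <= dis]
    return iv.clip(iv.normalize(valid, gap=0), *window)


def total_medication_days(profile: CoverageProfile, scope: str = "index") -> int:
    """Distinct covered days, for the index drug or the union of all drugs.

    A day covered by two concurrent products counts a single day.
    """
    if scope == "index":
        return iv.total_days(profile.drug_intervals.get(profile.index_drug, []))
    if scope == "all":
        return iv.total_days(profile.all_drug_intervals())
    raise ValueError(f"unknown scope {scope!r}")


def compute_pdc(covered_days: FrozenSet[int] | set, hospital: FrozenSet[int] | set) -> float:
    """PDC = |covered outside hospital| / (365 - hospital days), capped at 1.

    A fully institutionalized year (365 hospital days) is defined as PDC 1.
    """
    n_hosp = len(hospital)
    if n_hosp >= FOLLOWUP_LEN:
        return 1.0
    numer = len(set(covered_days) - set(hospital))
    return min(1.0, numer / (FOLLOWUP_LEN - n_hosp))


def classify_adherent(pdc: float, threshold: float = PDC_THRESHOLD) -> bool:
    """Adherent iff PDC >= threshold (closed bound)."""
    if math.isnan(pdc):
        return False
    return pdc >= threshold


def detect_switch(
    profile: CoverageProfile,
    fills: Sequence[Fill],
    window_days: int = SWITCH_WINDOW_DAYS,
) -> Tuple[bool, Optional[int]]:
    """Switch: a non-index product dispensed in the 30 days after the index
    drug's supply ends, with the index drug never refilled on or after that
    dispensing day.

    Let E be the last covered day of the index drug; a fill qualifies when
    its day lies in the half-open window (E, E + 30].
    """
    index_ivs = profile.drug_intervals.get(profile.index_drug, [])
    if not index_ivs:
        return False, None
    end = index_ivs[-1][1]
    index_fill_days = sorted(f.day for f in fills if f.drug == profile.index_drug)
    candidates = sorted(
        f.day
        for f in fills
        if f.drug != profile.index_drug and end < f.day <= end + window_days
    )
    for day in candidates:
        if not any(d >= day for d in index_fill_days):
            return True, day
    return False, None


def detect_augmentation(
    profile: CoverageProfile,
    fills: Sequence[Fill],
    min_overlap: int = AUGMENT_MIN_OVERLAP,
) -> bool:
    """Augmentation: the index product was refilled (>= 2 fills) and some
    other product's coverage overlaps the index drug's coverage on at least
    60 days."""
    n_index_fills = sum(1 for f in fills if f.drug == profile.index_drug and f.days_supply >= 1)
    if n_index_fills < 2:
        return False
    index_ivs = profile.drug_intervals.get(profile.index_drug, [])
    for drug, ivs in profile.drug_intervals.items():
        if drug == profile.index_drug:
            continue
        if iv.total_days(iv.intersect(ivs, index_ivs)) >= min_overlap:
            return True
    return False


def compute_exposure(
    patient_id: str,
    index_drug: str,
    oaap_fills: Sequence[Fill],
    stays: Iterable[Tuple[int, int]],
) -> ExposureResult:
    """Run the full exposure pipeline for one patient."""
    profile = build_coverage(patient_id, index_drug, oaap_fills)
    profile.hospital_intervals = hospital_days(stays)
    hosp = profile.hospital_day_set()

    index_days = total_medication_days(profile, "index")
    all_days = total_medication_days(profile, "all")
    pdc_index = compute_pdc(profile.day_set(index_drug), hosp)
    pdc_all = compute_pdc(profile.all_day_set(), hosp)
    switched, switch_day = detect_switch(profile, oaap_fills)
    augmented = detect_augmentation(profile, oaap_fills)

    return ExposureResult(
        patient_id=patient_id,
        index_drug=index_drug,
        index_medication_days=index_days,
        all_oaap_medication_days=all_days,
        hospital_day_count=len(hosp),
        pdc_index=pdc_index,
        pdc_all=pdc_all,
        adherent_index=classify_adherent(pdc_index),
        adherent_all=classify_adherent(pdc_all),
        switched=switched,
        switch_day=switch_day,
        augmented=augmented,
    )


def exposure_table(bundle, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-patient exposure rows for every cohort patient.

    ``bundle`` is a :class:`apclaims.io.ClaimsBundle`; ``cohort`` carries
    ``patient_id``, ``index_date`` and ``index_drug``.
    """
    pharm = bundle.pharmacy
    med = bundle.medical
    pharm_by_pid = dict(iter(pharm.groupby("patient_id"))) if len(pharm) else {}
    med_by_pid = dict(iter(med.groupby("patient_id"))) if len(med) else {}

    rows = []
    for rec in cohort.itertuples(index=False):
        pid = rec.patient_id
        index_date = pd.Timestamp(rec.index_date)
        pf = pharm_by_pid.get(pid)
        fills: List[Fill] = []
        if pf is not None:
            oaap = pf[pf["is_oaap"] == 1]
            for r in oaap.itertuples(index=False):
                day = (pd.Timestamp(r.fill_date) - index_date).days
                fills.append(Fill(drug=r.drug, day=day, days_supply=int(r.days_supply)))
        stays: List[Tuple[int, int]] = []
        mf = med_by_pid.get(pid)
        if mf is not None:
            inp = mf[mf["setting"] == "inpatient"]
            for r in inp.itertuples(index=False):
                adm = (pd.Timestamp(r.admit_date) - index_date).days
                dis = (pd.Timestamp(r.discharge_date) - index_date).days
                stays.append((adm, dis))
        res = compute_exposure(pid, rec.index_drug, fills, stays)
        rows.append(
            {
                "patient_id": pid,
                "index_drug": res.index_drug,
                "index_medication_days": res.index_medication_days,
                "all_oaap_medication_days": res.all_oaap_medication_days,
                "hospital_days": res.hospital_day_count,
                "pdc_index": res.pdc_index,
                "pdc_all": res.pdc_all,
                "adherent_index": int(res.adherent_index),
                "adherent_all": int(res.adherent_all),
                "switched": int(res.switched),
                "switch_day": res.switch_day if res.switch_day is not None else "",
                "augmented": int(res.augmented),
            }
        )
    cols = [
        "patient_id",
        "index_drug",
        "index_medication_days",
        "all_oaap_medication_days",
        "hospital_days",
        "pdc_index",
        "pdc_all",
        "adherent_index",
        "adherent_all",
        "switched",
        "switch_day",
        "augmented",
    ]
    return pd.DataFrame(rows, columns=cols)
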