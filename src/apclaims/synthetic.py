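"""Synthetic Medicaid-like claims generator with ground-truth labels.

Every patient is simulated index-anchored (index fill = day 0), then day
offsets are converted to calendar dates only when rows are emitted.  The
per-patient refill process is a two-state persistence model: at each supply
exhaustion the patient refills immediately with probability ``p``,
otherwise either resumes after a geometric gap or discontinues for good.

Ground truth (covered days, hospital days, PDC, treatment pattern,
inclusion status) is computed here by brute-force per-day enumeration —
deliberately NOT the interval algebra used by the analysis pipeline — so
downstream recovery checks compare two independent code paths.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ConfigurationError, GeneratorConfig, validated_config
from .io import (
    DX_COLS,
    ENROLLMENT_COLS,
    GROUND_TRUTH_COLS,
    MEDICAL_COLS,
    PATIENT_COLS,
    PHARMACY_COLS,
    ClaimsBundle,
)

BASELINE_START = -182
FOLLOWUP_END = 364
FOLLOWUP_LEN = 365

F20_CODES = ["F20.0", "F20.1", "F20.2", "F20.3", "F20.5", "F20.9"]
OTHER_DX = ["Z00.00", "R51.9", "M54.5", "J06.9", "K21.9", "R10.9"]
SMI_CODES = {
    "bipolar": ["F31.0", "F31.2", "F31.9"],
    "mdd": ["F32.1", "F32.9", "F33.1"],
    "schizoaffective": ["F25.0", "F25.1", "F25.9"],
}
CHARLSON_POOL = [
    "E11.9", "I50.9", "J44.9", "I21.9", "K25.9",
    "B18.2", "E11.5", "N18.3", "C50.9", "M05.9",
]
TYPICAL_APS = ["haloperidol", "chlorpromazine", "fluphenazine"]
LAI_DRUGS = ["risperidone-lai", "paliperidone-lai", "aripiprazole-lai"]

PATTERN_PERSISTENT = "persistent"
PATTERN_DISCONTINUED = "discontinued"
PATTERN_SWITCHED = "switched"
PATTERN_AUGMENTED = "augmented"

CRITERION_LABELS = {
    2: "c2_baseline_ap",
    3: "c3_dual_eligible",
    4: "c4_schizophrenia_evidence",
    5: "c5_age",
    6: "c6_enrollment_gap",
    7: "c7_lai",
}


def expected_covered_days(refill_prob: float, days_supply: int = 30) -> float:
    """Closed-form expected covered days for the pure-geometric persistence
    process (no gaps, no switching/augmentation, no hospital days).

    With on-time refill probability ``p`` the number of consecutive fills is
    geometric; fill ``k`` (1-based, day ``(k-1)*s``) contributes its supply
    clipped to the 365-day window.
    """
    total = 0.0
    k = 1
    while (k - 1) * days_supply <= FOLLOWUP_END:
        contrib = min(days_supply, FOLLOWUP_LEN - (k - 1) * days_supply)
        total += (refill_prob ** (k - 1)) * contrib
        k += 1
    return total


def _persistence_fill_days(rng: np.random.Generator, p: float, pm) -> List[int]:
    """Fill days (offsets) for one drug under the two-state refill process."""
    s = pm.days_supply
    fills = [0]
    day = 0
    while True:
        nxt = day + s
        if nxt > FOLLOWUP_END:
            break
        if rng.random() < p:
            day = nxt
        elif rng.random() < pm.gap_restart_prob:
            day = nxt + int(rng.geometric(min(1.0, 1.0 / pm.gap_mean_days)))
            if day > FOLLOWUP_END:
                break
        else:
            break
        fills.append(day)
    return fills


def _brute_force_truth(
    oaap_fills: Sequence[Tuple[int, int]], stays: Sequence[Tuple[int, int]]
) -> Tuple[int, int, float, bool]:
    """Per-day enumeration of covered/hospital days and PDC.

    Returns (covered outside hospital, hospital days, pdc, covers day 364).
    """
    covered: set = set()
    for day, supply in oaap_fills:
        covered.update(range(max(0, day), min(FOLLOWUP_LEN, day + supply)))
    hosp: set = set()
    for adm, dis in stays:
        if dis < adm:
            continue
        hosp.update(range(max(0, adm), min(FOLLOWUP_LEN, dis + 1)))
    n_hosp = len(hosp)
    n_cov = len(covered - hosp)
    pdc = 1.0 if n_hosp >= FOLLOWUP_LEN else min(1.0, n_cov / (FOLLOWUP_LEN - n_hosp))
    return n_cov, n_hosp, pdc, FOLLOWUP_END in covered


class _Tables:
    """Row accumulators for the five output tables."""

    def __init__(self) -> None:
        self.enrollment: List[dict] = []
        self.pharmacy: List[dict] = []
        self.medical: List[dict] = []
        self.patients: List[dict] = []
        self.ground_truth: List[dict] = []


def _cal(index_date: dt.date, offset: int) -> str:
    return (index_date + dt.timedelta(days=int(offset))).isoformat()


def _paid(rng: np.random.Generator, cfg: GeneratorConfig, setting: str) -> float:
    p = cfg.cost_params[setting]
    return round(float(rng.lognormal(p.mu, p.sigma)), 2)


def _dx_row(dx: Sequence[str]) -> Dict[str, str]:
    dx = list(dx)[:4]
    return {col: (dx[i] if i < len(dx) else "") for i, col in enumerate(DX_COLS)}


def _simulate_patient(rng: np.random.Generator, cfg: GeneratorConfig, pid: str, t: _Tables) -> None:
    window_days = (cfg.index_window[1] - cfg.index_window[0]).days
    index_date = cfg.index_window[0] + dt.timedelta(days=int(rng.integers(0, window_days + 1)))
    drugs = sorted(cfg.drug_mix)
    probs = np.array([cfg.drug_mix[d] for d in drugs])
    index_drug = str(rng.choice(drugs, p=probs / probs.sum()))
    pm = cfg.persistence_model
    s = pm.days_supply

    # independent inclusion-failure mechanisms
    fail_typical = rng.random() < cfg.typical_ap_baseline_prob
    fail_dual = rng.random() < cfg.dual_eligible_prob
    fail_evidence = rng.random() < cfg.dx_model.evidence_missing_prob
    fail_age = rng.random() < cfg.demographics.ineligible_age_prob
    fail_gap = rng.random() < cfg.enrollment_gap_prob
    fail_lai = rng.random() < cfg.lai_prob

    p_refill = float(np.clip(rng.normal(pm.refill_prob_mean, pm.refill_prob_sd), 0.02, 0.999))

    # treatment pattern
    u = rng.random()
    oaap_fills: List[Tuple[str, int, int]] = []  # (drug, day, supply)
    if u < cfg.switch_prob:
        pattern = PATTERN_SWITCHED
        n_fills = 1 + int(rng.integers(0, min(7, max(1, 300 // s))))
        for k in range(n_fills):
            oaap_fills.append((index_drug, k * s, s))
        end = n_fills * s - 1
        other = str(rng.choice([d for d in drugs if d != index_drug]))
        switch_day = end + 1 + int(rng.integers(0, 30))
        day = switch_day
        oaap_fills.append((other, day, s))
        while True:
            nxt = day + s
            if nxt > FOLLOWUP_END or rng.random() >= p_refill:
                break
            day = nxt
            oaap_fills.append((other, day, s))
    elif u < cfg.switch_prob + cfg.augment_prob:
        pattern = PATTERN_AUGMENTED
        b0 = 15 + int(rng.integers(0, 31))
        n_b = 2 + int(rng.integers(0, 2))
        overlap = n_b * s
        n_idx_min = math.ceil((b0 + overlap) / s)
        n_idx_max = max(n_idx_min, FOLLOWUP_LEN // s)
        n_idx = int(rng.integers(n_idx_min, n_idx_max + 1))
        for k in range(n_idx):
            oaap_fills.append((index_drug, k * s, s))
        other = str(rng.choice([d for d in drugs if d != index_drug]))
        for k in range(n_b):
            oaap_fills.append((other, b0 + k * s, s))
    else:
        for day in _persistence_fill_days(rng, p_refill, pm):
            oaap_fills.append((index_drug, day, s))
        pattern = None  # resolved below from coverage

    if fail_typical:
        typ_drug = str(rng.choice(TYPICAL_APS))
        typ_day = -int(rng.integers(1, 183))
        t.pharmacy.append(
            {
                "patient_id": pid,
                "drug": typ_drug,
                "fill_date": _cal(index_date, typ_day),
                "days_supply": 30,
                "paid": _paid(rng, cfg, "pharmacy"),
                "is_oaap": 0,
                "is_typical_ap": 1,
                "is_lai": 0,
            }
        )
    if fail_lai:
        t.pharmacy.append(
            {
                "patient_id": pid,
                "drug": str(rng.choice(LAI_DRUGS)),
                "fill_date": _cal(index_date, int(rng.integers(0, FOLLOWUP_LEN))),
                "days_supply": 28,
                "paid": _paid(rng, cfg, "pharmacy"),
                "is_oaap": 0,
                "is_typical_ap": 0,
                "is_lai": 1,
            }
        )
    for drug, day, supply in sorted(oaap_fills, key=lambda f: (f[1], f[0])):
        t.pharmacy.append(
            {
                "patient_id": pid,
                "drug": drug,
                "fill_date": _cal(index_date, day),
                "days_supply": supply,
                "paid": _paid(rng, cfg, "pharmacy"),
                "is_oaap": 1,
                "is_typical_ap": 0,
                "is_lai": 0,
            }
        )

    # hospitalizations
    stays: List[Tuple[int, int]] = []
    for _ in range(int(rng.poisson(cfg.hosp_rate))):
        adm = int(rng.integers(0, FOLLOWUP_LEN))
        los = 1 + int(rng.poisson(max(0.0, cfg.hosp_los_mean - 1)))
        stays.append((adm, adm + los - 1))
    stays.sort()

    # patient-level diagnosis propensities
    dxm = cfg.dx_model
    has_smi = {k: rng.random() < p for k, p in (
        ("bipolar", dxm.bipolar_prob),
        ("mdd", dxm.mdd_prob),
        ("schizoaffective", dxm.schizoaffective_prob),
    )}
    charlson_codes: List[str] = []
    if rng.random() < dxm.charlson_prob:
        n_codes = 1 + int(rng.integers(0, 2))
        charlson_codes = [str(c) for c in rng.choice(CHARLSON_POOL, size=n_codes, replace=False)]

    def _draw_dx(setting: str) -> List[str]:
        prob = {"inpatient": dxm.f20_inpatient_prob,
                "ed": dxm.f20_ed_prob,
                "outpatient": dxm.f20_outpatient_prob}[setting]
        dx = []
        if not fail_evidence and rng.random() < prob:
            dx.append(str(rng.choice(F20_CODES)))
        else:
            dx.append(str(rng.choice(OTHER_DX)))
        for cond, flag in has_smi.items():
            if flag and rng.random() < 0.25:
                dx.append(str(rng.choice(SMI_CODES[cond])))
        return dx

    med_rows: List[dict] = []
    for adm, dis in stays:
        med_rows.append(
            {
                "patient_id": pid,
                "setting": "inpatient",
                "service_date": _cal(index_date, adm),
                "admit_date": _cal(index_date, adm),
                "discharge_date": _cal(index_date, dis),
                "paid": _paid(rng, cfg, "inpatient"),
                **_dx_row(_draw_dx("inpatient")),
            }
        )
    for setting, rate in (("ed", cfg.ed_rate), ("outpatient", cfg.outpatient_rate)):
        for _ in range(int(rng.poisson(rate))):
            day = int(rng.integers(BASELINE_START, FOLLOWUP_LEN))
            med_rows.append(
                {
                    "patient_id": pid,
                    "setting": setting,
                    "service_date": _cal(index_date, day),
                    "admit_date": "",
                    "discharge_date": "",
                    "paid": _paid(rng, cfg, setting),
                    **_dx_row(_draw_dx(setting)),
                }
            )

    # attach Charlson codes to baseline outpatient claims (creating one if needed)
    if charlson_codes:
        baseline_op = [
            r for r in med_rows
            if r["setting"] == "outpatient"
            and BASELINE_START <= (dt.date.fromisoformat(r["service_date"]) - index_date).days < 0
        ]
        if not baseline_op:
            row = {
                "patient_id": pid,
                "setting": "outpatient",
                "service_date": _cal(index_date, -int(rng.integers(1, 183))),
                "admit_date": "",
                "discharge_date": "",
                "paid": _paid(rng, cfg, "outpatient"),
                **_dx_row([str(rng.choice(OTHER_DX))]),
            }
            med_rows.append(row)
            baseline_op = [row]
        for code in charlson_codes:
            row = baseline_op[int(rng.integers(0, len(baseline_op)))]
            for col in DX_COLS:
                if not row[col]:
                    row[col] = code
                    break

    # guarantee schizophrenia evidence unless this patient is meant to lack it
    if not fail_evidence:
        def _is_f20(row: dict) -> bool:
            return any(row[c].startswith("F20") for c in DX_COLS)

        n_inp = sum(1 for r in med_rows if r["setting"] == "inpatient" and _is_f20(r))
        n_out = sum(1 for r in med_rows if r["setting"] != "inpatient" and _is_f20(r))
        while n_inp < 1 and n_out < 2:
            med_rows.append(
                {
                    "patient_id": pid,
                    "setting": "outpatient",
                    "service_date": _cal(index_date, int(rng.integers(0, FOLLOWUP_LEN))),
                    "admit_date": "",
                    "discharge_date": "",
                    "paid": _paid(rng, cfg, "outpatient"),
                    **_dx_row([str(rng.choice(F20_CODES))]),
                }
            )
            n_out += 1
    med_rows.sort(key=lambda r: (r["service_date"], r["setting"], r["paid"]))
    t.medical.extend(med_rows)

    # enrollment
    dual = 1 if fail_dual else 0
    if fail_gap:
        gap_at = int(rng.integers(30, 300))
        t.enrollment.append(
            {
                "patient_id": pid,
                "span_start": _cal(index_date, -200),
                "span_end": _cal(index_date, gap_at - 1),
                "dual_eligible": dual,
            }
        )
        t.enrollment.append(
            {
                "patient_id": pid,
                "span_start": _cal(index_date, gap_at + int(rng.integers(5, 30))),
                "span_end": _cal(index_date, 380),
                "dual_eligible": dual,
            }
        )
    else:
        t.enrollment.append(
            {
                "patient_id": pid,
                "span_start": _cal(index_date, -200),
                "span_end": _cal(index_date, 380),
                "dual_eligible": dual,
            }
        )

    # demographics
    demo = cfg.demographics
    if fail_age:
        age = int(rng.choice([16, 17] + list(range(64, 76))))
    else:
        age = int(rng.integers(demo.age_min, demo.age_max + 1))
    birth_offset = int(round(age * 365.25)) + int(rng.integers(10, 300))
    sexes = sorted(demo.sex_probs)
    sex = str(rng.choice(sexes, p=np.array([demo.sex_probs[k] for k in sexes])))
    races = sorted(demo.race_probs)
    race = str(rng.choice(races, p=np.array([demo.race_probs[k] for k in races])))
    t.patients.append(
        {
            "patient_id": pid,
            "birth_date": _cal(index_date, -birth_offset),
            "sex": sex,
            "race_ethnicity": race,
        }
    )

    # ground truth by per-day enumeration
    n_cov, n_hosp, pdc, covers_last_day = _brute_force_truth(
        [(day, supply) for _, day, supply in oaap_fills], stays
    )
    if pattern is None:
        pattern = PATTERN_PERSISTENT if covers_last_day else PATTERN_DISCONTINUED
    failing = ""
    for crit, flag in ((2, fail_typical), (3, fail_dual), (4, fail_evidence),
                       (5, fail_age), (6, fail_gap), (7, fail_lai)):
        if flag:
            failing = CRITERION_LABELS[crit]
            break
    t.ground_truth.append(
        {
            "patient_id": pid,
            "true_covered_day_count": n_cov,
            "true_hospital_day_count": n_hosp,
            "true_pdc": pdc,
            "true_pattern": pattern,
            "passes_inclusion": int(failing == ""),
            "failing_criterion": failing,
            "is_edge_case": 0,
        }
    )


def generate_population(config: GeneratorConfig | dict) -> ClaimsBundle:
    """Generate the five claim tables for ``config.n_patients`` patients.

    Deterministic for a fixed seed: two calls with the same config produce
    byte-identical CSV serializations.
    """
    if isinstance(config, dict):
        config = validated_config(**config)
    elif not isinstance(config, GeneratorConfig):
        raise ConfigurationError("config must be a GeneratorConfig or mapping")
    rng = np.random.default_rng(config.seed)
    t = _Tables()
    width = max(6, len(str(config.n_patients)))
    for i in range(config.n_patients):
        _simulate_patient(rng, config, f"P{i + 1:0{width}d}", t)
    return ClaimsBundle(
        enrollment=pd.DataFrame(t.enrollment, columns=ENROLLMENT_COLS),
        pharmacy=pd.DataFrame(t.pharmacy, columns=PHARMACY_COLS),
        medical=pd.DataFrame(t.medical, columns=MEDICAL_COLS),
        patients=pd.DataFrame(t.patients, columns=PATIENT_COLS),
        ground_truth=pd.DataFrame(t.ground_truth, columns=GROUND_TRUTH_COLS),
    )


# ---------------------------------------------------------------------------
# hand-built edge-case fixtures

EDGE_INDEX_DATE = dt.date(2017, 6, 1)


def _edge_patient(
    t: _Tables,
    pid: str,
    oaap_fills: Sequence[Tuple[str, int, int]],
    *,
    stays: Sequence[Tuple[int, int]] = (),
    extra_pharmacy: Sequence[dict] = (),
    dual: int = 0,
    pattern: Optional[str] = None,
    failing: str = "",
) -> None:
    idx = EDGE_INDEX_DATE
    for drug, day, supply in oaap_fills:
        t.pharmacy.append(
            {
                "patient_id": pid,
                "drug": drug,
                "fill_date": _cal(idx, day),
                "days_supply": supply,
                "paid": 25.0,
                "is_oaap": 1,
                "is_typical_ap": 0,
                "is_lai": 0,
            }
        )
    for row in extra_pharmacy:
        t.pharmacy.append({"patient_id": pid, **row})
    for adm, dis in stays:
        t.medical.append(
            {
                "patient_id": pid,
                "setting": "inpatient",
                "service_date": _cal(idx, adm),
                "admit_date": _cal(idx, adm),
                "discharge_date": _cal(idx, dis),
                "paid": 5000.0,
                **_dx_row(["F20.9"]),
            }
        )
    for day in (10, 40):  # schizophrenia evidence: two outpatient F20 claims
        t.medical.append(
            {
                "patient_id": pid,
                "setting": "outpatient",
                "service_date": _cal(idx, day),
                "admit_date": "",
                "discharge_date": "",
                "paid": 100.0,
                **_dx_row(["F20.9"]),
            }
        )
    t.enrollment.append(
        {
            "patient_id": pid,
            "span_start": _cal(idx, -200),
            "span_end": _cal(idx, 380),
            "dual_eligible": dual,
        }
    )
    t.patients.append(
        {
            "patient_id": pid,
            "birth_date": "1980-01-15",
            "sex": "M",
            "race_ethnicity": "White",
        }
    )
    n_cov, n_hosp, pdc, covers_last = _brute_force_truth(
        [(day, supply) for _, day, supply in oaap_fills], list(stays)
    )
    if pattern is None:
        pattern = PATTERN_PERSISTENT if covers_last else PATTERN_DISCONTINUED
    t.ground_truth.append(
        {
            "patient_id": pid,
            "true_covered_day_count": n_cov,
            "true_hospital_day_count": n_hosp,
            "true_pdc": pdc,
            "true_pattern": pattern,
            "passes_inclusion": int(failing == ""),
            "failing_criterion": failing,
            "is_edge_case": 1,
        }
    )


def inject_edge_cases(bundle: ClaimsBundle) -> ClaimsBundle:
    """Append deterministic boundary-condition fixture patients.

    The fixtures exercise duplicate/overlapping fills, window clipping,
    hospital-overlapping supply, the 30-day switch boundary, the 60-day
    augmentation boundary, the PDC = 0.8 threshold, and the dual-eligible
    and LAI exclusions.  Every fixture id starts with ``EDGE-``.
    """
    t = _Tables()
    q = "quetiapine"

    _edge_patient(t, "EDGE-DUP-FILL", [(q, 0, 30), (q, 0, 30)])
    _edge_patient(t, "EDGE-OVERLAP-FILL", [(q, 0, 30), (q, 15, 30)])
    _edge_patient(t, "EDGE-TAIL-CLIP", [(q, 0, 30), (q, 350, 30)])
    _edge_patient(t, "EDGE-HOSP-OVERLAP", [(q, 0, 30)], stays=[(10, 19)])
    # index supply ends day 29; new product exactly 30 days later -> switched
    _edge_patient(
        t, "EDGE-SWITCH-30", [(q, 0, 30), ("risperidone", 59, 30)], pattern=PATTERN_SWITCHED
    )
    # 31 days later -> outside the window, not a switch
    _edge_patient(t, "EDGE-SWITCH-31", [(q, 0, 30), ("risperidone", 60, 30)])
    # index covers 0..89 (3 fills); second product overlap 59 vs 60 days
    _edge_patient(
        t, "EDGE-AUG-59", [(q, 0, 30), (q, 30, 30), (q, 60, 30), ("olanzapine", 1, 59)]
    )
    _edge_patient(
        t,
        "EDGE-AUG-60",
        [(q, 0, 30), (q, 30, 30), (q, 60, 30), ("olanzapine", 1, 60)],
        pattern=PATTERN_AUGMENTED,
    )
    # exactly 292 covered days, no hospital days -> PDC = 292/365 = 0.8
    pdc80 = [(q, 30 * k, 30) for k in range(9)] + [(q, 270, 22)]
    _edge_patient(t, "EDGE-PDC-080", pdc80)
    _edge_patient(t, "EDGE-DUAL", [(q, 0, 30)], dual=1, failing=CRITERION_LABELS[3])
    _edge_patient(
        t,
        "EDGE-LAI",
        [(q, 0, 30)],
        extra_pharmacy=[
            {
                "drug": "risperidone-lai",
                "fill_date": _cal(EDGE_INDEX_DATE, 50),
                "days_supply": 28,
                "paid": 400.0,
                "is_oaap": 0,
                "is_typical_ap": 0,
                "is_lai": 1,
            }
        ],
        failing=CRITERION_LABELS[7],
    )

    def _cat(base: pd.DataFrame, rows: List[dict], cols: List[str]) -> pd.DataFrame:
        extra = pd.DataFrame(rows, columns=cols)
        return pd.concat([base, extra], ignore_index=True) if len(rows) else base.copy()

    gt = bundle.ground_truth
    if gt is None:
        gt = pd.DataFrame(columns=GROUND_TRUTH_COLS)
    return ClaimsBundle(
        enrollment=_cat(bundle.enrollment, t.enrollment, ENROLLMENT_COLS),
        pharmacy=_cat(bundle.pharmacy, t.pharmacy, PHARMACY_COLS),
        medical=_cat(bundle.medical, t.medical, MEDICAL_COLS),
        patients=_cat(bundle.patients, t.patients, PATIENT_COLS),
        ground_truth=_cat(gt, t.ground_truth, GROUND_TRUTH_COLS),
    )
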