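"""CSV table I/O for the claims pipeline.

Five plain-text tables make up a dataset directory:

- ``enrollment.csv``  — patient_id, span_start, span_end, dual_eligible
- ``pharmacy.csv``    — patient_id, drug, fill_date, days_supply, paid,
                        is_oaap, is_typical_ap, is_lai
- ``medical.csv``     — patient_id, setting (inpatient|ed|outpatient),
                        service_date, admit_date, discharge_date, paid,
                        dx1..dx4
- ``patients.csv``    — patient_id, birth_date, sex, race_ethnicity
- ``ground_truth.csv``— generator labels (absent for real data)

Dates are ISO ``YYYY-MM-DD`` strings; flags are 0/1 integers; paid amounts
are dollars with two decimals.  See ``resources/schema.md`` for the full
column dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

DX_COLS = ["dx1", "dx2", "dx3", "dx4"]

PHARMACY_COLS = [
    "patient_id",
    "drug",
    "fill_date",
    "days_supply",
    "paid",
    "is_oaap",
    "is_typical_ap",
    "is_lai",
]
MEDICAL_COLS = [
    "patient_id",
    "setting",
    "service_date",
    "admit_date",
    "discharge_date",
    "paid",
    *DX_COLS,
]
ENROLLMENT_COLS = ["patient_id", "span_start", "span_end", "dual_eligible"]
PATIENT_COLS = ["patient_id", "birth_date", "sex", "race_ethnicity"]
GROUND_TRUTH_COLS = [
    "patient_id",
    "true_covered_day_count",
    "true_hospital_day_count",
    "true_pdc",
    "true_pattern",
    "passes_inclusion",
    "failing_criterion",
    "is_edge_case",
]


@dataclass
class ClaimsBundle:
    """The five tables of one synthetic (or real) dataset."""

    enrollment: pd.DataFrame
    pharmacy: pd.DataFrame
    medical: pd.DataFrame
    patients: pd.DataFrame
    ground_truth: Optional[pd.DataFrame] = None

    def tables(self) -> Dict[str, pd.DataFrame]:
        out = {
            "enrollment": self.enrollment,
            "pharmacy": self.pharmacy,
            "medical": self.medical,
            "patients": self.patients,
        }
        if self.ground_truth is not None:
            out["ground_truth"] = self.ground_truth
        return out


def write_bundle(bundle: ClaimsBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        df.to_csv(outdir / f"{name}.csv", index=False)


def read_bundle(indir: str | Path) -> ClaimsBundle:
    indir = Path(indir)
    gt_path = indir / "ground_truth.csv"
    return ClaimsBundle(
        enrollment=pd.read_csv(indir / "enrollment.csv", dtype={"patient_id": str}),
        pharmacy=pd.read_csv(indir / "pharmacy.csv", dtype={"patient_id": str}),
        medical=pd.read_csv(
            indir / "medical.csv", dtype={"patient_id": str}, keep_default_na=False
        ),
        patients=pd.read_csv(indir / "patients.csv", dtype={"patient_id": str}),
        ground_truth=(
            pd.read_csv(gt_path, dtype={"patient_id": str}) if gt_path.exists() else None
        ),
    )


def bundle_to_csv_strings(bundle: ClaimsBundle) -> Dict[str, str]:
    """Serialize every table to its CSV text (used for determinism checks)."""
    return {name: df.to_csv(index=False) for name, df in bundle.tables().items()}
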