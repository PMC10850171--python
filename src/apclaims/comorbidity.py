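"""Quan ICD-10 Charlson comorbidity scoring and severe-mental-illness flags.

The category/prefix/weight table ships as a versioned CSV resource
(``resources/quan_charlson.csv``) using the Quan 2005 ICD-10 coding
algorithm with the original Charlson weights (1/2/3/6).  Matching is
dot-insensitive prefix matching on normalized codes.  Three hierarchy
pairs apply: complicated diabetes supersedes uncomplicated, metastatic
cancer supersedes malignancy, and moderate/severe liver disease supersedes
mild liver disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

import pandas as pd

from .io import DX_COLS

_RESOURCE = "quan_charlson.csv"


def normalize_code(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


@dataclass(frozen=True)
class CharlsonCategory:
    name: str
    prefixes: Tuple[str, ...]
    weight: int
    dominated_by: Optional[str]  # category that supersedes this one, if any


@dataclass
class CharlsonMap:
    categories: Dict[str, CharlsonCategory]

    @classmethod
    def from_csv(cls, path: str | Path) -> "CharlsonMap":
        df = pd.read_csv(path, keep_default_na=False)
        cats: Dict[str, CharlsonCategory] = {}
        for name, grp in df.groupby("category", sort=False):
            weight = int(grp["weight"].iloc[0])
            dom = str(grp["dominated_by"].iloc[0]) or None
            prefixes = tuple(normalize_code(p) for p in grp["prefix"])
            if not prefixes or any(not p for p in prefixes):
                raise ValueError(f"category {name} has an empty prefix")
            if weight < 1:
                raise ValueError(f"category {name} has weight < 1")
            cats[str(name)] = CharlsonCategory(str(name), prefixes, weight, dom)
        for cat in cats.values():
            if cat.dominated_by is not None and cat.dominated_by not in cats:
                raise ValueError(
                    f"{cat.name} dominated_by unknown category {cat.dominated_by}"
                )
        return cls(cats)

    @classmethod
    def default(cls) -> "CharlsonMap":
        with resources.as_file(
            resources.files("apclaims.resources") / _RESOURCE
        ) as path:
            return cls.from_csv(path)

    def present_categories(self, codes: Iterable[str], hierarchy: bool = True) -> Set[str]:
        norm = [normalize_code(c) for c in codes if str(c).strip()]
        present = {
            cat.name
            for cat in self.categories.values()
            if any(code.startswith(p) for code in norm for p in cat.prefixes)
        }
        if hierarchy:
            present = {
                name
                for name in present
                if self.categories[name].dominated_by not in present
            }
        return present


def quan_cci(codes: Iterable[str], charlson_map: Optional[CharlsonMap] = None,
             hierarchy: bool = True) -> int:
    """Charlson score: sum of weights over present categories.

    Unmatched codes are ignored; duplicated codes score once; hierarchy
    drops the lesser member of each superseding pair.
    """
    cmap = charlson_map or CharlsonMap.default()
    present = cmap.present_categories(codes, hierarchy=hierarchy)
    return sum(cmap.categories[name].weight for name in present)


def cci_group(score: int) -> str:
    if score < 0:
        raise ValueError("CCI score must be >= 0")
    return "0" if score == 0 else ("1" if score == 1 else "2+")


SMI_PREFIXES = {
    "bipolar": ("F31",),
    "mdd": ("F32", "F33"),
    "schizoaffective": ("F25",),
}


def smi_flags(codes: Iterable[str]) -> Dict[str, bool]:
    """Bipolar (F31), major depressive (F32/F33) and schizoaffective (F25)
    disorder flags from baseline-plus-follow-up diagnosis codes."""
    norm = [normalize_code(c) for c in codes if str(c).strip()]
    return {
        name: any(code.startswith(p) for code in norm for p in prefixes)
        for name, prefixes in SMI_PREFIXES.items()
    }


def baseline_flags_table(bundle, cohort: pd.DataFrame,
                         charlson_map: Optional[CharlsonMap] = None) -> pd.DataFrame:
    """Per-patient CCI (baseline diagnoses only) and SMI flags
    (baseline plus follow-up) for every cohort patient."""
    cmap = charlson_map or CharlsonMap.default()
    med_by_pid = (
        dict(iter(bundle.medical.groupby("patient_id"))) if len(bundle.medical) else {}
    )
    demo = bundle.patients.set_index("patient_id")

    rows = []
    for rec in cohort.itertuples(index=False):
        pid = rec.patient_id
        index_date = pd.Timestamp(rec.index_date)
        baseline_codes: List[str] = []
        study_codes: List[str] = []
        mf = med_by_pid.get(pid)
        if mf is not None:
            days = (pd.to_datetime(mf["service_date"]) - index_date).dt.days
            for col in DX_COLS:
                codes = mf[col].astype(str)
                in_baseline = (days >= -182) & (days <= -1)
                in_study = (days >= -182) & (days <= 364)
                baseline_codes.extend(codes[in_baseline])
                study_codes.extend(codes[in_study])
        score = quan_cci(baseline_codes, cmap)
        flags = smi_flags(study_codes)
        age = None
        sex = race = ""
        if pid in demo.index:
            birth = pd.Timestamp(demo.loc[pid, "birth_date"])
            age = (
                index_date.year
                - birth.year
                - int((index_date.month, index_date.day) < (birth.month, birth.day))
            )
            sex = demo.loc[pid, "sex"]
            race = demo.loc[pid, "race_ethnicity"]
        rows.append(
            {
                "patient_id": pid,
                "age": age,
                "sex": sex,
                "race_ethnicity": race,
                "cci_score": score,
                "cci_group": cci_group(score),
                "bipolar": int(flags["bipolar"]),
                "mdd": int(flags["mdd"]),
                "schizoaffective": int(flags["schizoaffective"]),
            }
        )
    cols = [
        "patient_id",
        "age",
        "sex",
        "race_ethnicity",
        "cci_score",
        "cci_group",
        "bipolar",
        "mdd",
        "schizoaffective",
    ]
    return pd.DataFrame(rows, columns=cols)
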