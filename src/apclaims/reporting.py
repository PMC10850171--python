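"""Cohort-level report tables and between-group hypothesis tests.

Conventions: Pearson chi-square without continuity correction for
categorical variables; Mann-Whitney-Wilcoxon (two groups) or
Kruskal-Wallis H (more than two) for continuous ones, two-sided, midrank
ties; alpha = 0.05 per test with no multiplicity adjustment.  Display
rounding: percentages and means to one decimal, dollars to whole units.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
TOP_DRUGS = 4


@dataclass
class GroupComparison:
    variable: str
    kind: str  # 'categorical' | 'continuous'
    group_labels: List[str]
    summaries: Dict[str, dict]
    test_name: Optional[str]
    statistic: Optional[float]
    p_value: Optional[float]

    @property
    def significant(self) -> Optional[bool]:
        return None if self.p_value is None else bool(self.p_value < ALPHA)


def round1(x: float) -> float:
    """Half-up rounding to one decimal (matches printed-table precision)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pct(n: int, total: int) -> float:
    return round1(100.0 * n / total)


def fmt_count_pct(n: int, total: int) -> str:
    return f"{n} ({pct(n, total):.1f})"


def fmt_mean_sd_median(values: Sequence[float], decimals: int = 1) -> str:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return ""
    mean, sd, med = arr.mean(), arr.std(ddof=1) if arr.size > 1 else 0.0, np.median(arr)
    return f"{mean:.{decimals}f} ({sd:.{decimals}f}) [{med:g}]"


def chi_square_test(table: np.ndarray | Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty row or column")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def compare_groups(values: Sequence, groups: Sequence, kind: str,
                   variable: str = "") -> GroupComparison:
    """Compare one variable across groups.

    categorical -> Pearson chi-square on the values x groups contingency
    table; continuous -> Mann-Whitney-Wilcoxon for two groups, Kruskal-
    Wallis H otherwise.  A degenerate layout (empty row/column, or a
    constant variable) is reported without a test.
    """
    values = list(values)
    groups = [str(g) for g in groups]
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")

    summaries: Dict[str, dict] = {}
    test_name: Optional[str] = None
    statistic: Optional[float] = None
    p_value: Optional[float] = None

    if kind == "categorical":
        df = pd.DataFrame({"value": [str(v) for v in values], "group": groups})
        table = pd.crosstab(df["value"], df["group"])
        for g in labels:
            counts = table[g]
            total = int(counts.sum())
            summaries[g] = {
                "n": total,
                "counts": counts.to_dict(),
                "percents": {k: pct(v, total) for k, v in counts.to_dict().items()},
            }
        try:
            statistic, p_value = chi_square_test(table.to_numpy())
            test_name = "chi-square"
        except ValueError:
            pass
    elif kind == "continuous":
        by_group = {g: np.asarray([float(v) for v, gg in zip(values, groups) if gg == g])
                    for g in labels}
        for g, arr in by_group.items():
            summaries[g] = {
                "n": int(arr.size),
                "mean": float(arr.mean()) if arr.size else float("nan"),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "median": float(np.median(arr)) if arr.size else float("nan"),
            }
        samples = [by_group[g] for g in labels]
        if len(set(float(v) for v in values)) <= 1:
            # no variation at all: distributions identical by definition
            test_name = "mann-whitney" if len(labels) == 2 else "kruskal-wallis"
            statistic, p_value = 0.0, 1.0
        elif len(labels) == 2:
            res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
            test_name = "mann-whitney"
            statistic, p_value = float(res.statistic), float(res.pvalue)
        else:
            res = stats.kruskal(*samples)
            test_name = "kruskal-wallis"
            statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown variable kind {kind!r}")

    return GroupComparison(
        variable=variable, kind=kind, group_labels=labels, summaries=summaries,
        test_name=test_name, statistic=statistic, p_value=p_value,
    )


def _drug_grouping(exposure: pd.DataFrame) -> pd.Series:
    """Index-drug labels with the top-N drugs kept and the rest pooled."""
    counts = exposure["index_drug"].value_counts()
    top = list(counts.index[:TOP_DRUGS])
    return exposure["index_drug"].where(exposure["index_drug"].isin(top), "Other")


def _merged(cohort: pd.DataFrame, *frames: pd.DataFrame) -> pd.DataFrame:
    out = cohort
    for f in frames:
        out = out.merge(f, on="patient_id", how="left")
    return out


def _table_rows(df: pd.DataFrame, group_col: str, specs: List[Tuple[str, str, str]],
                total_label: str = "Overall") -> pd.DataFrame:
    """Generic characteristics table: one row per variable, one column per
    group plus Overall and the test p-value.

    ``specs`` entries are (variable label, column name, kind).
    """
    groups = sorted(df[group_col].astype(str).unique())
    rows = []
    n_total = len(df)
    header = {"variable": "N", total_label: str(n_total), "p_value": ""}
    for g in groups:
        header[g] = str(int((df[group_col].astype(str) == g).sum()))
    rows.append(header)
    for label, col, kind in specs:
        sub = df[[col, group_col]].dropna()
        try:
            comp = compare_groups(sub[col], sub[group_col], kind, variable=label)
            pv = "" if comp.p_value is None else f"{comp.p_value:.4g}"
        except ValueError:
            comp, pv = None, ""
        row = {"variable": label, "p_value": pv}
        if kind == "continuous":
            row[total_label] = fmt_mean_sd_median(sub[col])
            for g in groups:
                row[g] = fmt_mean_sd_median(sub.loc[sub[group_col].astype(str) == g, col])
        else:
            vals = sub[col].astype(str)
            if set(vals.unique()) <= {"0", "1"}:  # boolean flag: report the 1s
                row[total_label] = fmt_count_pct(int((vals == "1").sum()), n_total)
                for g in groups:
                    gmask = sub[group_col].astype(str) == g
                    row[g] = fmt_count_pct(int((vals[gmask] == "1").sum()), int(gmask.sum()))
            else:
                cats = sorted(vals.unique())
                row[total_label] = "; ".join(
                    f"{c}: {fmt_count_pct(int((vals == c).sum()), n_total)}" for c in cats
                )
                for g in groups:
                    gvals = vals[sub[group_col].astype(str) == g]
                    row[g] = "; ".join(
                        f"{c}: {fmt_count_pct(int((gvals == c).sum()), max(len(gvals), 1))}"
                        for c in cats
                    )
        rows.append(row)
    cols = ["variable", total_label] + groups + ["p_value"]
    return pd.DataFrame(rows, columns=cols)


def build_tables(
    cohort: pd.DataFrame,
    baseline_flags: pd.DataFrame,
    exposure: pd.DataFrame,
    utilization: pd.DataFrame,
    expenditures: pd.DataFrame,
    attrition: Optional[pd.DataFrame] = None,
) -> Dict[str, pd.DataFrame]:
    """Assemble the four report tables plus the attrition ledger.

    1. baseline characteristics by index medication (top 4 + Other pooled)
    2. treatment patterns and adherence by index medication
    3. baseline characteristics by all-OAAP adherence status
    4. utilization and expenditures by all-OAAP adherence status
    """
    for name, frame in (("baseline_flags", baseline_flags), ("exposure", exposure),
                        ("utilization", utilization), ("expenditures", expenditures)):
        if frame is None or frame.empty:
            raise ValueError(f"missing upstream stage output: {name}")

    exp = exposure.copy()
    exp["drug_group"] = _drug_grouping(exp)
    exp["adherence_group"] = np.where(exp["adherent_all"] == 1, "adherent", "nonadherent")

    base = _merged(cohort, baseline_flags, exp[
        ["patient_id", "drug_group", "adherence_group", "index_medication_days",
         "all_oaap_medication_days", "pdc_index", "pdc_all",
         "adherent_index", "adherent_all", "switched", "augmented"]
    ])
    base["age_group"] = pd.cut(
        base["age"], bins=[17, 34, 44, 54, 63],
        labels=["18-34", "35-44", "45-54", "55-63"],
    ).astype(str)

    char_specs = [
        ("Male", "male", "categorical"),
        ("Mean age at index", "age", "continuous"),
        ("Age group", "age_group", "categorical"),
        ("Race/ethnicity", "race_ethnicity", "categorical"),
        ("Mean Quan-CCI score", "cci_score", "continuous"),
        ("Quan-CCI group", "cci_group", "categorical"),
        ("Bipolar disorder", "bipolar", "categorical"),
        ("Major depressive disorder", "mdd", "categorical"),
        ("Schizoaffective disorder", "schizoaffective", "categorical"),
    ]
    base["male"] = (base["sex"] == "M").astype(int)

    table1 = _table_rows(base, "drug_group", char_specs)
    table3 = _table_rows(base, "adherence_group", char_specs)

    pattern_specs = [
        ("Mean index OAAP days", "index_medication_days", "continuous"),
        ("Mean all OAAP days", "all_oaap_medication_days", "continuous"),
        ("Added another OAAP", "augmented", "categorical"),
        ("Switched to another OAAP", "switched", "categorical"),
        ("Mean PDC for index OAAP", "pdc_index", "continuous"),
        ("Adherent to index OAAP", "adherent_index", "categorical"),
        ("Mean PDC for all OAAPs", "pdc_all", "continuous"),
        ("Adherent to all OAAPs", "adherent_all", "categorical"),
    ]
    table2 = _table_rows(base, "drug_group", pattern_specs)

    hru = base[["patient_id", "adherence_group"]]
    wide_frames = [hru]
    for scope in ("all_cause", "schizophrenia"):
        u = utilization[utilization["scope"] == scope].drop(columns=["scope"])
        u = u.rename(columns={c: f"{scope}_{c}" for c in u.columns if c != "patient_id"})
        e = expenditures[expenditures["scope"] == scope].drop(columns=["scope"])
        e = e.rename(columns={c: f"{scope}_{c}" for c in e.columns if c != "patient_id"})
        wide_frames.extend([u, e])
    wide = hru
    for f in wide_frames[1:]:
        wide = wide.merge(f, on="patient_id", how="left")

    hru_specs: List[Tuple[str, str, str]] = []
    for scope, label in (("all_cause", "all-cause"), ("schizophrenia", "schizophrenia-related")):
        hru_specs.extend(
            [
                (f">=1 inpatient visit ({label})", f"{scope}_any_inpatient", "categorical"),
                (f">=1 ED visit ({label})", f"{scope}_any_ed", "categorical"),
                (f">=1 outpatient visit ({label})", f"{scope}_any_outpatient", "categorical"),
                (f"Inpatient visits ({label})", f"{scope}_inpatient_visits", "continuous"),
                (f"Inpatient days ({label})", f"{scope}_inpatient_days", "continuous"),
                (f"ED visits ({label})", f"{scope}_ed_visits", "continuous"),
                (f"Outpatient visits ({label})", f"{scope}_outpatient_visits", "continuous"),
                (f"Inpatient expenditures ({label})", f"{scope}_inpatient", "continuous"),
                (f"ED expenditures ({label})", f"{scope}_ed", "continuous"),
                (f"Outpatient expenditures ({label})", f"{scope}_outpatient", "continuous"),
                (f"Prescription expenditures ({label})", f"{scope}_prescription", "continuous"),
                (f"Total medical expenditures ({label})", f"{scope}_total_medical", "continuous"),
                (f"Total expenditures ({label})", f"{scope}_total", "continuous"),
            ]
        )
    for _, col, kind in hru_specs:
        if kind == "continuous":
            wide[col] = pd.to_numeric(wide[col], errors="coerce")
    table4 = _table_rows(wide, "adherence_group", hru_specs)

    out = {"table1": table1, "table2": table2, "table3": table3, "table4": table4}
    if attrition is not None:
        out["attrition"] = attrition.copy()
    return out
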