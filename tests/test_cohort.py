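import datetime as dt

import pandas as pd
import pytest

import apclaims as ap
from apclaims.cohort import (
    AttritionTable,
    StudyWindows,
    apply_inclusion,
    find_index_event,
    schizophrenia_evidence,
)
from apclaims.io import ClaimsBundle

WINDOW = (dt.date(2016, 7, 1), dt.date(2019, 12, 31))


def _pharm(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "drug", "fill_date", "days_supply", "paid",
            "is_oaap", "is_typical_ap", "is_lai",
        ],
    )


def _med(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "setting", "service_date", "admit_date",
            "discharge_date", "paid", "dx1", "dx2", "dx3", "dx4",
        ],
    )


class TestFindIndexEvent:
    def test_earliest_qualifying_fill(self):
        ph = _pharm(
            [
                ("p", "haloperidol", "2016-01-01", 30, 5.0, 0, 1, 0),
                ("p", "olanzapine", "2017-03-01", 30, 5.0, 1, 0, 0),
                ("p", "olanzapine", "2017-05-01", 30, 5.0, 1, 0, 0),
            ]
        )
        ev = find_index_event(ph, WINDOW)
        assert ev.index_date == dt.date(2017, 3, 1)
        assert ev.index_drug == "olanzapine"
        assert ev.single_product

    def test_lai_only_yields_none(self):
        ph = _pharm([("p", "risperidone-lai", "2017-03-01", 28, 5.0, 0, 0, 1)])
        assert find_index_event(ph, WINDOW) is None

    def test_fill_outside_window_yields_none(self):
        ph = _pharm([("p", "olanzapine", "2016-01-01", 30, 5.0, 1, 0, 0)])
        assert find_index_event(ph, WINDOW) is None

    def test_two_products_same_day_flagged(self):
        ph = _pharm(
            [
                ("p", "olanzapine", "2017-03-01", 30, 5.0, 1, 0, 0),
                ("p", "quetiapine", "2017-03-01", 30, 5.0, 1, 0, 0),
            ]
        )
        ev = find_index_event(ph, WINDOW)
        assert not ev.single_product
        assert ev.index_drugs == ("olanzapine", "quetiapine")


class TestSchizophreniaEvidence:
    IDX = dt.date(2017, 6, 1)

    def test_one_inpatient_claim_suffices(self):
        med = _med([("p", "inpatient", "2017-07-01", "2017-07-01", "2017-07-05",
                     1000.0, "F20.0", "", "", "")])
        assert schizophrenia_evidence(med, self.IDX)

    def test_one_outpatient_claim_insufficient(self):
        med = _med([("p", "outpatient", "2017-07-01", "", "", 100.0, "F20.9", "", "", "")])
        assert not schizophrenia_evidence(med, self.IDX)

    def test_two_same_day_outpatient_claims_count(self):
        # claim rows, not distinct dates
        med = _med(
            [
                ("p", "outpatient", "2017-07-01", "", "", 100.0, "F20.9", "", "", ""),
                ("p", "outpatient", "2017-07-01", "", "", 90.0, "F20.9", "", "", ""),
            ]
        )
        assert schizophrenia_evidence(med, self.IDX)

    def test_schizoaffective_is_not_schizophrenia(self):
        med = _med(
            [
                ("p", "outpatient", "2017-07-01", "", "", 100.0, "F20.9", "", "", ""),
                ("p", "outpatient", "2017-08-01", "", "", 100.0, "F25.0", "", "", ""),
            ]
        )
        assert not schizophrenia_evidence(med, self.IDX)

    def test_claims_outside_study_period_ignored(self):
        med = _med(
            [
                ("p", "outpatient", "2015-01-01", "", "", 100.0, "F20.9", "", "", ""),
                ("p", "outpatient", "2019-07-01", "", "", 100.0, "F20.9", "", "", ""),
            ]
        )
        assert not schizophrenia_evidence(med, self.IDX)


class TestAttritionTable:
    def test_monotonic_enforced(self):
        t = AttritionTable()
        t.append("start", 10)
        t.append("step", 8)
        with pytest.raises(ValueError):
            t.append("bad", 9)

    def test_final_count(self):
        t = AttritionTable()
        t.append("start", 10)
        t.append("end", 4)
        assert t.final_count == 4


class TestApplyInclusion:
    def test_attrition_monotone_and_first_row(self, edge_bundle, edge_cohort):
        cohort, attrition = edge_cohort
        counts = [n for _, n in attrition.rows]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == len(edge_bundle.patients)
        assert attrition.final_count == len(cohort)

    def test_matches_ground_truth_labels(self, edge_bundle, edge_cohort):
        cohort, _ = edge_cohort
        gt = edge_bundle.ground_truth
        expected = set(gt.loc[gt["passes_inclusion"] == 1, "patient_id"])
        assert set(cohort["patient_id"]) == expected

    def test_row_order_invariance(self, small_config):
        bundle = ap.generate_population(
            ap.validated_config(**{**small_config.model_dump(), "n_patients": 80})
        )
        cohort_a, _ = apply_inclusion(bundle, small_config.index_window)
        shuffled = ClaimsBundle(
            enrollment=bundle.enrollment.sample(frac=1, random_state=3).reset_index(drop=True),
            pharmacy=bundle.pharmacy.sample(frac=1, random_state=4).reset_index(drop=True),
            medical=bundle.medical.sample(frac=1, random_state=5).reset_index(drop=True),
            patients=bundle.patients.sample(frac=1, random_state=6).reset_index(drop=True),
        )
        cohort_b, _ = apply_inclusion(shuffled, small_config.index_window)
        assert cohort_a.equals(cohort_b)

    def test_retained_patients_pass_brute_force_recheck(self, edge_bundle, edge_cohort):
        """Re-verify all seven predicates for every retained patient by a
        direct row scan, independent of the cascade implementation."""
        cohort, _ = edge_cohort
        ph = edge_bundle.pharmacy
        med = edge_bundle.medical
        enr = edge_bundle.enrollment
        demo = edge_bundle.patients.set_index("patient_id")
        for rec in cohort.itertuples(index=False):
            pid, idx = rec.patient_id, dt.date.fromisoformat(rec.index_date)
            mine = ph[ph["patient_id"] == pid]
            days = mine["fill_date"].map(lambda s: (dt.date.fromisoformat(s) - idx).days)
            # 1: index is the first in-window OAAP fill
            fill_dates = mine.loc[mine["is_oaap"] == 1, "fill_date"].map(dt.date.fromisoformat)
            in_win = [d for d in fill_dates if WINDOW[0] <= d <= WINDOW[1]]
            assert in_win and min(in_win) == idx
            # 1b: a single product on the index date
            index_drugs = mine.loc[
                (mine["is_oaap"] == 1) & (fill_dates == idx).reindex(mine.index, fill_value=False),
                "drug",
            ].unique()
            assert len(index_drugs) == 1
            # 2: no AP fill in baseline
            ap_mask = (mine["is_oaap"] == 1) | (mine["is_typical_ap"] == 1) | (mine["is_lai"] == 1)
            assert not any((-182 <= d <= -1) for d in days[ap_mask])
            # 3: no dual-eligible span
            spans = enr[enr["patient_id"] == pid]
            assert not (spans["dual_eligible"] == 1).any()
            # 4: schizophrenia evidence
            mymed = med[med["patient_id"] == pid]
            n_inp = n_out = 0
            for r in mymed.itertuples(index=False):
                d = (dt.date.fromisoformat(r.service_date) - idx).days
                if not -182 <= d <= 364:
                    continue
                if any(str(c).startswith("F20") for c in (r.dx1, r.dx2, r.dx3, r.dx4)):
                    if r.setting == "inpatient":
                        n_inp += 1
                    else:
                        n_out += 1
            assert n_inp >= 1 or n_out >= 2
            # 5: age 18-63
            birth = dt.date.fromisoformat(demo.loc[pid, "birth_date"])
            age = idx.year - birth.year - ((idx.month, idx.day) < (birth.month, birth.day))
            assert 18 <= age <= 63
            # 6: continuous enrollment over -182..364
            covered = set()
            for r in spans.itertuples(index=False):
                s = (dt.date.fromisoformat(r.span_start) - idx).days
                e = (dt.date.fromisoformat(r.span_end) - idx).days
                covered.update(range(s, e + 1))
            assert set(range(-182, 365)) <= covered
            # 7: no LAI ever
            assert not (mine["is_lai"] == 1).any()

    def test_criterion_boundaries(self):
        """One outpatient F20 claim only -> excluded at criterion 4; age 64
        at index -> excluded at criterion 5."""
        pharm = _pharm(
            [
                ("one-op", "olanzapine", "2017-06-01", 30, 5.0, 1, 0, 0),
                ("age64", "olanzapine", "2017-06-01", 30, 5.0, 1, 0, 0),
            ]
        )
        med = _med(
            [
                ("one-op", "outpatient", "2017-07-01", "", "", 50.0, "F20.9", "", "", ""),
                ("age64", "outpatient", "2017-07-01", "", "", 50.0, "F20.9", "", "", ""),
                ("age64", "outpatient", "2017-08-01", "", "", 50.0, "F20.9", "", "", ""),
            ]
        )
        enr = pd.DataFrame(
            [
                ("one-op", "2016-06-01", "2019-06-01", 0),
                ("age64", "2016-06-01", "2019-06-01", 0),
            ],
            columns=["patient_id", "span_start", "span_end", "dual_eligible"],
        )
        demo = pd.DataFrame(
            [
                ("one-op", "1980-01-01", "M", "White"),
                ("age64", "1953-05-31", "F", "White"),
            ],
            columns=["patient_id", "birth_date", "sex", "race_ethnicity"],
        )
        bundle = ClaimsBundle(enrollment=enr, pharmacy=pharm, medical=med, patients=demo)
        cohort, attrition = apply_inclusion(bundle, WINDOW)
        assert len(cohort) == 0
        rows = dict(attrition.rows)
        assert rows["4. schizophrenia diagnosis evidence"] == 1  # one-op dropped here
        assert rows["5. age 18-63 at index"] == 0  # age64 dropped here
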