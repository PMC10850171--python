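import hypothesis.strategies as st
import pandas as pd
import pytest
from hypothesis import given, settings

from apclaims import hru
from apclaims.hru import (
    ALL_CAUSE,
    SCHIZ,
    build_stays,
    cost_contrast,
    count_visits,
    stay_los,
    sum_expenditures,
)

from conftest import stay_day_oracle

IDX = pd.Timestamp("2017-06-01")

MED_COLS = [
    "patient_id", "setting", "service_date", "admit_date", "discharge_date",
    "paid", "dx1", "dx2", "dx3", "dx4",
]
PH_COLS = [
    "patient_id", "drug", "fill_date", "days_supply", "paid",
    "is_oaap", "is_typical_ap", "is_lai",
]


def _d(offset: int) -> str:
    return (IDX + pd.Timedelta(days=offset)).date().isoformat()


def _med(rows):
    return pd.DataFrame(rows, columns=MED_COLS)


def _inp(off_adm, off_dis, paid=1000.0, dx="F20.9"):
    return ("p", "inpatient", _d(off_adm), _d(off_adm), _d(off_dis), paid, dx, "", "", "")


def _svc(setting, off, paid=100.0, dx="Z00.00"):
    return ("p", setting, _d(off), "", "", paid, dx, "", "", "")


class TestBuildStays:
    def test_day_sharing_claims_merge(self):
        # (10,14) and (14,19) share day 14 -> one stay, LOS 10
        stays = build_stays([(10, 14), (14, 19)])
        assert stays == [(10, 19)]
        assert stay_los(stays) == 10

    def test_same_day_stay_has_los_one(self):
        stays = build_stays([(10, 10)])
        assert stay_los(stays) == 1

    def test_disjoint_stays_stay_separate(self):
        stays = build_stays([(10, 14), (20, 24)])
        assert len(stays) == 2
        assert stay_los(stays) == 10

    def test_consecutive_but_not_sharing_days_stay_separate(self):
        assert len(build_stays([(10, 14), (15, 19)])) == 2

    def test_malformed_rows_dropped(self):
        assert build_stays([(20, 10)]) == []

    @given(st.lists(st.tuples(st.integers(-20, 400), st.integers(0, 40)), max_size=5))
    @settings(max_examples=200)
    def test_merged_days_match_day_sweep_oracle(self, raw):
        stays = [(a, a + w) for a, w in raw]
        merged = build_stays(stays)
        from apclaims import intervals as iv

        assert iv.to_day_set(merged) == stay_day_oracle(stays)


class TestCountVisits:
    def test_ed_visits_collapse_per_date(self):
        med = _med([_svc("ed", 5), _svc("ed", 5), _svc("ed", 5), _svc("ed", 9)])
        u = count_visits(med, IDX, ALL_CAUSE)
        assert u.ed_visits == 2

    def test_outpatient_counts_rows(self):
        med = _med([_svc("outpatient", 5), _svc("outpatient", 5)])
        assert count_visits(med, IDX, ALL_CAUSE).outpatient_visits == 2

    def test_f20_stay_counts_in_both_scopes(self):
        med = _med([_inp(10, 14, dx="F20.9")])
        assert count_visits(med, IDX, ALL_CAUSE).inpatient_visits == 1
        assert count_visits(med, IDX, SCHIZ).inpatient_visits == 1

    def test_f25_claim_all_cause_only(self):
        med = _med([_svc("outpatient", 5, dx="F25.0")])
        assert count_visits(med, IDX, ALL_CAUSE).outpatient_visits == 1
        assert count_visits(med, IDX, SCHIZ).outpatient_visits == 0

    def test_inpatient_days_none_without_stays(self):
        u = count_visits(_med([_svc("outpatient", 5)]), IDX, ALL_CAUSE)
        assert u.inpatient_days is None
        assert not u.any_inpatient and u.any_outpatient

    def test_baseline_claims_not_counted(self):
        med = _med([_svc("ed", -10), _svc("outpatient", -10)])
        u = count_visits(med, IDX, ALL_CAUSE)
        assert u.ed_visits == 0 and u.outpatient_visits == 0

    def test_any_flags_match_counts(self):
        med = _med([_inp(10, 14), _svc("ed", 5)])
        u = count_visits(med, IDX, ALL_CAUSE)
        assert u.any_inpatient == (u.inpatient_visits >= 1)
        assert u.any_ed == (u.ed_visits >= 1)
        assert u.any_outpatient == (u.outpatient_visits >= 1)


class TestSumExpenditures:
    def test_empty(self):
        e = sum_expenditures(_med([]), pd.DataFrame(columns=PH_COLS), IDX)
        assert e.total == 0.0

    def test_additivity(self):
        med = _med([_inp(10, 14, paid=100.0), _svc("ed", 5, paid=50.0),
                    _svc("outpatient", 20, paid=25.0)])
        ph = pd.DataFrame(
            [("p", "olanzapine", _d(0), 30, 10.0, 1, 0, 0)], columns=PH_COLS
        )
        e = sum_expenditures(med, ph, IDX)
        assert e.total_medical == pytest.approx(175.0)
        assert e.total == pytest.approx(185.0)

    def test_schiz_scope_oaap_drugs_only(self):
        ph = pd.DataFrame(
            [
                ("p", "olanzapine", _d(0), 30, 10.0, 1, 0, 0),
                ("p", "metformin", _d(0), 30, 7.0, 0, 0, 0),
            ],
            columns=PH_COLS,
        )
        all_cause = sum_expenditures(_med([]), ph, IDX, ALL_CAUSE)
        schiz = sum_expenditures(_med([]), ph, IDX, SCHIZ)
        assert all_cause.prescription == pytest.approx(17.0)
        assert schiz.prescription == pytest.approx(10.0)

    def test_claim_in_both_scopes_full_amount_each(self):
        med = _med([_svc("outpatient", 5, paid=80.0, dx="F20.1")])
        a = sum_expenditures(med, pd.DataFrame(columns=PH_COLS), IDX, ALL_CAUSE)
        s = sum_expenditures(med, pd.DataFrame(columns=PH_COLS), IDX, SCHIZ)
        assert a.outpatient == pytest.approx(80.0)
        assert s.outpatient == pytest.approx(80.0)

    def test_negative_paid_rejected(self):
        med = _med([_svc("outpatient", 5, paid=-80.0)])
        e = sum_expenditures(med, pd.DataFrame(columns=PH_COLS), IDX)
        assert e.outpatient == 0.0

    def test_scope_monotonicity(self):
        med = _med(
            [_inp(10, 14, paid=500.0, dx="F20.0"), _inp(100, 104, paid=700.0, dx="Z00.00"),
             _svc("ed", 5, paid=60.0, dx="F20.9"), _svc("outpatient", 9, paid=40.0)]
        )
        ph = pd.DataFrame(columns=PH_COLS)
        a = sum_expenditures(med, ph, IDX, ALL_CAUSE)
        s = sum_expenditures(med, ph, IDX, SCHIZ)
        for cat in ("inpatient", "ed", "outpatient", "prescription"):
            assert getattr(s, cat) <= getattr(a, cat)


class TestCostContrast:
    def test_hospitalized_difference(self):
        c = cost_contrast([33464.0, 10203.0], [True, False])
        assert c.difference == pytest.approx(23261.0)

    def test_identical_groups(self):
        c = cost_contrast([5.0, 5.0, 5.0, 5.0], [True, True, False, False])
        assert c.difference == 0.0

    def test_empty_group_missing(self):
        c = cost_contrast([1.0, 2.0], [True, True])
        assert c.mean_unflagged is None
        assert c.difference is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cost_contrast([1.0], [True, False])


def test_hru_tables_invariants(edge_bundle, edge_cohort):
    cohort, _ = edge_cohort
    util, exp = hru.hru_tables(edge_bundle, cohort)
    assert set(util["scope"]) == {"all_cause", "schizophrenia"}
    # additivity within rounding noise
    assert (
        (exp["inpatient"] + exp["ed"] + exp["outpatient"] - exp["total_medical"]).abs() < 1e-6
    ).all()
    assert ((exp["total_medical"] + exp["prescription"] - exp["total"]).abs() < 1e-6).all()
    # scope monotonicity per patient per category
    wide_u = util.pivot(index="patient_id", columns="scope")
    for col in ("inpatient_visits", "ed_visits", "outpatient_visits"):
        assert (
            wide_u[(col, "schizophrenia")].astype(float)
            <= wide_u[(col, "all_cause")].astype(float)
        ).all()
    wide_e = exp.pivot(index="patient_id", columns="scope")
    for col in ("inpatient", "ed", "outpatient", "prescription", "total"):
        assert (
            wide_e[(col, "schizophrenia")] <= wide_e[(col, "all_cause")] + 1e-9
        ).all()
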