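"""Registry and hospital case-set construction."""

from __future__ import annotations

import pandas as pd
import pytest

from pacval.ascertain import (
    assign_record_groups,
    hospital_all_cases,
    hospital_index_cases,
    registry_cases,
)
from pacval.codes import record_group
from pacval.windows import WindowIndex

from .conftest import (
    make_hospital_frame,
    make_maternity_frame,
    make_registry_frame,
    random_small_cohort,
)


@pytest.fixture()
def simple_windows():
    return WindowIndex(
        make_maternity_frame(
            [
                {"woman_id": "W1", "maternity_id": "M1",
                 "delivery_date": "2004-06-30", "gestation_weeks": 40},
                {"woman_id": "W2", "maternity_id": "M2",
                 "delivery_date": "2005-03-15", "gestation_weeks": 38},
            ]
        )
    )


class TestRegistryCases:
    def test_incident_in_window_yields_one_case(self, simple_windows):
        reg = make_registry_frame(
            [{"woman_id": "W1", "registry_id": "R1",
              "diagnosis_date": "2004-02-01", "group": "melanoma"}]
        )
        cases = registry_cases(reg, simple_windows)
        assert len(cases) == 1
        assert cases.iloc[0]["maternity_id"] == "M1"
        assert cases.iloc[0]["group"] == "melanoma"

    def test_multiple_primaries_one_pregnancy_yield_distinct_cases(
        self, simple_windows
    ):
        reg = make_registry_frame(
            [
                {"woman_id": "W1", "registry_id": "R1",
                 "diagnosis_date": "2004-02-01", "group": "melanoma"},
                {"woman_id": "W1", "registry_id": "R2",
                 "diagnosis_date": "2004-08-01", "group": "breast"},
            ]
        )
        cases = registry_cases(reg, simple_windows)
        assert set(cases["group"]) == {"melanoma", "breast"}

    def test_prevalent_cancer_yields_no_case(self, simple_windows):
        reg = make_registry_frame(
            [{"woman_id": "W1", "registry_id": "R1",
              "diagnosis_date": "2004-02-01", "group": "melanoma",
              "first_notification_date": "2001-05-01"}]
        )
        assert registry_cases(reg, simple_windows).empty

    def test_same_group_duplicates_collapse_to_earliest(self, simple_windows):
        reg = make_registry_frame(
            [
                {"woman_id": "W1", "registry_id": "R2",
                 "diagnosis_date": "2004-09-01", "group": "breast"},
                {"woman_id": "W1", "registry_id": "R1",
                 "diagnosis_date": "2004-02-01", "group": "breast"},
            ]
        )
        cases = registry_cases(reg, simple_windows)
        assert len(cases) == 1
        assert cases.iloc[0]["source_record_id"] == "R1"


class TestHospitalCases:
    def test_records_are_the_unit_for_all_cases(self, simple_windows):
        hosp = make_hospital_frame(
            [
                {"woman_id": "W1", "record_id": "1",
                 "admission_date": "2004-02-01", "codes": ["C50.9"]},
                {"woman_id": "W1", "record_id": "2",
                 "admission_date": "2004-03-01", "codes": ["C50.1"]},
                {"woman_id": "W1", "record_id": "3",
                 "admission_date": "2004-04-01", "codes": ["O80", "C50.9"]},
            ]
        )
        all_cases = hospital_all_cases(hosp, simple_windows)
        assert len(all_cases) == 3
        index = hospital_index_cases(hosp, simple_windows)
        assert len(index) == 1
        assert index.iloc[0]["source_record_id"] == "1"

    def test_admission_outside_every_window_is_dropped(self, simple_windows):
        hosp = make_hospital_frame(
            [{"woman_id": "W1", "record_id": "1",
              "admission_date": "2001-01-01", "codes": ["C50.9"]}]
        )
        assert hospital_all_cases(hosp, simple_windows).empty

    def test_index_tie_breaks_on_smallest_record_id(self, simple_windows):
        hosp = make_hospital_frame(
            [
                {"woman_id": "W1", "record_id": "7",
                 "admission_date": "2004-02-01", "codes": ["C50.9"]},
                {"woman_id": "W1", "record_id": "3",
                 "admission_date": "2004-02-01", "codes": ["C50.9"]},
            ]
        )
        index = hospital_index_cases(hosp, simple_windows)
        assert list(index["source_record_id"]) == ["3"]

    def test_two_groups_give_two_index_cases(self, simple_windows):
        hosp = make_hospital_frame(
            [
                {"woman_id": "W1", "record_id": "1",
                 "admission_date": "2004-02-01", "codes": ["C50.9"]},
                {"woman_id": "W1", "record_id": "2",
                 "admission_date": "2004-03-01", "codes": ["C43.5"]},
            ]
        )
        index = hospital_index_cases(hosp, simple_windows)
        assert set(index["group"]) == {"breast", "melanoma"}

    def test_out_of_scope_only_records_do_not_change_case_sets(
        self, simple_windows
    ):
        cancer = [
            {"woman_id": "W1", "record_id": "1",
             "admission_date": "2004-02-01", "codes": ["C50.9"]}
        ]
        noise = [
            {"woman_id": "W1", "record_id": "9",
             "admission_date": "2004-03-01", "codes": ["O80", "Z37.0"]},
            {"woman_id": "W2", "record_id": "10",
             "admission_date": "2005-04-01", "codes": ["D05.1", "C78.0"]},
        ]
        with_noise = hospital_all_cases(
            make_hospital_frame(cancer + noise), simple_windows
        )
        without = hospital_all_cases(make_hospital_frame(cancer), simple_windows)
        pd.testing.assert_frame_equal(with_noise, without)

    def test_assign_record_groups_matches_scalar_record_group(self, codemap):
        hosp = make_hospital_frame(
            [
                {"woman_id": "W1", "record_id": "1",
                 "admission_date": "2004-02-01",
                 "codes": ["C78.0", "C18.2", "C50.9"]},
                {"woman_id": "W1", "record_id": "2",
                 "admission_date": "2004-02-01", "codes": ["O80"]},
            ]
        )
        got = assign_record_groups(hosp, codemap)
        assert list(got) == ["colorectal", None]
        assert record_group(["C78.0", "C18.2", "C50.9"], codemap).value == (
            "colorectal"
        )


def _brute_force_case_sets(maternities, hospital, registry, codemap):
    """Independent set construction written directly from the definitions."""
    from datetime import timedelta

    windows = {}
    for m in maternities.itertuples():
        start = m.delivery_date - timedelta(days=7 * m.gestation_weeks)
        end = m.delivery_date + timedelta(days=365)
        windows.setdefault(m.woman_id, []).append(
            (start, end, m.delivery_date, m.maternity_id)
        )

    def attr(woman, d):
        hits = [
            (dd, mid) for (s, e, dd, mid) in windows.get(woman, [])
            if s <= d <= e
        ]
        return min(hits)[1] if hits else None

    reg_best = {}
    for r in registry.itertuples():
        if r.first_notification_date != r.diagnosis_date:
            continue
        mid = attr(r.woman_id, r.diagnosis_date)
        if mid is None:
            continue
        key = (mid, r.group)
        cand = (r.diagnosis_date, str(r.registry_id))
        if key not in reg_best or cand < reg_best[key]:
            reg_best[key] = cand
    reg_set = set(reg_best)

    all_list = []
    diag_cols = sorted(
        (c for c in hospital.columns if c.startswith("diag")),
        key=lambda c: int(c[4:]),
    )
    for r in hospital.itertuples():
        group = None
        for c in diag_cols:
            code = getattr(r, c)
            if not str(code).strip():
                continue
            cls = codemap.classify(str(code))
            if cls.is_incident_candidate:
                group = cls.group.value
                break
        if group is None:
            continue
        mid = attr(r.woman_id, r.admission_date)
        if mid is None:
            continue
        all_list.append((mid, group, r.admission_date, str(r.record_id)))

    idx_best = {}
    for mid, group, adm, rid in all_list:
        key = (mid, group)
        rid_key = (0, int(rid)) if rid.isdigit() else (1, rid)
        cand = (adm, rid_key)
        if key not in idx_best or cand < idx_best[key]:
            idx_best[key] = cand
    return reg_set, sorted(all_list), {
        k: v[0] for k, v in idx_best.items()
    }


@pytest.mark.parametrize("seed", range(8))
def test_all_three_case_sets_match_brute_force_on_random_cohorts(seed, codemap):
    maternities, hospital, registry = random_small_cohort(seed)
    widx = WindowIndex(maternities)
    reg_set, all_list, idx_map = _brute_force_case_sets(
        maternities, hospital, registry, codemap
    )

    got_reg = registry_cases(registry, widx)
    assert set(zip(got_reg["maternity_id"], got_reg["group"])) == reg_set

    got_all = hospital_all_cases(hospital, widx, codemap)
    got_all_list = sorted(
        zip(
            got_all["maternity_id"], got_all["group"],
            got_all["event_date"], got_all["source_record_id"].astype(str),
        )
    )
    assert got_all_list == all_list

    got_idx = hospital_index_cases(hospital, widx, codemap)
    got_idx_map = {
        (r.maternity_id, r.group): r.event_date for r in got_idx.itertuples()
    }
    assert got_idx_map == idx_map
    # structural invariants
    assert len(got_idx) <= len(got_all)
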