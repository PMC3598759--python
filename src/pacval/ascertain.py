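"""Case ascertainment: registry gold standard and hospital case sets.

Three comparable case sets are produced, each keyed on (maternity, clinical
group):

* ``registry_cases`` — incident primary cancers notified to the registry
  whose diagnosis date falls in a maternity's exposure window.  A record is
  incident (not prevalent) when its diagnosis date equals the woman's first
  registry notification of that group; the notification history reaches back
  to a lookback horizon well before the study period, so earlier
  notifications mark the cancer as prevalent.  Distinct groups within one
  maternity yield distinct cases (multiple primaries in one pregnancy are
  kept); duplicates of one group collapse to the earliest diagnosis.

* ``hospital_all_cases`` — every admission carrying an eligible primary
  cancer diagnosis in any of up to 22 fields, attributed to a window by
  admission date.  The *record* is the unit: three admissions of one woman
  for one cancer give three cases.  This replicates analyses where
  individuals cannot be identified in hospital data.

* ``hospital_index_cases`` — per (maternity, group) the admission with the
  earliest admission date (ties broken on the smallest record id), i.e. the
  first admission treated as the incident event.

All three functions accept pandas DataFrames in the package's file schemas
and return a uniform case table with columns ``maternity_id, group, source,
event_date, source_record_id``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .codes import ClinicalGroup, CodeMap, CodeParseError, code_stem
from .windows import AttributionRule, WindowIndex

__all__ = [
    "AscertainedCase",
    "registry_cases",
    "hospital_all_cases",
    "hospital_index_cases",
    "assign_record_groups",
    "CASE_COLUMNS",
]

CASE_COLUMNS = ["maternity_id", "group", "source", "event_date", "source_record_id"]

SOURCE_REGISTRY = "registry"
SOURCE_HOSPITAL_ALL = "hospital_all"
SOURCE_HOSPITAL_INDEX = "hospital_index"


@dataclass(frozen=True)
class AscertainedCase:
    """A (maternity, group) cancer event attributed to one data source."""

    maternity_id: str
    group: ClinicalGroup
    source: str
    event_date: date
    source_record_id: str


def _empty_cases(source: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=CASE_COLUMNS)
    df["event_date"] = pd.to_datetime(df["event_date"])
    df["source"] = df["source"].astype(object)
    return df


def _record_id_sort_key(s: pd.Series) -> pd.Series:
    """Numeric where possible so record 3 sorts before record 7 and 10 after 7."""
    as_num = pd.to_numeric(s, errors="coerce")
    if as_num.notna().all():
        return as_num
    # mixed/string ids: lexicographic on the string form
    return s.astype(str)


def _resolve_attribution(df: pd.DataFrame, rule: AttributionRule) -> pd.DataFrame:
    """Drop unattributed rows; under the "all" rule explode list attributions."""
    if rule == "all":
        df = df.explode("maternity_id")
    return df[df["maternity_id"].notna()]


def registry_cases(
    registry: pd.DataFrame,
    windows: WindowIndex,
    rule: AttributionRule = "earliest",
) -> pd.DataFrame:
    """Incident registry cases per (maternity, group).

    Expects columns ``woman_id, registry_id, diagnosis_date, group,
    first_notification_date``.
    """
    if registry.empty:
        return _empty_cases(SOURCE_REGISTRY)
    reg = registry.copy()
    reg["diagnosis_date"] = pd.to_datetime(reg["diagnosis_date"])
    reg["first_notification_date"] = pd.to_datetime(reg["first_notification_date"])
    reg["group"] = reg["group"].map(lambda g: ClinicalGroup(g).value)
    incident = reg[reg["first_notification_date"] == reg["diagnosis_date"]].copy()
    if incident.empty:
        return _empty_cases(SOURCE_REGISTRY)
    incident["maternity_id"] = windows.attribute(
        incident.rename(columns={"diagnosis_date": "event_date"}), rule=rule
    )
    incident = _resolve_attribution(incident, rule)
    if incident.empty:
        return _empty_cases(SOURCE_REGISTRY)
    incident = incident.sort_values(
        ["maternity_id", "group", "diagnosis_date", "registry_id"]
    ).drop_duplicates(["maternity_id", "group"])
    out = pd.DataFrame(
        {
            "maternity_id": incident["maternity_id"].values,
            "group": incident["group"].values,
            "source": SOURCE_REGISTRY,
            "event_date": incident["diagnosis_date"].values,
            "source_record_id": incident["registry_id"].values,
        }
    )
    return out.sort_values(["maternity_id", "group"]).reset_index(drop=True)


def assign_record_groups(
    hospital: pd.DataFrame, codemap: CodeMap | None = None
) -> pd.Series:
    """Clinical group per hospital record from its diagnosis fields.

    Scans ``diag1..diagN`` in field order and returns the group of the first
    incident-candidate code (None if no code qualifies).  Malformed non-blank
    codes raise CodeParseError.
    """
    codemap = codemap or CodeMap.default()
    diag_cols = [c for c in hospital.columns if c.startswith("diag")]
    diag_cols.sort(key=lambda c: int(c[4:]))
    if not diag_cols:
        raise ValueError("hospital table has no diag1..diagN columns")

    # classify each distinct stem once; records are then a column-wise scan
    stem_to_group: dict[str, str | None] = {}

    def lookup(raw: object) -> str | None:
        if raw is None or (isinstance(raw, float) and pd.isna(raw)):
            return None
        text = str(raw).strip()
        if not text:
            return None
        stem = code_stem(text)
        if stem not in stem_to_group:
            c = codemap.classify(stem)
            stem_to_group[stem] = c.group.value if c.is_incident_candidate else None
        return stem_to_group[stem]

    result = pd.Series([None] * len(hospital), index=hospital.index, dtype=object)
    unresolved = pd.Series(True, index=hospital.index)
    for col in diag_cols:
        if not unresolved.any():
            break
        groups = hospital.loc[unresolved, col].map(lookup)
        found = groups.notna()
        result.loc[groups.index[found]] = groups[found]
        unresolved.loc[groups.index[found]] = False
    return result


def hospital_all_cases(
    hospital: pd.DataFrame,
    windows: WindowIndex,
    codemap: CodeMap | None = None,
    rule: AttributionRule = "earliest",
) -> pd.DataFrame:
    """All cancer hospitalisations: one case per qualifying admission record.

    Expects columns ``woman_id, record_id, admission_date, diag1..diagN``.
    """
    if hospital.empty:
        return _empty_cases(SOURCE_HOSPITAL_ALL)
    hosp = hospital.copy()
    hosp["admission_date"] = pd.to_datetime(hosp["admission_date"])
    hosp["group"] = assign_record_groups(hosp, codemap)
    eligible = hosp[hosp["group"].notna()].copy()
    if eligible.empty:
        return _empty_cases(SOURCE_HOSPITAL_ALL)
    eligible["maternity_id"] = windows.attribute(
        eligible.rename(columns={"admission_date": "event_date"}), rule=rule
    )
    eligible = _resolve_attribution(eligible, rule)
    if eligible.empty:
        return _empty_cases(SOURCE_HOSPITAL_ALL)
    out = pd.DataFrame(
        {
            "maternity_id": eligible["maternity_id"].values,
            "group": eligible["group"].values,
            "source": SOURCE_HOSPITAL_ALL,
            "event_date": eligible["admission_date"].values,
            "source_record_id": eligible["record_id"].values,
        }
    )
    return out.sort_values(
        ["maternity_id", "group", "event_date", "source_record_id"]
    ).reset_index(drop=True)


def hospital_index_cases(
    hospital: pd.DataFrame,
    windows: WindowIndex,
    codemap: CodeMap | None = None,
    all_cases: pd.DataFrame | None = None,
    rule: AttributionRule = "earliest",
) -> pd.DataFrame:
    """Index cancer hospitalisation: earliest admission per (maternity, group).

    Derived from :func:`hospital_all_cases` (which may be passed in to avoid
    recomputation); ties on admission date break on the smallest record id.
    """
    cases = (
        all_cases
        if all_cases is not None
        else hospital_all_cases(hospital, windows, codemap, rule=rule)
    )
    if cases.empty:
        return _empty_cases(SOURCE_HOSPITAL_INDEX)
    cases = cases.assign(_rid=_record_id_sort_key(cases["source_record_id"]))
    index = (
        cases.sort_values(["maternity_id", "group", "event_date", "_rid"])
        .drop_duplicates(["maternity_id", "group"])
        .drop(columns="_rid")
        .copy()
    )
    index["source"] = SOURCE_HOSPITAL_INDEX
    return index.reset_index(drop=True)
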