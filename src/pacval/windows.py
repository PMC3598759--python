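"""Pregnancy-associated exposure windows and event attribution.

A cancer is *pregnancy-associated* when diagnosed during pregnancy or within
12 months of delivery.  For a maternity with delivery date ``d`` and ``g``
completed weeks of gestation the exposure window is::

    [d - 7*g days,  d + 365 days]      (both endpoints inclusive)

Only births of at least 20 completed weeks of gestation enter the cohort;
the upper bound of 44 weeks guards against data errors.  "Within 12 months"
is fixed at 365 days rather than calendar-month arithmetic so window lengths
are reproducible across leap years.

A woman may contribute several maternities whose windows overlap (the
postpartum tail of one pregnancy can overlap the antenatal period of the
next).  ``attribute_event`` resolves the ambiguity: an event that falls in
more than one window is attributed to the maternity with the earliest
delivery date (rule ``"earliest"``), or to all containing maternities
(rule ``"all"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "MaternityRecord",
    "ExposureWindow",
    "WindowIndex",
    "make_window",
    "attribute_event",
    "GESTATION_MIN_WEEKS",
    "GESTATION_MAX_WEEKS",
    "POSTPARTUM_DAYS",
]

GESTATION_MIN_WEEKS = 20
GESTATION_MAX_WEEKS = 44
POSTPARTUM_DAYS = 365

AttributionRule = Literal["earliest", "all"]


@dataclass(frozen=True)
class MaternityRecord:
    """One delivery of one woman; the unit of analysis of the whole study."""

    maternity_id: str
    woman_id: str
    delivery_date: date
    gestation_weeks: int


@dataclass(frozen=True)
class ExposureWindow:
    """Inclusive date window in which a cancer counts as pregnancy-associated."""

    maternity_id: str
    delivery_date: date
    start_date: date
    end_date: date

    def contains(self, d: date) -> bool:
        return self.start_date <= d <= self.end_date

    @property
    def length_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


def make_window(m: MaternityRecord) -> ExposureWindow:
    """Build the exposure window for one maternity.

    Raises ValueError for gestation outside the 20–44 completed-week range.
    """
    if not (GESTATION_MIN_WEEKS <= m.gestation_weeks <= GESTATION_MAX_WEEKS):
        raise ValueError(
            f"maternity {m.maternity_id}: gestation {m.gestation_weeks} weeks "
            f"outside [{GESTATION_MIN_WEEKS}, {GESTATION_MAX_WEEKS}]"
        )
    start = m.delivery_date - timedelta(days=7 * m.gestation_weeks)
    end = m.delivery_date + timedelta(days=POSTPARTUM_DAYS)
    return ExposureWindow(m.maternity_id, m.delivery_date, start, end)


def attribute_event(
    event_date: date,
    windows: Iterable[ExposureWindow],
    rule: AttributionRule = "earliest",
) -> str | list[str] | None:
    """Attribute a dated event to a maternity among one woman's windows.

    Under the default ``"earliest"`` rule, returns the maternity_id of the
    containing window with the earliest delivery date (ties broken on
    maternity_id), or None if no window contains the event.  Under ``"all"``
    returns the list of all containing maternity_ids, possibly empty.
    """
    containing = sorted(
        (w for w in windows if w.contains(event_date)),
        key=lambda w: (w.delivery_date, w.maternity_id),
    )
    if rule == "all":
        return [w.maternity_id for w in containing]
    if rule != "earliest":
        raise ValueError(f"unknown attribution rule: {rule!r}")
    return containing[0].maternity_id if containing else None


class WindowIndex:
    """Vectorised exposure-window table over a maternity cohort.

    Built from a maternity table with columns ``woman_id, maternity_id,
    delivery_date, gestation_weeks``; validates gestation bounds and
    maternity-id uniqueness, and attributes batches of dated events.
    """

    def __init__(self, maternities: pd.DataFrame):
        required = {"woman_id", "maternity_id", "delivery_date", "gestation_weeks"}
        missing = required - set(maternities.columns)
        if missing:
            raise ValueError(f"maternity table missing columns: {sorted(missing)}")
        f = maternities.loc[:, list(required)].copy()
        f["delivery_date"] = pd.to_datetime(f["delivery_date"])
        gw = f["gestation_weeks"].astype(int)
        bad = ~gw.between(GESTATION_MIN_WEEKS, GESTATION_MAX_WEEKS)
        if bad.any():
            offender = f.loc[bad].iloc[0]
            raise ValueError(
                f"maternity {offender['maternity_id']}: gestation "
                f"{offender['gestation_weeks']} weeks outside "
                f"[{GESTATION_MIN_WEEKS}, {GESTATION_MAX_WEEKS}]"
            )
        if f["maternity_id"].duplicated().any():
            dup = f.loc[f["maternity_id"].duplicated(), "maternity_id"].iloc[0]
            raise ValueError(f"duplicate maternity_id: {dup}")
        f["gestation_weeks"] = gw
        f["start_date"] = f["delivery_date"] - pd.to_timedelta(7 * gw, unit="D")
        f["end_date"] = f["delivery_date"] + pd.Timedelta(days=POSTPARTUM_DAYS)
        self.frame = f[
            ["maternity_id", "woman_id", "delivery_date", "gestation_weeks",
             "start_date", "end_date"]
        ].reset_index(drop=True)

    @property
    def n_maternities(self) -> int:
        return len(self.frame)

    def windows_for(self, woman_id: str) -> list[ExposureWindow]:
        rows = self.frame[self.frame["woman_id"] == woman_id]
        return [
            ExposureWindow(
                r.maternity_id,
                r.delivery_date.date(),
                r.start_date.date(),
                r.end_date.date(),
            )
            for r in rows.itertuples()
        ]

    def attribute(
        self,
        events: pd.DataFrame,
        rule: AttributionRule = "earliest",
    ) -> pd.Series:
        """Attribute events (columns woman_id, event_date) to maternities.

        Returns a Series of maternity_id (None where unattributed) aligned to
        the index of ``events`` under the "earliest" rule; under "all", a
        Series of lists.
        """
        if rule not in ("earliest", "all"):
            raise ValueError(f"unknown attribution rule: {rule!r}")
        ev = events.loc[:, ["woman_id", "event_date"]].copy()
        ev["event_date"] = pd.to_datetime(ev["event_date"])
        ev = ev.reset_index(names="_event_index")
        merged = ev.merge(self.frame, on="woman_id", how="inner")
        hit = merged[
            (merged["event_date"] >= merged["start_date"])
            & (merged["event_date"] <= merged["end_date"])
        ]
        hit = hit.sort_values(["_event_index", "delivery_date", "maternity_id"])
        if rule == "all":
            lists = hit.groupby("_event_index")["maternity_id"].agg(list)
            out = pd.Series([[] for _ in range(len(events))], index=events.index,
                            dtype=object)
            out.loc[lists.index] = lists.values
            return out
        first = hit.drop_duplicates("_event_index").set_index("_event_index")
        out = pd.Series([None] * len(events), index=events.index, dtype=object)
        out.loc[first.index] = first["maternity_id"].values
        return out


def window_frame(maternities: pd.DataFrame) -> pd.DataFrame:
    """Convenience: the window table (one row per maternity) as a DataFrame."""
    return WindowIndex(maternities).frame
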