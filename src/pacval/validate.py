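"""Diagnostic-accuracy validation of hospital against registry ascertainment.

The hospital "index cancer hospitalisation" set is cross-classified against
the registry gold standard on (maternity, clinical group) units, giving a
2x2 table per group:

    tp = |index ∩ registry|       fp = |index \\ registry|
    fn = |registry \\ index|      tn = n_maternities - tp - fp - fn

From each table the four reporting characteristics are computed, each with
an exact (Clopper–Pearson) binomial confidence interval on its own
numerator/denominator:

    sensitivity = tp / (tp + fn)      completeness of hospital ascertainment
    ppv         = tp / (tp + fp)      confirmation rate of hospital cases
    specificity = tn / (tn + fp)
    npv         = tn / (tn + fn)

Negatives are maternities, so for a rare outcome specificity and NPV sit at
or above 99.9% by construction.  The "any" row is the element-wise sum over
the 13 group rows, i.e. it counts (maternity x group) units, so a maternity
with two primaries contributes twice.

Incidence is reported per 100,000 maternities; the incidence rate ratio
(IRR) divides a hospital-derived rate by the registry rate for the same
group, computed on unrounded rates.

False positives are adjudicated sequentially against the registry
notification history: *prevalent* when the woman has a notification of the
same group dated before the exposure-window start (lookback to the registry
horizon), else *misclassified_type* when the same maternity has an incident
registry cancer of a different group, else *unexplained*.

Timing discrepancies among true positives are binned by calendar-month
difference (registry month minus admission month): 0, 1–2, 3–5, >= 6 months
admission before registration, or admission after registration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

from .codes import GROUP_ORDER, ClinicalGroup
from .windows import WindowIndex

__all__ = [
    "TwoByTwo",
    "MetricEstimate",
    "ValidationRow",
    "FpAdjudication",
    "TimingDistribution",
    "cross_classify",
    "proportion_ci",
    "reporting_characteristics",
    "rates_and_irr",
    "adjudicate_fp",
    "timing_distribution",
    "round_half_up",
    "ANY_GROUP",
    "TIMING_BINS",
    "FP_CATEGORIES",
]

ANY_GROUP = "any"
TIMING_BINS = ("same_month", "prior_1_2", "prior_3_5", "prior_6_plus",
               "after_registration")
FP_CATEGORIES = ("prevalent", "misclassified_type", "unexplained")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at the presentation layer (1 decimal in tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoByTwo:
    """Per-group 2x2 counts on (maternity x group) units."""

    group: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative in group {self.group}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def registry_count(self) -> int:
        return self.tp + self.fn

    @property
    def index_count(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact CI; ``defined`` is False on a 0 denominator."""

    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    defined: bool = True

    @classmethod
    def undefined(cls) -> "MetricEstimate":
        return cls(None, None, None, defined=False)


@dataclass(frozen=True)
class ValidationRow:
    """One row of the validation table: 2x2 counts plus the four metrics."""

    group: str
    counts: TwoByTwo
    sensitivity: MetricEstimate
    ppv: MetricEstimate
    specificity: MetricEstimate
    npv: MetricEstimate
    level: float = 0.95


def _case_keys(cases: pd.DataFrame) -> set[tuple[str, str]]:
    if cases.empty:
        return set()
    return set(zip(cases["maternity_id"], cases["group"]))


def cross_classify(
    index_cases: pd.DataFrame,
    registry_cases: pd.DataFrame,
    n_maternities: int,
) -> dict[str, TwoByTwo]:
    """Cross-classify hospital-index vs registry cases per group plus "any".

    Both case tables are keyed on (maternity_id, group); the "any" row is
    the element-wise sum of the 13 group rows.
    """
    index_keys = _case_keys(index_cases)
    registry_keys = _case_keys(registry_cases)
    valid = {g.value for g in GROUP_ORDER}
    unknown = {g for _, g in index_keys | registry_keys} - valid
    if unknown:
        raise ValueError(f"unknown clinical groups in case tables: {sorted(unknown)}")
    out: dict[str, TwoByTwo] = {}
    tot_tp = tot_fp = tot_fn = 0
    for group in GROUP_ORDER:
        g = group.value
        idx = {k for k in index_keys if k[1] == g}
        reg = {k for k in registry_keys if k[1] == g}
        tp = len(idx & reg)
        fp = len(idx - reg)
        fn = len(reg - idx)
        if tp + fp + fn > n_maternities:
            raise ValueError(
                f"group {g}: tp+fp+fn = {tp + fp + fn} exceeds "
                f"n_maternities = {n_maternities}"
            )
        out[g] = TwoByTwo(g, tp, fp, fn, n_maternities - tp - fp - fn)
        tot_tp += tp
        tot_fp += fp
        tot_fn += fn
    out[ANY_GROUP] = TwoByTwo(
        ANY_GROUP, tot_tp, tot_fp, tot_fn,
        13 * n_maternities - tot_tp - tot_fp - tot_fn,
    )
    return out


def proportion_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact binomial confidence interval for x successes in n.

    low  = BetaInv(alpha/2;   x,   n-x+1)   (0 when x = 0)
    high = BetaInv(1-alpha/2; x+1, n-x)     (1 when x = n)
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"invalid binomial counts: x={x}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _metric(x: int, n: int, level: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate.undefined()
    low, high = proportion_ci(x, n, level)
    return MetricEstimate(x / n, low, high)


def reporting_characteristics(t: TwoByTwo, level: float = 0.95) -> ValidationRow:
    """Sensitivity, PPV, specificity and NPV with exact CIs for one 2x2 table."""
    return ValidationRow(
        group=t.group,
        counts=t,
        sensitivity=_metric(t.tp, t.tp + t.fn, level),
        ppv=_metric(t.tp, t.tp + t.fp, level),
        specificity=_metric(t.tn, t.tn + t.fp, level),
        npv=_metric(t.tn, t.tn + t.fn, level),
        level=level,
    )


def rates_and_irr(
    case_counts: dict[str, dict[str, int]],
    n_maternities: int,
    reference_source: str = "registry",
) -> pd.DataFrame:
    """Incidence per 100,000 maternities and IRR versus the registry.

    ``case_counts`` maps source -> {group -> count}; an "any" entry is
    derived as the sum over groups when absent.  IRRs divide unrounded
    rates; they are undefined (NaN) where the registry count is zero.
    """
    if n_maternities <= 0:
        raise ValueError("n_maternities must be positive")
    rows = []
    groups = [g.value for g in GROUP_ORDER]
    totals = {
        src: sum(counts.get(g, 0) for g in groups)
        for src, counts in case_counts.items()
    }
    ref = case_counts.get(reference_source, {})
    for src, counts in case_counts.items():
        for g in groups + [ANY_GROUP]:
            n = (
                totals[src]
                if g == ANY_GROUP
                else int(counts.get(g, 0))
            )
            rate = 1e5 * n / n_maternities
            ref_n = totals.get(reference_source, 0) if g == ANY_GROUP else ref.get(g, 0)
            ref_rate = 1e5 * ref_n / n_maternities
            irr = rate / ref_rate if ref_rate > 0 else math.nan
            share = 100.0 * n / totals[src] if totals[src] > 0 else math.nan
            rows.append(
                {
                    "source": src,
                    "group": g,
                    "n_cases": n,
                    "share_pct": share,
                    "rate_per_100k": rate,
                    "irr": irr,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FpAdjudication:
    """False positives labelled prevalent / misclassified_type / unexplained."""

    labels: pd.DataFrame  # maternity_id, group, category
    by_category: dict[str, int] = field(default_factory=dict)
    by_group: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.labels)

    def proportions(self) -> dict[str, float]:
        if self.total == 0:
            return {c: math.nan for c in FP_CATEGORIES}
        return {c: self.by_category.get(c, 0) / self.total for c in FP_CATEGORIES}


def adjudicate_fp(
    fp_cases: pd.DataFrame,
    registry: pd.DataFrame,
    registry_case_table: pd.DataFrame,
    windows: WindowIndex,
) -> FpAdjudication:
    """Adjudicate false-positive hospital cases against the registry history.

    ``fp_cases`` are index cases absent from the registry case set (columns
    maternity_id, group); ``registry`` is the raw registry table whose
    ``first_notification_date`` reaches back to the lookback horizon;
    ``registry_case_table`` is the output of
    :func:`pacval.ascertain.registry_cases`.  Precedence: prevalent, then
    misclassified_type, then unexplained.
    """
    frame = windows.frame.set_index("maternity_id")
    reg = registry.copy()
    if not reg.empty:
        reg["first_notification_date"] = pd.to_datetime(
            reg["first_notification_date"]
        )
        reg["group"] = reg["group"].map(lambda g: ClinicalGroup(g).value)
    # earliest notification per (woman, group), from the full lookback history
    first_notif: dict[tuple[str, str], pd.Timestamp] = {}
    if not reg.empty:
        grp = reg.groupby(["woman_id", "group"])["first_notification_date"].min()
        first_notif = grp.to_dict()
    registry_keys = _case_keys(registry_case_table)
    registry_maternity_groups: dict[str, set[str]] = {}
    for mid, g in registry_keys:
        registry_maternity_groups.setdefault(mid, set()).add(g)

    labels = []
    for row in fp_cases.itertuples():
        mid, g = row.maternity_id, row.group
        woman = frame.loc[mid, "woman_id"]
        window_start = frame.loc[mid, "start_date"]
        notified = first_notif.get((woman, g))
        if notified is not None and notified < window_start:
            category = "prevalent"
        elif registry_maternity_groups.get(mid, set()) - {g}:
            category = "misclassified_type"
        else:
            category = "unexplained"
        labels.append({"maternity_id": mid, "group": g, "category": category})
    labels_df = pd.DataFrame(labels, columns=["maternity_id", "group", "category"])
    by_category = {c: 0 for c in FP_CATEGORIES}
    by_group: dict[str, dict[str, int]] = {}
    for rec in labels:
        by_category[rec["category"]] += 1
        by_group.setdefault(rec["group"], {c: 0 for c in FP_CATEGORIES})
        by_group[rec["group"]][rec["category"]] += 1
    return FpAdjudication(labels=labels_df, by_category=by_category, by_group=by_group)


@dataclass
class TimingDistribution:
    """Calendar-month offsets between index admission and registry date of TPs."""

    counts: dict[str, int]
    n: int

    def proportions(self) -> dict[str, float]:
        if self.n == 0:
            return {b: math.nan for b in TIMING_BINS}
        return {b: self.counts.get(b, 0) / self.n for b in TIMING_BINS}


def month_difference(registry_date: pd.Timestamp, admission_date: pd.Timestamp) -> int:
    """Calendar months from the admission month to the registry month."""
    r = pd.Timestamp(registry_date)
    a = pd.Timestamp(admission_date)
    return (r.year - a.year) * 12 + (r.month - a.month)


def timing_bin(months: int) -> str:
    if months < 0:
        return "after_registration"
    if months == 0:
        return "same_month"
    if months <= 2:
        return "prior_1_2"
    if months <= 5:
        return "prior_3_5"
    return "prior_6_plus"


def timing_distribution(tp_pairs: pd.DataFrame) -> TimingDistribution:
    """Bin true positives by admission-versus-registration month offset.

    ``tp_pairs`` carries one row per TP with columns ``admission_date`` and
    ``registry_date``.
    """
    counts = {b: 0 for b in TIMING_BINS}
    for row in tp_pairs.itertuples():
        m = month_difference(row.registry_date, row.admission_date)
        counts[timing_bin(m)] += 1
    return TimingDistribution(counts=counts, n=len(tp_pairs))
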