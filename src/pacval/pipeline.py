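"""End-to-end analysis pipeline and table rendering.

``analyze`` runs the whole deterministic analytic sequence on in-memory
tables: exposure-window construction, registry / hospital-all /
hospital-index ascertainment, cross-classification with reporting
characteristics and exact CIs, incidence rates with IRRs, false-positive
adjudication and admission-versus-registration timing.  ``run_pipeline``
wraps it with file I/O, a machine-readable JSON summary, rendered text
tables and a run manifest recording config, input digests and package
version.  Hospital or registry rows whose woman_id has no maternity in the
cohort are counted and ignored (they simply attribute to no window).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .ascertain import (
    hospital_all_cases,
    hospital_index_cases,
    registry_cases,
)
from .codes import GROUP_ORDER, ClinicalGroup, CodeMap
from .io import read_hospital, read_maternities, read_registry
from .validate import (
    ANY_GROUP,
    FP_CATEGORIES,
    TIMING_BINS,
    FpAdjudication,
    MetricEstimate,
    TimingDistribution,
    TwoByTwo,
    ValidationRow,
    adjudicate_fp,
    cross_classify,
    rates_and_irr,
    reporting_characteristics,
    round_half_up,
    timing_distribution,
)
from .windows import WindowIndex

__all__ = ["analyze", "run_pipeline", "render_tables", "AnalysisResult"]

SOURCES = ("registry", "hospital_all", "hospital_index")


@dataclass
class AnalysisResult:
    """All analytic outputs of one pipeline run."""

    n_maternities: int
    n_women: int
    ci_level: float
    two_by_two: dict[str, TwoByTwo]
    validation: dict[str, ValidationRow]
    rates: pd.DataFrame
    fp_adjudication: FpAdjudication
    timing: TimingDistribution
    case_tables: dict[str, pd.DataFrame]

    def to_summary(self) -> dict:
        """JSON-serialisable summary of every count, estimate and CI."""

        def metric(m: MetricEstimate) -> dict:
            if not m.defined:
                return {"defined": False}
            return {
                "defined": True,
                "estimate": m.estimate,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
            }

        groups = [g.value for g in GROUP_ORDER] + [ANY_GROUP]
        validation = {}
        for g in groups + ["any_excluding_melanoma"]:
            row = self.validation[g]
            validation[g] = {
                "tp": row.counts.tp,
                "fp": row.counts.fp,
                "fn": row.counts.fn,
                "tn": row.counts.tn,
                "sensitivity": metric(row.sensitivity),
                "ppv": metric(row.ppv),
                "specificity": metric(row.specificity),
                "npv": metric(row.npv),
            }
        rates: dict[str, dict] = {src: {} for src in SOURCES}
        for rec in self.rates.to_dict("records"):
            rates[rec["source"]][rec["group"]] = {
                "n_cases": rec["n_cases"],
                "share_pct": rec["share_pct"],
                "rate_per_100k": rec["rate_per_100k"],
                "irr": None if pd.isna(rec["irr"]) else rec["irr"],
            }
        return {
            "package_version": __version__,
            "n_maternities": self.n_maternities,
            "n_women": self.n_women,
            "ci_level": self.ci_level,
            "validation": validation,
            "rates": rates,
            "fp_adjudication": {
                "total": self.fp_adjudication.total,
                "by_category": self.fp_adjudication.by_category,
                "by_group": self.fp_adjudication.by_group,
            },
            "timing": {
                "n_true_positives": self.timing.n,
                "counts": self.timing.counts,
                "proportions": {
                    b: (None if self.timing.n == 0 else p)
                    for b, p in self.timing.proportions().items()
                },
            },
        }


def _excluding_melanoma_row(
    two_by_two: dict[str, TwoByTwo], ci_level: float
) -> ValidationRow:
    mel = ClinicalGroup.MELANOMA.value
    tp = sum(t.tp for g, t in two_by_two.items() if g not in (mel, ANY_GROUP))
    fp = sum(t.fp for g, t in two_by_two.items() if g not in (mel, ANY_GROUP))
    fn = sum(t.fn for g, t in two_by_two.items() if g not in (mel, ANY_GROUP))
    tn = sum(t.tn for g, t in two_by_two.items() if g not in (mel, ANY_GROUP))
    return reporting_characteristics(
        TwoByTwo("any_excluding_melanoma", tp, fp, fn, tn), ci_level
    )


def analyze(
    maternities: pd.DataFrame,
    hospital: pd.DataFrame,
    registry: pd.DataFrame,
    codemap: CodeMap | None = None,
    ci_level: float = 0.95,
    attribution_rule: str = "earliest",
) -> AnalysisResult:
    """Run the full validation analysis on in-memory tables."""
    codemap = codemap or CodeMap.default()
    windows = WindowIndex(maternities)
    n_maternities = windows.n_maternities
    n_women = maternities["woman_id"].nunique()

    reg_cases = registry_cases(registry, windows, rule=attribution_rule)
    all_cases = hospital_all_cases(hospital, windows, codemap,
                                   rule=attribution_rule)
    index_cases = hospital_index_cases(
        hospital, windows, codemap, all_cases=all_cases
    )

    two_by_two = cross_classify(index_cases, reg_cases, n_maternities)
    validation = {
        g: reporting_characteristics(t, ci_level) for g, t in two_by_two.items()
    }
    validation["any_excluding_melanoma"] = _excluding_melanoma_row(
        two_by_two, ci_level
    )

    counts = {
        "registry": reg_cases.groupby("group").size().to_dict(),
        "hospital_all": all_cases.groupby("group").size().to_dict(),
        "hospital_index": index_cases.groupby("group").size().to_dict(),
    }
    rates = rates_and_irr(counts, n_maternities)

    reg_keys = set(zip(reg_cases["maternity_id"], reg_cases["group"]))
    idx_keyed = index_cases.set_index(["maternity_id", "group"])
    fp_mask = [
        (mid, g) not in reg_keys
        for mid, g in zip(index_cases["maternity_id"], index_cases["group"])
    ]
    fp_cases = index_cases[fp_mask]
    adjudication = adjudicate_fp(fp_cases, registry, reg_cases, windows)

    tp_rows = []
    for row in reg_cases.itertuples():
        key = (row.maternity_id, row.group)
        if key in idx_keyed.index:
            tp_rows.append(
                {
                    "admission_date": idx_keyed.loc[key, "event_date"],
                    "registry_date": row.event_date,
                }
            )
    timing = timing_distribution(
        pd.DataFrame(tp_rows, columns=["admission_date", "registry_date"])
    )

    return AnalysisResult(
        n_maternities=n_maternities,
        n_women=n_women,
        ci_level=ci_level,
        two_by_two=two_by_two,
        validation=validation,
        rates=rates,
        fp_adjudication=adjudication,
        timing=timing,
        case_tables={
            "registry": reg_cases,
            "hospital_all": all_cases,
            "hospital_index": index_cases,
        },
    )


# ---------------------------------------------------------------------------
# presentation


_GROUP_LABELS = {
    "melanoma": "Melanoma",
    "breast": "Breast",
    "thyroid_endocrine": "Thyroid and other endocrine",
    "gynaecological": "Gynaecological",
    "lymphohaematopoeitic": "Lymphohaematopoeitic",
    "colorectal": "Colorectal",
    "neurological": "Neurological",
    "bone_connective": "Bone and other connective tissue",
    "head_neck": "Head and neck",
    "upper_gi": "Upper gastrointestinal",
    "respiratory": "Respiratory",
    "ill_defined_unknown": "Ill-defined and unknown primary",
    "urogenital": "Urogenital",
    ANY_GROUP: "Any",
    "any_excluding_melanoma": "Any excluding melanoma",
}


def _fmt(x, nd: int = 1) -> str:
    if x is None or (isinstance(x, float) and pd.isna(x)):
        return "NA"
    return f"{round_half_up(float(x), nd):.{nd}f}"


def _fmt_metric(m: dict) -> tuple[str, str]:
    if not m.get("defined"):
        return "NA", "NA"
    pct = _fmt(100 * m["estimate"])
    ci = f"[{_fmt(100 * m['ci_low'])},{_fmt(100 * m['ci_high'])}]"
    return pct, ci


def render_tables(summary: dict) -> str:
    """Human-readable incidence-rate and validation tables from a summary."""
    groups = [g.value for g in GROUP_ORDER]
    lines = ["Pregnancy-associated cancer rates by data source", ""]
    header = (
        f"{'Clinical group':34} {'Reg N':>6} {'Reg rate':>9} "
        f"{'All N':>6} {'All rate':>9} {'All IRR':>8} "
        f"{'Idx N':>6} {'Idx rate':>9} {'Idx IRR':>8}"
    )
    lines.append(header)
    lines.append("-" * len(header))
    rates = summary["rates"]
    for g in groups + [ANY_GROUP]:
        reg = rates["registry"].get(g, {})
        al = rates["hospital_all"].get(g, {})
        ix = rates["hospital_index"].get(g, {})
        lines.append(
            f"{_GROUP_LABELS[g]:34} "
            f"{reg.get('n_cases', 0):>6} {_fmt(reg.get('rate_per_100k')):>9} "
            f"{al.get('n_cases', 0):>6} {_fmt(al.get('rate_per_100k')):>9} "
            f"{_fmt(al.get('irr')):>8} "
            f"{ix.get('n_cases', 0):>6} {_fmt(ix.get('rate_per_100k')):>9} "
            f"{_fmt(ix.get('irr')):>8}"
        )
    lines += ["", "Reporting characteristics of hospital index cases", ""]
    header2 = (
        f"{'Clinical group':34} {'TP':>5} {'FP':>5} {'FN':>5} "
        f"{'Sn %':>6} {'95% CI':>14} {'PPV %':>6} {'95% CI':>14}"
    )
    lines.append(header2)
    lines.append("-" * len(header2))
    for g in groups + [ANY_GROUP, "any_excluding_melanoma"]:
        row = summary["validation"][g]
        sn, sn_ci = _fmt_metric(row["sensitivity"])
        ppv, ppv_ci = _fmt_metric(row["ppv"])
        lines.append(
            f"{_GROUP_LABELS[g]:34} {row['tp']:>5} {row['fp']:>5} {row['fn']:>5} "
            f"{sn:>6} {sn_ci:>14} {ppv:>6} {ppv_ci:>14}"
        )
    timing = summary["timing"]
    lines += [
        "",
        f"Timing of index admission relative to registration "
        f"(n={timing['n_true_positives']} true positives)",
        "",
    ]
    labels = {
        "same_month": "same month",
        "prior_1_2": "1-2 months prior",
        "prior_3_5": "3-5 months prior",
        "prior_6_plus": ">=6 months prior",
        "after_registration": "after registration",
    }
    for b in TIMING_BINS:
        p = timing["proportions"][b]
        pct = "NA" if p is None else _fmt(100 * p)
        lines.append(f"  {labels[b]:20} {timing['counts'][b]:>5}  {pct:>6}%")
    adj = summary["fp_adjudication"]
    lines += ["", f"False-positive adjudication (n={adj['total']})", ""]
    for c in FP_CATEGORIES:
        n = adj["by_category"].get(c, 0)
        pct = "NA" if adj["total"] == 0 else _fmt(100 * n / adj["total"])
        lines.append(f"  {c:20} {n:>5}  {pct:>6}%")
    return "\n".join(lines) + "\n"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    maternity_path: str | Path,
    hospital_path: str | Path,
    registry_path: str | Path,
    out_dir: str | Path,
    codemap_path: str | Path | None = None,
    ci_level: float = 0.95,
    attribution_rule: str = "earliest",
    seed: int | None = None,
) -> AnalysisResult:
    """File-to-file pipeline run; writes summary, tables and a manifest.

    The analysis is fully deterministic — ``seed`` is only echoed into the
    manifest so synthetic-data provenance travels with the results.
    """
    maternity_path = Path(maternity_path)
    hospital_path = Path(hospital_path)
    registry_path = Path(registry_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    maternities = read_maternities(maternity_path)
    hospital = read_hospital(hospital_path)
    registry = read_registry(registry_path)
    codemap = CodeMap.from_yaml(codemap_path) if codemap_path else CodeMap.default()

    result = analyze(
        maternities,
        hospital,
        registry,
        codemap=codemap,
        ci_level=ci_level,
        attribution_rule=attribution_rule,
    )
    summary = result.to_summary()
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    (out_dir / "tables.txt").write_text(render_tables(summary))
    result.rates.to_csv(out_dir / "rates.tsv", sep="\t", index=False)
    _validation_tsv(summary).to_csv(out_dir / "validation.tsv", sep="\t",
                                    index=False)
    manifest = {
        "package_version": __version__,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "ci_level": ci_level,
        "attribution_rule": attribution_rule,
        "codemap": str(codemap_path) if codemap_path else "default",
        "inputs": {
            "maternities": {"path": str(maternity_path),
                            "sha256": _digest(maternity_path)},
            "hospital": {"path": str(hospital_path),
                         "sha256": _digest(hospital_path)},
            "registry": {"path": str(registry_path),
                         "sha256": _digest(registry_path)},
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _validation_tsv(summary: dict) -> pd.DataFrame:
    rows = []
    for g, row in summary["validation"].items():
        rec = {"group": g, "tp": row["tp"], "fp": row["fp"], "fn": row["fn"],
               "tn": row["tn"]}
        for metric in ("sensitivity", "ppv", "specificity", "npv"):
            m = row[metric]
            rec[metric] = m.get("estimate") if m.get("defined") else None
            rec[f"{metric}_ci_low"] = m.get("ci_low")
            rec[f"{metric}_ci_high"] = m.get("ci_high")
        rows.append(rec)
    return pd.DataFrame(rows)
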