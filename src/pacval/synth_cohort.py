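"""Seeded synthetic linked maternity / hospital / registry cohort generator.

No individual-level obstetric-cancer linkage data can be shipped, so this
module generates a synthetic stand-in with the statistical structure the
analysis assumes: a cohort of women with one or more maternities over an
eight-year study period; incident registry cancers planted per (maternity,
clinical group) at configured per-100,000 rates with diagnosis dates inside
the exposure window; hospital capture of each true cancer with a per-group
probability, an index admission preceding registration by a calendar-month
offset drawn from a configured mixture, and Poisson-distributed repeat
admissions; three false-positive mechanisms (prevalent cancers notified
before the window, miscoded cancer type, and noise admissions with no
registry counterpart); and optional linkage-error noise on the registry
side.  Every planted event is recorded in a truth ledger together with its
expected classification (TP/FP/FN) absent linkage noise, which serves as
the oracle for end-to-end tests.

The generator is deterministic under a fixed seed: the same configuration
and seed reproduce byte-identical output files.

What it does *not* emulate: demographic covariates, survival processes,
seasonality, gestation-dependent admission patterns, or within-registry
coding revisions.  See docs/methods.md for the fidelity discussion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .codes import GROUP_ORDER
from .validate import FP_CATEGORIES, TIMING_BINS, month_difference, timing_bin

__all__ = ["GeneratorConfig", "SyntheticCohort", "generate", "truth_summary"]

GROUPS: tuple[str, ...] = tuple(g.value for g in GROUP_ORDER)

#: Representative ICD-10 codes per clinical group, used to code planted
#: hospital admissions.  Every stem maps back to its group under the
#: default CodeMap.
GROUP_CODES: dict[str, tuple[str, ...]] = {
    "melanoma": ("C43.9", "C43.5", "C43.7"),
    "breast": ("C50.9", "C50.4", "C50.1"),
    "thyroid_endocrine": ("C73", "C74.9", "C75.0"),
    "gynaecological": ("C53.9", "C56", "C54.1"),
    "lymphohaematopoeitic": ("C81.9", "C91.0", "C85.9", "C92.0"),
    "colorectal": ("C18.9", "C20", "C19"),
    "neurological": ("C71.9", "C70.0", "C69.9"),
    "bone_connective": ("C40.2", "C49.9", "C41.9"),
    "head_neck": ("C02.9", "C11.9", "C32.9"),
    "upper_gi": ("C16.9", "C22.0", "C25.9"),
    "respiratory": ("C34.9", "C34.1"),
    "ill_defined_unknown": ("C80", "C76.0"),
    "urogenital": ("C64", "C67.9"),
}

#: Obstetric / administrative codes used to pad diagnosis fields ahead of a
#: cancer code and for plain delivery admissions.
NONCANCER_CODES: tuple[str, ...] = ("O26.8", "O99.8", "O47.0", "Z39.0")
DELIVERY_CODES: tuple[str, ...] = ("O80", "Z37.0")
SECONDARY_CODE = "C78.0"

N_DIAG_FIELDS = 22
_DAY = np.timedelta64(1, "D")


def _normalised(dist: dict, what: str) -> dict:
    total = float(sum(dist.values()))
    if total <= 0:
        raise ValueError(f"{what}: weights must sum to a positive value")
    if any(v < 0 for v in dist.values()):
        raise ValueError(f"{what}: negative weight")
    return {k: float(v) / total for k, v in dist.items()}


def _group_array(mapping: dict[str, float], what: str) -> np.ndarray:
    missing = set(GROUPS) - set(mapping)
    if missing:
        raise ValueError(f"{what}: missing groups {sorted(missing)}")
    return np.array([float(mapping[g]) for g in GROUPS])


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort; defaults ship in a versioned YAML.

    Rates are per-100,000-maternity incidences, capture probabilities are
    the per-group hospital sensitivities, ``extra_admissions_mean`` the mean
    repeat admissions per captured cancer, the timing mixture the
    calendar-month admission-before-registration offsets, and the three
    ``fp_*_rate`` values per-maternity planting probabilities of the
    false-positive mechanisms.  Linkage error rates detach or re-assign
    registry records to emulate imperfect probabilistic linkage.
    """

    n_women: int
    study_start: date
    study_end: date
    maternities_per_woman: dict[int, float]
    min_interdelivery_days: int
    gestation_weeks: dict[int, float]
    group_incidence_per_100k: dict[str, float]
    capture_prob: dict[str, float]
    extra_admissions_mean: dict[str, float]
    timing_mixture: dict[str, float]
    fp_prevalent_rate: float
    fp_prevalent_counts: dict[str, float]
    fp_miscode_rate: float
    miscode_sources: dict[str, dict]
    fp_noise_rate: float
    fp_noise_counts: dict[str, float]
    linkage_missed_rate: float
    linkage_false_rate: float
    lookback_start: date
    include_delivery_admissions: bool = True
    seed: int = 0
    version: int = 1

    def __post_init__(self) -> None:
        if self.n_women <= 0:
            raise ValueError("n_women must be positive")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.lookback_start >= self.study_start:
            raise ValueError("lookback_start must precede study_start")
        self.maternities_per_woman = _normalised(
            {int(k): v for k, v in self.maternities_per_woman.items()},
            "maternities_per_woman",
        )
        self.gestation_weeks = _normalised(
            {int(k): v for k, v in self.gestation_weeks.items()}, "gestation_weeks"
        )
        bad_weeks = [w for w in self.gestation_weeks if not 20 <= w <= 44]
        if bad_weeks:
            raise ValueError(f"gestation weeks outside [20, 44]: {bad_weeks}")
        self.timing_mixture = _normalised(
            {k: self.timing_mixture.get(k, 0.0) for k in TIMING_BINS},
            "timing_mixture",
        )
        for name in (
            "fp_prevalent_rate",
            "fp_miscode_rate",
            "fp_noise_rate",
            "linkage_missed_rate",
            "linkage_false_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for g, p in self.capture_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"capture_prob[{g}] must be a probability")
        _group_array(self.group_incidence_per_100k, "group_incidence_per_100k")
        _group_array(self.capture_prob, "capture_prob")
        _group_array(self.extra_admissions_mean, "extra_admissions_mean")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict, **overrides) -> "GeneratorConfig":
        data = dict(raw)
        data.update(overrides)
        for key in ("study_start", "study_end", "lookback_start"):
            if isinstance(data[key], str):
                data[key] = date.fromisoformat(data[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def default(cls, **overrides) -> "GeneratorConfig":
        raw = yaml.safe_load(
            resources.files("pacval").joinpath("data", "synth_defaults.yaml").read_text()
        )
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = yaml.safe_load(
            resources.files("pacval").joinpath("data", "synth_defaults.yaml").read_text()
        )
        base.update(raw or {})
        return cls.from_dict(base, **overrides)

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("study_start", "study_end", "lookback_start"):
            d[key] = d[key].isoformat()
        return d

    # -- derived weight vectors -------------------------------------------

    def prevalent_weights(self) -> np.ndarray:
        return self._split_other(self.fp_prevalent_counts, "fp_prevalent_counts")

    def noise_weights(self) -> np.ndarray:
        return self._split_other(self.fp_noise_counts, "fp_noise_counts")

    def _split_other(self, counts: dict[str, float], what: str) -> np.ndarray:
        named = {g: v for g, v in counts.items() if g != "other"}
        unknown = set(named) - set(GROUPS)
        if unknown:
            raise ValueError(f"{what}: unknown groups {sorted(unknown)}")
        w = np.array([float(named.get(g, 0.0)) for g in GROUPS])
        other = float(counts.get("other", 0.0))
        if other > 0:
            rest = np.array(
                [
                    self.group_incidence_per_100k[g] if g not in named else 0.0
                    for g in GROUPS
                ]
            )
            if rest.sum() > 0:
                w = w + other * rest / rest.sum()
        if w.sum() <= 0:
            raise ValueError(f"{what}: weights sum to zero")
        return w / w.sum()

    def miscode_tables(self) -> tuple[np.ndarray, dict[int, np.ndarray]]:
        """Source-group weights and per-source target distributions."""
        source_w = np.zeros(len(GROUPS))
        targets: dict[int, np.ndarray] = {}
        other_weight = 0.0
        for src, spec in self.miscode_sources.items():
            weight = float(spec.get("weight", 0.0))
            if src == "other":
                other_weight = weight
                continue
            i = GROUPS.index(src)
            source_w[i] += weight
            t = np.zeros(len(GROUPS))
            for tgt, p in spec.get("targets", {}).items():
                t[GROUPS.index(tgt)] = float(p)
            if t.sum() <= 0:
                raise ValueError(f"miscode_sources[{src}]: no targets")
            targets[i] = t / t.sum()
        if other_weight > 0:
            named = {i for i in range(len(GROUPS)) if source_w[i] > 0}
            inc = np.array([self.group_incidence_per_100k[g] for g in GROUPS])
            rest = np.where(
                [i not in named for i in range(len(GROUPS))], inc, 0.0
            )
            if rest.sum() > 0:
                source_w = source_w + other_weight * rest / rest.sum()
        for i in range(len(GROUPS)):
            if source_w[i] > 0 and i not in targets:
                # uniform over the other 12 groups
                t = np.ones(len(GROUPS))
                t[i] = 0.0
                targets[i] = t / t.sum()
        if source_w.sum() <= 0:
            raise ValueError("miscode_sources: weights sum to zero")
        return source_w / source_w.sum(), targets


@dataclass
class SyntheticCohort:
    """Generated linked tables plus the truth ledger."""

    maternities: pd.DataFrame
    hospital: pd.DataFrame
    registry: pd.DataFrame
    ledger: dict
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write maternities.csv, hospital.csv, registry.csv and ledger.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "maternities": outdir / "maternities.csv",
            "hospital": outdir / "hospital.csv",
            "registry": outdir / "registry.csv",
            "ledger": outdir / "ledger.json",
        }
        self.maternities.to_csv(
            paths["maternities"], index=False, date_format="%Y-%m-%d"
        )
        self.hospital.to_csv(paths["hospital"], index=False, date_format="%Y-%m-%d")
        self.registry.to_csv(paths["registry"], index=False, date_format="%Y-%m-%d")
        paths["ledger"].write_text(json.dumps(self.ledger, indent=2))
        return paths


# ---------------------------------------------------------------------------
# generation internals


def _uniform_dates(
    rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Uniform datetime64[D] draws on inclusive per-element ranges [lo, hi]."""
    span = ((hi - lo) / _DAY).astype(np.int64) + 1
    off = np.floor(rng.random(len(lo)) * span).astype(np.int64)
    return lo + off * _DAY

def _uniform_day_in_month(
    rng: np.random.Generator, months: np.ndarray
) -> np.ndarray:
    """Uniform day within each given datetime64[M] month."""
    first = months.astype("datetime64[D]")
    dim = (((months + np.timedelta64(1, "M")).astype("datetime64[D]") - first) / _DAY
           ).astype(np.int64)
    day = np.floor(rng.random(len(months)) * dim).astype(np.int64)
    return first + day * _DAY


def _draw_offset_months(rng: np.random.Generator, n: int, mixture: dict) -> np.ndarray:
    """Calendar-month offsets (admission before registration; negative = after)."""
    bins = list(TIMING_BINS)
    p = np.array([mixture[b] for b in bins])
    picks = rng.choice(len(bins), size=n, p=p)
    months = np.zeros(n, dtype=np.int64)
    months[picks == 1] = rng.integers(1, 3, size=int((picks == 1).sum()))
    months[picks == 2] = rng.integers(3, 6, size=int((picks == 2).sum()))
    months[picks == 3] = rng.integers(6, 9, size=int((picks == 3).sum()))
    months[picks == 4] = -rng.integers(1, 3, size=int((picks == 4).sum()))
    return months


def _admission_dates(
    rng: np.random.Generator,
    diagnosis: np.ndarray,
    months: np.ndarray,
    window_start: np.ndarray,
    window_end: np.ndarray,
) -> np.ndarray:
    """Admission dates a given number of calendar months before registration.

    A uniform day is drawn within the target calendar month, then clamped to
    the exposure window (an offset that would precede the window start is
    clamped to it, which can shorten the realised offset; the truth ledger
    records the realised dates).
    """
    target_month = diagnosis.astype("datetime64[M]") - months * np.timedelta64(1, "M")
    adm = _uniform_day_in_month(rng, target_month)
    return np.minimum(np.maximum(adm, window_start), window_end)


def _delivery_offsets(
    rng: np.random.Generator, n: int, k: int, total_days: int, gap: int
) -> np.ndarray:
    """(n, k) sorted day offsets with a minimum inter-delivery gap."""
    effective = total_days - (k - 1) * gap
    if effective < 1:
        raise ValueError(
            f"study period too short for {k} maternities {gap} days apart"
        )
    u = np.sort(rng.random((n, k)), axis=1)
    return np.floor(u * effective).astype(np.int64) + np.arange(k) * gap


def _plant_repeats(
    rng: np.random.Generator,
    hosp_rows: list,
    mat_hit: np.ndarray,
    group_idx: np.ndarray,
    first_adm: np.ndarray,
    win_end_hit: np.ndarray,
    extra_mean: np.ndarray,
) -> None:
    """Poisson repeat admissions between the first admission and window end."""
    lam = extra_mean[group_idx]
    n_extra = rng.poisson(lam)
    rep = np.repeat(np.arange(len(mat_hit)), n_extra)
    if len(rep) == 0:
        return
    dates = _uniform_dates(rng, first_adm[rep], win_end_hit[rep])
    for j, d in zip(rep, dates):
        hosp_rows.append((int(mat_hit[j]), int(group_idx[j]), d, None, True))


def generate(config: GeneratorConfig | None = None, seed: int | None = None
             ) -> SyntheticCohort:
    """Generate a synthetic linked cohort under ``config``.

    ``seed`` overrides ``config.seed`` when given.  Returns the three linked
    tables plus the truth ledger; outputs are deterministic functions of
    (config, seed).
    """
    cfg = config or GeneratorConfig.default()
    if seed is not None:
        cfg = cfg.replace(seed=int(seed))
    rng = np.random.default_rng(cfg.seed)

    start64 = np.datetime64(cfg.study_start.isoformat(), "D")
    end64 = np.datetime64(cfg.study_end.isoformat(), "D")
    lookback64 = np.datetime64(cfg.lookback_start.isoformat(), "D")
    total_days = int((end64 - start64) / _DAY) + 1

    # --- women and maternities -------------------------------------------
    k_values = sorted(cfg.maternities_per_woman)
    k_probs = np.array([cfg.maternities_per_woman[k] for k in k_values])
    k_per_woman = np.asarray(k_values)[
        rng.choice(len(k_values), size=cfg.n_women, p=k_probs)
    ]
    woman_idx_parts = []
    delivery_parts = []
    for k in k_values:
        women = np.flatnonzero(k_per_woman == k)
        if len(women) == 0:
            continue
        offs = _delivery_offsets(
            rng, len(women), k, total_days, cfg.min_interdelivery_days
        )
        woman_idx_parts.append(np.repeat(women, k))
        delivery_parts.append(start64 + offs.reshape(-1) * _DAY)
    woman_idx = np.concatenate(woman_idx_parts)
    delivery = np.concatenate(delivery_parts)
    order = np.lexsort((delivery.astype(np.int64), woman_idx))
    woman_idx, delivery = woman_idx[order], delivery[order]
    n_mat = len(delivery)

    weeks = np.asarray(sorted(cfg.gestation_weeks))
    week_p = np.array([cfg.gestation_weeks[w] for w in sorted(cfg.gestation_weeks)])
    gestation = weeks[rng.choice(len(weeks), size=n_mat, p=week_p)]

    win_start = delivery - gestation * 7 * _DAY
    win_end = delivery + np.timedelta64(365, "D")

    woman_ids = np.array([f"W{i:06d}" for i in range(cfg.n_women)])
    maternity_ids = np.array([f"M{i:07d}" for i in range(n_mat)])

    incidence = _group_array(cfg.group_incidence_per_100k, "group_incidence") / 1e5
    capture = _group_array(cfg.capture_prob, "capture_prob")
    extra_mean = _group_array(cfg.extra_admissions_mean, "extra_admissions_mean")

    # planted rows; maternity index kept for the ledger reconciliation
    reg_rows: list[tuple] = []   # (mat_i, group_i, diag, first_notif, event_i)
    hosp_rows: list[tuple] = []  # (mat_i, group_i, adm, event_i, is_repeat)
    events: list[dict] = []

    def _new_event(mechanism: str, mat_i: int, **extra) -> int:
        events.append(
            {
                "mechanism": mechanism,
                "maternity_id": str(maternity_ids[mat_i]),
                "woman_id": str(woman_ids[woman_idx[mat_i]]),
                **extra,
            }
        )
        return len(events) - 1

    # --- incident cancers -------------------------------------------------
    for gi, gname in enumerate(GROUPS):
        hit = np.flatnonzero(rng.random(n_mat) < incidence[gi])
        if len(hit) == 0:
            continue
        diag = _uniform_dates(rng, win_start[hit], win_end[hit])
        captured = rng.random(len(hit)) < capture[gi]
        months = np.zeros(len(hit), dtype=np.int64)
        adm = np.full(len(hit), np.datetime64("NaT", "D"))
        n_cap = int(captured.sum())
        if n_cap:
            months[captured] = _draw_offset_months(rng, n_cap, cfg.timing_mixture)
            adm[captured] = _admission_dates(
                rng,
                diag[captured],
                months[captured],
                win_start[hit][captured],
                win_end[hit][captured],
            )
        n_extra = np.zeros(len(hit), dtype=np.int64)
        if n_cap and extra_mean[gi] > 0:
            n_extra[captured] = rng.poisson(extra_mean[gi], size=n_cap)
        for j, mat_i in enumerate(hit):
            ev = _new_event(
                "incident",
                int(mat_i),
                group=gname,
                diagnosis_date=str(diag[j]),
                captured=bool(captured[j]),
                admission_date=str(adm[j]) if captured[j] else None,
                drawn_timing_bin=timing_bin(int(months[j])) if captured[j] else None,
                n_extra=int(n_extra[j]),
            )
            reg_rows.append((int(mat_i), gi, diag[j], diag[j], ev))
            if captured[j]:
                hosp_rows.append((int(mat_i), gi, adm[j], ev, False))
        # repeat admissions, uniform between index admission and window end
        rep_src = np.repeat(np.flatnonzero(captured), n_extra[captured])
        if len(rep_src):
            rep_dates = _uniform_dates(rng, adm[rep_src], win_end[hit][rep_src])
            for j, d in zip(rep_src, rep_dates):
                hosp_rows.append((int(hit[j]), gi, d, None, True))

    # --- miscoded cancers: true group A in the registry, coded B in hospital
    if cfg.fp_miscode_rate > 0:
        source_w, target_tables = cfg.miscode_tables()
        hit = np.flatnonzero(rng.random(n_mat) < cfg.fp_miscode_rate)
        if len(hit):
            src = rng.choice(len(GROUPS), size=len(hit), p=source_w)
            diag = _uniform_dates(rng, win_start[hit], win_end[hit])
            months = _draw_offset_months(rng, len(hit), cfg.timing_mixture)
            adm = _admission_dates(rng, diag, months, win_start[hit], win_end[hit])
            tgt = np.array(
                [
                    int(rng.choice(len(GROUPS), p=target_tables[int(s)]))
                    for s in src
                ]
            )
            for j, mat_i in enumerate(hit):
                ev = _new_event(
                    "miscode",
                    int(mat_i),
                    group=GROUPS[src[j]],
                    coded_group=GROUPS[tgt[j]],
                    diagnosis_date=str(diag[j]),
                    admission_date=str(adm[j]),
                )
                reg_rows.append((int(mat_i), int(src[j]), diag[j], diag[j], ev))
                hosp_rows.append((int(mat_i), int(tgt[j]), adm[j], ev, False))
            # cancers under treatment re-admit like captured true cancers
            _plant_repeats(rng, hosp_rows, hit, tgt, adm, win_end[hit], extra_mean)

    # --- prevalent cancers: pre-window notification + in-window admission -
    if cfg.fp_prevalent_rate > 0:
        prev_w = cfg.prevalent_weights()
        hit = np.flatnonzero(rng.random(n_mat) < cfg.fp_prevalent_rate)
        if len(hit):
            grp = rng.choice(len(GROUPS), size=len(hit), p=prev_w)
            lo = np.maximum(lookback64, win_start[hit] - np.timedelta64(5475, "D"))
            hi = win_start[hit] - np.timedelta64(30, "D")
            notif = _uniform_dates(rng, lo, hi)
            adm = _uniform_dates(rng, win_start[hit], win_end[hit])
            for j, mat_i in enumerate(hit):
                ev = _new_event(
                    "prevalent_fp",
                    int(mat_i),
                    group=GROUPS[grp[j]],
                    first_notification_date=str(notif[j]),
                    admission_date=str(adm[j]),
                )
                reg_rows.append((int(mat_i), int(grp[j]), notif[j], notif[j], ev))
                hosp_rows.append((int(mat_i), int(grp[j]), adm[j], ev, False))
            _plant_repeats(rng, hosp_rows, hit, grp, adm, win_end[hit], extra_mean)

    # --- noise admissions: cancer-coded, no registry counterpart ----------
    if cfg.fp_noise_rate > 0:
        noise_w = cfg.noise_weights()
        hit = np.flatnonzero(rng.random(n_mat) < cfg.fp_noise_rate)
        if len(hit):
            grp = rng.choice(len(GROUPS), size=len(hit), p=noise_w)
            adm = _uniform_dates(rng, win_start[hit], win_end[hit])
            for j, mat_i in enumerate(hit):
                ev = _new_event(
                    "noise_fp",
                    int(mat_i),
                    group=GROUPS[grp[j]],
                    admission_date=str(adm[j]),
                )
                hosp_rows.append((int(mat_i), int(grp[j]), adm[j], ev, False))

    # --- registry table (with per-woman/group first-notification harmonised)
    registry = _registry_frame(reg_rows, woman_idx, woman_ids)

    # --- truth-ledger reconciliation (before linkage noise) ---------------
    outcomes = _reconcile(
        reg_rows, hosp_rows, registry, woman_idx, delivery, win_start, win_end,
        maternity_ids, woman_ids, events,
    )

    # --- hospital table ---------------------------------------------------
    hospital = _hospital_frame(
        cfg, rng, hosp_rows, woman_idx, woman_ids, delivery
    )

    # --- linkage noise on the registry side -------------------------------
    linkage_log = {"missed_link_women": 0, "false_link_records": 0}
    if not registry.empty and (cfg.linkage_missed_rate > 0 or cfg.linkage_false_rate > 0):
        reg_women = registry["woman_id"].unique()
        missed = reg_women[rng.random(len(reg_women)) < cfg.linkage_missed_rate]
        if len(missed):
            repl = {w: f"X{w}" for w in missed}
            registry["woman_id"] = registry["woman_id"].map(lambda w: repl.get(w, w))
            linkage_log["missed_link_women"] = int(len(missed))
        false_mask = rng.random(len(registry)) < cfg.linkage_false_rate
        if false_mask.any():
            targets = woman_ids[
                rng.integers(0, cfg.n_women, size=int(false_mask.sum()))
            ]
            registry.loc[false_mask, "woman_id"] = targets
            linkage_log["false_link_records"] = int(false_mask.sum())

    maternity_frame = pd.DataFrame(
        {
            "woman_id": woman_ids[woman_idx],
            "maternity_id": maternity_ids,
            "delivery_date": delivery,
            "gestation_weeks": gestation,
        }
    )

    ledger = {
        "seed": int(cfg.seed),
        "n_women": int(cfg.n_women),
        "n_maternities": int(n_mat),
        "events": events,
        "outcomes": outcomes,
        "linkage_noise": linkage_log,
    }
    return SyntheticCohort(
        maternities=maternity_frame,
        hospital=hospital,
        registry=registry,
        ledger=ledger,
        config=cfg,
    )


def _registry_frame(reg_rows, woman_idx, woman_ids) -> pd.DataFrame:
    if not reg_rows:
        return pd.DataFrame(
            columns=[
                "woman_id", "registry_id", "diagnosis_date", "group",
                "first_notification_date",
            ]
        )
    df = pd.DataFrame(
        {
            "woman_id": [woman_ids[woman_idx[r[0]]] for r in reg_rows],
            "diagnosis_date": [pd.Timestamp(r[2]) for r in reg_rows],
            "group": [GROUPS[r[1]] for r in reg_rows],
            "first_notification_date": [pd.Timestamp(r[3]) for r in reg_rows],
        }
    )
    # a registry reports the earliest notification of a group per woman
    df["first_notification_date"] = df.groupby(["woman_id", "group"])[
        "first_notification_date"
    ].transform("min")
    df = df.sort_values(
        ["woman_id", "diagnosis_date", "group"], kind="stable"
    ).reset_index(drop=True)
    df.insert(1, "registry_id", [f"R{i:06d}" for i in range(len(df))])
    return df


def _hospital_frame(cfg, rng, hosp_rows, woman_idx, woman_ids, delivery
                    ) -> pd.DataFrame:
    n_cancer = len(hosp_rows)
    frames = []
    if n_cancer:
        mat_i = np.array([r[0] for r in hosp_rows])
        grp_i = np.array([r[1] for r in hosp_rows])
        adm = np.array([r[2] for r in hosp_rows], dtype="datetime64[D]")
        is_repeat = np.array([r[4] for r in hosp_rows])
        codes = np.array(
            [
                GROUP_CODES[GROUPS[g]][rng.integers(0, len(GROUP_CODES[GROUPS[g]]))]
                for g in grp_i
            ]
        )
        # position of the cancer code among the diagnosis fields
        pos = rng.choice([1, 2, 3], size=n_cancer, p=[0.7, 0.2, 0.1])
        pad = rng.choice(NONCANCER_CODES, size=(n_cancer, 2))
        trail = is_repeat & (rng.random(n_cancer) < 0.1)
        diag = {i: np.full(n_cancer, "", dtype=object) for i in range(1, 5)}
        diag[1] = np.where(pos == 1, codes, pad[:, 0])
        diag[2] = np.where(pos == 2, codes, np.where(pos == 3, pad[:, 1], ""))
        diag[3] = np.where(pos == 3, codes, "")
        diag[4] = np.where(trail, SECONDARY_CODE, "")
        cancer = pd.DataFrame(
            {
                "woman_id": woman_ids[woman_idx[mat_i]],
                "admission_date": adm,
                **{f"diag{i}": diag[i] for i in range(1, 5)},
            }
        )
        frames.append(cancer)
    if cfg.include_delivery_admissions:
        deliv = pd.DataFrame(
            {
                "woman_id": woman_ids[woman_idx],
                "admission_date": delivery,
                "diag1": DELIVERY_CODES[0],
                "diag2": DELIVERY_CODES[1],
                "diag3": "",
                "diag4": "",
            }
        )
        frames.append(deliv)
    if not frames:
        cols = ["woman_id", "record_id", "admission_date"] + [
            f"diag{i}" for i in range(1, N_DIAG_FIELDS + 1)
        ]
        return pd.DataFrame(columns=cols)
    hospital = pd.concat(frames, ignore_index=True)
    for i in range(5, N_DIAG_FIELDS + 1):
        hospital[f"diag{i}"] = ""
    hospital = hospital.sort_values(
        ["woman_id", "admission_date", "diag1", "diag2"], kind="stable"
    ).reset_index(drop=True)
    hospital.insert(1, "record_id", [f"H{i:08d}" for i in range(len(hospital))])
    cols = ["woman_id", "record_id", "admission_date"] + [
        f"diag{i}" for i in range(1, N_DIAG_FIELDS + 1)
    ]
    return hospital[cols]


def _reconcile(
    reg_rows, hosp_rows, registry, woman_idx, delivery, win_start, win_end,
    maternity_ids, woman_ids, events,
) -> list[dict]:
    """Expected (maternity, group) classifications absent linkage noise.

    Implemented as plain brute-force set logic over the planted rows,
    independent of the ascertainment code path, so it can serve as the
    oracle in end-to-end tests.
    """
    involved_women = {woman_idx[r[0]] for r in reg_rows} | {
        woman_idx[r[0]] for r in hosp_rows
    }
    windows_by_woman: dict[int, list[tuple]] = {}
    if involved_women:
        mask = np.isin(woman_idx, np.fromiter(involved_women, dtype=np.int64))
        for i in np.flatnonzero(mask):
            windows_by_woman.setdefault(int(woman_idx[i]), []).append(
                (win_start[i], win_end[i], delivery[i], i)
            )

    def attribute(woman: int, d) -> int | None:
        best = None
        for s, e, dd, mi in windows_by_woman.get(woman, ()):  # few windows per woman
            if s <= d <= e and (best is None or (dd, mi) < best):
                best = (dd, mi)
        return None if best is None else int(best[1])

    # harmonised first-notification per (woman, group) from the emitted table
    first_notif: dict[tuple[str, str], pd.Timestamp] = {}
    if not registry.empty:
        first_notif = registry.groupby(["woman_id", "group"])[
            "first_notification_date"
        ].min().to_dict()

    reg_keys: dict[tuple[int, int], tuple] = {}  # key -> (diag, event_i)
    for mat_i, gi, diag, _notif, ev in reg_rows:
        woman = int(woman_idx[mat_i])
        if first_notif[(str(woman_ids[woman]), GROUPS[gi])] != pd.Timestamp(diag):
            continue  # prevalent under the harmonised history
        target = attribute(woman, diag)
        if target is None:
            continue
        key = (target, gi)
        if key not in reg_keys or (pd.Timestamp(diag), ev) < reg_keys[key]:
            reg_keys[key] = (pd.Timestamp(diag), ev)

    hosp_keys: dict[tuple[int, int], tuple] = {}  # key -> (adm, seq, event_i)
    for seq, (mat_i, gi, adm, ev, _rep) in enumerate(hosp_rows):
        target = attribute(int(woman_idx[mat_i]), adm)
        if target is None:
            continue
        key = (target, gi)
        cand = (pd.Timestamp(adm), seq, ev)
        if key not in hosp_keys or cand < hosp_keys[key]:
            hosp_keys[key] = cand

    reg_by_mat: dict[int, set[int]] = {}
    for mi, gi in reg_keys:
        reg_by_mat.setdefault(mi, set()).add(gi)

    outcomes: list[dict] = []
    for key in sorted(set(reg_keys) | set(hosp_keys)):
        mi, gi = key
        base = {
            "maternity_id": str(maternity_ids[mi]),
            "group": GROUPS[gi],
        }
        in_reg, in_hosp = key in reg_keys, key in hosp_keys
        if in_reg and in_hosp:
            diag, ev_r = reg_keys[key]
            adm = hosp_keys[key][0]
            outcomes.append(
                {
                    **base,
                    "label": "tp",
                    "timing_bin": timing_bin(month_difference(diag, adm)),
                    "mechanism": events[ev_r]["mechanism"],
                }
            )
        elif in_reg:
            outcomes.append(
                {**base, "label": "fn",
                 "mechanism": events[reg_keys[key][1]]["mechanism"]}
            )
        else:
            adm, _seq, ev_h = hosp_keys[key]
            woman = str(woman_ids[woman_idx[mi]])
            notified = first_notif.get((woman, GROUPS[gi]))
            if notified is not None and notified < pd.Timestamp(win_start[mi]):
                category = "prevalent"
            elif reg_by_mat.get(mi, set()) - {gi}:
                category = "misclassified_type"
            else:
                category = "unexplained"
            outcomes.append(
                {
                    **base,
                    "label": "fp",
                    "category": category,
                    "mechanism": events[ev_h]["mechanism"] if ev_h is not None
                    else "repeat",
                }
            )
    return outcomes


def truth_summary(ledger: dict) -> dict:
    """Tally the truth ledger into expected per-group TP/FP/FN counts.

    Also returns false-positive category counts, timing-bin counts over
    expected true positives, and planted-mechanism counts.  With linkage
    noise off, the analysis pipeline must reproduce these tallies exactly.
    """
    per_group = {g: {"tp": 0, "fp": 0, "fn": 0} for g in GROUPS}
    fp_categories = {c: 0 for c in FP_CATEGORIES}
    timing = {b: 0 for b in TIMING_BINS}
    for o in ledger.get("outcomes", []):
        per_group[o["group"]][o["label"]] += 1
        if o["label"] == "fp":
            fp_categories[o["category"]] += 1
        elif o["label"] == "tp":
            timing[o["timing_bin"]] += 1
    mechanisms: dict[str, int] = {}
    for e in ledger.get("events", []):
        mechanisms[e["mechanism"]] = mechanisms.get(e["mechanism"], 0) + 1
    any_row = {
        k: sum(per_group[g][k] for g in GROUPS) for k in ("tp", "fp", "fn")
    }
    return {
        "per_group": per_group,
        "any": any_row,
        "fp_categories": fp_categories,
        "timing_counts": timing,
        "mechanisms": mechanisms,
        "registry_case_count": any_row["tp"] + any_row["fn"],
    }
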