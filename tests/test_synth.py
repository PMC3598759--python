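"""Synthetic linked-cohort generator: determinism, structure and truth ledger."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pacval.pipeline import analyze
from pacval.synth_cohort import (
    GROUPS,
    GeneratorConfig,
    generate,
    truth_summary,
)
from pacval.windows import WindowIndex

SMALL = dict(n_women=3000, linkage_missed_rate=0.0, linkage_false_rate=0.0)

#: degenerate study conditions: every cancer captured, no false positives,
#: no repeat admissions, no registration delay, one maternity per woman
PERFECT = dict(
    n_women=30_000,
    maternities_per_woman={1: 1.0},
    capture_prob={g: 1.0 for g in GROUPS},
    extra_admissions_mean={g: 0.0 for g in GROUPS},
    timing_mixture={"same_month": 1.0},
    fp_prevalent_rate=0.0,
    fp_miscode_rate=0.0,
    fp_noise_rate=0.0,
    linkage_missed_rate=0.0,
    linkage_false_rate=0.0,
)


def test_same_seed_reproduces_byte_identical_files(tmp_path):
    a = generate(GeneratorConfig.default(**SMALL, seed=11))
    b = generate(GeneratorConfig.default(**SMALL, seed=11))
    pa = a.write(tmp_path / "a")
    pb = b.write(tmp_path / "b")
    for key in pa:
        assert pa[key].read_bytes() == pb[key].read_bytes(), key


def test_distinct_seeds_differ():
    a = generate(GeneratorConfig.default(**SMALL, seed=1))
    b = generate(GeneratorConfig.default(**SMALL, seed=2))
    assert not a.maternities.equals(b.maternities)


def test_planted_registry_diagnoses_fall_inside_windows():
    cohort = generate(GeneratorConfig.default(n_women=20_000, seed=3,
                                              linkage_missed_rate=0.0,
                                              linkage_false_rate=0.0))
    widx = WindowIndex(cohort.maternities).frame.set_index("maternity_id")
    for e in cohort.ledger["events"]:
        if e["mechanism"] not in ("incident", "miscode"):
            continue
        row = widx.loc[e["maternity_id"]]
        d = pd.Timestamp(e["diagnosis_date"])
        assert row.start_date <= d <= row.end_date


def test_gestation_and_interdelivery_constraints():
    cohort = generate(GeneratorConfig.default(**SMALL, seed=4))
    m = cohort.maternities
    assert m["gestation_weeks"].between(20, 44).all()
    gaps = m.sort_values(["woman_id", "delivery_date"]).groupby("woman_id")[
        "delivery_date"
    ].diff().dropna()
    assert (gaps >= pd.Timedelta(days=301)).all()
    start = pd.Timestamp("2001-01-01")
    end = pd.Timestamp("2008-12-31")
    assert m["delivery_date"].between(start, end).all()


def test_perfect_capture_limit_gives_unit_sensitivity_and_ppv():
    cohort = generate(GeneratorConfig.default(**PERFECT, seed=5))
    res = analyze(cohort.maternities, cohort.hospital, cohort.registry)
    any_row = res.validation["any"]
    assert any_row.counts.fp == 0 and any_row.counts.fn == 0
    assert any_row.sensitivity.estimate == 1.0
    assert any_row.ppv.estimate == 1.0
    rates = res.rates
    irr_idx = rates[
        (rates.source == "hospital_index") & (rates.group == "any")
    ].iloc[0].irr
    assert irr_idx == pytest.approx(1.0)


def test_perfect_capture_all_to_index_ratio_is_mean_multiplicity():
    mult = 1.5
    cfg = GeneratorConfig.default(
        **{**PERFECT, "extra_admissions_mean": {g: mult for g in GROUPS}},
        seed=6,
    )
    cohort = generate(cfg)
    res = analyze(cohort.maternities, cohort.hospital, cohort.registry)
    rates = res.rates.set_index(["source", "group"])
    irr_all = rates.loc[("hospital_all", "any")].irr
    n_cases = rates.loc[("registry", "any")].n_cases
    # Poisson mean recovered within 4 sigma of the sample mean's SE
    se = np.sqrt(mult / n_cases)
    assert irr_all == pytest.approx(1 + mult, abs=4 * se)


def test_timing_mixture_recovered_from_pipeline():
    incidence = {g: 10 * v for g, v in
                 GeneratorConfig.default().group_incidence_per_100k.items()}
    cfg = GeneratorConfig.default(
        **{
            **PERFECT,
            "group_incidence_per_100k": incidence,
            "n_women": 60_000,
            "timing_mixture": {"same_month": 0.66, "prior_1_2": 0.28,
                               "prior_3_5": 0.05, "prior_6_plus": 0.01},
        },
        seed=7,
    )
    cohort = generate(cfg)
    res = analyze(cohort.maternities, cohort.hospital, cohort.registry)
    ts = truth_summary(cohort.ledger)
    # the pipeline's bins equal the ledger's realised bins exactly
    assert res.timing.counts == ts["timing_counts"]
    # and the realised bins recover the configured mixture within Monte-Carlo
    # error (4 sigma) plus 0.5% absolute slack for window-start clamping
    props = res.timing.proportions()
    n = res.timing.n
    for b, p in cfg.timing_mixture.items():
        if p == 0:
            continue
        tol = 4 * np.sqrt(p * (1 - p) / n) + 0.005
        assert props[b] == pytest.approx(p, abs=tol), (b, props[b], p)


def test_registry_group_composition_matches_configured_rates():
    """At the default study scale (~680k maternities, ~1,000 registry
    cases) the melanoma share of registry cases recovers its configured
    incidence share (32.6% of the total rate) within Monte-Carlo error."""
    cohort = generate(
        GeneratorConfig.default(seed=8, linkage_missed_rate=0.0,
                                linkage_false_rate=0.0,
                                include_delivery_admissions=False)
    )
    ts = truth_summary(cohort.ledger)
    reg_counts = {
        g: ts["per_group"][g]["tp"] + ts["per_group"][g]["fn"] for g in GROUPS
    }
    total = sum(reg_counts.values())
    inc = GeneratorConfig.default().group_incidence_per_100k
    expected_share = inc["melanoma"] / sum(inc.values())
    share = reg_counts["melanoma"] / total
    tol = 4 * np.sqrt(expected_share * (1 - expected_share) / total) + 0.01
    assert share == pytest.approx(expected_share, abs=tol)


def test_truth_summary_tallies_hand_made_ledger():
    ledger = {
        "events": [
            {"mechanism": "prevalent_fp"},
            {"mechanism": "prevalent_fp"},
            {"mechanism": "prevalent_fp"},
            {"mechanism": "incident"},
        ],
        "outcomes": [
            {"group": "breast", "label": "tp", "timing_bin": "same_month"},
            {"group": "breast", "label": "fp", "category": "prevalent"},
            {"group": "melanoma", "label": "fn"},
        ],
    }
    ts = truth_summary(ledger)
    assert ts["mechanisms"]["prevalent_fp"] == 3
    assert ts["per_group"]["breast"] == {"tp": 1, "fp": 1, "fn": 0}
    assert ts["any"] == {"tp": 1, "fp": 1, "fn": 1}
    assert ts["registry_case_count"] == 2
    empty = truth_summary({"events": [], "outcomes": []})
    assert empty["any"] == {"tp": 0, "fp": 0, "fn": 0}
    assert empty["mechanisms"] == {}


def test_prevalent_mechanism_dominates_false_positives():
    """With the false-positive planting rates in their default proportions
    (prevalent largest), prevalent cancers are the modal adjudicated
    category.  Rates are scaled up tenfold to make the test decisive at a
    small cohort size; single maternities remove window-overlap ambiguity."""
    base = GeneratorConfig.default()
    cfg = GeneratorConfig.default(
        n_women=80_000,
        maternities_per_woman={1: 1.0},
        fp_prevalent_rate=10 * base.fp_prevalent_rate,
        fp_miscode_rate=10 * base.fp_miscode_rate,
        fp_noise_rate=10 * base.fp_noise_rate,
        linkage_missed_rate=0.0,
        linkage_false_rate=0.0,
        seed=9,
    )
    cohort = generate(cfg)
    res = analyze(cohort.maternities, cohort.hospital, cohort.registry)
    cats = res.fp_adjudication.by_category
    assert cats["prevalent"] > cats["misclassified_type"]
    assert cats["prevalent"] > cats["unexplained"]
    assert cats == truth_summary(cohort.ledger)["fp_categories"]


def test_missed_links_surface_as_extra_false_positives():
    cfg_clean = GeneratorConfig.default(n_women=40_000, seed=10,
                                        linkage_missed_rate=0.0,
                                        linkage_false_rate=0.0)
    cfg_noisy = cfg_clean.replace(linkage_missed_rate=0.5)
    clean = generate(cfg_clean)
    noisy = generate(cfg_noisy)
    res_clean = analyze(clean.maternities, clean.hospital, clean.registry)
    res_noisy = analyze(noisy.maternities, noisy.hospital, noisy.registry)
    assert noisy.ledger["linkage_noise"]["missed_link_women"] > 0
    # detaching registry records turns hospital TPs into FPs and removes
    # registry cases
    assert res_noisy.two_by_two["any"].fp > res_clean.two_by_two["any"].fp
    assert (res_noisy.two_by_two["any"].tp + res_noisy.two_by_two["any"].fn
            ) < (res_clean.two_by_two["any"].tp + res_clean.two_by_two["any"].fn)


def test_config_validation_rejects_bad_inputs():
    with pytest.raises(ValueError, match="probability"):
        GeneratorConfig.default(fp_noise_rate=1.5)
    with pytest.raises(ValueError, match="n_women"):
        GeneratorConfig.default(n_women=0)
    with pytest.raises(ValueError, match="unknown generator config"):
        GeneratorConfig.default(not_a_key=1)
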