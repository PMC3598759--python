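# Methods

## Problem and design

Population-based cancer registries are the gold standard for identifying
incident cancers, but their quality-assurance cycle delays data
availability; hospital discharge abstracts are timely but of unproven
validity for the obstetric population.  `pacval` implements the
diagnostic-accuracy design used to settle this question for
*pregnancy-associated* cancers — cancers newly diagnosed during pregnancy
or within 12 months of delivery.  The unit of analysis is the **maternity**
(one delivery of one woman; a woman may contribute several maternities).
Hospital ascertainment is cross-classified against registry ascertainment
per maternity and clinical cancer group, and summarised as sensitivity,
positive predictive value, specificity and negative predictive value with
exact binomial confidence intervals, together with incidence rates per
100,000 maternities and hospital-to-registry incidence rate ratios (IRRs).

## Exposure windows

For a maternity delivered on date `d` after `g` completed weeks of
gestation the exposure window is `[d − 7g days, d + 365 days]`, both
endpoints inclusive.  "Within 12 months" is fixed at 365 days rather than
calendar-month arithmetic so the window length is an exact function of
gestation (`7g + 365` days) independent of leap years.  Only births of
20–44 completed weeks are accepted; anything else is rejected as a data
error.  Consecutive windows of one woman may overlap (the postpartum tail
of one pregnancy against the antenatal period of the next).  An event
falling in several windows is attributed to the maternity with the
earliest delivery date; this rule is a package choice (the alternative,
attributing to all containing maternities, is available as
`attribution_rule="all"`).  A consequence worth knowing: when a cancer's
registry date falls just after the end of the previous window while its
(earlier) hospital admission falls just inside it, the two sources
attribute the same cancer to different maternities, producing a matched
false-positive/false-negative pair.  This affects a few percent of cases in
multi-maternity cohorts and is faithfully mirrored by the truth ledger.

## Code classification

Hospital diagnoses are ICD-10(-AM) codes searched across up to 22 fields
per record.  Primary-cancer candidates are the stems C00–C96 with C77–C79
(secondary/metastatic sites) excluded; in-situ and benign neoplasms carry
D codes and are excluded by the range filter itself.  C44 (non-melanoma
skin) is out of scope because registries do not collect it, as are the
stems ICD-10 leaves unassigned (C27–C29, C35–C36, C42, C59).  The 13
clinical groups follow the ICD-10 chapter blocks:

| group | stems |
|---|---|
| head_neck | C00–C14, C30–C32 |
| upper_gi | C15–C17, C22–C26 |
| colorectal | C18–C21 |
| respiratory | C33–C34, C37–C39 |
| bone_connective | C40–C41, C45–C49 |
| melanoma | C43 |
| breast | C50 |
| gynaecological | C51–C58 |
| urogenital | C60–C68 |
| neurological | C69–C72 |
| thyroid_endocrine | C73–C75 |
| ill_defined_unknown | C76, C80 |
| lymphohaematopoeitic | C81–C96 |

Registry clinical-grouping boundaries are not published at stem level, so
this mapping is a documented approximation and is overridable from a YAML
file (`CodeMap.from_yaml`).  A record with several eligible codes is
assigned the group of the first-listed one, consistent with per-group
hospitalisation counts summing exactly to the "any" total.

## Ascertainment

* **Registry cases** — registry records whose diagnosis date equals the
  woman's earliest notification of that group (the incident/prevalent
  distinction, with notification history reaching back to a 1994 lookback
  horizon) and falls in an exposure window; duplicates of one group within
  a maternity collapse to the earliest, distinct groups stay distinct
  (multiple primaries in one pregnancy are counted separately).
* **All cancer hospitalisations** — every qualifying admission, the record
  being the unit.  This replicates analyses of hospital data in which
  individuals cannot be identified.
* **Index cancer hospitalisation** — per (maternity, group) the earliest
  qualifying admission, ties broken on the smallest record id (numeric
  comparison when all ids are numeric, else lexicographic).

## Statistics

With `tp`, `fp`, `fn` counted on (maternity × group) units and
`tn = n_maternities − tp − fp − fn` per group: sensitivity `tp/(tp+fn)`,
PPV `tp/(tp+fp)`, specificity `tn/(tn+fp)`, NPV `tn/(tn+fn)`.  The "any"
row sums the 13 group rows element-wise (so a maternity with two primaries
contributes two units).  Zero-denominator metrics are flagged undefined,
never reported as 0.  Confidence intervals are Clopper–Pearson, computed
from Beta quantiles via `scipy.stats.beta.ppf`, with the closed-form
endpoints 0 (at x=0) and 1 (at x=n).  Rates are `1e5·n/n_maternities`;
IRRs divide unrounded rates and are undefined when the registry count is 0.
All rounding (half away from zero, one decimal) happens only at the
presentation layer.

False positives are adjudicated sequentially: **prevalent** when the woman
has a same-group registry notification dated before the window start,
else **misclassified_type** when the same maternity carries an incident
registry cancer of a different group, else **unexplained**.  Timing among
true positives is the calendar-month difference between the registry month
and the index-admission month, binned as same month / 1–2 / 3–5 / ≥6
months prior, or after registration.  Calendar months are used because
registries effectively record diagnosis dates at month precision.

A note on one reference number: the source counts give an overall registry
rate of 988/679,736 = 145.4 per 100,000 maternities, while the printed
overall table value is 145.0; the package follows the arithmetic.

## Synthetic cohort generator

No linkable obstetric-cancer data can ship with the package, so
`synth_cohort` generates a synthetic stand-in whose defaults encode the
reference study conditions (all overridable via
`src/pacval/data/synth_defaults.yaml`):

* 470,277 women over 2001–2008; maternities per woman distributed
  {1: 0.62, 2: 0.32, 3: 0.055, 4: 0.005} (mean 1.445, matching 679,736
  maternities), delivery dates uniform given a minimum inter-delivery gap
  of 301 days; gestation drawn from a term-centred categorical
  distribution on 20–44 weeks (mode 40, ~6.3% preterm).
* Incident cancers per (maternity, group) as independent Bernoulli draws
  at the per-group registry rates (melanoma 47.4 per 100,000 maternities,
  breast 32.1, … overall 145.3), diagnosis date uniform in the window.
* Hospital capture of each true cancer with the per-group sensitivity
  (0.361 melanoma … 1.0 respiratory/urogenital); the index admission
  precedes registration by a month offset drawn from the mixture
  0.66/0.28/0.05/0.01 over {0, 1–2, 3–5, 6–8} months.  The admission day
  is drawn uniformly *within the target calendar month* and clamped to the
  window, so the realised calendar-month bin equals the drawn one except
  at the window edge; 30-day arithmetic was rejected because it leaks mass
  across calendar-month bins and would break exact ledger/pipeline
  agreement on the timing distribution.
* Repeat admissions per captured, miscoded or prevalent cancer are Poisson
  with the per-group all/index hospitalisation ratio minus one as mean
  (breast 2.23, lymphohaematopoeitic 2.09, melanoma 0.18, …); no
  distributional information beyond the ratio is available, so Poisson is
  a documented approximation.
* Three false-positive mechanisms, planted per maternity: **prevalent**
  (rate 86/679,736; a pre-window first notification plus an in-window
  admission; group split 38 lymphohaematopoeitic / 14 breast / 13
  melanoma / 10 thyroid out of 86, remainder spread by incidence),
  **miscode** (rate 22/679,736; a true registry cancer whose admission is
  coded to a confusion target — colorectal→upper GI weight 7, melanoma→
  breast/bone 3, gynaecological→upper GI 4, remainder by incidence with
  uniform-other targets) and **noise** (rate 58/679,736; an admission with
  no registry counterpart, group split following the overall
  false-positive distribution).  Miscode planting is used rather than code
  replacement on drawn cancers because per-maternity rates are the natural
  parameterisation when cancer prevalence is ~10⁻³.
* Optional linkage noise applied last: each registry woman's records
  detached with probability 0.005 (missed links) and each record
  re-assigned to a random cohort woman with probability 0.003 (false
  links), matching the reported linkage quality bounds.
* A delivery admission (O80/Z37.0) per maternity exercises the code
  filter; cancer codes sit in diagnosis field 1–3 behind obstetric codes
  with probability 0.3, and 10% of repeat admissions carry a trailing
  C78.0 to exercise the secondary-code skip.

Every planted event is recorded in a **truth ledger**; expected
classifications are derived by plain brute-force set logic over the
planted rows (window containment, earliest-delivery attribution,
harmonised first notifications), independent of the ascertainment code
path.  With linkage noise off, the pipeline must — and in the test suite
does — reproduce the ledger's per-group TP/FP/FN, adjudication categories
and timing bins *exactly*, at every seed tested.

### What the generator does not emulate

Demographic covariates, survival and death, seasonality,
gestation-dependent admission intensity, within-registry coding revisions,
and hospital-side linkage error.  Passing tests therefore demonstrate the
correctness of the analytic machinery under the declared generative model,
not the validity of hospital data in any real jurisdiction.

## Test design and problem sizes

End-to-end exactness is checked across 20 seeds at ~50,000 maternities
under the default mechanism rates with linkage noise off.
Confidence-interval calibration (the capture probability falling inside
the estimated sensitivity's 95% CI at the nominal rate) is checked on 20
single-maternity cohorts of 50,000 women with the false-positive
mechanisms off, because miscode-planted cancers are genuine false
negatives not generated by the capture coin and overlapping windows split
a few percent of cases across maternities — with either active, the
per-group sensitivity estimand is no longer the capture probability.
Pooled coverage over seeds × groups is required to be ≥ 0.91 (nominal 0.95
minus a 3σ Monte-Carlo allowance for ~230 binomial checks; Clopper–Pearson
is conservative, so observed coverage typically exceeds 0.95).  Mixture-
recovery and multiplicity tests scale incidence or mechanism rates up
(never the acceptance conditions) to make small-cohort checks decisive,
and state their tolerances (4σ plus explicit clamping slack) inline.

## Known limitations

* The stem-level group mapping approximates unpublished registry grouping
  boundaries (e.g., eye C69 is placed with neurological).
* Early pregnancy losses never enter the cohort (no birth record exists
  for them), so pregnancy-associated counts are conservative by design.
* The earliest-delivery attribution rule is one defensible reading of an
  under-specified step; the "all" rule is provided for sensitivity
  analyses.
* Record linkage itself is out of scope: inputs are assumed already
  linked, and linkage error is only injected, never modelled or corrected.
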