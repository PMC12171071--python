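# Methods

## Scope and data model

The package analyzes long-format administrative claims in three tables:
persons (opaque id, sex, banded age, region, drug-plan coverage intervals),
medical service claims (date, ICD-9/10 diagnosis, care setting, physician
specialty, optional procedure flag, fee), and pharmacy claims (date,
treatment class, days supplied, cost). Ages exist only as bands (<1, 1–4,
then 5-year bands to 80–84, 85+), mirroring the redaction practised by
public insurers; when a continuous age is needed it is estimated as the
band midpoint (85+ → 87.5 by convention).

## Case algorithm and cohort

A person is a treated-vitiligo case iff they carry ≥1 ICD-10 L80.x claim,
or ≥1 ICD-9 709.x claim together with ≥1 vitiligo-related treatment record
(tacrolimus, pimecrolimus, or phototherapy), inside the ascertainment
window (default 2010-01-01..2019-09-30). Diagnosis and treatment may
co-occur anywhere in the window — no maximum lag — because the algorithm
is defined by co-occurrence; a configurable `max_treatment_lag_days` is
provided for sensitivity analyses. The index date is the first qualifying
diagnosis claim. Phototherapy is a billed medical procedure, not a
dispensation, and is recognised through the claim's procedure flag.

Controls: ≥1 medical service in the activity window (default 2018–2019),
zero 709.x/L80.x claims in the ascertainment window, and ≥1 pharmacy claim
in the study period (whose first date is the control's index). The package
does not require a control's index date to precede or follow the activity
window — the first pharmacy service anywhere in 2010–2019 is accepted;
this ambiguity is inherent to the design and is surfaced here rather than
resolved silently.

Matching is exact on (coarse age band, sex), up to `ratio` controls per
case, without replacement. Within a stratum the pool is shuffled once
under the run seed and handed out to cases in ascending person-id order;
when a stratum runs dry, earlier-id cases keep their controls and later
cases receive fewer ("up to" semantics). The tie-break is arbitrary but
deterministic, which is what reproducibility requires.

Everyone must be covered by the drug plan for ≥3 calendar months after
index; follow-up ends at the earlier of coverage end and study end.

## Treatment patterns

Records of one (person, class) sorted by start date merge into an episode
while the gap between the supply exhausted so far and the next start is
below the threshold (default 90 days; 180 for sensitivity). "Supply
exhausted so far" is the running maximum of start + days-supplied: a long
fill followed by a short one still protects continuity, but leftover
overlap is never stockpiled (the exhaustion date never exceeds the latest
start + supply). A start-to-start gap mode is available
(`gap_mode="start"`). Episode duration counts both endpoints, so a single
30-day fill is a 30-day episode.

Sequences keep episodes ≥30 days, ordered by start date with same-day ties
broken lexicographically by class name; a class appears once, at its first
qualifying episode — a restart after discontinuation does not advance the
line-of-therapy numbering. Concomitance sums calendar-day overlap
(endpoints inclusive) over episode pairs of distinct classes.

MPR = days supplied within the horizon (90/180/365 from first fill)
divided by min(horizon, follow-up), reported uncapped — possession above
1.0 is informative and the 80% adherence dichotomy is unaffected.
Aggregate adherence tables include only (person, class) pairs not yet
discontinued at the horizon and observed through it. Persistence is the
duration of episode #1; discontinuation at a horizon means episode #1
ended before first-start + horizon (the gap rule that closed the episode
is itself the confirmation; an episode truncated by the end of data is
counted as ended, a conservative convention).

## Epidemiology

Incidence in year *y*: persons with a qualifying diagnosis in *y* and none
in *y − 1* (calendar-year washout, not a rolling 365 days), over persons
with ≥1 coverage day in *y*. The first study year has no estimate. A
person whose diagnoses skip a calendar year can re-enter the numerator;
that is the rule's literal behaviour, kept deliberately.

Point prevalence at date *t*: persons qualifying within [*t* − 5y, *t*]
with ≥1 medical or pharmacy service in [*t* − 1y, *t*], over persons whose
coverage contains *t*. "Under observation" for denominators uses coverage
alone because medical coverage in the emulated system is universal.
Estimates stratify by sex and coarse band (strata partition persons, so
stratum numerators sum to the overall numerator) and extrapolate as
round(proportion × target population); the target population is a config
input, never inferred.

## Visits, HCRU and costs

Inpatient claims of a person chain into one admission while consecutive
dates are ≤7 days apart — transitively, so claims at days 1, 7, 13 form
one stay (a strict-anchor reading is intentionally not used; the pairwise
rule reads as consecutive-claim distance). ED claims on one date are one
visit; outpatient and "other" claims merge per claim-day. Derivation is
order-invariant.

Visit costs are imputed: inpatient days × daily unit cost, plus per-visit
ED/outpatient costs, each CPI-adjusted (amount × CPI(target)/CPI(base)).
The shipped CPI series is an approximate Statistics Canada Québec
all-items annual series (2002 = 100) and is deliberately editable config —
production costing should drop in an exact extract. No unit cost is
published for "other" visits; the outpatient cost is applied and exposed
as config. `total_services_cost` = visit-imputed costs + physician fees;
`total_healthcare_cost` adds pharmacy amounts (in-hospital medication
never appears in pharmacy claims). Both compositions are reported
separately so either reading of "medical service cost" can be used.
Annualization multiplies by 365.25 / person-days of follow-up; group means
average per-person rates (never ratio-of-sums). Pre/post windows are
[anchor − 365, anchor) and (anchor, anchor + 365], anchored at the index
date or the first treatment date; persons qualify only with a full year of
in-study, in-coverage data on both sides.

Cause subsets: mental health = ICD-9 290–319 or ICD-10 F00–F99;
vitiligo-related = 709.x or L80.x (cases only, by design).

## Comorbidities and statistics

Comorbidity flags require ≥1 mapped claim in (index, index + 365]. The
condition → ICD-prefix map is a reconstruction (the source tabulation
names conditions, not codes) and ships as versioned, editable config. The
Charlson index uses the Quan 2005 claims coding with the original integer
weights; a severe form supersedes its mild counterpart (complicated
diabetes, severe liver disease, metastatic disease).

Continuous comparisons use the equal-variance independent t test
(unequal-variance mode available); categorical comparisons use Pearson
chi-square without continuity correction, switching to the two-sided
Fisher exact test when any expected cell is <5 — sparse rows of the
reference tabulation show p = 1.00, which only an exact test produces.
Pre/post contrasts use paired t tests, with explicit degenerate-case
reports (all-zero differences → p = 1; zero-variance non-zero differences
→ no p, flagged). Percentages are tabulated at one decimal, half-up.

## The synthetic-data generator

The generator emulates the structure of a public-insurer extract, not any
real population. Treated vitiligo is chronic: a case draws an onset date
uniform over the ascertainment window, emits one 709.x claim in the onset
year and one per later calendar year, and starts its assigned treatment
classes 0–120 days after onset (capped at the window end so every case is
identifiable). Under this model the configured prevalence equals the
active-case fraction at study end and implies annual incidence =
prevalence / window-years; either knob may be set, and both together must
agree. Defaults: prevalence 9 × 10⁻⁴ — which makes a 125,000-person sample
carry ≈113 identifiable cases, the reference cohort size — implying a
yearly incidence of ≈0.009%, inside the reported 0.006–0.014% range.

Treatment assignment is Bernoulli per class with the treated-fraction mix
(TCS 69%, tacrolimus 42.5%, phototherapy 33.6% anchored to the reported
distribution; minor classes set to small realistic shares); a case drawing
no qualifying class is forced one, sampled proportionally to the mix,
because the algorithm's premise is that identified cases received
qualifying treatment. Dispensation chains use per-class mean supply/refill
intervals (topicals 30-day fills ~45 days apart; phototherapy ~2 sessions
per week billed as procedures). Comorbidity claims arrive as per-condition
Poisson processes whose yearly hit probability equals the configured
annual rate (anchored to the control column of the reference tabulation,
plus Charlson conditions for a realistic severity mix). Background
utilization is Poisson per setting (outpatient 5.0/year, anchored to the
control mean of 5.5 visits/year), with benign diagnosis codes disjoint
from every mapped range. Decoy persons (709.x without treatment;
treatment without 709.x) probe the algorithm's specificity and are never
labelled cases.

Coverage gaps (one mid-study break of 30–365 days, probability 5%) are
assigned to non-case persons only: chronically treated patients are
modelled as continuously covered, and this guarantees a gap can never
delete a case's qualifying claims — on decoy-free data the algorithm must
recover truth exactly, and the tests assert it. All claims fall inside
coverage intervals; everything derives from one seeded generator, so a
config reruns byte-identically.

What the generator does *not* model: inter-person correlation, seasonal
treatment effects, regional structure beyond configured weights, coding
error, death (coverage end stands in for all exit), or treatment given for
other indications. Passing recovery tests therefore shows the estimators
are calibrated under clean chronic-disease assumptions — not that real
claims meet those assumptions.

## Validation design and problem sizes

- Episode and visit engines are checked for exact agreement with naive
  brute-force oracles (explicit loops implementing the stated rules) on
  1000 random instances each, for both gap thresholds.
- The exact 2×2 test is checked against full hypergeometric enumeration
  (exact integer arithmetic, conventional 1e-7 tie tolerance) on every
  table with total count ≤40.
- Type-I error of the paired and two-group t tests is measured on 1000
  null replicates against a 99% Monte-Carlo band around 0.05.
- Parameter recovery: point prevalence at p₀ ∈ {0.0005, 0.002} over 100
  seeded runs each at n = 50,000; yearly incidence at i₀ = 0.002 over 200
  runs at n = 50,000; an injected post-index ED-rate shift of 2
  visits/person-year over 200 runs at n = 20,000. Each run must land in
  the exact 99% interval implied by the generative model — binomial for
  the proportions, Skellam for the pre/post difference of Poisson visit
  totals — in ≥98% of runs. Recovery runs thin the background-utilization
  rates: the estimators under test depend on case claims, coverage and
  the activity indicator, not on background claim volume, so the thinning
  is a simulation-size choice that keeps the suite inside a practical
  runtime. The shift is injected on ED claims because a case's own
  vitiligo care (annual diagnosis claims, phototherapy sessions) adds
  genuine post-index outpatient utilization that would confound an
  outpatient-rate recovery.

## Known limitations

- The comorbidity ICD map and the CPI series are reconstructions/
  approximations shipped as editable config, not authoritative extracts.
- Episodes truncated by end of follow-up count as discontinuations; no
  censoring correction is applied (none is applied in the reference
  design either).
- MPR for topicals inherits the usual supply-estimation noise; the
  generator does not model it.
- The exact-vs-chi-square switch is a reconstruction of common practice
  consistent with the reference tabulation's sparse-row p-values.
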