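# Methods

`crcsim` is a discrete-time, person-level microsimulation of an organized
colorectal cancer (CRC) screening program based on the fecal immunochemical
test (FIT). Its purpose is to compare two follow-up strategies for patients
who have 1–2 low-risk adenomas (LRAs) removed at colonoscopy:

* **status quo** — surveillance colonoscopy 5 years after polypectomy;
* **return to FIT** — resumption of routine FIT screening 5 years after
  polypectomy, applied only to index colonoscopies performed in 2023 or
  later and only to people screened within the FIT program.

Outcomes are reported as average annual values over the 2023–2042 horizon:
CRC cases and deaths, complications, FIT screens, colonoscopies in five
mutually exclusive categories, and undiscounted 2021-CAD costs in three
groups.

## Model structure

Time advances in 1-year cycles. Within a year, each alive person is
processed in a fixed order: (1) natural-history update, (2) symptomatic
presentation, (3) scheduled follow-up event, (4) routine screening,
(5) non-CRC mortality and aging. The fixed order makes paired runs exactly
reproducible and keeps the common-random-numbers coupling tight.

### Demography

The starting cohort represents the screening-eligible population aged
50–74 (1,190,189 people at full scale; any smaller cohort via
`scale_factor`). Ages are sampled from a configurable distribution
(uniform by default). Each year a configurable inflow of new 50-year-olds
(default 4% of the scaled starting population) keeps the eligible pool
approximately stationary. All-cause non-CRC mortality follows a synthetic
Gompertz-shaped life table, `q(age) = min(1, 0.004·e^{0.085(age−50)})` for
ages 50–110; ages beyond the table die with certainty. People leave FIT
eligibility at 75 but remain simulated until death, so surveillance
obligations incurred before 75 still complete.

The simulation starts in 2008 (the program is assumed in place since
then), giving a 15-year burn-in before the 2023 policy change so that the
surveillance states and screening cadences are well mixed when reporting
starts.

### Adenoma–carcinoma natural history

Adenomas occupy three size classes (0–5, 6–9, ≥10 mm) with histology flags
(villous, dysplasia) fixed at onset. Each year an adenoma progresses to
preclinical cancer, grows one size class, reverts to normal mucosa, or
stays, resolved from a single uniform draw with progression first in the
cumulative ordering — so raising a progression probability can only move
draws into the progression region, which underpins the monotone-hazard
property test. New adenomas arise at an age-increasing rate (at most one
per year by default) and always start in the 0–5 mm class; size moves only
between adjacent classes in one step.

Preclinical cancer becomes clinical when a geometrically distributed
sojourn (mean 4 years) elapses, triggering a same-year diagnostic
colonoscopy for symptomatic presentation; clinical cancer carries a 12%
annual death hazard. One cancer state per person: additional progressing
adenomas can only shorten the active sojourn.

Cohort members do not enter lesion-free: each person's adenoma dynamics
are pre-run from age 20 to their entry age, which produces a
near-stationary adenoma prevalence (~20% carriage) and a small undiagnosed
preclinical cancer pool at baseline. Progressions whose sojourn would have
ended before baseline correspond to cancers diagnosed pre-baseline; they
are dropped, i.e. baseline clinical-cancer survivors are outside the
model. Their ongoing management costs are therefore under-counted equally
in both arms; incremental results are unaffected.

### Default rates and calibration

Production microsimulation platforms calibrate their rates to cancer
registries with data that are not public, so the default natural-history
parameter set here is synthetic and makes no claim to registry fidelity. It was fixed in two steps, in this order:

1. Onset (0.012 + 0.0008/year of age over 50), growth (0.05/0.05),
   reversion (0.10/0.05/0.02), and progression (0.0004/0.004/0.04) were
   chosen from steady-state arithmetic to give realistic adenoma carriage
   (~20% of the population) and a full-scale annual CRC case count of a
   plausible order, with progression risk strictly increasing in size
   class and positive in every class (small adenomas also carry elevated
   risk relative to normal mucosa).
2. The sub-10 mm FIT sensitivities and the false-positive rate were then
   calibrated once so that LRA findings occur at roughly 26 per 100
   FIT-positive colonoscopies — the observed program-level yield the base
   case is specified to match — and frozen as the shipped defaults
   (`analysis/01_calibrate_lra_yield.py` re-measures this; it lands at
   25–26/100 at desk scale).

### FIT screening

Participation is a lifetime trait: 42% of the eligible population are
participants, split 50/50 between annual and biennial cadence (biennial
phases staggered uniformly). FIT positivity is governed by the most
advanced lesion at test time, ordered none < adenoma 0–5 mm < 6–9 mm <
≥10 mm < preclinical CRC. Base-case (75 ng/mL) operating characteristics:
sensitivity (0.09, 0.19, 0.45, 0.80) along that hierarchy and a 2.6%
false-positive rate; the ≥10 mm and CRC values follow published
magnitudes, the rest are the calibrated stand-ins described above. The
100 ng/mL preset lowers the sub-10 mm sensitivities (relative reductions)
and the false-positive rate. Compliance with the colonoscopy after a
positive FIT, and with post-polypectomy follow-up, is 100%; a positive FIT
leads to colonoscopy in the same simulated year.

A configurable 12% of the population is screened primarily by colonoscopy
(significant family history; every 10 years), contributing the "screening
colonoscopies without FIT" volume. These people are outside the FIT
program: the LRA strategy change never applies to them (their 1–2-LRA
findings always get the status-quo surveillance colonoscopy), and after a
normal surveillance outcome they resume primary colonoscopy screening
rather than FIT. Under common random numbers their incremental volume is
exactly zero.

### Colonoscopy and follow-up pathways

A colonoscopy detects each adenoma independently (sensitivity 0.85/0.95/1.0
by size class) and removes what it detects; a procedure with any
polypectomy is "operative". Preclinical cancer is detected with
probability 1 and becomes clinical, with the detection route implied by
the colonoscopy category. Complications are sampled per procedure: major
bleeding 0.3/1000, perforation 1.7/1000, mortality 0 (all configurable).

Findings classification: cancer overrides all; 1–2 adenomas, all tubular
< 10 mm without dysplasia → `lra_1_2`; any villous adenoma, any ≥10 mm
adenoma, any dysplasia, or > 2 LRAs → `high_risk`. (The published LRA
definition — tubular, < 10 mm, no dysplasia — leaves a sub-10 mm
dysplastic adenoma without a class under a literal villous/≥10 mm/>2-LRA
high-risk rule; this package classifies any non-low-risk adenoma as
high-risk to make the classification total.)

Follow-up rules: normal → routine FIT in 10 years; `lra_1_2` → the active
strategy's 5-year rule, policy-gated as above; `high_risk` → colonoscopy
in 3 years, then — if that check is normal — a second colonoscopy 5 years
later; repeated high-risk findings restart the 3-year clock. Findings at a
surveillance colonoscopy are re-classified under the active strategy, so
pathways recurse. Cancer diagnosis triggers annual surveillance-after-
cancer colonoscopies for 5 years (a configurable stub; the schedule's
published volume exists but not its rule), and cancer patients do not
return to routine screening. While any follow-up is pending, routine FIT
is suspended; a "return to FIT" event re-enables routine screening in its
due year (people past 74 at that point simply stop screening).

### Costs

All costs are undiscounted 2021 CAD, held internally as integer cents so
group totals are exact. Unit costs: FIT kit $26.13 plus a $38.03
result-discussion visit per screen; $146.03 consultation attached to each
colonoscopy after a positive FIT (only that category — surveillance
colonoscopies have no preceding FIT); diagnostic colonoscopy $866.43;
operative colonoscopy $1,036.43; major bleed $3,864.74; perforation
$37,779.83; recruitment $0. Cost groups follow the colonoscopy categories:
screening (screening colonoscopies without FIT + after positive FIT + all
FIT/consult costs), clinical diagnosis (symptomatic diagnostic +
surveillance after adenoma), cancer management (surveillance after cancer
+ an annual $12,000 per-person cancer-management stand-in). The stand-in
gives the three-group report its structure; its absolute level is not
reproducible from published unit costs and should not be compared to
program accounting.

### Experiment design and statistics

Each comparison runs `n_replicates` (12 by default) paired simulations.
Within a replicate both strategies run on the same freshly built
population; common random numbers are the default (every person carries a
private random stream seeded from the replicate seed and their id, shared
across arms), with a flag for independent streams. Outcomes are averaged
over the 20 reporting years within each run; per-replicate differences
(new − status quo) are summarised by their mean and a two-sided 95%
t-interval, `mean ± t(0.975, n−1)·sd/√n`, degenerating to a point at zero
variance. Incremental major bleeds and perforations are derived by
multiplying the incremental colonoscopy count by the per-1000 rates, and
displayed rounded to integers (halves away from zero); counts are
displayed to the nearest integer, costs to the dollar, percentages to one
decimal.

Because the new rule is gated to index colonoscopies from 2023 onward and
the diverted follow-up sits 5 years out, paired arms under common random
numbers are *identical* through 2027; incremental colonoscopies and
savings appear in 2028 and grow thereafter. The test suite asserts this
exact-zero window and the subsequent negative trend at desk scale.

## Problem sizes used

Test and analysis runs are deliberately desk-scale: the paired comparison
tests use 50,000 persons × 12 replicates; the analysis drivers use
20,000–30,000 persons; invariant tests use 800–4,500. Counts scale
linearly in cohort size (verified within Monte Carlo error), so
full-provincial volumes correspond to multiplying by the scale factor;
Monte Carlo noise does not, so desk-scale confidence intervals are wider
than full-scale ones.

## Numerical choices and degenerate inputs

* Single-uniform fate draws with progression-first threshold ordering
  (monotone in the progression probability).
* Geometric sojourn sampled by inverse CDF, support {1, 2, …}.
* Seeds: every stream derives deterministically from the run seed
  (31-bit child seeds; 63-bit per-person seeds), so runs are bitwise
  reproducible.
* Configs validate eagerly; zero-probability degenerate configs (no
  onset, no progression, zero costs) are admitted for controlled
  experiments, while the shipped default satisfies the strict
  progression-risk ordering.
* Ages beyond the life table force death; an empty cohort, malformed age
  weights, or a frequency mix not summing to 1 raise configuration
  errors.

## What the synthetic data do and do not show

The generator emulates the *structure* of a provincial screening program —
participation, cadence mix, threshold-dependent positivity, surveillance
pathways, category volumes, and cost flows — under synthetic demography
and natural history. Absolute levels (CRC cases, deaths, total costs)
depend on unpublished registry calibration and are explicitly not
reproduced; the package's claims are therefore about *incremental* and
*directional* results: fewer adenoma-surveillance colonoscopies, slightly
more FIT screens, lower total cost, complication reductions proportional
to averted colonoscopies, and the 5-year delay before any of this
materialises. Passing tests support those incremental statements under
the stated synthetic conditions, not the absolute projections of any
particular jurisdiction.

## Known limitations

* No sex stratification, migration, serrated-pathway lesions, anatomical
  site, or stage-structured cancer survival.
* Baseline clinical-cancer survivors are excluded; cancer-management
  costs are a stand-in.
* FIT hemoglobin is modelled only as a binary threshold result; kit
  return delays and appointment no-shows are not modelled.
* Participation is a lifetime trait (the per-round interpretation is a
  config switch away but untested at scale).
* The 3-year/5-year high-risk sequence repeats the 3-year interval on
  repeated high-risk findings; real guidelines vary.
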