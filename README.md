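# crcsim

Person-level microsimulation of an organized colorectal cancer (CRC)
screening program based on the fecal immunochemical test (FIT), built to
answer a resource-planning question screening programs currently face:
**what happens if patients with 1–2 low-risk adenomas (LRAs) removed at
colonoscopy return to routine FIT screening in 5 years instead of
receiving a surveillance colonoscopy in 5 years?**

The package is aimed at screening-program analysts and health-economics
modellers. It simulates individual histories — adenoma onset, growth,
regression, and progression to cancer; FIT participation and
threshold-dependent positivity; colonoscopy pathways with polypectomy and
complications; undiscounted 2021-CAD costs — and compares the two
follow-up strategies as paired replicate experiments with Monte Carlo
confidence intervals.

## Model sketch

* **Natural history.** Adenomas occupy three size classes (0–5, 6–9,
  ≥10 mm). Each year an adenoma progresses to preclinical cancer with
  probability `p_k`, grows one class with `g_k`, reverts with `r_k`, or
  stays, where `p₃ > p₂ ≥ p₁ > 0` — every adenoma class carries elevated
  cancer risk. Preclinical cancer surfaces clinically after a geometric
  sojourn (mean 4 y); clinical cancer carries an annual death hazard.
* **Screening.** 42% of the 50–74 population are lifetime FIT
  participants (50% annual / 50% biennial). FIT positivity is governed by
  the *most advanced lesion*; a positive test triggers a same-year
  colonoscopy (100% compliance).
* **Follow-up.** Normal colonoscopy → FIT in 10 y; 1–2 LRAs → the
  strategy under study (colonoscopy@5y vs FIT@5y, the latter gated to
  index colonoscopies from 2023 on); high-risk findings (villous, ≥10 mm,
  dysplasia, or >2 LRAs) → colonoscopy at 3 y then 5 y; cancer → annual
  surveillance for 5 y.
* **Statistics.** Both strategies run on the same replicate populations
  (common random numbers). Average-annual outcomes over 2023–2042 are
  differenced per replicate and summarised as `mean ± t(0.975, n−1)·sd/√n`
  over 12 replicates. Incremental complications are the incremental
  colonoscopy count times the per-1000 rates (0.3 bleeds, 1.7
  perforations).

See `docs/methods.md` for the full model description, parameter defaults,
calibration, and limitations.

## Worked example

```python
from crcsim import Scenario, build_incremental_report, run_replicates, write_reports

scenario = Scenario().scaled(20_000)            # 20,000-person desk-scale cohort
pairs = run_replicates(scenario, n_replicates=12, seed=1)
report = build_incremental_report(pairs, scenario.complications)
frames = write_reports(report, "results")
print(frames["volumes"].to_string())
```

prints (average annual values over 2023–2042):

```
                                                    status_quo  new_strategy  diff  pct_change
outcome
FIT screens                                               4662          4755    92         2.0
Screening colonoscopies without FIT                        206           206     0         0.0
Colonoscopies after a positive FIT                         166           169     3         1.9
Colonoscopies for symptomatic patients                      11            11     0         0.0
Surveillance colonoscopies after adenoma detection          85            53   -32       -37.7
Surveillance colonoscopies after cancer detection           34            34     0        -0.2
Total number of colonoscopies                              502           473   -29        -5.8
```

Reading it: returning LRA patients to FIT instead of surveillance
colonoscopy trades a small rise in FIT screens (+2.0%) for a large drop
in adenoma-surveillance colonoscopies and a 5.8% drop in total
colonoscopy demand, with CRC cases and deaths unchanged within the
replicate confidence interval. The companion cost table shows total
annual cost falling about 1.4% at these unit costs. Because the new rule
only applies to index colonoscopies from 2023 onward and the diverted
follow-up sits 5 years out, the two arms are *identical* until 2028 —
the incremental colonoscopy series is exactly zero through 2027 and
negative afterwards.

The same comparison is scripted as a narrative analysis chain:

```bash
python analysis/01_calibrate_lra_yield.py   # study-condition check: ~26 LRAs /100 FIT+ colonoscopies
python analysis/02_compare_strategies.py    # the main paired comparison (tables above)
python analysis/03_scenarios.py             # fit100, all-annual/biennial, cost & complication sensitivity
crcsim compare --preset base --scale 0.02 --seed 1   # CLI equivalent
```

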