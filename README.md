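# stormsurge

Disaster-utilization analytics for administrative health-insurance claims.

When a severe storm is forecast, hospitals discharge patients early to
free beds, skilled nursing facilities (SNFs) transfer their sickest
residents to hospitals, and after landfall emergency departments (EDs)
absorb a surge of visits that is strongly graded by local storm impact.
`stormsurge` packages the estimators needed to quantify all of this from
claims-shaped data — and, because real fee-for-service claims are
restricted, a synthetic claims generator that plants known effects so the
whole pipeline is testable end to end.

It is written for health-services and disaster-epidemiology researchers
who work with beneficiary-level enrollment, inpatient, and ED tables.

## What it computes

**Pre-landfall** (week before landfall vs the weekday-aligned week a year
earlier):

- discharge proportions (census-based denominator), by chi-square and by
  a logistic model adjusted for age, sex, and race;
- inter-facility transfer admissions, linked via the admission-source
  code *or* an admission date falling inside a source stay
  (hospital/SNF/hospice → hospital);
- case-mix index (CMI = mean DRG service-intensity weight, range
  0.1–30.0) by Welch's t;
- average length of stay (ALOS) by OLS within DRG-matched strata.

**Post-landfall** — the ED surge:

- a difference-in-differences (DD) linear model of beneficiary-week ED
  visit counts (pre/post × study-year/prior-year, HC1 robust errors),
  read out as a percent surge against the counterfactual post-week mean;
- a 1,000-iteration Monte Carlo **matched triple difference** (DDD):
  every study beneficiary is matched 1:1 with replacement to an
  out-of-state comparison beneficiary in the same (5-year age band, sex,
  race) cell, and the matched pool's DD is subtracted — removing shocks
  (e.g. seasonal influenza) common to both regions;
- stratification by county impact quartile (community-hardship scores
  binned Q1 ≤ 39 < Q2 ≤ 47 < Q3 ≤ 58 < Q4) and by ED disposition
  (discharged vs admitted), plus extrapolation from a claims sampling
  fraction to population counts.

The model and the data schema are documented in `docs/methods.md` and
`docs/data_dictionary.md`.

## Worked example

One command simulates a 20,000-beneficiary population under the
`sandy_like` scenario (planted effects: +7.1% relative discharge
increase, +38.9% SNF-transfer increase with a 1.40 → 1.96 case-mix shift,
−0.3 day ALOS shift, quartile ED-surge multipliers averaging +14.3%
statewide and +35.5% in Q4) and runs every stage:

```bash
stormsurge run-all --seed 17 --out results/demo
```

`results/demo/report.md` then contains, among others (output from this
exact command):

```text
## Difference-in-differences ED surge
| design | estimate | se    | p_value | percent_surge | percent_se | outcome       |
| dd     | 0.024    | 0.007 | 0.000   | 25.156        | 7.105      | ed_visits     |
| dd     | 0.018    | 0.005 | 0.001   | 30.977        | 9.511      | ed_discharges |
| dd     | 0.006    | 0.004 | 0.151   | 16.352        | 11.387     | ed_admissions |

## Estimated increase in ED utilization
| outcome    | actual_increase | extrapolated_increase | percent_increase |
| ED visits  | 201             | 1005                  | 25.2             |
| Discharged | 149             | 745                   | 31.0             |
| Admitted   | 52              | 260                   | 16.4             |
```

Reading: the storm week carried 0.024 extra ED visits per
beneficiary-week — a 25.2% surge (±7.1 percentage points at one standard
error, so consistent with the planted 14.3%) — amounting to 201 extra
visits among the 8,506 cohort members, or ~1,005 visits when extrapolated
through the 20% sampling fraction. The Q4 row of the quartile table shows
36.2% ± 11.5 against the planted 35.5%. Precision tightens as `--n`
grows; the validation suite runs the same recovery at n = 50,000.

Library use mirrors the CLI:

```python
import stormsurge as ss

scn = ss.get_preset("sandy_like", n_beneficiaries=50_000, seed=17)
bundle = ss.generate_bundle(scn)
cohort = ss.filter_continuous_ffs(bundle.beneficiaries, "NJ")
panel = ss.build_panel(cohort["bene_id"], bundle.beneficiaries,
                       bundle.ed_visits, bundle.county_chi)
print(ss.dd_estimate(panel).percent_surge)
```

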