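# Methods

`stormsurge` quantifies how a severe, forecast storm reshapes hospital and
emergency department (ED) utilization in an elderly fee-for-service (FFS)
insured population. The package has two halves: a set of estimators that
operate on administrative-claims-shaped tables, and a synthetic claims
generator that plants known effects so every estimator can be validated
end to end without access to restricted claims data.

## Study design

All contrasts compare four one-week windows around the storm's landfall
(2012-10-29 in New Jersey): the week before landfall (Oct 22–28, 2012) and
the week after (Oct 29–Nov 4, 2012), each paired with the weekday-aligned
week of the prior year (Oct 24–30 and Oct 31–Nov 6, 2011). Windows are
inclusive 7-day calendar-date spans; all date arithmetic is day-granular
(a same-day stay has length of stay 0).

### Pre-landfall outcomes

- **Discharge proportion.** Numerator: inpatients discharged within the
  target week. Denominator: inpatients occupying a bed at any point during
  that week (admitted on or before its last day and discharged on or after
  its first). Administrative sources rarely define this denominator; the
  census-based reading used here is the most natural one and is applied
  identically to both years, so the relative change is insensitive to the
  convention. Compared by Pearson chi-square on the 2×2 table (no
  continuity correction by default — samples are large; a flag enables
  Yates' correction) and by a logistic model of discharge on the
  study-week indicator adjusted for age (continuous, at Jan 1 of the claim
  year), sex, and race (indicator set, most frequent level as reference).
- **Inter-facility transfers.** A hospital admission is a transfer from a
  source stay (hospital, skilled nursing facility, or hospice) of the same
  beneficiary at a different facility when the admission-source code names
  that source type *or* the admission date falls inside the source stay
  (inclusive endpoints: a same-day move counts). When several source stays
  qualify, the code-matching candidate with the latest admission date wins
  (ties: smallest facility id). When the code and the date rule disagree on
  the type, the explicit code wins and the disagreement is logged. The
  outcome is the share of through-ED hospital admissions attributable to
  SNF transfers, contrasted across years by chi-square.
- **Case-mix index (CMI).** The arithmetic mean of the DRG (diagnosis
  related group) service-intensity weights of a claim population, valid
  weight range 0.1–30.0. Year-over-year CMI contrasts use Welch's
  two-sample t (unequal variances). CMI is pooled statewide rather than
  per hospital.
- **Length of stay (ALOS).** Ordinary least squares of length of stay on a
  target-week indicator plus DRG stratum indicators, restricted to DRGs
  present in both the target week's discharges and the reference pool
  (discharges at any other time in the two panel years). With a single
  stratum the fit falls back to the unstratified difference and is
  flagged.

All p-values are two-sided with significance at 0.05 and no
multiple-testing correction (a small set of pre-specified outcomes, each
reported on its own).

### Post-landfall surge

The outcome is the beneficiary-week ED visit count (at most one counted
visit per beneficiary-week; the beneficiary-week is the analysis unit).
The panel has one row per beneficiary × year (study/prior) ×
period (pre/post).

- **Difference in differences (DD).** A linear model of the count on year,
  period, year×period, and optionally age/sex/race, with HC1
  heteroskedasticity-consistent standard errors. A linear (rather than
  logistic) link is the default so the interaction coefficient reads
  directly in visits per beneficiary-week; *percent surge* divides it by
  the counterfactual post-week mean (study pre-week mean plus the prior
  year's post-minus-pre difference), making the published percent
  increases exact functions of the coefficients.
- **Matched triple difference (DDD), Monte Carlo.** Each of 1,000
  iterations draws, for every study-state beneficiary, one comparison-pool
  beneficiary uniformly at random *with replacement* from the same
  (5-year age band, sex, race) cell — the adjustment set used elsewhere in
  the analysis — and evaluates DDD = (study DD) − (matched comparison DD).
  An empty cell widens to 10-year bands with a warning. Without covariate
  adjustment the pooled triple-interaction OLS coefficient is algebraically
  identical to this difference of DDs computed from cell means, so the
  Monte Carlo loop uses the cell-mean identity (a test verifies the
  equality against the full regression); the regression route with
  covariates remains available. The DDD percent surge divides by the
  study counterfactual *plus* the matched comparison DD, so a shock common
  to both regions cancels from numerator and denominator alike. The point
  estimate is the iteration mean (median available) with 2.5–97.5
  percentile intervals.
- **Impact stratification.** County scores on a 1–100 community-hardship
  scale are binned into quartiles (Q1 ≤ 39 < Q2 ≤ 47 < Q3 ≤ 58 < Q4); the
  published bins leave 39 and 59 unassigned, closed here downward at 39
  and upward at 59 (configurable). DD runs per quartile and per ED
  disposition (total / discharged / admitted).
- **Scale-up.** Sample counts extrapolate to the full population as
  `round(count / sampling_fraction)`. The reference analysis's printed
  extrapolations differ slightly from this rule (312 → 1,558 rather than
  1,560); the rule here is the plain one and the discrepancy is not
  reverse-engineered.

### Uncertainty conventions

DD uses HC1 robust standard errors; DDD uses the Monte Carlo percentile
spread. When a DDD point estimate is compared against a planted truth in
the validation suite, the tolerance combines the study-side sampling
standard error with the Monte Carlo matching spread,
`3·sqrt(se_DD² + sd_MCS²)`, because the matching spread alone ignores
study-side sampling noise.

## The synthetic generator

The generator emulates the *structure* of FFS claims around a two-year
enrollment panel (2011–2012): a beneficiary table with demographics,
county (with hardship scores spanning the published quartile bins, county
shares proportional to the published per-quartile cohort sizes
37,581/52,754/56,193/77,588), and a comparison population in unaffected
states; weekly ED-visit Bernoulli processes with sinusoidal seasonality
(amplitude 0.10, peak mid-January — a flu-like confounder shape); hospital
stays admitted through the ED with log-normal latent severity snapped to a
40-code DRG weight grid (grid at equiprobable normal quantiles, σ = 0.5,
mean weight ≈ 1.40); weekly discharge draws (baseline weekly discharge
probability 0.518, giving the discharge-proportion outcome its baseline);
and inter-facility transfer admissions (9% SNF, 3% hospital, 1% hospice at
baseline) with source-facility stays ending on the admission day, 30% of
them carrying an `unknown` admission-source code so the date-overlap
linkage rule is exercised.

Planted storm effects, all exact in expectation:

| effect | mechanism | `sandy_like` value |
|---|---|---|
| discharge acceleration | weekly discharge probability × a in the pre-landfall week | a = 1.071 (+7.1% relative) |
| SNF-transfer surge | SNF source probability × m for pre-week admissions | m = 12.5/9 (+38.9%) |
| SNF severity shift | latent log-weight + δ for pre-week SNF transfers | δ = ln(1.96/1.40) |
| ALOS shift | pre-week discharges moved −1 day with calibrated probability | −0.3 days |
| ED surge | post-week visit probability × m(quartile), study state only | (0.97, 1.02, 1.0815, 1.355); beneficiary-weighted statewide mean +14.3% |
| surge disposition | storm-attributable visits admitted at 0.20 vs 0.40 baseline | 80/20 split of extra visits |
| common shock (`confounded`) | post-week visit probability × 1.25 in *every* state, study year | biases DD, removed by DDD |

The ALOS move is confined within the discharge week (never crossing the
window boundary or the admission date) with its probability scaled by the
realized movable fraction, so the planted −0.3 day mean shift is exact
*and* the census discharge proportion is untouched; consequently
`|alos_shift_days|` may not exceed 6/7 day. The severity grid snap
attenuates the planted log-shift slightly at the grid edges, which is one
reason recovery checks use estimator standard errors rather than exact
equality.

**Deliberate non-reproductions.** The baseline weekly ED-visit rate
(default 0.10 visits per beneficiary-week) and the weekly discharge
probability are statistical-convenience choices that control how much
information a run of a given size carries about the planted effects; they
are far above real elderly-population ED rates and are not calibrated to
any claims statistic. The DRG vocabulary (40 synthetic codes), facility
rosters, and county hardship scores are structural stand-ins. Beneficiary
processes are independent (no household or facility clustering), visits
can occur while an earlier stay is still open, and enrollment gaps are a
single missing month. Passing validation therefore demonstrates that the
estimators recover known effects from data with this covariance structure
— not that real claims satisfy the estimators' assumptions.

**Determinism.** All randomness flows through counter-based (Philox)
streams keyed by the scenario seed with a fixed draw budget per record,
laid out beneficiary-major: identical scenario + seed reproduces output
byte for byte, and enlarging the population leaves existing beneficiaries'
records unchanged. Pipeline stages derive their seeds from the run seed
(cohort: seed+1, Monte Carlo: seed+2), so a rerun with the same
configuration and seed is byte-identical.

## Problem sizes

Validation runs use n = 50,000 beneficiaries for planted-parameter
recovery and confounder removal (the Monte Carlo loop at 1,000
iterations), 200 replicates of n = 8,000 for null calibration of type-I
error (window cell counts at that size are large enough for the
chi-square and Welch approximations the estimators rely on), and 100
random fixtures of up to 1,000 claims for the transfer-linkage oracle
check. The reproduction script (`scripts/acceptance.py`) runs one
n = 200,000 scenario (30% of it the out-of-state comparison pool).

## Numerical and degenerate-input choices

- Sample size for cohort draws is `round(fraction·n)` with banker's
  rounding; sampling is without replacement from the id-sorted eligible
  set, so membership is seed-reproducible.
- A degenerate 2×2 table (zero margin) yields a flagged estimate with an
  absent p-value rather than an exception; logistic separation or
  non-convergence yields a `non_convergence` status; an empty DRG
  intersection yields an empty matched frame; an empty quartile yields an
  `absent` row.
- Visit-occurrence probabilities are clipped at 0.95 per beneficiary-week;
  stays are forced closed after 13 weekly discharge draws.
- Monte Carlo iterations whose matched DD is undefined are recorded as
  missing; the run aborts if 5% or more go missing.

## Known limitations

- The discharge-proportion denominator convention, while symmetric across
  years, is one of several defensible readings of "percent discharged".
- The DRG-matched ALOS contrast carries a small seasonal composition term
  (window discharges weight admission weeks unequally), visible as
  seed-level wobble around the planted value at very large n.
- The transfer linkage trusts the admission-source code over the date
  rule on disagreement; with miscoded sources this choice, like any
  deterministic resolution, is unverifiable from claims alone.
- Hospital-occupancy analysis is out of scope: claims do not carry bed
  capacity, so surge is measured in utilization, not occupancy.
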