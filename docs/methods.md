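# Methods

## Design

The pipeline estimates the attributable direct medical cost of
hospital-onset infections (HOIs) by analogy: hospitalizations with the
infection as the principal diagnosis serve as measurable analogs for the
unmeasurable incremental cost the same infection adds when it arises
during a stay for something else. Four stages:

1. **Cohorts.** Per infection type and coding dialect, records are
   classified from the ordered diagnosis fields: principal (first code
   in the catalog), secondary (catalog code in a later field, first code
   not in the catalog, LOS ≥ 3 days), or neither. The 3-day floor
   excludes short stays that are unlikely to harbor a hospital-onset
   event. A record that is principal for one type may independently be
   secondary for another; within a type, a principal record never also
   counts as secondary. Catheter-associated UTI and
   ventilator-associated pneumonia are flagged by the conjunction of a
   diagnosis code and the corresponding procedure code; bloodstream
   infections are kept as a single combined type because line-insertion
   coding is too unreliable to split them. A 5:1 no-infection comparison
   group is drawn by exact stratification on the secondary group's
   principal diagnosis codes, sampling without replacement among pool
   records carrying no infection code of any type; stratum shortfalls
   are reported, never back-filled. The matched group is descriptive
   only — it supports the ordering diagnostic, not the estimation.
2. **Stage 1.** Median regression of cost on nine covariates plus
   intercept, fitted on the principal cohort.
3. **Stage 2.** The fitted linear predictor applied to every secondary
   record with LOS replaced by the principal cohort's mean LOS
   (the attributable LOS), averaged over the cohort.
4. **National totals.** Mean attributable costs, inflated to a common
   currency year, times central/low/high incident-case counts, summed
   into device-associated and nondevice subtotals and a grand total.

Key assumptions: treatment resources for a given infection are similar
for community-onset and hospital-onset episodes (in both directions —
the comorbidity cost structure transfers too); secondary-coded
infections proxy hospital onset despite some misclassification; costs
are linear in the covariates at the median. The design requires the
secondary group to have strictly higher mean cost and LOS than both
comparison groups (otherwise economies of scope would break the
analogy); `reporting.ordering_holds` checks exactly that.

No survey weights are applied anywhere: the framework operates on raw
case counts, and all means are unweighted.

## Stage-1 solver

The τ = 0.5 quantile regression is posed as the exact LP
`min 1'u + 1'v  s.t.  Xb + u − v = y, u, v ≥ 0` and solved with HiGHS
via `scipy.optimize.linprog` (sparse constraint matrix; ~6 s at
n = 10⁴, p = 10). Any L1 minimizer is acceptable: with ties or
degeneracy the optimum can be non-unique, so comparisons (including the
brute-force enumeration oracle in the tests, which tries every exact-fit
hyperplane through as many points as parameters) are made on the
objective, never on coefficients. A vertex interpolating more points
than parameters sets `nonunique_hint` — a cheap degeneracy heuristic,
not a certificate. Rank deficiency is detected before solving and the
collinear columns are named. Standard errors and 95% intervals are
nonparametric case-resampling bootstrap percentiles; no asymptotic SEs
are offered, and no claim is made that bootstrap SEs match any
published standard errors whose method is unstated.

## Stage-2 conventions

The functional form is the full linear predictor *including the
intercept*, with facility dummies and all non-LOS covariates taken from
each secondary record. This reconstruction is validated numerically: at
the published 2011 secondary-group covariate means it reproduces the
published decomposition ($1324.03 × 3.83 = $5,071 LOS component; non-LOS
remainder within 0.5% of $6,230 at plausible facility-dummy shares),
whereas intercept-free or difference-based alternatives miss by > 30%.
Because the facility-dummy shares are unpublished, the reconstruction is
only bounded: the extreme all-small-hospital corner deviates 5.4% from
the published mean; realistic shares (urban-teaching ≈ 0.55,
small-bedsize ≈ 0.2) stay within 3%.

Negative per-record predictions are retained — the estimand is the mean,
and flooring would bias it upward. The decomposition identity
`los_component + other_component = mean` holds to the cent before any
rounding. Full precision is kept throughout; published tables round the
LOS coefficient to whole dollars before multiplying, which is why the
package reports the 2016 LOS component as $6,260 (1476.475 × 4.24)
where $6,258 (1476 × 4.24) appears in print. The wage-index
counterfactual uses linearity: shifting the mean by
`b_wage × (w_new − w̄)` is identical to re-running every record at the
new wage index, and a test verifies that equivalence.

## Costing and aggregation

Cost is `charges × CCR` per record; records with missing or
non-positive CCR are excluded and counted. Inflation is a single
multiplicative factor per (from-year, to-year) pair; the bundled
defaults (2011→2017 = 1.0921, 2016→2017 = 1.0226) are the common ratio
implied by the paired cost columns of the bundled reference tables,
consistent across all 16 infection rows to ±0.001. Aggregation refuses
to mix currency-year tags. Burden counts are multiples of 100 (ties
rounded away from zero); device/nondevice splits are rounded from
unrounded intermediates independently, so the parts need not re-sum to
the rounded total. Reproduction mode multiplies printed (rounded) costs
by printed burdens and therefore matches printed totals only to ~0.1%;
pipeline mode keeps full precision and is exactly additive. Money is
rounded to whole dollars (and billions to three significant figures)
only at report boundaries. Univariate tables compute the mode on
dollar-rounded values with ties broken toward the smallest value — a
declared convention, since the original convention is unknowable.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, not any
real population: one row per hospitalization with ordered diagnosis
fields (25 for ICD-9 layouts, 30 for ICD-10), procedure fields, and the
nine model covariates. Costs follow
`max(floor, (b'x)·ε)` with ε log-normal, median exactly 1, so the
conditional median equals the linear index and the generating
coefficients are recoverable by median regression — the generator is its
own oracle. Charges are emitted as `cost / CCR` and the stored cost is
the bit-exact product `charges × CCR`, making the downstream conversion
exactly invertible (CSV I/O uses round-trip float formatting).

The LRTI fixture uses the published 2011/2016 stage-1 coefficients as
ground truth and targets the published group means: principal-group
LOS 3.83/4.24 days, secondary-group covariates inflated by strictly
positive additive shifts (LOS +6.5/+6.1 days, +6.8/+8.7 diagnosis
codes, …), no-infection pool at the published matched-group means.
Facility shares (urban-teaching 0.55, small-bedsize 0.20) and the CCR
range (0.20–0.65) are typical discharge-data magnitudes chosen once.
Count covariates are shifted Poissons, the 1–4 indices are
`1 + Binomial(3, ·)` with exact means, age and wage index clipped
normals. The cost floor defaults to $31, the smallest observed cost in
the reference univariate table.

The default noise scale is σ = 0.02. This is deliberately small: the
generator's stated design goal is that *all ten* coefficients be
recoverable within ±5% from ~10⁴ principal records, and the binding
constraints are the small-magnitude coefficients (age ≈ $2.3/year,
mortality risk ≈ $104) whose median-regression sampling error under
realistic cost noise (σ ≈ 0.5–1) exceeds 5% by an order of magnitude at
that n. The log-normal shape keeps the disturbance right-skewed at any
σ; users wanting realistic dispersion should raise σ and expect
recovery only of the large coefficients (LOS, procedures, wage index).
Consequently, passing recovery tests show the estimator and plumbing are
correct, not that real NIS fits would be this precise. Other realism
gaps, by construction: no survey weights, no hospital-level clustering
or state composition, no within-hospital cost-accounting differences,
covariates drawn independently rather than with NIS's correlation
structure, and invented filler/underlying-disease code pools (only the
LRTI catalog is real; device procedure codes are placeholders).

## Problem sizes and tolerances

Test and acceptance runs use 10⁴–4×10⁴ synthetic records (≈10⁴
principal records for recovery), bootstrap B in the tens to low
hundreds, and 25 small instances per arity for the LP-vs-enumeration
oracle — sizes at which every check is exact or comfortably inside its
tolerance while the full suite runs in well under a minute plus ~40 s
for the recovery fits. Determinism: every stochastic step (generation,
matching, bootstrap) takes an explicit integer seed and is bit-for-bit
reproducible.

## Known limitations

* The stage-2 functional form is a numerically validated reconstruction;
  the original model statement (in particular the intercept's presence
  and the dummies' source) is not printed anywhere recoverable.
* Secondary-diagnosis cohorts inevitably contain community-onset and
  non-confirmed infections; the framework accepts this misclassification
  as the price of administrative data.
* Reproduction-mode totals inherit the rounding of their printed inputs;
  agreement is tolerance-based by design.
* The bundled catalog covers one infection type fully (LRTI); all other
  types ship as synthetic toy code sets, and real multi-type analyses
  must supply their own catalogs.
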