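# Methods

## Data model

The unit of analysis is the calendar month.  Daily inputs (pollutant
concentrations in µg/m³, CO in mg/m³; air pressure hPa; temperature °C;
relative humidity %; precipitation mm/day; wind speed m/s; visibility km;
outpatient-visit counts) are aggregated to months by arithmetic mean over
observed days, except precipitation, which is accumulated into a monthly
total.  The outcome is the *normalized monthly index*: the percentage of a
year's DED visits occurring in each month.  It sums to 100 within a year by
construction, removes inter-year level shifts (caseload growth, catchment
changes), and is the response for every downstream model.

Missing handling: monthly means use available days only; months with fewer
than 20 observed days (configurable) are set missing rather than estimated,
and no gap imputation is performed.  Cleaning flags rather than drops:
range violations (negative concentrations, humidity outside [0, 100]) are
set missing and counted; a per-column z-score rule (default k = 4) flags
monthly outliers; whole months can be excluded with a recorded reason —
February 2020 (hospital lockdown) is excluded by default because the visit
series that month does not measure DED incidence.  Partial years keep their
index computed over observed months and are marked partial rather than
extrapolated.

## Grey relational analysis

Series are first made dimensionless; the default is mean-value normalization
(divide by the series mean), with initial-value and min–max offered.  With
deviations Δ_i(k) = |x₀′(k) − x_i′(k)|, the coefficient is
ξ_i(k) = (Δmin + ρΔmax)/(Δ_i(k) + ρΔmax) and the grade is the mean over
time points; ranks order grades decreasingly with ties broken by the fixed
factor order (pollutants before meteorology).  Defaults — ρ = 0.5 (the
standard convention), mean-value normalization, Δmin/Δmax taken globally
over all factors and months — were fixed once because they reproduce the
published ranking on the packaged climatology (air pressure first, air
temperature last); every convention is configurable and echoed in output,
and `sensitivity_sweep` reports whether the ranking is stable across a
ρ/normalization grid.  Mean-value normalization is applied as-is to series
with negative entries (temperature: mean 7 °C > 0 here); min–max is the
escape hatch for series whose mean could vanish.

Two caveats are inherent and documented rather than patched.  First, the
published coefficient table cannot be matched cell-for-cell from the
published (rounded) monthly means: the best standard convention reaches
about 71% of cells within ±0.05, and no choice of ρ, scheme or delta scope
does better, because the original computation used unrounded per-year
series that were not deposited.  Second, grades reward closeness of
*normalized* shape: a factor with a small relative seasonal amplitude (air
pressure varies by ±1% of its mean) is structurally favoured over one with
a huge relative amplitude (temperature spans −13 to +24 around a mean of
7), which is exactly why temperature ranks last in both the published table
and this implementation.

## Association models

Pearson correlations are computed pairwise-complete with two-sided p-values
from t = r√((n−2)/(1−r²)); constant columns are reported as undefined, not
as zero, and the correlation screen is explicitly unadjusted for multiple
testing.  Stepwise selection is forward entry by smallest partial-F p-value
(entry p = 0.05) with backward pruning (stay p = 0.10), ties resolved by
the fixed factor order; the final term set is refit by OLS and VIF-checked.
An intercept-only outcome is a legitimate result, not an error.  The model
family is linear regression on the percentage index — the reported
multivariate equation in the source analysis is linear despite being
labelled logistic, and the discrepancy is carried in the model card's
notes.  With three independent candidates the null probability of an
intercept-only model at entry p = 0.05 is 0.95³ ≈ 0.857 (each candidate's
entry test is marginal at level 0.05); the test suite checks the simulated
null rate against this analytic value with a binomial band.

## Regression tree

CART with greedy variance-reduction splits; thresholds are midpoints of
consecutive distinct values; growth stops at max depth 4, minimum leaf 3
(sized for ~60 monthly rows), or zero residual variance.  The split search
is deterministic: strictly larger gain wins, and at ties the first
candidate encountered — earliest factor in the given order, then lowest
threshold — is kept, so identical data always reproduce identical trees.
Importance is the normalized per-factor sum of weighted impurity decreases
(the convention behind published importance percentages); a seeded
permutation importance is available as a diagnostic.  The 70/30 split is
chronological (earliest ⌈0.7n⌉ rows train) because the evaluation is a
forecast of the latest months; a seeded random split exists for comparison
only.  The default factor set is the seven screened dominant factors (AT,
PM10, O3, AP, WS, CO, NO2).

## Synergy surfaces

Joint effects of factor pairs on the index are modelled as full quadratic
surfaces fit by least squares.  R² and the overall F-test against the
intercept-only model quantify the joint association; the interaction
coefficient b₅ with its t-test quantifies synergy proper, since a claim of
"combined impact" needs a statistic for the cross term.  The reported
surface maximum is the argmax over a 50×50 grid clipped to the convex hull
of the observed points — never an extrapolated stationary point.  Default
pairs: PM10×AT, PM10×AP, NO2×AT, NO2×AP.

## PM2.5 speciation

Hourly ions (SO4, NO3, Cl, NH4, Ca2+, K+), element Ca, OC/EC and total
PM2.5 are validated (negatives flagged to missing) and checked for mass
closure: hours whose component sum exceeds the total by more than 15% (a
typical closure slack) are flagged but kept.  Ion Ca2+ (ion chromatography)
and element Ca (ICP-AES) are distinct columns and never merged.  Monthly
means feed the same single Pearson implementation used for the factor
screen, so shared inputs give identical numbers.  Component shares are
reported as percent of total PM2.5 mass (component mean / PM2.5 mean ×
100).

## Synthetic generator

The generator emulates the structure the analyses assume:

* **Seasonality** — the tabulated monthly climatology itself.  A one/two
  harmonic representation was evaluated and rejected: its residuals exceed
  the published monthly SDs for NO2, O3 and WS (one WS month has a printed
  SD of 0.0), so no harmonic generator can stay within one SD of the
  climatology for 10 of 12 months, which is the calibration this package
  holds itself to.
* **Interannual anomalies** — independent per-(year, month) Gaussian draws
  with the published monthly SDs (these SDs *are* interannual dispersions
  of monthly means).  Without them all factors are collinear seasonal
  curves and no selection method could attribute effects; with them the
  generator matches the published "mean ± SD" structure.
* **Daily noise** — stationary AR(1) with φ = 0.6 and marginal SD equal to
  the factor's mean published SD (the only published dispersion scale;
  visibility, which has none, uses 15% of its mean).  Nonnegative factors
  are clipped at zero.
* **Outcome** — daily visits ~ Poisson(exp(β₀ + Σ βⱼxⱼ)), optionally
  negative-binomial.  Defaults: β(PM10) = 0.014, β(AT) = 0.020,
  β(O3) = −0.008 per unit, β₀ set for 8 visits/day at mean exposures.
  These were chosen once, at design time, to give seasonal index swings
  comparable to the observed 3.2–13.3% range, with PM10 the dominant
  standardized effect (a temperature-dominant plant can never lead a GRA
  ranking, for the normalization reason above).  A log-rate above 30 is
  rejected as a configuration error rather than risked as overflow.

What passing synthetic tests do *not* show: real monthly anomalies are
cross-correlated (weather drives pollution), visit counts carry day-of-week
and holiday structure, and exposure–response may be lagged (explicitly out
of scope).  Recovery rates measured here are therefore best-case for the
estimators, not field performance.

## Problem sizes and numerical choices

Simulation-backed checks use the sizes stated with each test: 60 monthly
rows (5 simulated years), 100 seeds for stepwise recovery and the
end-to-end pipeline, 50 for tree-importance ranking, 200 for the surface
F-test size and correlation calibration.  Printed-table comparisons round
half away from zero to the printed precision and accept one unit in the
last printed digit, because the fixture's inputs are themselves rounded
(averaging the printed monthly means gives PM2.5 = 40.67 against a
published 40.6 computed from daily data).  Equality oracles (vectorized GRA
vs double loop, tree vs exhaustive recursion, surface vs normal equations)
use 1e-12/1e-9 absolute tolerances.  CSVs are written with 17 significant
digits and read with round-trip float parsing so tables survive write/read
bit-exactly.

## Known limitations

Single-city, single-hospital design assumptions are inherited: the index
normalizes within years, so effects that shift a whole year's caseload are
invisible.  No distributed-lag modelling, no case-crossover design, no
source apportionment, no spatial structure.  The grey-relational and
published-table comparisons are bounded by the rounding of the deposited
tables, as described above.
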