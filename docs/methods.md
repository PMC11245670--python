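# Methods

`lrspipe` quantifies associations between stressors a dairy cow
experiences during gestation and the lifetime resilience of the calf
she is carrying. This note describes the models and procedures the
package implements, the choices made where the design was genuinely
open, and what the bundled synthetic-herd generator does and does not
emulate.

## Lifetime resilience score (LRS)

Resilience is scored per cow as the cumulative result of her ability to
recalve, with corrections relative to her herd:

```
LRS_i = C̄Int + 300·L_i + (730 − AFC_i)
        + Σ_{j=1..L_i−1} (C̄Int_j − CInt_{i,j})
        + Σ_{j=1..L_i} [ Σ_k MY_{i,j,k} / Σ_k M̄Y_{j,k} − 1 ] × 100
        + min(0, DIM_{i,L_i} − 100)
```

with `C̄Int` the herd mean calving interval over all selected years,
`L_i` the exit lactation, `AFC_i` the age at first calving in days
(reference 730 d), `CInt_{i,j}` the j-th calving interval against the
herd mean for that transition, the yield term comparing the cow's
summed daily milk against the herd-average daily curve over days
`k = 1..max(305, DIM_{i,j})` of each lactation, and a penalty for
exiting the herd before 100 days in milk.

Implementation decisions:

* **Daily yields come from fitted lactation curves.** Monthly test-day
  recordings cannot supply daily sums, so `MY_{i,j,k}` is the cow's
  fitted curve evaluated at day k (floored at 0 kg), and the herd
  average `M̄Y_{j,k}` is the mean of the fitted curves of all selected
  cows in lactation j. For lactations longer than 305 d the curve is
  extrapolated to the end of the lactation.
* **The yield-term denominator** is the herd-average daily-yield sum,
  matching the component's verbal definition ("the percentage that the
  305-d milk yield is higher or lower than the herd average").
* **DIM at the end of lactation j** is the calving interval for
  non-final lactations and exit date − last calving for the final one;
  a missing exit date falls back to the last milk-recording date + 1 d
  and is flagged.
* **Cows with a non-converged curve in any lactation** get a missing
  LRS (counted) and are excluded from the herd averages; this mirrors
  the shrinking selection counts of commercial datasets where cows with
  zero yield in a non-final lactation are removed.
* Herd averages are computed over all selected cows and years, per farm
  (or per farm × subherd for research herds split by feed trial and
  genetic line). They are not time-varying.

A herd-average cow therefore scores exactly `C̄Int + 300·L`, each
completed lactation is worth exactly 300 points, the AFC component
crosses zero at 730 d, and the exit penalty activates strictly below
100 DIM — these identities are asserted in the test suite and
recomputed by `scripts/acceptance.py`.

## Lactation model

Daily yield is modelled with the four-parameter MilkBot curve
`y(t) = scale·(1 − e^((offset−t)/ramp)/2)·e^(−decay·t)`
fitted per cow-lactation by bounded least squares (analytic Jacobian,
data-driven starts `scale ≈ 1.2·max yield, ramp 25 d, offset −5 d,
decay 0.002 /d`, up to 3 jittered restarts). Records enter the fit only
for DIM 0–305 and yield > 0; fewer than 4 usable records with 4
distinct DIM values give a non-converged fit. Nonlinear fits on ~10
monthly points are fragile, hence the multi-start policy; a Wood-curve
fallback (`a·t^b·e^(−ct)`) is available for robustness comparisons.
The 305-d yield is the sum of predicted daily yields over days 1..305,
with predictions floored at 0. Cows with a non-converged lactation are
dropped from scoring (the `drop-cow` policy), consistent with the
cleaning cascade's monotone counts.

## Thermal exposure

Daily station summaries supply maximum temperature T and dewpoint DP
(°C). Minimum relative humidity uses the Magnus form
`RH = 100·exp(17.625·DP/(243.04+DP)) / exp(17.625·T/(243.04+T))`
(records with DP > T are physically inconsistent and clamped to 100%,
counted), and the maximum temperature-humidity index is
`THI_max = 0.8·T + RH/100·(T − 14.4) + 46.4`. The humidity term
vanishes at T = 14.4 °C, giving the fixed point THI = 57.92.

Station-years missing more than 10% of calendar days (strict >, leap
years handled) are dropped for multi-herd data; single-station
research-herd data keep but flag them. Farms are matched once to their
nearest station by haversine distance on a spherical Earth. Window
exposures are arithmetic means of THI_max over closed date intervals;
days missing from the record are simply absent from the mean. The
dewpoint column supplied is used as-is — pairing the daily mean
dewpoint with the daily maximum temperature is an approximation the
upstream data force.

## Gestation windows and features

Conception is estimated as calving − 283 d where insemination dates are
unknown. Exposure windows in days from conception: T1 = −7..94
(including 7 preconception days), T2 = 95..189, T3 = 190..283; they
partition the 291-day span exactly. Per window, the dam's health events
reduce to presence/absence per category (mastitis, lameness,
antimicrobial excluding dry-cow therapy by default, anti-inflammatory),
THI_max to its mean, and milk quality to min/median/max mapped onto
categorical bands. Band convention: ">a–b" is the half-open interval
(a, b], ">b" is (b, ∞), so bands are exhaustive and disjoint, with an
explicit "missing" level when no recording falls in the window. For
research herds, mean BCS maps to under (<1.5) / normal ([1.5, 3.25]) /
over (>3.25) — the text definition is canonical where sources disagree
— and a window is "lame" iff the maximum locomotion score is ≥ 4.
Event categories are treated as independent flags; overlapping
mastitis and antimicrobial records are not de-duplicated.

Free-text treatments are matched to a licensed-product list by the
partial-ratio measure: the shorter case-folded string (length m) is
compared against every length-m substring of the longer by normalised
Levenshtein similarity `100·(1 − d/m)` and the window maximum is taken.
The acceptance threshold defaults to 90/100 and is configurable, with
an audit table of all matches emitted for manual review — the original
workflow checked matches by hand, and the audit file reproduces that
step as a reviewable artifact. Products whose names contain a dry-cow
keyword ("dry cow", "DC") are flagged so dry-cow therapy can be
included or excluded per analysis.

Cow-level features add the pregnancy-number category (2, 3, 4+), the
calf's season of birth (meteorological seasons), and the mother's LRS
centred on the dataset mean. Farm-level features are the mean 305-d
yield of lactations started in the 12 months before the calf's birth
and the mean parity of dams calving on the farm in the birth year.

## Mixed-model analysis

The outcome (offspring LRS) is modelled with random intercepts at farm
and dam level (3-level) or dam level only (2-level), fitted by maximum
likelihood through statsmodels MixedLM. Dam labels are re-coded within
farm so the variance-component design stays small; for nested dams this
is statistically equivalent. The optimizer runs Powell and then
polishes with L-BFGS/CG from the Powell solution, keeping the best
log-likelihood — this reproduces lme4's ML optimum on shared test data
(asserted in the suite to |Δllf| < 0.05).

Forward stepwise selection refits every remaining candidate against the
growing model at each step (candidate P-values are recomputed, not
screened marginally) and admits the smallest joint Wald chi-square
P-value below 0.05; multi-level categorical candidates are tested
jointly across their columns. Within a min/median/max subgroup of a
milk variable at most one member may enter (lowest P); ties break by
declaration order and the full trace is emitted. After main effects,
square and cube terms of selected continuous predictors are tested, and
declared interactions are admitted when significant *and* AIC-reducing.
No multiple-testing correction is applied. Variance explained follows
the marginal/conditional decomposition for mixed models:
`marginal = var(Xβ)/(var(Xβ) + Σσ² + σ²_e)`, conditional adds the
non-residual components to the numerator. Leave-one-group-out CV refits
the selected fixed structure per fold and predicts held-out rows from
fixed effects only (the random effect of an unseen group is zero).
Spearman rank correlations among numeric predictors use
pairwise-complete observations, with constant columns flagged.

## Synthetic-herd generator

The generator emulates multi-farm longitudinal herd exports: pedigree
links over three generations (founder dams, daughters,
granddaughters), monthly milk recording on a per-farm schedule,
free-text treatment events with realistic product names and typos,
sparse and farm-heterogeneous event recording (true events are thinned
per farm-year by a recording-completeness probability), and seasonal
station weather (sinusoidal annual cycle with a latitude gradient,
station-month anomalies, daily noise; the dewpoint depression is drawn
non-negative so dewpoint never exceeds the daily maximum).

Injected in-utero effects act on a **latent resilience scale**:
`r = farm_effect + dam_effect + Σ_w β_w·(x_w − x_ref) + noise`, with
exposures x_w computed from the same weather the pipeline later sees.
The latent is translated into survival (expected exit lactation linear
in r), age at first calving, calving-interval deviations and a yield
multiplier, with shares (0.45/0.15/0.15/0.25) calibrated so one latent
point moves the expected *computed* LRS by about one point. The signal
therefore reaches the analysis only through the actual scoring
function. Defaults follow the published multi-herd conditions: daily
stressor hazards reproducing per-pregnancy proportions of ~0.11
(mastitis), ~0.13 (antimicrobial excluding dry-cow), ~0.02 (lameness
and anti-inflammatory); variance components farm 142.27, dam 81.42,
residual 477.17 score points; injected THI effects −5.18 (T1) and
−5.76 (T3) points per index unit.

What the generator does **not** emulate, and hence what passing tests
do not establish about real data:

* No genetics or breeding values — the dam effect is a plain shared
  intercept; mother-LRS heritability signal is weaker than in reality.
* Survival, AFC and intervals are independent of season and management
  era; real culling policy changes are a major source of farm variance.
* The latent→phenotype mapping rounds the exit lactation and clips the
  yield multiplier, so the realized residual variance exceeds the
  injected 477 and the effective gain is slightly below 1 (mild
  attenuation of injected effects through the full pipeline).
* **Within-herd centring absorbs farm effects.** Because most LRS
  components are deviations from the farm's own averages, much of an
  injected farm-level shift cancels in the computed score; realized
  farm variance is well below the injected 142². Real farm variance
  survives because it enters through channels the score does not
  centre (survival, AFC).
* **Seasonal collinearity.** Window means of THI for T1 and T3 of the
  same pregnancy are strongly negatively correlated (they sit ~6 months
  apart in an annual cycle), and with a modest number of farms the
  random farm effects correlate with farm climate by chance. Both are
  properties of the real design too; they make joint T1+T3 estimates
  at small scale unstable, which is why the recovery tests inject and
  test a single trimester-3 effect.

## Problem sizes and numerical choices

Test problem sizes are chosen from power calculations so that seeded
runs sit well inside their acceptance regions: the direct
model-recovery check uses 50 farms × 100 cows per replicate (exposure
SD 4 index points gives a slope SE ≈ 1.7, so a −5 effect is detected
and covered with ~95% probability per replicate); the full-pipeline
recovery uses 30 farms × 60 founder dams (~1,500 scored offspring
pairs), where the linear THI slope has SE ≈ 1.6. The null-calibration
check uses 200 single-candidate selections at n = 500 and accepts 3–19
entries (±2.5 binomial SD around the nominal 10). All stochastic tests
are seeded; mixed-model fits are deterministic given the data.

Optimisation tolerances: lactation fits use xtol = ftol = 1e-10 with
parameter bounds (scale 0.1–200 kg/d, ramp 0.5–200 d, offset −60–100 d,
decay 0–0.05 /d); mixed models use the statsmodels default convergence
criteria with maxiter 1000 per optimizer stage. Degenerate inputs are
defined failures, not errors: < 4 usable milk records → non-converged
fit; empty exposure window → missing mean; no recording in a window →
"missing" category; a group without calving intervals raises, naming
the group.

## Known limitations

* The estimated conception date (calving − 283 d) ignores gestation-
  length variation (±~7 d), blurring window boundaries for dataset-1
  style data.
* Barn microclimate (shade, ventilation, airflow) is unobserved;
  station THI is a noisy proxy for the animal's exposure.
* The partial-ratio threshold trades recall for precision at 90/100;
  heavily corrupted free text stays unmatched and is retained under an
  explicit `unmatched` category rather than guessed.
* Granddaughter analyses reuse the same machinery but at sharply
  reduced pair counts; at research-herd scale they are descriptive
  only.
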