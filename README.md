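# lrspipe

Lifetime resilience scoring and in-utero stressor analysis for dairy
herds.

Events a cow experiences while pregnant — heat stress, mastitis,
lameness, treatments, perturbations in her milk — can leave lasting
marks on the calf she is carrying ("developmental programming"). This
package provides a tested, reusable pipeline for quantifying such
effects from ordinary herd-management exports: it scores every cow's
lifetime resilience, reconstructs her dam's gestation-window exposures
from health records and weather-station data, and relates the two with
hierarchical mixed models. A synthetic multi-farm herd generator with
known ground truth makes every stage testable without proprietary
data.

It is aimed at veterinary epidemiologists and quantitative dairy
scientists working with longitudinal herd data (calving events,
monthly milk recording, free-text treatment logs) plus daily weather
summaries.

## The score and the model

Each cow's **lifetime resilience score** (LRS) rewards recalving, with
corrections relative to her herd:

```
LRS_i = C̄Int + 300·L_i + (730 − AFC_i)
        + Σ_{j<L_i} (C̄Int_j − CInt_{i,j})
        + Σ_{j≤L_i} [ Σ_k MY_{i,j,k} / Σ_k M̄Y_{j,k} − 1 ]·100
        + min(0, DIM_{i,L_i} − 100)
```

Daily milk `MY` comes from a four-parameter MilkBot lactation curve
fitted to monthly test-day records. Heat-stress exposure uses the
maximum temperature-humidity index
`THI_max = 0.8·T + RH/100·(T − 14.4) + 46.4`, with minimum relative
humidity derived from dewpoint via the Magnus formula, averaged over
gestation windows (T1 = 7 d preconception..94 d, T2 = 95..189,
T3 = 190..283 days from conception). Offspring LRS is then modelled as

```
y_ijk = β0 + β·x + f_k + u_jk + e_ijk,   f ~ N(0, σ²_farm),
u ~ N(0, σ²_dam), e ~ N(0, σ²_resid)
```

fitted by maximum likelihood, with forward stepwise selection (Wald
P < 0.05), polynomial and interaction testing, marginal/conditional
variance-explained, and leave-one-farm-out cross-validation.
See `docs/methods.md` for the full account and `docs/schema.md` for
the CSV schemas.

## Worked example

Simulate a herd, clean it, fit lactations, derive THI, score, build
features and fit the model — either in Python via
`lrspipe.pipeline.run_pipeline(SimConfig(...))` or from the shell:

```sh
lrspipe simulate --out sim --seed 42
#   wrote 614 cows to sim
lrspipe clean --in sim --out cleaned
#   retained 614 cows, 21708 milk records
lrspipe fit-lactations --in cleaned/milk.csv --out lactations.csv
#   fitted 1954 lactations (1939 converged)
lrspipe thi --weather sim/weather.csv --farms sim/farms.csv --out weather_thi.csv
#   8 stations retained; mean match distance 11.6 km
lrspipe score --cows cleaned/cows.csv --calvings cleaned/calvings.csv \
              --lactations lactations.csv --milk cleaned/milk.csv --out lrs.csv
#   scored 598 of 614 cows
lrspipe features --in cleaned --lrs lrs.csv --weather weather_thi.csv \
                 --farm-station farm_station.csv --out features.csv
#   235 feature rows (4 pairs dropped)
lrspipe fit --features features.csv --out model
#   selected terms: ['preg_cat']; marginal R2 0.0239, conditional R2 0.0239
```

Reading the output: 1,939 of 1,954 cow-lactations gave a converged
curve; 598 cows received a score (the rest lack a usable curve in some
lactation); 235 mother–daughter pairs survived the first-pregnancy
exclusion and the herd-year recording filter. At this small
demonstration scale the stepwise search retained only the
pregnancy-number category — detecting the injected THI effects needs
more farms and cows (the test suite's recovery run uses 30 farms × 60
founder dams and recovers the injected −5 points per THI_max unit in
trimester 3 with its 95% CI covering the truth). `model/` holds the
coefficient table, Wald P-value trace, variance components, R² pair
and per-farm cross-validation predictions.

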