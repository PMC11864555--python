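# chumrun

Statistical pipeline for studying how autumn sea-surface-temperature (SST)
regimes shape the migration phenology of Chum salmon (*Oncorhynchus keta*)
at the species' southern distribution limit — the eastern and southern
coastal waters of Korea, six coastal regions (CR1–CR3 north of 37 °N,
CR4–CR6 south of it), October–December runs.

It is written for fisheries and quantitative-ecology analysts who have
daily regional SST series and daily coastal (port) / riverine (weir) catch
counts and want to:

1. **Type each year's SST regime.** From the date each region's daily SST
   first drops strictly below 20 °C (the riverine-migration cue in this
   area), years are classified as **T1** (whole area cools earlier than the
   average year), **T3** (later), or **T2** (the north cools well before
   the south — mean southern crossing anomaly exceeding the northern one by
   ≥ 7 days, regardless of the overall sign).
2. **Compute migration phenology.** The *median date of migration timing*
   (MDMT) is the first day the running cumulative catch strictly exceeds
   50 % of the Oct–Dec total; *coastal residence time* is riverine MDMT −
   coastal MDMT.
3. **Compare mixed-effects model structures by AIC.** Three candidates for
   each response *y* (coastal MDMT or residence days), with SST type *T*
   and region *R*:

   | # | model | notes |
   |---|-------------------------|----------------------------------|
   | 1 | `y ~ T`                 | common timing across regions     |
   | 2 | `y ~ T + (1 | R)`       | random region intercept          |
   | 3 | `y ~ T * R`             | fully regional regime effects    |

   All fits are maximum likelihood (not REML, since the fixed parts
   differ), AIC = 2k − 2·logLik with k counting every estimated parameter
   including variance components, and the lowest AIC wins (ties: smaller
   k, then lower structure number). Contrasts are Wald t-tests with
   n − k_fixed degrees of freedom.
4. **Fit thermal-response curves.** Catch is accumulated into 1 °C SST
   bins, normalized, and regressed on bin-center temperature under three
   families — quadratic polynomial `y = b1 + b2·x + b3·x²`, exponential
   `y = a·e^(bx)`, and logistic `y = L / (1 + e^(−k(x − x0)))` — compared
   by Gaussian-ML AIC (MSE reported alongside, flagged above 0.002). When
   `b3 < 0`, the peak migration temperature is the vertex `−b2 / (2·b3)`.

Because the original catch and reanalysis SST data are not publicly
deposited, the package ships a **synthetic-data generator** with exact
ground truth (logistic autumn cooling ramps with analytic 20 °C crossings,
regime-shifted per region; Poisson catch pulses cued by the climatological
cooling, with a 4-day earlier coastal arrival injected in T2 years;
riverine entry as a thinned, residence-shifted copy of the coastal pulse),
so every stage is validated by parameter recovery.

## Worked example

```python
from chumrun import (make_scenario_preset, simulate_dataset, label_years,
                     phenology_table)
from chumrun.lme import MixedModelSelector

scenario = make_scenario_preset("mixed-13yr", seed=42)   # 3 T1, 5 T2, 5 T3 years
data = simulate_dataset(scenario).data
crossings, labels = label_years(data[data.location == "sst"])
phen = phenology_table(data[data.location == "coast"],
                       data[data.location == "river"], labels)
sel = MixedModelSelector(response="coastal_mdmt").fit(phen)
print(sel.comparison_[["structure", "fixed", "random", "k", "aic", "selected"]])
print(sel.fits_[1].contrasts)       # the random-intercept fit's contrasts
```

prints

```
 structure           fixed           random  k    aic  selected
         1          regime                   4 452.54     False
         2          regime region intercept  5 434.17     False
         3 regime * region                  19 428.39      True

contrast  estimate    se     p marker   tier
   T2-T1    -3.311 1.011 0.002      * p<0.01
   T3-T1    -0.378 1.011 0.710            ns
   T3-T2     2.933 0.876 0.001      * p<0.01
```

Reading this: adding region structure improves on the regime-only model by
~20 AIC points; on this replicate the fully regional model edges out the
random intercept (see `docs/methods.md` on why AIC's preference between
structures 2 and 3 is sensitive to the region-spread-to-residual ratio).
The random-intercept fit estimates that coastal arrival in split-cooling
T2 years is 3.3 ± 1.0 days earlier than in T1 years (the generator
injected 4 days) while T1 and T3 do not differ — the phenological
signature of years in which the north cools well before the south.

The same analysis runs from the shell:

```bash
chumrun run --preset mixed-13yr --seed 42 --out results/
chumrun simulate --preset mixed-13yr --seed 42 --out data/
chumrun type-years --sst data/data.csv --threshold 20 --ns-gap 7 --out results/
```

`run` writes every intermediate (crossings, labels, phenology, binned
volumes, model tables) plus `report.json` with a provenance block; the same
config and seed reproduce the report byte for byte. Exit codes: 0 success,
2 validation failure, 3 fit failure.

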