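# heatrhythm

Heat-load classification and circadian behavior modelling for dairy cattle
monitored with barn climate sensors and activity collars.

## The problem

Dairy cows under heat stress change how they budget their day: panting (heavy
breathing) rises sharply, resting and rumination fall, and the daily timing of
eating, resting and activity shifts toward cooler hours. Precision-livestock
collars report minutes per hour devoted to six behaviors (eating, rumination,
rest, mid activity, high activity, heavy breathing) per animal, and barn
sensors log temperature and relative humidity every few minutes. `heatrhythm`
turns those two data streams into a heat-stress analysis:

1. **THI** — hourly temperature-humidity index from pooled sensor means
   (NRC form), `THI = (1.8·T + 32) − (0.55 − 0.555·RH)·(1.8·T − 26)` with T in
   °C and RH as a fraction (the API takes percent).
2. **Heat load** — `THI_load(t) = Σ THI(t−24 … t−1)`, the accumulated THI over
   the 24 hours preceding hour *t*; hours are classified into quartiles of
   THI_load, with Q1 labelled *no stress* (NS) and Q4 *heat stress* (HS).
3. **Behavior budgets** — per-behavior NS vs HS means ± s.e. and a one-way
   ANOVA (`y_ij = μ + τ_i + ε_ij`, Fisher's F test).
4. **Circadian models** — nonlinear least squares fits of
   `μ + a·sin(2π/24·h + b)` (single daily peak: rest, activity, heavy
   breathing) or `μ + a·sin(2π/T·h + b) + c·cos(2π/T′·h + d)` with free
   periods (multi-peak: eating, rumination), initialized by a deterministic
   brute-force grid search and scored with R² and
   `R²_adj = 1 − ((n−1)/(n−p))(1−R²)`.

Because real collar data of this kind is proprietary, the package ships a
synthetic farm generator (`heatrhythm.simulate`) whose environmental defaults
describe a Mediterranean summer and whose behavior models default to reference
circadian equations fitted on such a farm — so the entire pipeline is testable
end to end.

## Worked example

Simulate a default 14-day study (15 sensors, 40 collared cows, a +5 °C
heatwave over the second week) and run the full pipeline:

```
$ printf 'n_days: 14\nseed: 7\n' > farm.yaml
$ heatrhythm simulate --config farm.yaml --out sim
wrote 60480 sensor readings and 13440 behavior records to sim
$ heatrhythm run --sensors sim/sensors.csv --behavior sim/behavior.csv --out results
report written to results (10 circadian fits)
```

`results/summary.md` then starts:

```
## Heat load
- hours analysed: 336
- THI_load quartile boundaries: 1645.48, 1761.41, 1819.19
- hours per stress class: {'INTERMEDIATE': 156, 'NS': 78, 'HS': 78, 'UNDEFINED': 24}

## NS vs HS behavior comparison (min/h)
       behavior   ns_mean    ns_se   hs_mean    hs_se            f             p
         eating  8.462302 0.091046  8.066511 0.095228     9.024846  2.673920e-03
     rumination 21.889354 0.098473 20.839181 0.087480    63.566192  1.830468e-15
           rest 15.198904 0.082681 12.527578 0.096972   439.415477  2.438915e-94
       activity  7.156429 0.080345  7.413125 0.080322     5.105187  2.388877e-02
heavy_breathing  2.558465 0.054199  5.828571 0.082906  1089.962883 1.912088e-220
```

Reading it: the first 24 hours have no complete heat-load window
(`UNDEFINED`); of the 312 classifiable hours, the coolest quarter (78 h) is
NS and the hottest quarter HS. Every behavior differs significantly between
the regimes, in the direction heat-stress physiology predicts — heat-stressed
hours show about 3.3 more min/h of panting and 2.7 fewer min/h of rest, while
general activity rises. `results/fits.csv` holds the ten circadian fits
(5 behaviors × NS/HS) and `results/curve_<behavior>.csv` the fitted daily
curves with pointwise standard-error bands; the heat-stress panting curve
peaks mid-afternoon (~15:30) and the heat-stress rest curve runs below the
no-stress curve through the whole afternoon.

The same stages are available as library calls (`compute_thi`,
`compute_heat_load`, `classify_stress`, `join_with_stress`,
`comparison_table`, `fit_model` / `CircadianRegressor`, `run_pipeline`) and
as separate subcommands (`thi`, `classify`, `label`, `compare`, `fit`).

## Layout

- `src/heatrhythm/thi.py` — THI, hourly aggregation, heat load, quartiles
- `src/heatrhythm/behavior.py` — collar-log IO and stress-label join
- `src/heatrhythm/compare.py` — group summaries, one-way ANOVA
- `src/heatrhythm/circadian.py` — models, grid search, NLS fits, patterns
- `src/heatrhythm/reference.py` — reference study parameter sets
- `src/heatrhythm/simulate.py` — synthetic farm generator
- `src/heatrhythm/report.py`, `cli.py` — pipeline runner and CLI

See `docs/methods.md` for the modelling assumptions and numerical choices.
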