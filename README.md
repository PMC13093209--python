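# sdmshift

Ensemble species distribution modelling with committee averaging, Jenks
habitat classification, spherical area accounting, and standard
deviational ellipse (SDE) centroid tracking — the full analytical chain
used to ask how a species' suitable range moves between climate periods
(e.g., Mid-Holocene → current → future emission scenarios).

It is written for spatial ecologists and conservation modellers who want
that chain as a tested, scriptable library instead of a desktop-GIS
workflow, and for anyone validating such pipelines: a synthetic landscape
and virtual species generator provides inputs whose correct answers are
known analytically.

## The method

Given presence records and a stack of environmental raster layers on a
common geographic grid (2.5 arcmin by default):

1. **Thinning** — occurrences are cleaned (duplicates, (0,0) sentinels)
   and thinned to one record per grid cell.
2. **Screening** — continuous predictors are greedily reduced until every
   retained pair satisfies |Pearson r| < 0.80.
3. **Modelling** — 10,000 random pseudo-absences join the presences;
   ten algorithms (ANN, CTA, FDA, GAM, GBM, GLM, MARS, MAXENT, RF, and a
   from-definition surface range envelope) are fitted under stratified
   four-fold cross-validation (75% train / 25% test) and scored by AUC
   and the true skill statistic, TSS = sensitivity + specificity − 1,
   maximized over the score threshold τ.
4. **Ensembling** — algorithms with mean TSS > 0.70 contribute all their
   fold models to a committee average: each member votes
   1[score ≥ τ_member] and the ensemble score is the fraction of suitable
   votes, CA(cell) = (1/M) Σ_m 1[s_m ≥ τ_m]. Randomization variable
   importance (1 − r between intact and column-shuffled predictions,
   normalized to sum to 1) and median-profile response curves describe
   the fitted niche.
5. **Classification & areas** — each period's CA map is classified by
   Fisher–Jenks natural breaks into four levels (unsuitable / low /
   moderate / high; two levels for coarse historical periods), with
   breaks recomputed per period; class areas use exact spherical cell
   areas (R = 6371 km) and between-period change is cross-tabulated.
6. **Range dynamics** — the suitability-weighted SDE of the suitable
   cells summarizes each period's range; its center is the distribution
   centroid, and consecutive centroids give displacement (haversine) and
   compass bearing.

## Worked example

A synthetic landscape (120×80 cells at 2.5′) with a temperature layer
declining 1 unit per degree latitude, a virtual species with a sharp
Gaussian niche on that layer, and a +0.5-unit warming scenario:

```python
import sdmshift as s

cfg = s.RunConfig(
    landscape=s.LandscapeConfig(
        n_rows=120, n_cols=80, origin_lon=100.0, origin_lat=35.0,
        layer_specs=[
            s.LayerSpec("temp", trend_slope=-1.0, std=0.4),
            s.LayerSpec("precip"),
            s.LayerSpec("landcov", kind="categorical", n_classes=3),
        ],
        seed=1,
    ),
    species_terms=[("temp", 0.0, 0.5, 30.0)],   # optimum, breadth, weight
    prevalence=0.05, n_presences=150,
    algorithms=["GLM", "GAM", "CTA", "RF", "SRE"],
    n_pseudo_absences=1000,
    periods=[
        s.PeriodSpec("current", k=4),
        s.PeriodSpec("2050s-warm", offsets={"temp": 0.5}, k=4),
    ],
    seed=42,
)
rep = s.run_pipeline(cfg)
```

which prints (via the snippet in `RunReport`'s fields):

```
selected: ['CTA', 'GAM', 'GLM', 'RF', 'SRE']
ensemble TSS 0.894 +/- 0.036, AUC 0.959 +/- 0.018
importance: {'temp': 0.957, 'precip': 0.033, 'landcov': 0.01}
current suitable: 2.74 x 10^4 km^2 (15.75%)
net change: -2.36 pct points
centroid shift: 55.4 km N
```

Read: every algorithm cleared the TSS bar on this easy niche; the
committee identifies temperature as the dominant driver (96% of the
normalized contribution); warming by 0.5 units moves the distribution
centroid 55.4 km north — matching the analytic expectation
ΔT/b · 111.195 ≈ 55.6 km for a trend of b = 1 unit/degree, which is
exactly the kind of ground-truth check the synthetic generator exists
for.

A command-line front end wraps the same pipeline:

```bash
sdmshift run-all config.json --out results/
sdmshift thin occurrences.csv --out thinned.csv \
    --origin-lon 73 --origin-lat 54 --n-rows 864 --n-cols 1488
```

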