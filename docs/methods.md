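# Methods

This note records what `sdmshift` computes, the assumptions behind each
stage, and the choices made where the methodology is conventionally
under-specified.

## Occurrence handling

Occurrences are WGS84 decimal-degree points. Cleaning collapses exact
coordinate duplicates after rounding to 6 decimal places (~0.1 m, the
precision below which two records cannot be distinguished in practice)
and removes records at exactly (0, 0), the classic data-entry sentinel.
Thinning keeps at most one record per grid cell. Cells are half-open —
closed on their west and north edges, `col = floor((lon − lon0)/res)`,
`row = floor((lat0 − lat)/res)` — so a point on a shared boundary belongs
to exactly one cell. Within a cell the first record in input order wins;
the rule is arbitrary but deterministic, and every removed record lands
in a rejects table with a reason, so the filtering is auditable and can
be re-done under a different rule.

## Predictor screening

Collinearity is screened on Pearson correlations computed over **all
unmasked cells** (optionally a seeded sample for very large grids), not
over presence locations: the screen concerns redundancy of the
environment space, not the species' use of it. Elimination is greedy:
while any pair has |r| ≥ 0.80, drop the layer with the most violating
partners, breaking ties by larger mean absolute correlation, then by
later input position. Zero-variance layers are removed first (they have
no defined correlation), and categorical layers never enter the matrix.
The full report (matrix, drop order, reasons) is returned, and a
`retain` list lets users impose an expert choice instead; the greedy
rule is a default, not a claim about which member of a correlated pair
is ecologically preferable.

## Learners

All ten algorithm slots satisfy one contract: fit on labelled predictor
rows, score new rows into [0, 1]. The surface range envelope is
implemented from its definition — suitable iff every continuous
predictor lies inside the central [q, 100−q] percentile interval of the
presence training values, q = 2.5 by default (the conventional 95%
envelope), configurable down to q = 0 (presence min/max). The other nine
are realized with scikit-learn estimators: tree (CTA), random forest
(RF), gradient boosting (GBM), a small one-hidden-layer perceptron
(ANN), logistic regression on linear+quadratic terms (GLM), on
per-variable cubic-spline bases (GAM), on piecewise-linear hinge bases
at quartile knots (MARS), discriminant analysis on a quadratic basis
(FDA), and a presence/background logistic model on a degree-2 polynomial
expansion for the MAXENT slot — the standard logistic surrogate for
maximum-entropy modelling.

Class imbalance against the much larger pseudo-absence set is handled by
weighting so the total presence weight equals the total absence weight
(prevalence = 0.5), the common convention in ensemble SDM platforms.
Estimators whose `fit` takes no sample weights (the perceptron,
discriminant analysis) receive integer-replicated presence rows, which
realizes the same weighting to rounding. Categorical predictors are
one-hot encoded before fitting; the envelope model uses continuous
predictors only.

## Evaluation

"Four-fold cross-validation with 75% training" is implemented as a
disjoint stratified 4-fold partition, under which the 75/25 split arises
exactly; four independent random 75/25 splits are available behind
`make_folds(method="random_split")` as the alternative reading. One
pseudo-absence draw (10,000 by default, uniform over unmasked cells not
holding a presence) is shared across algorithms and folds.

AUC uses the Mann–Whitney form (ties count ½), computed by ranking. TSS
is maximized over candidate thresholds at the midpoints of consecutive
distinct scores plus {0, 1}; prediction is positive iff score ≥ τ, and
the smallest maximizing τ is returned. Both are oracle-tested against
pairwise enumeration and an exhaustive threshold scan.

## Ensemble

Member selection operates at the algorithm level: an algorithm whose
mean TSS across folds strictly exceeds 0.70 contributes **all** its fold
models as members, each carrying its own fold's TSS-optimal threshold.
Committee averaging binarizes each member at that threshold and averages
the votes, so ensemble scores live on the lattice {0, 1/M, …, 1}. The
ensemble's own skill is cross-validated: per fold, only members trained
with that fold held out score the fold's test rows, and the committee
score is then thresholded/ranked like any model's. Reported spreads are
sample standard deviations across folds.

Variable importance follows the randomization convention: for each
member and predictor, the predictor's column is shuffled (10 shuffles by
default, seeded) and the contribution sample is 1 − Pearson r between
intact and shuffled predictions, floored at 0 (a negative value means no
detectable contribution, not a negative one). Means are normalized to
sum to exactly 1; SDs are scaled by the same constant. A member with
constant predictions contributes zeros and is flagged. Response curves
use the median-profile (evaluation strip) method: probe one variable
over its observed range with the others pinned at their median (mode for
categoricals).

## Classification and areas

Habitat classes come from Fisher–Jenks natural breaks: the exact
dynamic-programming minimizer of within-class sums of squared deviations,
run on the **distinct** values with their multiplicities — exact and
fast for committee scores, which take at most M+1 distinct values. Cost
ties resolve toward the smallest upper class. Inputs with more than
10⁴ distinct values are first reduced to a seeded 10⁴-value sample (a
documented approximation that the lattice-valued pipeline never
triggers). Breaks are computed independently for each period; the
four-level scheme labels the classes unsuitable/low/moderate/high in
ascending score order, with "unsuitable" simply the lowest Jenks class —
an explicit floor threshold can be imposed instead by reclassifying the
committee map directly. A constant map has no breaks and is rejected.

Cell areas are exact spherical areas on the R = 6371 km sphere,
A(row) = R²·Δλ·(sin φ_N − sin φ_S), constant along a row. Class areas
and percentages therefore conserve the study-area total to rounding.
Between-period change is a suitable/unsuitable cross-tabulation weighted
by cell area; the headline "net change" is in percentage points of the
study area, with percent-of-prior-suitable-area also emitted under a
distinct name.

## Standard deviational ellipses and centroids

The SDE of a period's range is computed on the centers of all
non-unsuitable cells, weighted by their committee scores (binary weights
are available by passing unit weights). Geometry is solved in a local
equirectangular plane about the weighted mean (x = Δlon·111.195·cos lat̄
km, y = Δlat·111.195 km) — adequate at the ~10² km scale of range
ellipses. The orientation θ (clockwise from north) solves
tan θ = [(Σwx′² − Σwy′²) + √((Σwx′² − Σwy′²)² + 4(Σwx′y′)²)] / (2Σwx′y′);
axis lengths are the rotated weighted standard deviations scaled by √2,
matching the one-standard-deviation ellipse convention of desktop GIS
(the flag `arcgis_scaling=False` restores the unscaled Yuill textbook
definition). When Σwx′y′ = 0 the orientation is taken in the limit of
the formula (θ = 90° if the x-variance dominates, else 0°), and axes are
swapped with θ → θ+90° whenever needed so that σ_major ≥ σ_minor always
names the major axis. Coincident points give a degenerate σ = 0 ellipse.
Axes are oracle-tested against the √2-scaled eigen-decomposition of the
weighted covariance.

Centroid displacement uses the exact haversine great circle (R = 6371
km) with the initial bearing, labelled by 45° compass sectors centered
on the eight compass points.

## Synthetic landscapes and virtual species

The generator emulates the statistical structure a real bioclimatic
stack presents to this pipeline: spatially autocorrelated continuous
fields (moving-average-smoothed white noise; spectral synthesis was
deliberately avoided as unnecessary), exact control of pairwise Pearson
correlations (the smoothed fields are orthonormalized and mixed through
a matrix square root of the target correlation, so the realized
cell-wise correlations equal the targets), an optional linear
latitudinal trend (a temperature analogue, in units per degree), a
per-layer noise amplitude, and categorical patch layers from a
nearest-seed tessellation. Correlation targets apply to the trend-free
components; trends add shared structure that can raise realized |r|.

A virtual species has suitability
p = logistic(β₀ + Σ_v β_v·exp(−(x_v − μ_v)²/2s_v²)); β₀ is calibrated by
bisection (60 iterations, tolerance 0.005) so mean suitability over
unmasked cells hits a target prevalence. Presences are drawn without
replacement with probability proportional to true suitability, at cell
centers — mirroring the one-record-per-cell structure of thinned field
data. Scenario deltas are additive per-layer offsets; for a species
driven only by a layer trending b units/degree, a +ΔT offset moves the
suitability surface poleward by exactly ΔT/b degrees, giving the
centroid machinery an analytic target. Realized pipeline shifts scatter
around that target because the suitable band follows the specific noise
realization; the low-noise regime (noise std ≲ 0.3 of a trend unit)
keeps that scatter within a few percent.

What the generator does **not** emulate: precipitation–temperature
covariance physics, anisotropic or nonstationary autocorrelation,
observation bias in the presences, dispersal limits, or GCM-specific
change patterns. Passing the recovery tests therefore demonstrates that
the pipeline recovers what its own model class can express under clean
sampling — not that any real species obeys these assumptions.

A companion helper builds a deliberately messy raw occurrence table
(within-cell repeats, exact duplicates, impossible coordinates, a (0,0)
sentinel) around a known number of distinct cells, as a synthetic
stand-in for a compiled field/literature dataset; cleaning and thinning
recover the constructed cell count exactly.

## Problem sizes and defaults

Pipeline defaults follow the standard study configuration: |r| < 0.80
screen, 10,000 pseudo-absences, 4 folds, TSS > 0.70 selection, q = 2.5
envelope, 10 importance shuffles, 4 suitability classes (2 for coarse
historical periods), R = 6371 km. The validation suite and the
acceptance script run the same code on smaller instances chosen as the
package's own test sizes — grids of 50×50 to 240×80 cells, 100–150
presences, 500–2,000 pseudo-absences, and 3–10 algorithms per experiment
— which keep every experiment's statistical signal (skill well above the
selection bar, recovery rates at 9–10/10) while completing in seconds to
a few minutes.

## Known limitations

* No spatial-block cross-validation; random folds share spatial
  structure between train and test, which flatters skill estimates on
  autocorrelated data.
* The MAXENT slot is a logistic surrogate, not the standalone
  maximum-entropy implementation with its feature classes and
  regularization path.
* No hyperparameter tuning: each learner runs with fixed, conventional
  settings.
* Ellipse geometry assumes a locally flat Earth about the weighted mean;
  at continental ellipse scales (σ ≫ 10³ km) the equirectangular frame
  distorts.
* Raster I/O is ESRI ASCII only; projections other than WGS84 geographic
  grids are out of scope.
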