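# Methods

This note documents the models, procedures and numerical choices behind the
package: a desk-scale species-distribution-modelling (SDM) study of a
wetland plant (the marsh gentian, *Gentiana pneumonanthe*) driven entirely
by a synthetic climate/terrain system, so that every stage of the analysis —
from daily gridded climate to protected-area change statistics — runs in
minutes and can be tested against known ground truth.

## The synthetic study system

The generator replaces the external data a real study would ingest (daily
downscaled climate ensembles, occurrence databases, protected-area
registers) with a fully seeded simulation. Everything is a pure function of
one `SyntheticConfig`; two runs with the same configuration are
bit-identical.

**Terrain.** Elevation is a gently tilted plane plus 2–4 Gaussian ridges
with seeded centres, widths and amplitudes (default relief ≈ 1200 m over a
100 × 100 km grid at 1 km). The tilt scales with the ridge amplitude so a
zero-amplitude configuration degenerates to a constant plane — a useful
regression probe.

**Geography beyond elevation.** Three smooth Gaussian random fields
(correlation length 10% of the domain) modulate the climate:

* *continentality* widens the seasonal temperature cycle per cell (colder
  winters **and** hotter summers where it is positive);
* *winter moisture* and *summer moisture* scale the wet-season and
  dry-season precipitation separately.

These fields are what keep the four headline indicators (winter cold `It`,
annual moisture `Io`, summer rain `RR_summer`, summer heat `TXX_aug`) from
collapsing onto a single elevation gradient. Real mountain climates have
exactly this property — maritimity and continentality are not functions of
altitude — and the collinearity-screening stage is only a meaningful test
when the generator plants that structure. Because a 100 × 100 km domain
holds only a few tens of independent patches at this correlation length,
independently drawn fields would align with each other (or with elevation)
by chance for an appreciable fraction of seeds; each field is therefore
orthogonalised over cells against elevation and the fields before it, so
the independence is planted exactly for every seed. At the default
configuration the four roles come out mutually |r| < 0.7 and VIF < 5
(measured across ten seeds: max pairwise |r| = 0.65, max VIF = 2.3), while
their close proxies (De Martonne index, annual precipitation, coldest-month
minimum, warmest-month maximum…) sit well above the screening threshold and
must be removed.

**Daily climate.** For each of the 9 ensemble members and each scenario the
generator produces 20 years of daily tasmax/tas/tasmin/pr on a 365-day
no-leap calendar:

* temperature = seasonal profile (monthly anchors interpolated to days;
  coldest in January, warmest in August) × (1 + 0.35·continentality)
  − 6.5 °C/km lapse × elevation + member offset + synoptic (per-day) and
  local (per-day-per-cell) Gaussian noise;
* diurnal half-range 4–6 °C, wider in summer; tasmax/tasmin are tas ± the
  half-range, so the ordering invariant holds by construction;
* precipitation is an occurrence/amount model: wet-day probability 0.25–0.65
  and mean rate 0.6–4.2 mm/day follow the winter weight; amounts are
  exponential; totals are multiplied by the seasonal moisture fields and a
  winter-weighted orographic factor (1 + winter·elevation/2500 m —
  orographic enhancement acts on stratiform winter rain, not on convective
  summer showers, which also keeps summer rainfall from being a mere
  elevation proxy).

Member spread is an additive temperature offset (σ = 0.6 °C) and a
multiplicative precipitation factor (log-σ = 0.08) drawn once per member —
the cheapest structure that makes a 9-member ensemble mean meaningful.

**Scenario.** The perturbed climate adds a uniform ΔT (default +4 °C) to all
temperatures and scales precipitation by 1 + ΔP (default −30%) — a
late-century high-forcing analogue. Random streams are keyed by
(seed, purpose, member) and never by scenario, so baseline and future share
their weather noise exactly; scenario differences are therefore exact
(+ΔT additive, ×(1+ΔP) multiplicative) rather than statistical.

**Ground truth and occurrences.** True suitability is
`logistic(intercept + Σ coef·z(indicator))` over per-stack standardised
ensemble-mean indicators; the defaults weight moisture positively
(`Io`: +2.5) and summer heat negatively (`TXX_aug`: −1.5) with intercept −1,
yielding a strongly bimodal suitability surface concentrated in wet, cool
terrain. 1,000 presence draws select cells ∝ suitability and jitter the
point inside the cell. The generator then *deliberately* injects dirty
records — 5% exact coordinate duplicates, 3 out-of-domain points, 2 records
with missing coordinates — and reports their exact counts, so the cleaning
stage can be tested against a bookkept oracle rather than a heuristic.

**Protected areas.** 1–5 seeded axis-aligned rectangles per designation
(`natura2000`, `ramsar`), strictly inside the grid.

### What the generator does not emulate

Spatial autocorrelation of daily weather beyond the synoptic scalar; frontal
versus convective precipitation; interannual climate modes; observation bias
in occurrence records (sampling is unbiased given suitability); coastline
and real CRS geometry (the grid is a local equal-area km frame, so area
percentages are exact cell-count ratios). A green test suite therefore shows
the *machinery* is correct and that the pipeline recovers a known signal
under controlled conditions — not that any real-data artefact (bias,
autocorrelated residuals, projection distortion) is handled.

## Bio-ecological indicators

Computed per member from daily data, then ensemble-averaged cell-wise
(unweighted, permutation-invariant):

| name | definition | units |
|---|---|---|
| `It` | (T + M + m) × 10; T = annual mean of monthly means, M/m = coldest month's mean daily max/min | – |
| `Io` | 10·Pp/Tp; Pp = precipitation of months with mean T > 0 °C, Tp = those months' mean T in tenths of °C | – |
| `Ic` | warmest − coldest monthly mean | °C |
| `DMI` | annual P / (annual T + 10) | – |
| `RR_summer` | mean annual June–August precipitation total | mm |
| `TXX_aug` | mean over years of August max of daily max temperature | °C |
| `R95PTOT` | % of precipitation from days above the baseline wet-day (≥ 1 mm, ETCCDI) 95th percentile, per-year then averaged | % |
| `TX90P` | % of days above the baseline 90th percentile of all daily tasmax (whole-period percentile, no calendar-day windowing) | % |

plus six generic candidates (annual mean/max temperature, annual
precipitation, coldest-month minimum, warmest-month maximum, wet-day count)
and two topographic ones (`DTM`, `Slope`), for 16 in total. `It`/`Io` are
computed from the period climatology (bioclimatic-normal practice), not
per-year-then-averaged; coldest/warmest months are chosen per cell with ties
broken by earliest calendar month. Cells where an index is undefined (no
month above 0 °C; T ≤ −10 °C; no reference wet days) are set to NaN and
logged, and point rows hitting such cells are dropped.

Note that `TX90P` of the baseline period against its own reference is ≈ 10%
everywhere by construction — a zero-variance column the screening stage
removes immediately (it is also on the manual exclusion list).

**Classification.** Thermotype horizons span upper supramediterranean
[−150, 150) through upper inframediterranean [450, 515); ombrotype horizons
span arid [0.2, 1.0) through hyperhumid [12, 24). All intervals are
lower-inclusive/upper-exclusive (the published tables print shared endpoints
without stating a convention; one had to be fixed). The arid belt's bounds
are not printed in the source tables; the worldwide-classification value
[0.2, 1.0) is adopted. Values outside every interval map to `out_of_table`.

## Occurrence preparation

Cleaning drops records with non-finite coordinates, exact
(species, x, y)-duplicates, and points outside the grid, and reports each
count. Thinning keeps one record per occupied 1-km cell; retention is
deterministic (lowest `source_id`) so tests are exact, with an optional
seeded-random mode matching common thinning tools. Pseudo-absences are drawn
uniformly without replacement from non-presence cells — exactly
ratio × n_presences of them for ratios 1:1, 1:3, 1:5, 1:7, 1:9 — and placed
at cell centres; the exclusion zone is exactly the presence-occupied cells
(plain random design, no buffer). Cross-validation is a stratified-by-label
random 80/20 split repeated 10 times; stratification prevents empty test
strata at extreme prevalence.

## Predictor screening

Pearson first: while any pair has |r| ≥ 0.7, drop one member of the worst
pair — a priority-listed ("pinned") variable survives its partner; otherwise
the variable with the larger mean |r| against the remaining candidates
drops, ties breaking toward the higher-priority name. The priority list
defaults to the four ecologically preferred indicators. Zero-variance
columns (undefined r) drop first. Manual exclusions (`Slope`, `TX90P`)
follow, recorded separately. Finally iterative VIF: VIF_j = 1/(1−R²_j) from
OLS of candidate j on the other survivors with intercept; remove the max
while any VIF ≥ 5; perfect collinearity counts as +∞. Correlations and VIFs
are computed over the 1:1 presence/pseudo-absence table.

## Models and evaluation

Six learners behind one fit/predict contract (probabilities in [0, 1],
deterministic under a seed): GLM = unpenalised logistic regression;
GAM = cubic B-spline basis (6 knots) + ridge-logistic; RF = 100 bagged trees
(min leaf 5); GBM = 100 depth-3 boosted trees (lr 0.1); CTA = one depth-8
tree; MARS = hinge basis at 5 interior quantile knots per predictor +
ridge-logistic. Hyperparameters are pinned, not tuned per run. Every
algorithm × pseudo-absence set × CV repeat is fitted on that repeat's train
rows (6 × 5 × 10 = 300 models at the default), and scored on both blocks
(calibration = train, validation = test) with five metrics.

TSS, CSI and BIAS are threshold-dependent and are reported at the optimal
cutoff over the grid {0.000, 0.001, …, 1.000}: maximum for TSS/CSI, closest
to the unbiased value 1 for BIAS; the record stores the cutoff and the
sensitivity/specificity achieved there. AUC is the rank statistic (ties
count ½).

**Continuous Boyce index.** 101 overlapping windows, each spanning 10% of
the *background probability mass* (the window edges are defined through the
background prediction ECDF); per window, F = (fraction of presence
predictions inside)/(fraction of background inside); the index is the
Spearman correlation of F with the window midpoint. Defining windows on the
quantile rather than the raw-value scale makes the index exactly invariant
under any strictly increasing transform of the predictions — the property
that justifies calling it a rank-based metric — and guarantees no window is
empty however skewed the model output. During cross-validation the
background is the model's own pseudo-absence table and the presences are the
test-block presences; at projection time the background is the full raster.

Two caveats, verified by simulation and reflected in the tests: (i) a
perfectly calibrated model scores ≥ 0.95 with these windows, but (ii) under
the null (presences carrying no signal) the index has a *wide* distribution
whose spread does not shrink with sample size — a rank correlation is
blind to the amplitude of window noise, and ~10%-mass windows give only ~10
effectively independent values. Single Boyce values near ±0.3 are therefore
uninformative; only values near 1 (or averages over many models) carry
evidence. Narrower windows would tighten the null at the cost of the
calibrated score and of stability on CV-sized presence sets; the
field-standard 10% width is kept.

## Ensemble, projection, change

Models with validation Boyce > 0.8 (pooled across pseudo-absence sets and
repeats) form the mean ensemble; the projected suitability is the unweighted
cell-wise mean of member probabilities, stored as integers 0–1000. Four
classes partition the scale at 250/500/750 (lower-inclusive; the upper two
are also reported under their synonym names "considerable"/"high" used in
some outputs). Variable importance is permutational: 1 − r(original
predictions, predictions with one column shuffled), averaged over 10
permutations and normalised to percent. Response curves use the
evaluation-strip construction (vary one predictor across its observed range,
others at their table medians).

Binarisation threshold = the smallest value on the 0–1000 grid at which the
Boyce P/E ratio first reaches 1, i.e. where predicted presence density first
matches the background density; if P/E never reaches 1 the TSS-maximising
cutoff is used and logged. For a calibrated model this crossing sits at the
mean background suitability, so the suitable region captures the presence
mass above that mean (~84% under the default study's bimodal suitability
distribution — a distribution-dependent figure, not a universal constant).
The calibration-period threshold is also applied to the future projection so
change maps compare like with like.

Change maps classify each cell as loss (1→0), stable (1→1), gain (0→1) or
never (0→0); percentages are reported on the *total* basis (all cells) and
the *dynamic* basis (loss+stable+gain only, which sums to 100 by
construction). Protected-area reports use cell-centre-in-polygon membership
(exact, testable counts on a toy grid) per designation, with polygons
unioned within a designation so overlaps are not double-counted.

## Problem sizes and determinism

The default study — 100 × 100 cells, 9 members × 2 scenarios × 20 years of
daily data (≈ 2.6 × 10⁹ daily values processed member-streamed), 300 model
fits — completes in roughly 7–10 minutes on one CPU core and under 4 GiB of
memory; unit tests use 5 × 5 × 2-year cubes and 40 × 40 study grids. All
randomness flows from `SyntheticConfig.seed` (sub-streams keyed by purpose
tags), the pseudo-absence/CV seeds, and the learners' `random_state`; reruns
are bit-identical.

## Known limitations

* Pseudo-absence sampling ignores geographic bias; no target-group or
  environmental-profile designs.
* No spatial-block cross-validation, so validation scores inherit the
  optimism of random splits under spatial autocorrelation.
* The Boyce-based binarisation threshold is one operationalisation of a
  "Boyce-optimised" cutoff; other platforms use different rules.
* Variable importance is correlation-based permutation importance on the
  ensemble's own predictions; correlated predictors share credit.
* The synthetic truth is a logistic function of the very indicators offered
  to the models — recovery tests probe machinery, not model realism.
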