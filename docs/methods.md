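# Methods

This note documents the models and procedures implemented in `resurvey`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic-data generator does and does not emulate.

## Study design assumptions

The analysis assumes a *quasi-permanent plot* resurvey design: each
historical plot is known only to lie somewhere inside a potential area;
the resurvey places 3–5 plots at random inside that area (3 below
10,000 m², 4 from 10,000 to 100,000 m² inclusive, 5 above; never fewer
than the number of historical plots sharing the area; minimum spacing the
fourth root of the area in m²). Relocation error therefore inflates
within-area variance but, with random placement, does not bias the
survey contrast. Interval endpoints (exactly 10,000 or 100,000 m²) are
assigned to the middle class, reading the interval notation as inclusive.

## Abundance comparability

Historical records are per-species biomass fractions, resurvey records
percent cover. The biomass→cover map is log–log linear per growth-form
group (graminoid, forb): `cover = exp(a_g + b_g · ln biomass)`, b_g > 0 so
within-group rank order is preserved. The published regression
coefficients belong to a specific calibration campaign and are not
bundled; they enter through configuration and default to the identity
(a = 0, b = 1), which after standardization leaves relative composition
unchanged. Both surveys are then standardized to fractional cover
(`100 · value / Σ values`), which is idempotent and erases the arbitrary
total-cover scale.

Species richness receives the detection correction +0.9 on every resurvey
plot (the visual cover method records on average 0.9 fewer species per
plot than destructive biomass sorting). The correction applies to
richness only — Rao-based metrics, CWMs and cover shares are left
uncorrected, because the overlooked species are predominantly rare and
carry negligible abundance weight.

Taxon harmonization consumes a pre-built synonym/aggregate map
(observed name → accepted name) and sums abundances of taxa mapping to
the same aggregate within a plot. No fuzzy matching or backbone lookup is
attempted; unmapped names pass through with a warning.

## Diversity model

Rao's quadratic entropy `Q = Σᵢ Σⱼ pᵢ pⱼ dᵢⱼ` is used for all three
facets, differing only in the distance matrix:

* **taxonomic** — identity distances (dᵢⱼ = 1 for i≠j), making Q the
  Gini–Simpson index, so taxonomic β runs through exactly the same
  machinery as the other facets;
* **functional** — Gower distances on SLA (mm²/mg), canopy height (m,
  log₁₀) and seed mass (mg, log₁₀). Traits are range-normalized over the
  full analysis pool (union of both surveys), not per plot, so each dᵢⱼ
  is a global constant and β is well defined. Missing traits are handled
  pairwise-available (mean over traits observed in both species); species
  with no trait at all are excluded with a warning. Multiple database
  entries per taxon are averaged on the raw scale before the log
  transform.
* **phylogenetic** — cophenetic distances (sum of branch lengths on the
  tip-to-tip path) from a user-supplied Newick tree; every edge must
  carry a length.

Functional and phylogenetic distance matrices are rescaled by their
maximum over the analysis pool so all dᵢⱼ ∈ [0, 1]; the constant is
logged. This makes the Jost transform `1/(1 − Q)` well defined, placing
diversity on the equivalent-numbers scale on which α/β/γ decompose
additively. Pairwise β between plots is `γ_eq − ᾱ_eq`, with the pooled
community the unweighted mean of the two relative-abundance vectors
(plots are equal-sized). The proportional form `β/γ_eq` is emitted
alongside because percent-change statements are scale dependent; reports
default to the additive form. Note that for arbitrary (non-identity,
non-ultrametric) distance matrices Q is not concave, so additive β can be
marginally negative; under identity distances it is provably
nonnegative and zero only for identical composition.

α-diversity survey contrasts use raw Q (on the [0, 1]-rescaled matrices);
richness is reported separately as the taxonomic α headline.

γ diversity per elevational band is the union richness over one randomly
selected plot per potential area and survey; bands holding more eligible
areas than the band minimum randomly skip the surplus areas so every band
contributes the same number of plots per survey. All selections flow from
the run seed.

## Community characteristics

Community-weighted means renormalize abundances over the species with a
non-missing value and report the abundance coverage alongside; plots with
coverage below a configurable threshold (default 0.8) are flagged rather
than dropped. Community CSR is the abundance-weighted mean of per-species
(c, s, r) simplex coordinates obtained by letter counting on 3-letter
Grime codes; only the 3-letter scheme is supported. Group cover splits
fractional cover between Poaceae, Cyperaceae+Juncaceae (kept separate
from the grasses because of their association with wet grasslands), and
forbs.

## Inference

**Survey contrast.** Linear mixed model per metric, fixed effect survey
(resurvey − historical), random intercept for the potential-area × survey
cell — plots inside one cell are pseudo-replicates of one relocated
community. Fitting is REML via `statsmodels.MixedLM` with a cascade of
optimizers; a singular interaction fit falls back to an area-only random
intercept and is flagged in the output. The p-value uses a t reference
with df ≈ (number of cells − 2), a conservative between-cell
approximation adopted in place of an exact Satterthwaite computation;
in balanced designs the fixed-effect estimate reduces exactly to the
difference of survey means (verified in tests to 1e-8). Metrics may be
transformed (`identity`, `log1p`, `sqrt`, `logit`; default identity,
logged in the output) and percent change is always back-transformed:
`(m_res − m_hist)/m_hist · 100` from the model's marginal means.

**Elevation dependence.** Per-area Δ (resurvey area mean − historical
area mean, areas observed in both surveys only) regressed on elevation by
OLS with adjusted R²; the zero crossing −a/b of the fitted line estimates
the elevation at which the surveys agree.

**Bands.** Areas sorted by elevation are split into 11 bands; when the
count is not divisible, the remainder r is absorbed by the r lowest bands
(277 areas → 26, 26, then nine bands of 25). Band β contrasts fit the
mixed model on all same-survey plot pairs within the band with the
area-pair as random factor; within-area pairs are excluded throughout
because they confound relocation noise with temporal change. Per-band
effects are then regressed on band median elevation. The nationwide β
headline pools every same-survey between-area pair and contrasts the
survey means directly from the vectorized β matrix: at ~10⁵–10⁶ pairs a
random-factor model is computationally disproportionate and the simple
mean contrast estimates the same quantity; the per-band models retain the
area-pair dependence structure.

**Pseudo-turnover.** Per area (≥2 resurvey plots, ≥1 historical): mean
Bray–Curtis between historical and resurvey plots minus mean Bray–Curtis
among resurvey plots. The overall excess is estimated by a mixed model of
all dissimilarities on their type with the area as random intercept; a
positive excess indicates temporal change beyond relocation noise.

No multiple-testing correction is applied. Spatial autocorrelation beyond
the area grouping is not modeled.

## Synthetic-data generator

The generator emulates the hierarchical design at its real scale:
defaults are 277 potential areas evenly spread (with jitter) over
322–2497 m, a 600-species pool, 1–2 historical plots per area, resurvey
plot counts from the area-size rule, and log-uniform area sizes spanning
all three plot-count classes.

Community assembly: each species has a Gaussian elevational occurrence
response (optimum uniform over the extended gradient; niche width
log-normal, median ≈ 350 m) scaled so the latent area community holds ≈40
species; each plot detects latent species independently (≈22 species per
plot, matching small-plot grassland richness). Abundances are log-normal
around a species abundance potential (grasses doubled), historical totals
converted to biomass fractions through the inverse allometric map.
Crucially, each survey cell (area × survey) realizes its *own* latent
community: the resurvey plots cluster at a different random location
within the potential area than the historical plot, which is exactly the
relocation error the design anticipates, and which makes the area×survey
random-intercept model correctly specified (its type-I error is verified
to be nominal in the tests).

Change signals between the cells:

* **species loss** — removal probability per species = intensity(e) ×
  sensitivity / mean sensitivity, clipped to [0, 1], where intensity
  interpolates linearly from `decline_at_low` at 500 m (default 0.38) to
  `decline_at_high` at 2000 m (default 0.11) and is clamped outside;
  sensitivity rises with stress-tolerance and low nutrient affinity.
  The truth record stores each area's occurrence-weighted expected loss.
* **grass inflation** — Poaceae abundance weights × (1 + `poaceae_shift`)
  (default 0.47). The realized change in cover *share* is smaller than
  the raw inflation because shares renormalize within plots.
* **indicator shifts** — an exponential tilt of abundance weights whose
  coefficient vector solves C t = δ against the local abundance-weighted
  indicator covariance C, so correlated indicators (nutrients, mowing
  tolerance, hemeroby) do not compound each other. Defaults: temperature
  +0.19 constant; nutrients +0.50 and mowing tolerance +0.58 at 500 m,
  each declining to zero near 1800 m and changing sign above; hemeroby
  +0.30. The tilt is first-order, so realized shifts and crossing points
  are approximate.
* **detection deficit** — each resurvey plot drops Poisson(0.9) randomly
  chosen species, the method difference the +0.9 richness correction
  compensates.

The phylogeny is a random ultrametric coalescent-style tree in which
confamilial species coalesce shallowly before families join deeply, so
phylogenetic diversity responds to family-composition shifts. A small
fraction of species (2%) is recorded under synonym names in the resurvey
tables, exercising the harmonization step; the emitted synonym map
resolves them.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: spatial coordinates and autocorrelation
(the minimum-distance rule is emitted as metadata only); species
interactions and succession; regional (spatially correlated) extirpation —
species losses are drawn independently per area, so band-level γ declines
are attenuated relative to plot-level α declines compared with real
floras where losses are regionally correlated; observer and seasonal
effects beyond the mean detection deficit; real trait/indicator
covariance structure beyond the few built-in correlations.

## Numerical choices and degenerate inputs

* Distance matrices are validated (symmetry 1e-10, zero diagonal,
  nonnegativity) on every build and symmetrized against rounding.
* `1/(1−Q)` raises for Q ≥ 1 rather than returning infinities; the
  pipeline prevents this by rescaling distances.
* Mixed-model optimizer cascade: lbfgs → bfgs → cg → powell; a fit is
  accepted only with finite fixed-effect standard errors.
* Zero-range traits contribute zero to Gower distances (with a warning);
  all-zero plots, empty selections, one-survey areas, and constant
  elevations raise or are skipped with a log entry as documented per
  function.
* Ties in elevation sorting are broken by area id, keeping band
  assignment deterministic.

## Problem sizes in the test suite

The suite validates exact machinery at full precision (oracle equality to
1e-12) and statistical behavior at deliberately moderate scale chosen for
sharp run times: sign- and recovery-checks use 100-area scenarios with
250–600-species pools, the type-I calibration uses 200 replicates of a
25-area null scenario, and end-to-end runs use 12–100 areas. The
acceptance script runs the full 277-area default scenario. Power at these
sizes was chosen so every asserted effect sits at ≥3 standard errors
under the default configuration.

## Known limitations

* The df approximation for mixed-model p-values is conservative relative
  to Satterthwaite for severely unbalanced cells.
* Additive β can be slightly negative for non-concave distance matrices;
  no ultrametric correction of the functional distance matrix is applied.
* The allometric defaults (identity) understate the graminoid/forb
  correction of real biomass data; supply campaign coefficients for real
  analyses.
* CWM coverage below 1 renormalizes rather than imputes; heavily
  incomplete attribute tables bias CWMs toward well-scored species.
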