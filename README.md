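# resurvey

Statistical tooling for **century-scale vegetation resurvey studies**:
comparing historical grassland plot records with modern resurveys to
quantify change in taxonomic, functional and phylogenetic diversity and in
community characteristics, and to test how that change depends on
elevation.

The package is aimed at vegetation ecologists analysing paired
historical/modern plot data of the "quasi-permanent plot" kind: each
historical plot is relocated only to within a *potential area*, inside
which several modern plots are placed at random, so all inference must be
robust to relocation error. It ships a synthetic-data generator that
emulates this design with configurable, known change signals, so every
stage of the analysis can be validated against ground truth without any
external data.

## The analysis

**Abundance comparability.** Historical plots were measured as per-species
dry biomass fractions, modern plots as visual percent cover. Biomass is
mapped to cover through per-group (graminoid/forb) log–log allometric
regressions, `cover = exp(a_g + b_g ln biomass)`, and both surveys are
standardized to *fractional cover* (plot totals = 100). Because the cover
method overlooks on average 0.9 species per plot relative to lab biomass
sorting, 0.9 is added to every resurvey plot's species richness.

**Diversity.** All three facets run through Rao's quadratic entropy

    Q = Σᵢ Σⱼ pᵢ pⱼ dᵢⱼ,

the expected dissimilarity between two random individuals, with facet
defined by the species-pairwise distance dᵢⱼ: identity distances
(taxonomic; Q is then Gini–Simpson), Gower distances on the
leaf–height–seed traits with log₁₀-transformed height and seed mass
(functional), or cophenetic distances from a phylogeny (phylogenetic).
The Jost correction `1/(1 − Q)` converts Q to equivalent numbers, on which
pairwise β decomposes additively: β = γ_eq − ᾱ_eq, with γ computed on the
pooled pair. γ diversity per elevational band is the union species
richness of one randomly selected plot per potential area and survey.

**Community characteristics.** Community-weighted means of the seven
Landolt indicator values (temperature, light, moisture, reaction,
nutrients, mowing tolerance, hemeroby), Grime CSR strategy coordinates
(e.g. `ssr → c=0, s=2/3, r=1/3`), and cover shares of Poaceae,
Cyperaceae+Juncaceae, and forbs.

**Inference.** Plot metrics are contrasted between surveys with a linear
mixed model (fixed effect: survey; random intercept: potential-area ×
survey cell). Elevation dependence comes from regressing per-area Δ values
(resurvey mean − historical mean) on elevation; the zero crossing −a/b of
a Δ line is the elevation where the surveys agree. β and γ are contrasted
within 11 elevational bands of near-equal size (remainder areas absorbed
by the lowest bands). A pseudo-turnover check compares historical-to-
resurvey Bray–Curtis dissimilarity against the dissimilarity among
resurvey plots of the same area: only the excess reflects temporal change
rather than relocation error.

## Worked example

```python
from resurvey import RunConfig, ScenarioConfig, run_pipeline

bundle = run_pipeline(
    RunConfig(seed=7, scenario=ScenarioConfig(n_areas=30, pool_size=200, seed=7))
)
eff = bundle.survey_effects.set_index("metric")
for m in ("richness", "alpha_functional", "alpha_phylogenetic", "poaceae_pct"):
    row = eff.loc[m]
    print(f"{m:22s} {row['percent_change']:+7.1f}%   p = {row['p']:.2g}")
fit = bundle.delta_fits.set_index("metric").loc["richness"]
print(f"Δrichness = {fit['intercept']:.2f} + {fit['slope']:.5f} · m")
```

prints

```
richness                 -22.6%   p = 4.7e-06
alpha_functional         -11.9%   p = 0.0042
alpha_phylogenetic       -11.7%   p = 8.1e-05
poaceae_pct              +21.4%   p = 0.073
Δrichness = -9.64 + 0.00346 · m
```

Read: in this 30-area scenario the resurvey plots hold 22.6% fewer species
than their historical counterparts, functional and phylogenetic α
diversity are each ~12% lower, grass cover share is up, and the richness
deficit shrinks by ~0.35 species per 100 m of elevation (positive Δ
slope), i.e. lowland grasslands changed the most.

The same pipeline runs from the command line:

```bash
resurvey simulate --seed 1 --outdir sim/          # write a synthetic dataset
resurvey all --seed 1 --scenario --outdir out/    # full analysis, CSV outputs
resurvey all --config run.yaml --outdir out/      # real data via a YAML config
```

Real-data runs take the long abundance table, plot metadata, species
attribute table, Newick tree and optional synonym map documented in
`resurvey.preprocess` / `resurvey.pipeline`.

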