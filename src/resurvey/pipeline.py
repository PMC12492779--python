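"""End-to-end pipeline: raw plot tables → diversity change along elevation.

Stages: taxon harmonization → biomass→cover transformation →
fractional-cover standardization → distance matrices (identity, Gower on
LHS traits, cophenetic) → per-plot metrics (corrected richness, Rao α per
facet, indicator CWMs, CSR, group cover) → survey mixed models, per-area
Δ-vs-elevation regressions, elevational-band β/γ contrasts and the
pseudo-turnover check. All randomness flows from one seed; a manifest
records enough to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .community_metrics import (
    INDICATORS,
    community_csr,
    community_weighted_mean,
    group_proportions,
)
from .distances import (
    DissimilarityMatrix,
    cophenetic_distance,
    gower_trait_distance,
    identity_distance,
)
from .diversity import AbundanceVector, beta_matrix
from .inference import (
    InferenceError,
    assign_bands,
    band_beta_contrast,
    band_gamma_contrast,
    band_trend,
    crossing_elevation,
    delta_by_area,
    fit_delta_elevation,
    fit_survey_lmm,
    pairwise_beta_table,
    pseudo_turnover_check,
)
from .preprocess import (
    HISTORICAL,
    RESURVEY,
    AllometricModel,
    PlotRecord,
    biomass_to_cover,
    corrected_richness,
    harmonize_taxa,
    records_from_frames,
    read_synonym_map,
    standardize_fractional_cover,
)
from .synthetic_data import ScenarioConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)

FACETS = ("taxonomic", "functional", "phylogenetic")


@dataclass
class RunConfig:
    """One pipeline run: either a synthetic scenario or real input paths."""

    seed: int
    outdir: Optional[Path] = None
    scenario: Optional[ScenarioConfig] = None
    abundance_path: Optional[Path] = None
    metadata_path: Optional[Path] = None
    attributes_path: Optional[Path] = None
    tree_path: Optional[Path] = None
    synonym_path: Optional[Path] = None
    allometric: AllometricModel = field(default_factory=AllometricModel)
    transformations: dict[str, str] = field(default_factory=dict)
    n_bands: int = 11
    cwm_coverage_threshold: float = 0.8

    def __post_init__(self) -> None:
        real = [self.abundance_path, self.metadata_path, self.attributes_path,
                self.tree_path]
        if self.scenario is not None and any(p is not None for p in real):
            raise ValueError("give either a scenario or real input paths, not both")
        if self.scenario is None and any(p is None for p in real):
            raise ValueError("real-data runs need abundance, metadata, attributes and tree paths")


@dataclass
class ResultBundle:
    plot_metrics: pd.DataFrame
    survey_effects: pd.DataFrame
    area_deltas: pd.DataFrame
    delta_fits: pd.DataFrame
    band_summary: pd.DataFrame
    band_beta: pd.DataFrame
    beta_trends: pd.DataFrame
    nationwide_beta: pd.DataFrame
    band_gamma: pd.DataFrame
    pseudo_turnover: pd.DataFrame
    pseudo_turnover_effect: pd.DataFrame
    manifest: dict
    truth: Optional[dict] = None


# --------------------------------------------------------------- loading


def _load_records(config: RunConfig):
    if config.scenario is not None:
        ds: SyntheticDataset = generate_dataset(config.scenario)
        synonym = dict(zip(ds.synonym_map["observed_name"], ds.synonym_map["accepted_name"]))
        return ds.plots, ds.species_attributes(), ds.tree_newick, synonym, \
            config.scenario.allometric, ds.truth
    abundance = pd.read_csv(config.abundance_path)
    metadata = pd.read_csv(config.metadata_path)
    attributes = pd.read_csv(config.attributes_path)
    tree = Path(config.tree_path).read_text()
    synonym = read_synonym_map(config.synonym_path) if config.synonym_path else {}
    records = records_from_frames(abundance, metadata)
    return records, attributes, tree, synonym, config.allometric, None


def preprocess_records(
    records: list[PlotRecord],
    attributes: pd.DataFrame,
    synonym: dict[str, str],
    allometric: AllometricModel,
) -> list[PlotRecord]:
    """Harmonize names, convert historical biomass to cover, standardize."""
    if synonym:
        records = harmonize_taxa(records, synonym)
    group_map = dict(zip(attributes["species_id"], attributes["group"]))
    out = []
    for rec in records:
        if rec.abundance_type == "biomass_fraction":
            rec = biomass_to_cover(rec, allometric, group_map)
        out.append(standardize_fractional_cover(rec))
    return out


def _wide_matrix(records: list[PlotRecord]) -> pd.DataFrame:
    species = sorted({s for r in records for s in r.abundances})
    pos = {s: i for i, s in enumerate(species)}
    mat = np.zeros((len(records), len(species)))
    for i, r in enumerate(records):
        for s, a in r.abundances.items():
            mat[i, pos[s]] = a
    mat /= mat.sum(axis=1, keepdims=True)
    return pd.DataFrame(mat, index=[r.plot_id for r in records], columns=species)


def build_distances(
    species: list[str], attributes: pd.DataFrame, tree_newick: str
) -> dict[str, DissimilarityMatrix]:
    """The three facet distance matrices over the analysis pool, on [0, 1]."""
    attrs = attributes.set_index("species_id").loc[species]
    taxonomic = identity_distance(species)
    functional = gower_trait_distance(attrs[["sla", "height", "seed_mass"]])
    if set(functional.labels) != set(species):
        raise InferenceError("species lost to missing traits; supply trait values")
    phylo = cophenetic_distance(tree_newick)
    missing = sorted(set(species) - set(phylo.labels))
    if missing:
        raise InferenceError(f"species absent from the phylogeny: {missing[:5]}")
    phylo = phylo.submatrix(species)
    return {
        "taxonomic": taxonomic,
        "functional": functional.submatrix(species).rescaled(),
        "phylogenetic": phylo.rescaled(),
    }


# ------------------------------------------------------------ plot metrics


def compute_plot_metrics(
    records: list[PlotRecord],
    attributes: pd.DataFrame,
    dms: dict[str, DissimilarityMatrix],
    coverage_threshold: float = 0.8,
) -> pd.DataFrame:
    """Tidy per-plot metric table (plot_id, metric, value, coverage)."""
    wide = _wide_matrix(records)
    attrs = attributes.set_index("species_id")
    fam_map = attrs["family"].to_dict()
    csr_map = attrs["csr"].to_dict()
    ind_maps = {name: attrs[name].to_dict() for name in INDICATORS}

    # Rao α per facet, vectorized over plots
    p = wide.to_numpy()
    alpha: dict[str, np.ndarray] = {}
    for facet, dm in dms.items():
        idx = dm.indices_of(list(wide.columns))
        d = dm.d[np.ix_(idx, idx)]
        alpha[facet] = np.einsum("ij,jk,ik->i", p, d, p)

    rows = []
    for i, rec in enumerate(records):
        base = (rec.plot_id, rec.area_id, rec.survey, rec.elevation)
        rows.append(base + ("richness", corrected_richness(rec), 1.0))
        rows.append(base + ("alpha_taxonomic", alpha["taxonomic"][i], 1.0))
        rows.append(base + ("alpha_functional", alpha["functional"][i], 1.0))
        rows.append(base + ("alpha_phylogenetic", alpha["phylogenetic"][i], 1.0))
        av = AbundanceVector.from_mapping(rec.abundances)
        for name in INDICATORS:
            cwm = community_weighted_mean(av, ind_maps[name])
            if 0 < cwm.coverage < coverage_threshold:
                logger.warning(
                    "plot %s: CWM %s coverage %.2f below threshold",
                    rec.plot_id, name, cwm.coverage,
                )
            rows.append(base + (f"cwm_{name}", cwm.value, cwm.coverage))
        c, s, r = community_csr(av, csr_map)
        rows.append(base + ("csr_c", c.value, c.coverage))
        rows.append(base + ("csr_s", s.value, s.coverage))
        rows.append(base + ("csr_r", r.value, r.coverage))
        gp = group_proportions(av, fam_map)
        rows.append(base + ("poaceae_pct", gp.poaceae_pct, 1.0))
        rows.append(base + ("cypjunc_pct", gp.cypjunc_pct, 1.0))
        rows.append(base + ("forb_pct", gp.forb_pct, 1.0))
    return pd.DataFrame(
        rows,
        columns=["plot_id", "area_id", "survey", "elevation_m", "metric", "value", "coverage"],
    )


# ------------------------------------------------------------ β nationwide


def nationwide_beta_contrast(
    abund: pd.DataFrame, meta: pd.DataFrame, dm: DissimilarityMatrix
) -> dict[str, float]:
    """Percent difference of mean pairwise β between the surveys.

    Pools every same-survey, between-area pair nationwide; computed from
    the vectorized β matrix (a mixed model over ~10⁵–10⁶ pairs would add
    nothing to a simple mean contrast at this size).
    """
    meta = meta.loc[abund.index]
    additive, proportional = beta_matrix(abund, dm)
    surveys = meta["survey"].to_numpy()
    areas = meta["area_id"].to_numpy().astype(str)
    iu, ju = np.triu_indices(len(abund), k=1)
    keep = areas[iu] != areas[ju]
    iu, ju = iu[keep], ju[keep]
    out = {}
    for scale, mat in (("additive", additive), ("proportional", proportional)):
        means = {}
        for survey in (HISTORICAL, RESURVEY):
            mask = (surveys[iu] == survey) & (surveys[ju] == survey)
            means[survey] = float(mat[iu[mask], ju[mask]].mean())
        out[f"beta_{scale}_historical"] = means[HISTORICAL]
        out[f"beta_{scale}_resurvey"] = means[RESURVEY]
        out[f"beta_{scale}_pct_change"] = (
            (means[RESURVEY] - means[HISTORICAL]) / means[HISTORICAL] * 100.0
        )
    return out


# ----------------------------------------------------------------- driver


def run_pipeline(config: RunConfig) -> ResultBundle:
    records, attributes, tree, synonym, allometric, truth = _load_records(config)
    records = preprocess_records(records, attributes, synonym, allometric)
    species = sorted({s for r in records for s in r.abundances})
    missing_attr = sorted(set(species) - set(attributes["species_id"]))
    if missing_attr:
        raise InferenceError(f"species without attributes: {missing_attr[:5]}")
    dms = build_distances(species, attributes, tree)

    metrics = compute_plot_metrics(
        records, attributes, dms, config.cwm_coverage_threshold
    )

    # survey mixed models + per-area Δ regressions, per metric
    effects = []
    deltas_all = []
    fits = []
    for metric, grp in metrics.groupby("metric", sort=True):
        transformation = config.transformations.get(metric, "identity")
        eff = fit_survey_lmm(grp, transformation=transformation, metric=metric)
        effects.append(dataclasses.asdict(eff))
        deltas = delta_by_area(grp)
        deltas_all.append(deltas.assign(metric=metric))
        try:
            fit = fit_delta_elevation(deltas)
        except InferenceError:
            continue
        cross = crossing_elevation(fit)
        fits.append(
            {
                "metric": metric,
                "intercept": fit.intercept,
                "slope": fit.slope,
                "r2_adj": fit.r2_adj,
                "p_slope": fit.p_slope,
                "n": fit.n,
                "crossing_elevation_m": cross,
            }
        )
    survey_effects = pd.DataFrame(effects)
    area_deltas = pd.concat(deltas_all, ignore_index=True)
    delta_fits = pd.DataFrame(fits)

    # elevational bands
    areas = (
        metrics[["area_id", "elevation_m"]].drop_duplicates("area_id").reset_index(drop=True)
    )
    assignment, band_summary = assign_bands(areas, n_bands=config.n_bands)
    band_of = assignment.set_index("area_id")["band"].to_dict()

    wide = _wide_matrix(records)
    meta = pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in records],
            "survey": [r.survey for r in records],
            "area_id": [r.area_id for r in records],
        }
    ).set_index("plot_id")
    meta["band"] = meta["area_id"].map(band_of)

    band_beta_rows = []
    for facet in FACETS:
        for band in band_summary["band"]:
            plot_ids = meta.index[meta["band"] == band]
            pairs = pairwise_beta_table(wide.loc[plot_ids], meta, dms[facet])
            eff = band_beta_contrast(pairs, metric=f"beta_{facet}")
            if eff is None:
                continue
            band_beta_rows.append(
                {"facet": facet, "band": band, **dataclasses.asdict(eff)}
            )
    band_beta = pd.DataFrame(band_beta_rows)
    trend_rows = []
    for facet in FACETS:
        sub = band_beta[band_beta["facet"] == facet].merge(band_summary, on="band")
        if len(sub) >= 3:
            tr = band_trend(sub)
            trend_rows.append(
                {"facet": facet, "intercept": tr.intercept, "slope": tr.slope,
                 "r2_adj": tr.r2_adj, "p_slope": tr.p_slope, "n": tr.n}
            )
    beta_trends = pd.DataFrame(trend_rows)

    nationwide = pd.DataFrame(
        [
            {"facet": facet, **nationwide_beta_contrast(wide, meta, dms[facet])}
            for facet in FACETS
        ]
    )

    # γ per band: equal effort via the smallest number of eligible areas
    rng = np.random.default_rng(config.seed)
    by_band: dict[int, list[PlotRecord]] = {}
    for rec in records:
        by_band.setdefault(band_of[rec.area_id], []).append(rec)
    eligible_counts = []
    for band, recs in sorted(by_band.items()):
        pairs_ok = {
            r.area_id
            for r in recs
            if {HISTORICAL, RESURVEY}
            <= {x.survey for x in recs if x.area_id == r.area_id}
        }
        eligible_counts.append(len(pairs_ok))
    n_target = min(eligible_counts)
    gamma_rows = []
    for band, recs in sorted(by_band.items()):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            g_hist, g_res = band_gamma_contrast(recs, rng, n_target=n_target)
        med = float(
            band_summary.loc[band_summary["band"] == band, "median_elevation_m"].iloc[0]
        )
        gamma_rows.append(
            {
                "band": band,
                "median_elevation_m": med,
                "gamma_historical": g_hist,
                "gamma_resurvey": g_res,
                "pct_change": (g_res - g_hist) / g_hist * 100.0,
            }
        )
    band_gamma = pd.DataFrame(gamma_rows)

    pt_area, pt_effect = pseudo_turnover_check(records)
    pt_effect_df = pd.DataFrame([dataclasses.asdict(pt_effect)])

    manifest = {
        "seed": config.seed,
        "n_plots": len(records),
        "n_areas": int(areas.shape[0]),
        "n_species": len(species),
        "n_bands": config.n_bands,
        "gamma_plots_per_band": n_target,
        "transformations": config.transformations,
        "versions": _versions(),
        "scenario": truth["config"] if truth else None,
    }

    bundle = ResultBundle(
        plot_metrics=metrics,
        survey_effects=survey_effects,
        area_deltas=area_deltas,
        delta_fits=delta_fits,
        band_summary=band_summary,
        band_beta=band_beta,
        beta_trends=beta_trends,
        nationwide_beta=nationwide,
        band_gamma=band_gamma,
        pseudo_turnover=pt_area,
        pseudo_turnover_effect=pt_effect_df,
        manifest=manifest,
        truth=truth,
    )
    if config.outdir is not None:
        write_bundle(bundle, config.outdir)
    return bundle


def write_bundle(bundle: ResultBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.plot_metrics.to_csv(out / "plot_metrics.csv", index=False)
    bundle.survey_effects.to_csv(out / "survey_effects.csv", index=False)
    bundle.area_deltas.to_csv(out / "area_deltas.csv", index=False)
    bundle.delta_fits.to_csv(out / "delta_fits.csv", index=False)
    bundle.band_summary.to_csv(out / "band_summary.csv", index=False)
    bundle.band_beta.to_csv(out / "band_contrasts.csv", index=False)
    bundle.beta_trends.to_csv(out / "beta_trends.csv", index=False)
    bundle.nationwide_beta.to_csv(out / "nationwide_beta.csv", index=False)
    bundle.band_gamma.to_csv(out / "band_gamma.csv", index=False)
    bundle.pseudo_turnover.to_csv(out / "pseudo_turnover.csv", index=False)
    bundle.pseudo_turnover_effect.to_csv(out / "pseudo_turnover_effect.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    if bundle.truth is not None:
        (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))


def _versions() -> dict[str, str]:
    import dendropy
    import scipy
    import statsmodels

    from . import __version__

    return {
        "resurvey": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "dendropy": dendropy.__version__,
    }
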