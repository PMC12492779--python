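"""Synthetic paired historical/resurvey grassland datasets with known truth.

The generator emulates the hierarchical structure of a national grassland
resurvey: potential areas spread along an elevational gradient, each
holding one or more historical plots (destructive biomass sampling,
recorded as biomass fractions) and 3–5 relocated resurvey plots (visual
percent-cover estimates). Species occurrence follows Gaussian elevational
response curves, so community composition turns over with elevation.

Configurable change signals between the surveys:

* an elevation-dependent species loss (extirpation probability per species
  proportional to its intensification sensitivity times an intensity
  factor that interpolates linearly between a low-elevation and a
  high-elevation loss fraction),
* inflation of Poaceae abundance (grass encroachment),
* exponential-tilt shifts of indicator-value composition (e.g. more
  nutrient-demanding communities), optionally crossing zero at a given
  elevation,
* a detection deficit of the cover method (on average 0.9 species per
  resurvey plot overlooked), which the preprocessing's +0.9 richness
  correction compensates.

Every draw flows from one seed; identical configs give identical output.
A truth record stores the realized per-area expected declines so
downstream estimates can be validated against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .community_metrics import INDICATORS
from .preprocess import HISTORICAL, RESURVEY, AllometricModel, PlotRecord

#: reference elevations (m) at which the configured loss fractions apply
DECLINE_REF_LOW = 500.0
DECLINE_REF_HIGH = 2000.0

_FORB_FAMILIES = (
    "Asteraceae", "Fabaceae", "Rosaceae", "Apiaceae", "Ranunculaceae",
    "Caryophyllaceae", "Lamiaceae", "Plantaginaceae", "Orchidaceae",
    "Gentianaceae", "Campanulaceae", "Brassicaceae", "Polygonaceae",
    "Primulaceae", "Scrophulariaceae",
)
_GRAMINOID_FAMILIES = ("Poaceae", "Cyperaceae", "Juncaceae")
_FAMILY_WEIGHTS = {"Poaceae": 0.17, "Cyperaceae": 0.06, "Juncaceae": 0.02}


class ScenarioError(ValueError):
    pass


def plots_for_area(area_m2: float) -> int:
    """Number of resurvey plots for a potential area of the given size.

    < 10,000 m²: 3 plots; 10,000–100,000 m² (inclusive): 4 plots;
    > 100,000 m²: 5 plots. Callers with more historical plots than this in
    an area must raise the count to that floor.
    """
    if not area_m2 > 0:
        raise ScenarioError(f"non-positive area: {area_m2}")
    if area_m2 < 10_000:
        return 3
    if area_m2 <= 100_000:
        return 4
    return 5


def min_plot_distance(area_m2: float) -> float:
    """Minimum distance between resurvey plots: fourth root of the area."""
    if not area_m2 > 0:
        raise ScenarioError(f"non-positive area: {area_m2}")
    return float(area_m2) ** 0.25


@dataclass(frozen=True)
class IndicatorShift:
    """Additive CWM shift of one indicator at the low reference elevation.

    With ``crossing_m`` set, the shift declines linearly with elevation,
    reaching zero at the crossing point (and changing sign above it);
    without, it is constant along the gradient.
    """

    delta: float
    crossing_m: Optional[float] = None

    def at(self, elevation: float) -> float:
        if self.crossing_m is None:
            return self.delta
        return self.delta * (self.crossing_m - elevation) / (
            self.crossing_m - DECLINE_REF_LOW
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the real survey's scale: 277 potential areas between
    322 and 2497 m, a 38% expected species loss at 500 m declining to 11%
    at 2000 m, a 47% relative increase in Poaceae cover share, and
    indicator shifts for temperature (constant) and for nutrients and
    mowing tolerance (declining with elevation, crossing zero near
    1800 m).
    """

    n_areas: int = 277
    elevation_range: tuple[float, float] = (322.0, 2497.0)
    pool_size: int = 600
    decline_at_low: float = 0.38
    decline_at_high: float = 0.11
    poaceae_shift: float = 0.47
    indicator_shift: dict[str, IndicatorShift] = field(
        default_factory=lambda: {
            "temperature": IndicatorShift(0.19),
            "nutrients": IndicatorShift(0.50, crossing_m=1778.0),
            "mowing_tolerance": IndicatorShift(0.58, crossing_m=1816.0),
            "hemeroby": IndicatorShift(0.30),
        }
    )
    noise_sd: float = 0.25
    seed: int = 0
    # structural knobs not fixed by the study design
    hist_plots_min: int = 1
    hist_plots_max: int = 2
    overlook_mean: float = 0.9  # mean species per resurvey plot missed by the cover method
    target_area_richness: float = 40.0  # latent species per potential area
    target_plot_richness: float = 22.0  # detected species per 0.09 m² plot
    alias_fraction: float = 0.02  # species recorded under a synonym name
    allometric: AllometricModel = field(default_factory=AllometricModel)

    def __post_init__(self) -> None:
        if self.n_areas < 2:
            raise ScenarioError("need at least 2 potential areas")
        for frac in (self.decline_at_low, self.decline_at_high):
            if not 0.0 <= frac < 1.0:
                raise ScenarioError(f"decline fraction {frac} outside [0, 1)")
        if self.elevation_range[0] >= self.elevation_range[1]:
            raise ScenarioError("elevation_range must be increasing")
        if self.pool_size < 4 * self.target_plot_richness:
            raise ScenarioError("species pool too small to populate plots")

    def intensity(self, elevation: float) -> float:
        """Expected loss fraction at an elevation (linear, clamped)."""
        return float(
            np.interp(
                elevation,
                [DECLINE_REF_LOW, DECLINE_REF_HIGH],
                [self.decline_at_low, self.decline_at_high],
            )
        )


def null_config(**overrides) -> ScenarioConfig:
    """A no-change scenario: both surveys draw from the same communities."""
    base = dict(
        decline_at_low=0.0,
        decline_at_high=0.0,
        poaceae_shift=0.0,
        indicator_shift={},
    )
    base.update(overrides)
    return ScenarioConfig(**base)


# ------------------------------------------------------------------- pool


def generate_pool(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Species pool with elevational niches, traits, indicators and CSR."""
    n = config.pool_size
    emin, emax = config.elevation_range
    species_id = [f"sp{i:04d}" for i in range(n)]

    fams = list(_GRAMINOID_FAMILIES) + list(_FORB_FAMILIES)
    forb_w = (1.0 - sum(_FAMILY_WEIGHTS.values())) / len(_FORB_FAMILIES)
    weights = [_FAMILY_WEIGHTS.get(f, forb_w) for f in fams]
    family = rng.choice(fams, size=n, p=np.array(weights) / np.sum(weights))
    group = np.where(np.isin(family, _GRAMINOID_FAMILIES), "graminoid", "forb")
    taxon_group = np.select(
        [family == "Poaceae", np.isin(family, ("Cyperaceae", "Juncaceae"))],
        ["Poaceae", "CypJunc"],
        default="Forb",
    )

    span = emax - emin
    optimum = rng.uniform(emin - 0.15 * span, emax + 0.15 * span, size=n)
    niche_width = rng.lognormal(mean=np.log(350.0), sigma=0.4, size=n)
    base_freq = rng.uniform(0.2, 1.0, size=n)
    abund_pot = rng.lognormal(mean=0.0, sigma=0.8, size=n)
    abund_pot[taxon_group == "Poaceae"] *= 2.0  # grasses dominate biomass

    sla = rng.lognormal(np.log(20.0), 0.4, size=n)  # mm²/mg
    height = rng.lognormal(np.log(0.3), 0.7, size=n)  # m
    height[group == "graminoid"] *= 1.3
    seed_mass = rng.lognormal(np.log(1.0), 1.0, size=n)  # mg

    # temperature indicator tracks the elevational optimum (lowland = warm)
    t_cont = 5.0 - 4.0 * (optimum - emin) / span + rng.normal(0, 0.5, n)
    indicators = {"temperature": np.clip(np.rint(t_cont), 1, 5).astype(int)}
    for name in ("light", "moisture", "reaction", "nutrients"):
        indicators[name] = rng.integers(1, 6, size=n)
    # mowing tolerance and hemeroby co-vary with nutrient affinity
    for name in ("mowing_tolerance", "hemeroby"):
        indicators[name] = np.clip(
            indicators["nutrients"] + rng.integers(-1, 2, size=n), 1, 5
        )

    nut01 = (indicators["nutrients"] - 1) / 4.0
    pc = 0.2 + 0.5 * nut01
    ps = 0.2 + 0.5 * (1.0 - nut01)
    pr = np.maximum(1.0 - pc - ps, 0.05)
    probs = np.stack([pc, ps, pr], axis=1)
    probs /= probs.sum(axis=1, keepdims=True)
    letters = np.array(["c", "s", "r"])
    csr = [
        "".join(rng.choice(letters, size=3, p=probs[i])) for i in range(n)
    ]
    s_frac = np.array([c.count("s") / 3.0 for c in csr])

    sens = np.clip(
        0.15 + 0.5 * s_frac + 0.3 * (1.0 - nut01) + rng.normal(0, 0.1, n), 0.0, 1.0
    )

    pool = pd.DataFrame(
        {
            "species_id": species_id,
            "family": family,
            "group": group,
            "taxon_group": taxon_group,
            "elevation_optimum": optimum,
            "niche_width": niche_width,
            "base_freq": base_freq,
            "abundance_potential": abund_pot,
            "sla": sla,
            "height": height,
            "seed_mass": seed_mass,
            "csr": csr,
            "intensification_sensitivity": sens,
        }
    )
    for name in INDICATORS:
        pool[name] = indicators[name]
    return pool


# ---------------------------------------------------------------- dataset


@dataclass
class SyntheticDataset:
    pool: pd.DataFrame
    historical: list[PlotRecord]
    resurvey: list[PlotRecord]
    plot_meta: pd.DataFrame
    tree_newick: str
    synonym_map: pd.DataFrame
    truth: dict
    allometric: AllometricModel

    @property
    def plots(self) -> list[PlotRecord]:
        return self.historical + self.resurvey

    def abundance_long(self) -> pd.DataFrame:
        rows = [
            (r.plot_id, s, a, r.abundance_type)
            for r in self.plots
            for s, a in sorted(r.abundances.items())
        ]
        return pd.DataFrame(
            rows, columns=["plot_id", "species_id", "abundance", "abundance_type"]
        )

    def species_attributes(self) -> pd.DataFrame:
        cols = ["species_id", "family", "group", "sla", "height", "seed_mass", "csr"]
        cols += list(INDICATORS)
        return self.pool[cols].copy()

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.abundance_long().to_csv(out / "abundance.csv", index=False)
        self.plot_meta.to_csv(out / "plot_metadata.csv", index=False)
        self.species_attributes().to_csv(out / "species_attributes.csv", index=False)
        self.synonym_map.to_csv(out / "synonym_map.csv", index=False)
        (out / "tree.nwk").write_text(self.tree_newick)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def _occurrence_probs(
    config: ScenarioConfig, pool: pd.DataFrame, elevation: float
) -> np.ndarray:
    gauss = np.exp(
        -0.5
        * ((elevation - pool["elevation_optimum"].to_numpy()) / pool["niche_width"].to_numpy())
        ** 2
    )
    w = pool["base_freq"].to_numpy() * gauss
    total = w.sum()
    if total <= 0:
        raise ScenarioError(f"no species can occur at {elevation} m")
    return np.clip(w * (config.target_area_richness / total), 0.0, 0.95)


def _removal_probs(
    config: ScenarioConfig, pool: pd.DataFrame, elevation: float
) -> np.ndarray:
    sens = pool["intensification_sensitivity"].to_numpy()
    mean_sens = sens.mean() if sens.mean() > 0 else 1.0
    return np.clip(config.intensity(elevation) * sens / mean_sens, 0.0, 1.0)


def expected_decline(
    config: ScenarioConfig, pool: pd.DataFrame, elevation: float
) -> float:
    """Occurrence-weighted expected fraction of a plot's species lost."""
    q = _occurrence_probs(config, pool, elevation)
    r = _removal_probs(config, pool, elevation)
    return float((q * r).sum() / q.sum())


def _poaceae_multiplier(config: ScenarioConfig) -> float:
    """Resurvey abundance-weight multiplier for Poaceae: 1 + poaceae_shift.

    The realized change in Poaceae cover *share* is smaller than the raw
    inflation because shares renormalize within each plot.
    """
    return 1.0 + config.poaceae_shift


def _tilt_exponents(
    config: ScenarioConfig, pool: pd.DataFrame, elevation: float
) -> np.ndarray:
    """Per-species log abundance-weight tilt realizing the indicator shifts.

    An exponential tilt exp(Σ_k t_k v_ik) changes the CWM of indicator j by
    ≈ Σ_k C_jk t_k to first order, with C the abundance-weighted indicator
    covariance of the local community. Solving C t = δ for the configured
    shift vector δ keeps correlated indicators (e.g. nutrients and mowing
    tolerance) from compounding each other's shift.
    """
    names = list(config.indicator_shift)
    v = pool[names].to_numpy(dtype=float)
    q = _occurrence_probs(config, pool, elevation)
    w = q * pool["abundance_potential"].to_numpy()
    w = w / w.sum()
    mean = w @ v
    centered = v - mean
    cov = (centered * w[:, None]).T @ centered
    cov += 1e-6 * np.eye(len(names))
    delta = np.array([config.indicator_shift[n].at(elevation) for n in names])
    t = np.linalg.solve(cov, delta)
    return centered @ t


def _assemble_plot(
    rng: np.random.Generator,
    config: ScenarioConfig,
    pool: pd.DataFrame,
    latent: np.ndarray,
    detect_p: float,
    weight_tilt: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Detected species indices and their raw abundance weights."""
    detected = latent & (rng.random(len(pool)) < detect_p)
    idx = np.flatnonzero(detected)
    if idx.size == 0:
        # extremely unlikely at the default richness; resample once
        idx = np.flatnonzero(latent)[:1]
    w = pool["abundance_potential"].to_numpy()[idx] * rng.lognormal(
        0.0, config.noise_sd, idx.size
    )
    if weight_tilt is not None:
        w = w * np.exp(weight_tilt[idx])
    return idx, w


def generate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Generate one paired historical/resurvey dataset plus its truth record."""
    rng = np.random.default_rng(config.seed)
    pool = generate_pool(config, rng)
    ids = pool["species_id"].to_numpy()
    groups = pool["group"].to_numpy()
    is_poa = (pool["taxon_group"] == "Poaceae").to_numpy()

    emin, emax = config.elevation_range
    n = config.n_areas
    elevations = np.linspace(emin, emax, n)
    if n > 2:
        jitter = rng.uniform(-0.3, 0.3, n) * (emax - emin) / (n - 1)
        elevations = np.clip(elevations + jitter, emin, emax)
    area_m2 = 10.0 ** rng.uniform(3.2, 5.6, n)
    n_hist = rng.integers(config.hist_plots_min, config.hist_plots_max + 1, n)

    detect_p = min(config.target_plot_richness / config.target_area_richness, 1.0)
    poa_mult = _poaceae_multiplier(config)

    # species occasionally recorded under a synonym in the field
    n_alias = int(round(config.alias_fraction * config.pool_size))
    alias_species = set(rng.choice(ids, size=n_alias, replace=False)) if n_alias else set()

    historical: list[PlotRecord] = []
    resurvey: list[PlotRecord] = []
    meta_rows = []
    truth_areas = []

    for a in range(n):
        area_id = f"A{a:03d}"
        e = float(elevations[a])
        q = _occurrence_probs(config, pool, e)
        r = _removal_probs(config, pool, e)
        # each survey cell realizes its own community: the resurvey plots
        # cluster at a different (random) location within the potential
        # area than the historical plot, so their local species sets are
        # independent draws from the area's occurrence probabilities
        latent = rng.random(len(pool)) < q
        latent_res = (rng.random(len(pool)) < q) & (rng.random(len(pool)) >= r)
        tilt = _tilt_exponents(config, pool, e) if config.indicator_shift else None

        n_res = max(plots_for_area(area_m2[a]), int(n_hist[a]))
        truth_areas.append(
            {
                "area_id": area_id,
                "elevation_m": e,
                "expected_decline": expected_decline(config, pool, e),
                "n_historical": int(n_hist[a]),
                "n_resurvey": n_res,
            }
        )

        for j in range(int(n_hist[a])):
            idx, w = _assemble_plot(rng, config, pool, latent, detect_p, None)
            cover_total = rng.uniform(60.0, 95.0)
            covers = cover_total * w / w.sum()
            biomass = np.array(
                [config.allometric.biomass(c, g) for c, g in zip(covers, groups[idx])]
            )
            fractions = biomass / biomass.sum()
            plot_id = f"{area_id}-H{j}"
            historical.append(
                PlotRecord(
                    plot_id=plot_id,
                    area_id=area_id,
                    survey=HISTORICAL,
                    elevation=e,
                    abundances=dict(zip(ids[idx], fractions)),
                    abundance_type="biomass_fraction",
                )
            )
            meta_rows.append((plot_id, area_id, HISTORICAL, e, area_m2[a]))

        for j in range(n_res):
            idx, w = _assemble_plot(rng, config, pool, latent_res, detect_p, tilt)
            w = w * np.where(is_poa[idx], poa_mult, 1.0)
            # cover-method detection deficit: a few species overlooked
            k = min(int(rng.poisson(config.overlook_mean)), max(idx.size - 1, 0))
            if k > 0:
                keep = rng.choice(idx.size, size=idx.size - k, replace=False)
                keep.sort()
                idx, w = idx[keep], w[keep]
            cover_total = rng.uniform(60.0, 95.0)
            covers = cover_total * w / w.sum()
            names = [
                s + "_syn" if (s in alias_species and rng.random() < 0.5) else s
                for s in ids[idx]
            ]
            plot_id = f"{area_id}-R{j}"
            resurvey.append(
                PlotRecord(
                    plot_id=plot_id,
                    area_id=area_id,
                    survey=RESURVEY,
                    elevation=e,
                    abundances=dict(zip(names, covers)),
                    abundance_type="percent_cover",
                )
            )
            meta_rows.append((plot_id, area_id, RESURVEY, e, area_m2[a]))

    plot_meta = pd.DataFrame(
        meta_rows, columns=["plot_id", "area_id", "survey", "elevation_m", "area_m2"]
    )
    plot_meta["min_plot_distance_m"] = plot_meta["area_m2"].map(min_plot_distance)

    synonym_rows = [(s, s) for s in ids] + [(s + "_syn", s) for s in sorted(alias_species)]
    synonym_map = pd.DataFrame(synonym_rows, columns=["observed_name", "accepted_name"])

    tree_newick = random_family_tree(pool, rng)

    truth = {
        "config": _config_dict(config),
        "expected_decline_at_low_ref": expected_decline(config, pool, DECLINE_REF_LOW),
        "expected_decline_at_high_ref": expected_decline(config, pool, DECLINE_REF_HIGH),
        "poaceae_multiplier": poa_mult,
        "areas": truth_areas,
    }

    return SyntheticDataset(
        pool=pool,
        historical=historical,
        resurvey=resurvey,
        plot_meta=plot_meta,
        tree_newick=tree_newick,
        synonym_map=synonym_map,
        truth=truth,
        allometric=config.allometric,
    )


def _config_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["allometric"] = config.allometric.coefficients
    d["indicator_shift"] = {
        k: {"delta": v.delta, "crossing_m": v.crossing_m}
        for k, v in config.indicator_shift.items()
    }
    return d


# ------------------------------------------------------------------- tree


def random_family_tree(pool: pd.DataFrame, rng: np.random.Generator) -> str:
    """Random ultrametric coalescent-style Newick tree over the pool.

    Confamilial species coalesce at shallow depths before families join at
    deep nodes, so phylogenetic distances respond to family-composition
    shifts (e.g. grass encroachment).
    """

    def coalesce(items: list[tuple[str, float]], scale: float, start: float) -> tuple[str, float]:
        items = list(items)
        depth = start
        while len(items) > 1:
            i, j = sorted(rng.choice(len(items), size=2, replace=False))
            (n2, d2) = items.pop(j)
            (n1, d1) = items.pop(i)
            depth += rng.exponential(scale / max(len(items) + 1, 1))
            merged = f"({n1}:{depth - d1:.6f},{n2}:{depth - d2:.6f})"
            items.append((merged, depth))
        return items[0]

    family_nodes: list[tuple[str, float]] = []
    for fam, members in pool.groupby("family", sort=True):
        tips = [(s, 0.0) for s in members["species_id"]]
        node, depth = coalesce(tips, scale=30.0, start=0.0)
        family_nodes.append((node, depth))
    if len(family_nodes) == 1:
        node, _ = family_nodes[0]
        return node + ";"
    max_d = max(d for _, d in family_nodes)
    root, _ = coalesce(family_nodes, scale=60.0, start=max_d + 50.0)
    return root + ";"
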