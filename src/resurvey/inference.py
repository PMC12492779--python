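"""Statistical layer: survey contrasts, elevation dependence, banding.

The central comparison is historical vs. resurvey plots. Plot-level
metrics are compared with a linear mixed model whose fixed effect is the
survey and whose random intercept is the potential-area × survey cell —
plots relocated inside the same potential area are pseudo-replicates of
one historical location, and the cell-level intercept absorbs that
dependence. Elevation dependence is assessed by regressing per-area
Δ-values (resurvey area mean minus historical area mean) on elevation;
the zero crossing −a/b of such a fit is the elevation at which the two
surveys are expected to agree. β and γ diversity are contrasted within 11
elevational bands of (nearly) equal size. A pseudo-turnover check compares
within-area spatial dissimilarity of resurvey plots against the
historical-to-resurvey dissimilarity: only the excess of the latter over
the former reflects temporal change rather than imprecise relocation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
import statsmodels.api as sm

from .diversity import beta_matrix, bray_curtis
from .distances import DissimilarityMatrix
from .preprocess import HISTORICAL, RESURVEY, PlotRecord

logger = logging.getLogger(__name__)


class InferenceError(ValueError):
    pass


# ----------------------------------------------------------- transformations

TRANSFORMS: dict[str, tuple[Callable, Callable]] = {
    "identity": (lambda x: x, lambda y: y),
    "log1p": (np.log1p, np.expm1),
    "sqrt": (np.sqrt, lambda y: np.square(y)),
    "logit": (scipy.special.logit, scipy.special.expit),
}


@dataclass
class SurveyEffect:
    """Fixed-effect contrast resurvey − historical for one metric."""

    metric: str
    estimate: float  # on the transformed analysis scale
    se: float
    p: float
    df: float
    percent_change: float  # back-transformed, relative to historical mean
    transformation: str = "identity"
    n_obs: int = 0
    n_groups: int = 0
    fallback: bool = False  # True if refit with area-only random intercept


def _fit_mixedlm(y, exog, groups):
    """REML MixedLM fit robust to optimizer breakdowns.

    Tries a cascade of optimizers; returns None if every attempt raises or
    yields non-finite fixed-effect standard errors.
    """
    last = None
    for method in ("lbfgs", "bfgs", "cg", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, exog, groups=groups).fit(reml=True, method=method)
                ok = bool(np.all(np.isfinite(res.bse_fe)))  # caches bse under the guard
        except (np.linalg.LinAlgError, ValueError, OverflowError):
            continue
        last = res
        if ok:
            return res
    return last


@dataclass
class LinearFit:
    intercept: float
    slope: float
    r2_adj: float
    p_slope: float
    n: int


def fit_survey_lmm(
    data: pd.DataFrame,
    value_col: str = "value",
    survey_col: str = "survey",
    area_col: str = "area_id",
    transformation: str = "identity",
    metric: str = "",
) -> SurveyEffect:
    """Mixed model of a plot metric on the survey contrast.

    Fixed effect: survey (resurvey = 1). Random intercept: the potential
    area × survey interaction (independent intercept per cell). Fitted by
    REML; p-value from a t statistic with df ≈ number of cells − 2, an
    approximation in the spirit of Satterthwaite that is conservative for
    the between-cell survey contrast. If the interaction fit is singular
    the model falls back to an area-only random intercept (flagged).
    """
    df = data[[value_col, survey_col, area_col]].dropna()
    areas_both = (
        df.groupby(area_col)[survey_col].nunique().pipe(lambda s: (s == 2).sum())
    )
    if areas_both < 2:
        raise InferenceError("need ≥2 areas observed in both surveys")
    fwd, _ = TRANSFORMS[transformation]
    y = fwd(df[value_col].to_numpy(dtype=float))
    x = (df[survey_col] == RESURVEY).to_numpy(dtype=float)
    exog = sm.add_constant(x)
    cells = df[area_col].astype(str) + ":" + df[survey_col].astype(str)

    fallback = False
    res = _fit_mixedlm(y, exog, cells.to_numpy())
    if res is None or not np.all(np.isfinite(res.bse_fe)):
        fallback = True
        logger.warning("singular area×survey fit for %s; area-only intercept", metric)
        res = _fit_mixedlm(y, exog, df[area_col].astype(str).to_numpy())
    if res is None:
        raise InferenceError(f"mixed model failed to fit for metric {metric!r}")

    est = float(res.fe_params[1])
    se = float(res.bse_fe[1])
    n_groups = int(cells.nunique())
    dof = max(n_groups - 2, 1)
    t = est / se if se > 0 else np.inf
    p = float(2.0 * scipy.stats.t.sf(abs(t), dof))

    _, inv = TRANSFORMS[transformation]
    m_hist = float(inv(res.fe_params[0]))
    m_res = float(inv(res.fe_params[0] + est))
    pct = (m_res - m_hist) / m_hist * 100.0 if m_hist != 0 else np.nan

    return SurveyEffect(
        metric=metric,
        estimate=est,
        se=se,
        p=p,
        df=dof,
        percent_change=pct,
        transformation=transformation,
        n_obs=len(df),
        n_groups=n_groups,
        fallback=fallback,
    )


def delta_by_area(
    data: pd.DataFrame,
    value_col: str = "value",
    survey_col: str = "survey",
    area_col: str = "area_id",
    elevation_col: str = "elevation_m",
) -> pd.DataFrame:
    """Per-area resurvey mean minus historical mean (areas with both surveys).

    Returns a frame with columns area_id, elevation_m, delta; one-survey
    areas are skipped with a log entry.
    """
    rows = []
    skipped = 0
    for area, grp in data.groupby(area_col, sort=True):
        means = grp.groupby(survey_col)[value_col].mean()
        if HISTORICAL not in means or RESURVEY not in means:
            skipped += 1
            continue
        rows.append(
            (area, grp[elevation_col].iloc[0], means[RESURVEY] - means[HISTORICAL])
        )
    if skipped:
        logger.info("delta_by_area: skipped %d one-survey areas", skipped)
    return pd.DataFrame(rows, columns=["area_id", "elevation_m", "delta"])


def fit_delta_elevation(deltas: pd.DataFrame) -> LinearFit:
    """OLS of per-area Δ on elevation."""
    df = deltas.dropna(subset=["delta"])
    if len(df) < 3:
        raise InferenceError("need at least 3 area deltas")
    elev = df["elevation_m"].to_numpy(dtype=float)
    if np.ptp(elev) == 0:
        raise InferenceError("constant elevation: slope undefined")
    res = sm.OLS(df["delta"].to_numpy(dtype=float), sm.add_constant(elev)).fit()
    return LinearFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r2_adj=float(res.rsquared_adj),
        p_slope=float(res.pvalues[1]),
        n=len(df),
    )


def crossing_elevation(fit: LinearFit) -> Optional[float]:
    """Elevation where the fitted Δ line crosses zero; None for a flat line."""
    if fit.slope == 0:
        return None
    return -fit.intercept / fit.slope


def assign_bands(
    areas: pd.DataFrame, n_bands: int = 11
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition areas into elevational bands of (nearly) equal size.

    Areas are sorted by ascending elevation; when n is not divisible by the
    band count, the remainder r is absorbed by the r lowest bands (n = 277
    gives sizes 26, 26, 25 × 9). Returns (assignment, band summary); the
    summary holds band index (1-based, lowest first), member count and
    median elevation.
    """
    df = areas[["area_id", "elevation_m"]].drop_duplicates("area_id")
    n = len(df)
    if n < n_bands:
        raise InferenceError(f"{n} areas cannot fill {n_bands} bands")
    df = df.sort_values(["elevation_m", "area_id"], kind="mergesort").reset_index(drop=True)
    base, r = divmod(n, n_bands)
    sizes = [base + 1] * r + [base] * (n_bands - r)
    band_idx = np.repeat(np.arange(1, n_bands + 1), sizes)
    df = df.assign(band=band_idx)
    summary = (
        df.groupby("band")
        .agg(n_areas=("area_id", "size"), median_elevation_m=("elevation_m", "median"))
        .reset_index()
    )
    return df, summary


# --------------------------------------------------------------- β contrast


def pairwise_beta_table(
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    dm: DissimilarityMatrix,
) -> pd.DataFrame:
    """Same-survey, between-area pairwise β values for a set of plots.

    ``abund``: plots × species relative abundances (rows sum to 1) indexed
    by plot_id; ``meta``: per-plot survey and area_id indexed by plot_id.
    Within-area pairs are excluded — they confound relocation noise with
    temporal change. Returns plot_1, plot_2, survey, area_pair,
    beta_additive, beta_proportional.
    """
    meta = meta.loc[abund.index]
    additive, proportional = beta_matrix(abund, dm)
    surveys = meta["survey"].to_numpy()
    areas = meta["area_id"].to_numpy().astype(str)
    plots = abund.index.to_numpy().astype(str)
    iu, ju = np.triu_indices(len(abund), k=1)
    keep = (surveys[iu] == surveys[ju]) & (areas[iu] != areas[ju])
    iu, ju = iu[keep], ju[keep]
    lo_first = areas[iu] <= areas[ju]
    pair_lo = np.where(lo_first, areas[iu], areas[ju])
    pair_hi = np.where(lo_first, areas[ju], areas[iu])
    return pd.DataFrame(
        {
            "plot_1": plots[iu],
            "plot_2": plots[ju],
            "survey": surveys[iu],
            "area_pair": np.char.add(np.char.add(pair_lo, "|"), pair_hi),
            "beta_additive": additive[iu, ju],
            "beta_proportional": proportional[iu, ju],
        }
    )


def band_beta_contrast(
    pair_table: pd.DataFrame,
    value_col: str = "beta_additive",
    metric: str = "beta",
    min_pairs: int = 10,
) -> Optional[SurveyEffect]:
    """Survey contrast of pairwise β with the area pair as random factor."""
    df = pair_table.dropna(subset=[value_col])
    if len(df) < min_pairs or df["survey"].nunique() < 2:
        logger.info("band skipped for %s: too few β pairs (%d)", metric, len(df))
        return None
    y = df[value_col].to_numpy(dtype=float)
    x = (df["survey"] == RESURVEY).to_numpy(dtype=float)
    exog = sm.add_constant(x)
    res = _fit_mixedlm(y, exog, df["area_pair"].to_numpy())
    if res is None:
        logger.info("band skipped for %s: mixed model failed", metric)
        return None
    est = float(res.fe_params[1])
    se = float(res.bse_fe[1])
    n_groups = int(df["area_pair"].nunique())
    dof = max(n_groups - 2, 1)
    p = float(2.0 * scipy.stats.t.sf(abs(est / se), dof)) if se > 0 else 0.0
    m_hist = float(res.fe_params[0])
    pct = est / m_hist * 100.0 if m_hist != 0 else np.nan
    return SurveyEffect(
        metric=metric,
        estimate=est,
        se=se,
        p=p,
        df=dof,
        percent_change=pct,
        n_obs=len(df),
        n_groups=n_groups,
    )


def band_trend(band_effects: pd.DataFrame, value_col: str = "estimate") -> LinearFit:
    """Linear model of per-band survey effects on band median elevation."""
    return fit_delta_elevation(
        band_effects.rename(
            columns={value_col: "delta", "median_elevation_m": "elevation_m"}
        )[["elevation_m", "delta"]].assign(area_id="band")
    )


# --------------------------------------------------------------- γ contrast


def band_gamma_contrast(
    records: Sequence[PlotRecord],
    rng: np.random.Generator,
    n_target: Optional[int] = None,
) -> tuple[int, int]:
    """Band-level γ richness (union over one random plot per area and survey).

    Areas missing one survey are skipped with a warning. If ``n_target`` is
    given and the band holds more areas, a random subset of areas is
    skipped so both surveys contribute exactly ``n_target`` plots —
    equalizing sampling effort across bands.
    """
    by_area: dict[str, dict[str, list[PlotRecord]]] = {}
    for rec in records:
        by_area.setdefault(rec.area_id, {}).setdefault(rec.survey, []).append(rec)
    eligible = []
    for area_id in sorted(by_area):
        surveys = by_area[area_id]
        if HISTORICAL in surveys and RESURVEY in surveys:
            eligible.append(area_id)
        else:
            warnings.warn(f"area {area_id} lacks one survey; skipped for γ", stacklevel=2)
    if not eligible:
        raise InferenceError("no area with both surveys in the band")
    if n_target is not None and len(eligible) > n_target:
        chosen = rng.choice(len(eligible), size=n_target, replace=False)
        eligible = [eligible[i] for i in sorted(chosen)]

    gamma = {}
    for survey in (HISTORICAL, RESURVEY):
        species: set[str] = set()
        for area_id in eligible:
            plots = sorted(by_area[area_id][survey], key=lambda p: p.plot_id)
            pick = plots[int(rng.integers(len(plots)))]
            species.update(s for s, a in pick.abundances.items() if a > 0)
        gamma[survey] = len(species)
    return gamma[HISTORICAL], gamma[RESURVEY]


# ------------------------------------------------------------ pseudo-turnover


def pseudo_turnover_check(
    records: Sequence[PlotRecord],
) -> tuple[pd.DataFrame, SurveyEffect]:
    """Temporal change vs. relocation noise, per area and overall.

    For each area with ≥2 resurvey plots and ≥1 historical plot:
    difference = mean Bray–Curtis(historical, resurvey) − mean Bray–Curtis
    among resurvey plots. A positive overall value means between-survey
    dissimilarity exceeds the within-area spatial noise, i.e. real temporal
    turnover. The overall contrast is a mixed model of all dissimilarities
    on their type (between-survey vs. within-resurvey) with the area as
    random intercept.
    """
    by_area: dict[str, dict[str, list[PlotRecord]]] = {}
    for rec in records:
        by_area.setdefault(rec.area_id, {}).setdefault(rec.survey, []).append(rec)

    rows = []
    long_rows = []
    skipped = 0
    for area_id in sorted(by_area):
        hist = by_area[area_id].get(HISTORICAL, [])
        res = by_area[area_id].get(RESURVEY, [])
        if len(res) < 2 or len(hist) < 1:
            skipped += 1
            continue
        between = [
            bray_curtis(h.abundances, r.abundances) for h in hist for r in res
        ]
        within = [
            bray_curtis(res[i].abundances, res[j].abundances)
            for i in range(len(res))
            for j in range(i + 1, len(res))
        ]
        elev = res[0].elevation
        rows.append(
            (area_id, elev, np.mean(between), np.mean(within),
             np.mean(between) - np.mean(within))
        )
        long_rows += [(area_id, "between_survey", v) for v in between]
        long_rows += [(area_id, "within_resurvey", v) for v in within]
    if skipped:
        logger.info("pseudo_turnover_check: skipped %d ineligible areas", skipped)
    if not rows:
        raise InferenceError("no area eligible for the pseudo-turnover check")

    per_area = pd.DataFrame(
        rows,
        columns=["area_id", "elevation_m", "bc_between", "bc_within", "difference"],
    )
    long = pd.DataFrame(long_rows, columns=["area_id", "type", "value"])
    y = long["value"].to_numpy(dtype=float)
    x = (long["type"] == "between_survey").to_numpy(dtype=float)
    res_fit = _fit_mixedlm(y, sm.add_constant(x), long["area_id"].to_numpy())
    if res_fit is None:
        raise InferenceError("pseudo-turnover mixed model failed to fit")
    est = float(res_fit.fe_params[1])
    se = float(res_fit.bse_fe[1])
    dof = max(len(per_area) - 1, 1)
    p = float(2.0 * scipy.stats.t.sf(abs(est / se), dof)) if se > 0 else 0.0
    base = float(res_fit.fe_params[0])
    effect = SurveyEffect(
        metric="bray_curtis_pseudo_turnover",
        estimate=est,
        se=se,
        p=p,
        df=dof,
        percent_change=est / base * 100.0 if base else np.nan,
        n_obs=len(long),
        n_groups=len(per_area),
    )
    return per_area, effect


# ------------------------------------------------------------- analytic aid


def expected_warming_indicator_shift(
    warming_c: float = 2.0,
    lapse_rate_c_per_100m: float = 0.65,
    indicator_change_per_100m: float = 0.098,
) -> float:
    """Expected CWM temperature-indicator increase under a warming.

    A warming of ΔT °C is thermally equivalent to a downslope displacement
    of ΔT / lapse-rate (in 100 m units); multiplying by the observed
    spatial indicator gradient per 100 m gives the community-level
    indicator shift expected if vegetation tracked climate fully.
    """
    return warming_c / lapse_rate_c_per_100m * indicator_change_per_100m
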