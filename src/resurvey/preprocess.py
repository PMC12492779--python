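"""Make the two surveys comparable.

Historical plots were sampled destructively (dry biomass per species),
resurvey plots by visual percent-cover estimation. Comparability requires:
(1) an allometric biomass→cover transformation fitted separately for
graminoids and forbs; (2) standardization of both surveys to fractional
cover (plot totals = 100); (3) taxon harmonization onto a common
synonym/aggregate map; and (4) a detection correction adding 0.9 species to
each resurvey plot's richness, compensating the cover method's higher
overlooking probability relative to lab biomass sorting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import math
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HISTORICAL = "historical"
RESURVEY = "resurvey"

#: richness added to each resurvey plot (detection-method correction)
RICHNESS_CORRECTION = 0.9


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PlotRecord:
    """One survey observation of one plot."""

    plot_id: str
    area_id: str
    survey: str  # historical | resurvey
    elevation: float  # m a.s.l.
    abundances: dict[str, float]
    abundance_type: str  # biomass_fraction | percent_cover | fractional_cover

    def __post_init__(self) -> None:
        if self.survey not in (HISTORICAL, RESURVEY):
            raise PreprocessError(f"unknown survey label {self.survey!r}")
        if any(a < 0 for a in self.abundances.values()):
            raise PreprocessError(f"negative abundance in plot {self.plot_id}")

    @property
    def richness(self) -> int:
        return sum(1 for a in self.abundances.values() if a > 0)


@dataclass(frozen=True)
class AllometricModel:
    """Per-group log–log maps from biomass fraction to percent cover.

    cover = exp(a_g + b_g · ln(biomass)) for group g ∈ {graminoid, forb}.
    The published regressions' coefficients are survey-campaign specific
    and supplied via configuration; the default is the identity map
    (a = 0, b = 1), which preserves rank order and, after standardization
    to fractional cover, relative composition.
    """

    coefficients: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"graminoid": (0.0, 1.0), "forb": (0.0, 1.0)}
    )

    def __post_init__(self) -> None:
        for g, (a, b) in self.coefficients.items():
            if b <= 0:
                raise PreprocessError(f"non-positive slope for group {g!r}")

    def cover(self, biomass: float, group: str) -> float:
        a, b = self.coefficients[group]
        return math.exp(a + b * math.log(biomass))

    def biomass(self, cover: float, group: str) -> float:
        """Inverse map (used by the synthetic generator's forward model)."""
        a, b = self.coefficients[group]
        return math.exp((math.log(cover) - a) / b)


def biomass_to_cover(
    plot: PlotRecord,
    model: AllometricModel,
    group_map: Mapping[str, str],
) -> PlotRecord:
    """Transform a biomass-fraction plot to percent cover.

    Zero-biomass entries are dropped (logged); species without a
    graminoid/forb assignment raise an error listing the offenders.
    """
    if plot.abundance_type != "biomass_fraction":
        raise PreprocessError(
            f"plot {plot.plot_id} has abundance_type {plot.abundance_type!r}"
        )
    unmapped = [s for s in plot.abundances if s not in group_map]
    if unmapped:
        raise PreprocessError(
            f"species without graminoid/forb group in plot {plot.plot_id}: {unmapped}"
        )
    zeros = [s for s, a in plot.abundances.items() if a == 0]
    if zeros:
        logger.info("dropping %d zero-biomass entries in plot %s", len(zeros), plot.plot_id)
    covers = {
        s: model.cover(a, group_map[s])
        for s, a in plot.abundances.items()
        if a > 0
    }
    return replace(plot, abundances=covers, abundance_type="percent_cover")


def standardize_fractional_cover(plot: PlotRecord) -> PlotRecord:
    """Rescale abundances so the plot total is exactly 100."""
    total = sum(plot.abundances.values())
    if total <= 0:
        raise PreprocessError(f"plot {plot.plot_id} has no positive abundance")
    frac = {s: 100.0 * a / total for s, a in plot.abundances.items() if a > 0}
    return replace(plot, abundances=frac, abundance_type="fractional_cover")


def corrected_richness(plot: PlotRecord, correction: float = RICHNESS_CORRECTION) -> float:
    """Species richness, plus the detection correction for resurvey plots."""
    r = plot.richness
    if r == 0:
        logger.warning("plot %s has zero richness", plot.plot_id)
    if plot.survey == RESURVEY:
        return r + correction
    return float(r)


def harmonize_taxa(
    plots: Iterable[PlotRecord], synonym_map: Mapping[str, str]
) -> list[PlotRecord]:
    """Map observed names to accepted/aggregate names, summing within plot.

    Names absent from the map pass through unchanged with a single warning.
    """
    plots = list(plots)
    unmapped: set[str] = set()
    out = []
    for plot in plots:
        merged: dict[str, float] = {}
        for s, a in plot.abundances.items():
            target = synonym_map.get(s)
            if target is None:
                unmapped.add(s)
                target = s
            merged[target] = merged.get(target, 0.0) + a
        out.append(replace(plot, abundances=merged))
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} observed names not in synonym map (passed through): "
            f"{sorted(unmapped)[:5]}...",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------- I/O glue


def records_from_frames(
    abundance: pd.DataFrame, metadata: pd.DataFrame
) -> list[PlotRecord]:
    """Assemble PlotRecords from the long abundance table + plot metadata.

    ``abundance``: plot_id, species_id, abundance, abundance_type;
    ``metadata``: plot_id, area_id, survey, elevation_m (extra columns kept
    out). Every plot in the abundance table must have metadata.
    """
    meta = metadata.set_index("plot_id")
    missing = set(abundance["plot_id"]) - set(meta.index)
    if missing:
        raise PreprocessError(f"plots without metadata: {sorted(missing)[:5]}")
    records = []
    for plot_id, grp in abundance.groupby("plot_id", sort=True):
        types = grp["abundance_type"].unique()
        if len(types) != 1:
            raise PreprocessError(f"mixed abundance types in plot {plot_id}")
        row = meta.loc[plot_id]
        records.append(
            PlotRecord(
                plot_id=str(plot_id),
                area_id=str(row["area_id"]),
                survey=str(row["survey"]),
                elevation=float(row["elevation_m"]),
                abundances=dict(
                    zip(grp["species_id"].astype(str), grp["abundance"].astype(float))
                ),
                abundance_type=str(types[0]),
            )
        )
    return records


def frames_from_records(records: Sequence[PlotRecord]) -> pd.DataFrame:
    """Long abundance table (plot_id, species_id, abundance, abundance_type)."""
    rows = [
        (r.plot_id, s, a, r.abundance_type)
        for r in records
        for s, a in sorted(r.abundances.items())
    ]
    return pd.DataFrame(rows, columns=["plot_id", "species_id", "abundance", "abundance_type"])


def abundance_wide(records: Sequence[PlotRecord], normalize: bool = True) -> pd.DataFrame:
    """Plots × species matrix; rows normalized to sum 1 when requested."""
    long = frames_from_records(records)
    wide = long.pivot_table(
        index="plot_id", columns="species_id", values="abundance", fill_value=0.0
    )
    if normalize:
        wide = wide.div(wide.sum(axis=1), axis=0)
    return wide


def read_synonym_map(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["observed_name", "accepted_name"]:
        raise PreprocessError(
            "synonym map must have columns observed_name, accepted_name"
        )
    return dict(zip(df["observed_name"], df["accepted_name"]))
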