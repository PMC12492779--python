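"""Community-level characteristics: indicator CWMs, CSR strategy, group cover.

Ecological indicator values (Landolt scheme) score each species 1–5 for its
affinity along environmental gradients; the community-weighted mean (CWM)
is the abundance-weighted average over the plot's species. Grime CSR
strategies are 3-letter codes over {c, s, r} decomposed to fractional
coordinates on the simplex (e.g. "ssr" → c=0, s=2/3, r=1/3). Taxonomic
group cover splits fractional cover between Poaceae, Cyperaceae+Juncaceae,
and forbs (all other families).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .diversity import AbundanceVector

INDICATORS = (
    "temperature",
    "light",
    "moisture",
    "reaction",
    "nutrients",
    "mowing_tolerance",
    "hemeroby",
)

#: families pooled into the sedge/rush group
CYPJUNC_FAMILIES = frozenset({"Cyperaceae", "Juncaceae"})

_CSR_RE = re.compile(r"^[csr]{3}$")


class CommunityMetricError(ValueError):
    pass


@dataclass
class CWMResult:
    """A community-weighted mean plus the abundance coverage behind it.

    ``value`` is NaN when no species in the plot has the attribute;
    ``coverage`` is the fraction of total abundance carried by species with
    a non-missing value (CWMs renormalize over those species).
    """

    value: float
    coverage: float


def community_weighted_mean(
    p: AbundanceVector, values: Mapping[str, float]
) -> CWMResult:
    """Abundance-weighted mean of a species attribute.

    Missing values (absent key or NaN) are handled by renormalizing the
    abundances over covered species; the coverage fraction is reported so
    poorly covered plots can be flagged downstream.
    """
    num = 0.0
    cov = 0.0
    for s, a in zip(p.labels, p.p):
        v = values.get(s)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        num += a * float(v)
        cov += a
    if cov == 0.0:
        return CWMResult(value=float("nan"), coverage=0.0)
    return CWMResult(value=num / cov, coverage=cov)


def csr_decompose(strategy: str) -> tuple[float, float, float]:
    """Fractional (c, s, r) coordinates of a 3-letter Grime strategy code."""
    code = str(strategy).strip().lower()
    if not _CSR_RE.match(code):
        raise CommunityMetricError(f"malformed CSR strategy string: {strategy!r}")
    return (code.count("c") / 3.0, code.count("s") / 3.0, code.count("r") / 3.0)


def community_csr(
    p: AbundanceVector, strategies: Mapping[str, str]
) -> tuple[CWMResult, CWMResult, CWMResult]:
    """Abundance-weighted mean CSR coordinates of a community."""
    comp = {}
    for s in p.labels:
        code = strategies.get(s)
        if code is None or (isinstance(code, float) and math.isnan(code)):
            continue
        comp[s] = csr_decompose(code)
    return tuple(
        community_weighted_mean(p, {s: t[k] for s, t in comp.items()})
        for k in range(3)
    )


@dataclass
class GroupProportions:
    poaceae_pct: float
    cypjunc_pct: float
    forb_pct: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.poaceae_pct, self.cypjunc_pct, self.forb_pct)


def group_proportions(
    p: AbundanceVector, family_map: Mapping[str, str]
) -> GroupProportions:
    """Percent of fractional cover in Poaceae / Cyperaceae+Juncaceae / forbs."""
    missing = [s for s in p.labels if s not in family_map]
    if missing:
        raise CommunityMetricError(f"species without family assignment: {missing}")
    totals = np.zeros(3)
    for s, a in zip(p.labels, p.p):
        fam = family_map[s]
        if fam == "Poaceae":
            totals[0] += a
        elif fam in CYPJUNC_FAMILIES:
            totals[1] += a
        else:
            totals[2] += a
    pct = 100.0 * totals / totals.sum()
    return GroupProportions(*pct)
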