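"""α, β and γ diversity built on Rao's quadratic entropy.

Rao's Q = Σ_i Σ_j p_i p_j d_ij is the expected dissimilarity between two
randomly drawn individuals of a community. With identity distances it is
Gini–Simpson diversity; with trait or phylogenetic distances it is
functional or phylogenetic diversity. The Jost correction 1/(1−Q) converts
Q to equivalent numbers (effective species), on which α, β and γ decompose
additively: for a pair of plots, β_add = γ_eq − mean(α_eq) with γ computed
on the pooled (mean) relative-abundance vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DissimilarityMatrix

__all__ = [
    "AbundanceVector",
    "DiversityError",
    "rao_q",
    "jost_equivalent",
    "pairwise_beta",
    "beta_matrix",
    "bray_curtis",
    "gamma_band_richness",
]


class DiversityError(ValueError):
    pass


@dataclass
class AbundanceVector:
    """Relative abundances of the species in one plot (sums to 1)."""

    labels: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.labels) != self.p.size:
            raise DiversityError("labels and abundances differ in length")
        if np.any(self.p < 0):
            raise DiversityError("negative abundances")
        s = self.p.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise DiversityError(f"abundances sum to {s}, expected 1")

    @classmethod
    def from_mapping(cls, abundances: Mapping[str, float]) -> "AbundanceVector":
        """Build from species→abundance, dropping zeros and normalizing."""
        items = [(s, a) for s, a in abundances.items() if a > 0]
        if not items:
            raise DiversityError("empty abundance vector")
        labels, vals = zip(*items)
        v = np.array(vals, dtype=float)
        return cls(list(labels), v / v.sum())


def rao_q(p: AbundanceVector, dm: DissimilarityMatrix) -> float:
    """Rao's quadratic entropy Q = Σ_i Σ_j p_i p_j d_ij."""
    idx = dm.indices_of(p.labels)  # raises listing missing species
    d = dm.d[np.ix_(idx, idx)]
    return float(p.p @ d @ p.p)


def jost_equivalent(q: float) -> float:
    """Equivalent numbers 1/(1−Q); requires 0 ≤ Q < 1 (d_ij ≤ 1)."""
    if not 0.0 <= q < 1.0:
        raise DiversityError(f"Rao Q = {q} outside [0, 1); rescale distances to [0, 1]")
    return 1.0 / (1.0 - q)


@dataclass
class BetaResult:
    alpha_eq: float  # mean of the two plots' equivalent numbers
    gamma_eq: float  # equivalent number of the pooled community
    additive: float  # gamma_eq − alpha_eq
    proportional: float  # additive / gamma_eq


def _pooled(p1: AbundanceVector, p2: AbundanceVector) -> AbundanceVector:
    union = list(dict.fromkeys(p1.labels + p2.labels))
    pos = {s: i for i, s in enumerate(union)}
    v = np.zeros(len(union))
    for av in (p1, p2):
        for s, a in zip(av.labels, av.p):
            v[pos[s]] += 0.5 * a
    return AbundanceVector(union, v)


def pairwise_beta(
    p1: AbundanceVector, p2: AbundanceVector, dm: DissimilarityMatrix
) -> BetaResult:
    """Jost-corrected additive β between two plots.

    Pooling uses the unweighted mean of the two relative-abundance vectors
    (plots are equal-sized); β_add = γ_eq − ᾱ_eq ≥ 0, with equality iff the
    plots have identical composition (identity-distance case).
    """
    a1 = jost_equivalent(rao_q(p1, dm))
    a2 = jost_equivalent(rao_q(p2, dm))
    g = jost_equivalent(rao_q(_pooled(p1, p2), dm))
    alpha = 0.5 * (a1 + a2)
    add = g - alpha
    return BetaResult(alpha_eq=alpha, gamma_eq=g, additive=add, proportional=add / g)


def beta_matrix(
    abund: pd.DataFrame, dm: DissimilarityMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairwise β for many plots at once.

    Parameters
    ----------
    abund
        Plots × species matrix of relative abundances (rows sum to 1);
        columns must be a subset of ``dm`` labels.

    Returns
    -------
    (additive, proportional)
        Square arrays over the plot rows; entry (i, j) equals
        ``pairwise_beta`` of plots i and j.

    Notes
    -----
    Uses Q_pool(i, j) = (M_ii + M_jj + 2 M_ij)/4 with M = P D Pᵀ, which is
    exact because pooling averages the abundance vectors.
    """
    cols = list(abund.columns)
    idx = dm.indices_of(cols)
    d = dm.d[np.ix_(idx, idx)]
    p = abund.to_numpy(dtype=float)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise DiversityError("rows of the abundance matrix must sum to 1")
    m = p @ d @ p.T
    q = np.diag(m)
    if np.any(q >= 1.0):
        raise DiversityError("plot-level Q ≥ 1; rescale distances to [0, 1]")
    alpha_eq = 1.0 / (1.0 - q)
    q_pool = (q[:, None] + q[None, :] + 2.0 * m) / 4.0
    gamma_eq = 1.0 / (1.0 - q_pool)
    additive = gamma_eq - 0.5 * (alpha_eq[:, None] + alpha_eq[None, :])
    np.fill_diagonal(additive, 0.0)
    proportional = additive / gamma_eq
    return additive, proportional


def bray_curtis(x: Mapping[str, float], y: Mapping[str, float]) -> float:
    """Bray–Curtis dissimilarity Σ|x_i − y_i| / Σ(x_i + y_i) over the union."""
    union = set(x) | set(y)
    num = 0.0
    den = 0.0
    for s in union:
        xi = float(x.get(s, 0.0))
        yi = float(y.get(s, 0.0))
        if xi < 0 or yi < 0:
            raise DiversityError("negative abundance")
        num += abs(xi - yi)
        den += xi + yi
    if den == 0:
        raise DiversityError("both communities are empty")
    return num / den


def gamma_band_richness(plots: Iterable[Mapping[str, float]]) -> int:
    """Total species richness (set-union) across the selected plots."""
    species: set[str] = set()
    n = 0
    for plot in plots:
        n += 1
        species.update(s for s, a in plot.items() if a > 0)
    if n == 0:
        raise DiversityError("empty plot selection")
    return len(species)
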