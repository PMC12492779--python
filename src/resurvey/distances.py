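"""Species-pairwise dissimilarity matrices for the three diversity facets.

Taxonomic diversity uses the identity distance (d_ij = 1 for distinct
species), which turns Rao's quadratic entropy into Gini–Simpson diversity.
Functional diversity uses Gower distances on the leaf-height-seed (LHS)
trait triplet — specific leaf area, canopy height, seed mass — with the two
skewed traits log10-transformed. Phylogenetic diversity uses cophenetic
distances: the sum of branch lengths separating two tips of a phylogeny.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: traits that are log10-transformed before range normalization (strongly
#: right-skewed across vascular plants)
LOG_TRAITS = ("height", "seed_mass")
LHS_TRAITS = ("sla", "height", "seed_mass")


class DistanceError(ValueError):
    """Invalid input to a distance-matrix builder."""


@dataclass
class DissimilarityMatrix:
    """Symmetric species-pairwise dissimilarities with labels.

    Parameters
    ----------
    labels
        Ordered species identifiers.
    d
        Square symmetric matrix, zero diagonal, nonnegative entries.
    """

    labels: list[str]
    d: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise DistanceError("duplicate species labels in distance matrix")
        if self.d.shape != (n, n):
            raise DistanceError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise DistanceError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise DistanceError("distance matrix diagonal is not zero")
        if np.any(self.d < -1e-12):
            raise DistanceError("negative distances")
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)
        self._index = {s: i for i, s in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def max(self) -> float:
        return float(self.d.max()) if len(self.labels) > 1 else 0.0

    def indices_of(self, species: Sequence[str]) -> np.ndarray:
        missing = [s for s in species if s not in self._index]
        if missing:
            raise DistanceError(f"species absent from distance matrix: {missing}")
        return np.array([self._index[s] for s in species], dtype=int)

    def submatrix(self, species: Sequence[str]) -> "DissimilarityMatrix":
        idx = self.indices_of(species)
        return DissimilarityMatrix(list(species), self.d[np.ix_(idx, idx)])

    def rescaled(self) -> "DissimilarityMatrix":
        """Divide by the maximum so distances lie in [0, 1].

        The Jost equivalent-number transform requires Rao's Q < 1, which is
        guaranteed when all d_ij ≤ 1; the rescaling constant is logged.
        """
        m = self.max
        if m == 0:
            return DissimilarityMatrix(self.labels, self.d.copy())
        logger.info("rescaling distance matrix by its maximum %.6g", m)
        return DissimilarityMatrix(self.labels, self.d / m)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def identity_distance(species: Sequence[str]) -> DissimilarityMatrix:
    """Distance 1 between distinct species, 0 on the diagonal.

    With this matrix Rao's quadratic entropy reduces to Gini–Simpson
    diversity 1 − Σ p_i², making the taxonomic facet commensurable with the
    functional and phylogenetic ones.
    """
    species = list(species)
    if not species:
        raise DistanceError("empty species list")
    n = len(species)
    d = 1.0 - np.eye(n)
    return DissimilarityMatrix(species, d)


def gower_trait_distance(
    traits: pd.DataFrame,
    trait_columns: Sequence[str] = LHS_TRAITS,
    log10_columns: Sequence[str] = LOG_TRAITS,
) -> DissimilarityMatrix:
    """Gower distance on species traits with pairwise-available averaging.

    Parameters
    ----------
    traits
        DataFrame indexed by species id with the trait columns; NaN marks a
        missing trait value.
    trait_columns
        Traits entering the distance (defaults to the LHS triplet).
    log10_columns
        Traits log10-transformed before range normalization; must be
        strictly positive where present.

    Notes
    -----
    Each trait is range-normalized over the full supplied species set so
    that every pairwise distance is a global constant for the analysis
    pool. d_ij is the mean of |x_ik − x_jk| / range_k over traits observed
    in both species. Species with no observed trait at all are excluded
    with a warning.
    """
    traits = traits.loc[:, list(trait_columns)].astype(float).copy()
    if traits.index.has_duplicates:
        raise DistanceError("duplicate species labels in trait table")
    for col in log10_columns:
        if col not in traits.columns:
            continue
        vals = traits[col]
        if (vals <= 0).any():
            bad = list(traits.index[vals <= 0])
            raise DistanceError(f"non-positive values in log-trait {col!r}: {bad}")
        traits[col] = np.log10(vals)

    all_missing = traits.isna().all(axis=1)
    if all_missing.any():
        dropped = list(traits.index[all_missing])
        warnings.warn(
            f"excluding {len(dropped)} species with no trait values: {dropped[:5]}...",
            stacklevel=2,
        )
        traits = traits.loc[~all_missing]

    x = traits.to_numpy()
    n, k = x.shape
    ranges = np.nanmax(x, axis=0) - np.nanmin(x, axis=0)
    zero_range = ranges == 0
    if zero_range.any():
        warnings.warn(
            f"zero range for traits {list(np.array(trait_columns)[zero_range])}; "
            "they contribute 0 to all distances",
            stacklevel=2,
        )
    safe_ranges = np.where(zero_range, 1.0, ranges)

    obs = ~np.isnan(x)
    xf = np.where(obs, x, 0.0)
    d = np.zeros((n, n))
    both = np.zeros((n, n))
    for j in range(k):
        col = xf[:, j]
        m = obs[:, j].astype(float)
        pair_obs = np.outer(m, m)
        diff = np.abs(col[:, None] - col[None, :]) / safe_ranges[j]
        if zero_range[j]:
            diff = np.zeros_like(diff)
        d += diff * pair_obs
        both += pair_obs
    if np.any(both == 0):
        i, j = np.argwhere((both == 0) & ~np.eye(n, dtype=bool))[0]
        raise DistanceError(
            "species pair with no shared observed trait: "
            f"({traits.index[i]}, {traits.index[j]})"
        )
    d = d / both
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(list(traits.index.astype(str)), d)


def cophenetic_distance(tree: "str | dendropy.Tree") -> DissimilarityMatrix:
    """Patristic (cophenetic) distances between all pairs of tree tips.

    ``tree`` may be a Newick string or a dendropy Tree; every non-root edge
    must carry a branch length. The distance between two tips is the sum of
    branch lengths on the path connecting them.
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        t = dendropy.Tree.get(data=str(tree), schema="newick")
    for edge in t.preorder_edge_iter():
        if edge.tail_node is None:
            continue  # root edge may be lengthless
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise DistanceError(f"missing branch length on edge above {name!r}")
    labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise DistanceError("tree tip labels are not unique")
    pdm = t.phylogenetic_distance_matrix()
    taxa = {taxon.label: taxon for taxon in t.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return DissimilarityMatrix(labels, d)


def check_species_on_tree(species: Iterable[str], dm: DissimilarityMatrix) -> None:
    """Raise with the offending names if plot species are absent from ``dm``."""
    missing = sorted(set(species) - set(dm.labels))
    if missing:
        raise DistanceError(f"species absent from phylogeny: {missing}")
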