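"""Tanimoto set similarity and the trait-weighted pairwise distance.

The similarity between two species mixes two channels: the Tanimoto
(Jaccard) similarity of their binary trait sets and the Tanimoto similarity
of their prey sets.  With trait weight ``w_t`` the distance is

    d(x, y; w_t) = w_t * (1 - tanimoto(x_traits, y_traits))
                 + (1 - w_t) * (1 - tanimoto(x_preys, y_preys))

so ``w_t = 0`` uses interactions only and ``w_t = 1`` traits only.  All
n(n-1)/2 pairwise distances are stored in a packed triangular array without
the diagonal; lookups are symmetric and the diagonal is zero by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import squareform

from .core import FoodWeb, SpeciesId


def tanimoto(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets are identical, hence similarity 1."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def tanimoto_distance(a: set, b: set) -> float:
    return 1.0 - tanimoto(a, b)


def _check_weight(w_t: float) -> None:
    if not (0.0 <= w_t <= 1.0):
        raise ValueError(f"trait weight w_t must lie in [0, 1], got {w_t}")


def weighted_distance(web: FoodWeb, x: SpeciesId, y: SpeciesId, w_t: float) -> float:
    """Trait-weighted Tanimoto distance between species ``x`` and ``y``."""
    _check_weight(w_t)
    rx, ry = web.species[x], web.species[y]
    d_traits = tanimoto_distance(rx.binary_traits, ry.binary_traits)
    d_preys = tanimoto_distance(web.prey_set(x), web.prey_set(y))
    return w_t * d_traits + (1.0 - w_t) * d_preys


@dataclass
class RecommenderConfig:
    """KNN recommender settings: neighbourhood size, trait weight, cutoff."""

    k: int
    w_t: float = 0.0
    max_recommendations: int = 10

    def __post_init__(self):
        if int(self.k) != self.k or self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        self.k = int(self.k)
        _check_weight(self.w_t)
        if self.max_recommendations < 1:
            raise ValueError("max_recommendations must be >= 1")


class DistanceMatrix:
    """All-pairs species distances in packed triangular storage.

    Stores the n(n-1)/2 off-diagonal distances once (condensed vector,
    row-major upper triangle — the same set of entries as a lower triangle
    without the diagonal).  ``lookup(i, j) == lookup(j, i)`` and
    ``lookup(i, i) == 0`` by convention; all entries lie in [0, 1].
    """

    def __init__(self, ids: Sequence[SpeciesId], condensed: np.ndarray):
        ids = list(ids)
        n = len(ids)
        condensed = np.asarray(condensed, dtype=float)
        if condensed.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"expected {n * (n - 1) // 2} packed entries for {n} species, "
                f"got {condensed.shape}"
            )
        if condensed.size and (condensed.min() < -1e-12 or condensed.max() > 1 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")
        self.ids = ids
        self._index = {s: i for i, s in enumerate(ids)}
        self.condensed = np.clip(condensed, 0.0, 1.0)
        self._square: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, species_id: SpeciesId) -> int:
        try:
            return self._index[species_id]
        except KeyError:
            raise KeyError(f"species {species_id!r} not in distance matrix") from None

    def _pack_index(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        n = self.n
        return n * i - i * (i + 1) // 2 + (j - i - 1)

    def lookup(self, a: SpeciesId, b: SpeciesId) -> float:
        """Symmetric distance lookup; lookup(x, x) = 0."""
        i, j = self.index(a), self.index(b)
        if i == j:
            return 0.0
        return float(self.condensed[self._pack_index(i, j)])

    def to_square(self) -> np.ndarray:
        """Full symmetric matrix (cached)."""
        if self._square is None:
            self._square = squareform(self.condensed, checks=False)
        return self._square

    def row(self, species_id: SpeciesId) -> np.ndarray:
        """Distances from one species to all species, in ``ids`` order."""
        return self.to_square()[self.index(species_id)]

    def to_csv(self, path) -> None:
        """Dump the full square form as CSV for inspection."""
        import pandas as pd

        pd.DataFrame(self.to_square(), index=self.ids, columns=self.ids).to_csv(path)

    def __repr__(self) -> str:
        return f"DistanceMatrix({self.n} species, {self.condensed.size} packed entries)"


def _membership_matrix(sets: list[set], universe: list) -> np.ndarray:
    pos = {u: i for i, u in enumerate(universe)}
    mat = np.zeros((len(sets), len(universe)), dtype=np.float64)
    for r, s in enumerate(sets):
        for el in s:
            mat[r, pos[el]] = 1.0
    return mat


def _pairwise_tanimoto_similarity(mat: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity of the row sets of a 0/1 matrix."""
    inter = mat @ mat.T
    sizes = mat.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return sim


def build_distance_matrix(
    web: FoodWeb, w_t: float, ids: Optional[Sequence[SpeciesId]] = None
) -> DistanceMatrix:
    """Compute all pairwise trait-weighted distances of a web.

    Deterministic given the web and ``w_t``; the result does not depend on
    species insertion order (rows follow sorted species id).
    """
    _check_weight(w_t)
    if ids is None:
        ids = web.species_ids
    else:
        ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError(f"need at least 2 species to build a distance matrix, got {n}")

    trait_universe = sorted({t for s in ids for t in web.species[s].binary_traits})
    prey_sets = web.prey_sets()
    traits = _membership_matrix([web.species[s].binary_traits for s in ids], trait_universe)
    # prey universe = all registered species (every prey endpoint is registered)
    preys = _membership_matrix([prey_sets[s] for s in ids], web.species_ids)

    dist = w_t * (1.0 - _pairwise_tanimoto_similarity(traits)) + (1.0 - w_t) * (
        1.0 - _pairwise_tanimoto_similarity(preys)
    )
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(ids, squareform(dist, checks=False))
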