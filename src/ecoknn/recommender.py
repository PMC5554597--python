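"""Positive-only KNN prey recommendation.

For a focal species, find the K most similar species under the
trait-weighted Tanimoto distance, pool their prey sets, drop everything the
focal already consumes, and rank the remaining candidates by how many
neighbours endorse them.  Ties in the vote count are broken by the summed
similarity of the endorsing neighbours (then by ascending candidate id) —
the most strongly endorsed candidate wins.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import FoodWeb, SpeciesId
from .similarity import DistanceMatrix, RecommenderConfig


@dataclass(frozen=True)
class RecommendedPrey:
    candidate_id: SpeciesId
    votes: int
    endorsement_similarity: float


@dataclass
class RecommendationList:
    """Ranked candidate preys for one focal species.

    Votes are non-increasing down the list; within equal votes the summed
    endorsement similarity is non-increasing.  No candidate is in the
    focal's current prey set.
    """

    focal_id: SpeciesId
    ranked: list[RecommendedPrey]

    def ids(self) -> list[SpeciesId]:
        return [r.candidate_id for r in self.ranked]

    def rank_of(self, candidate: SpeciesId) -> int | None:
        """1-based position of ``candidate``, or None if not recommended."""
        for pos, rec in enumerate(self.ranked, start=1):
            if rec.candidate_id == candidate:
                return pos
        return None

    def __len__(self) -> int:
        return len(self.ranked)


def k_nearest(focal: SpeciesId, dm: DistanceMatrix, k: int) -> list[tuple[SpeciesId, float]]:
    """The k species nearest to ``focal``, ascending by distance.

    The focal itself is excluded.  Ties at equal distance (including at the
    K-th position) are broken by ascending species id, so the result is
    deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > dm.n - 1:
        raise ValueError(f"k={k} exceeds the {dm.n - 1} available neighbours")
    fi = dm.index(focal)  # raises on unknown focal
    row = dm.row(focal)
    order = sorted((j for j in range(dm.n) if j != fi), key=lambda j: (row[j], dm.ids[j]))
    return [(dm.ids[j], float(row[j])) for j in order[:k]]


def recommend(
    focal: SpeciesId, web: FoodWeb, dm: DistanceMatrix, cfg: RecommenderConfig
) -> RecommendationList:
    """Recommend novel preys to ``focal`` from its K nearest neighbours.

    The candidate pool is the multiset union of the neighbours' prey sets
    minus the focal's current preys; a candidate's vote count is its
    multiplicity in the pool.  Ranking is by (votes desc, summed similarity
    of endorsing neighbours desc, candidate id asc), truncated to
    ``cfg.max_recommendations``.  The list may be empty — with low K the
    most similar species can have exactly the focal's preys.  Neighbours
    themselves may appear as candidates; only the focal's existing preys are
    filtered.
    """
    neighbors = k_nearest(focal, dm, cfg.k)
    own_preys = web.prey_set(focal)
    votes: dict[SpeciesId, int] = {}
    endorsement: dict[SpeciesId, float] = {}
    for nb_id, dist in neighbors:
        sim = 1.0 - dist
        for prey in web.prey_set(nb_id):
            if prey in own_preys:
                continue
            votes[prey] = votes.get(prey, 0) + 1
            endorsement[prey] = endorsement.get(prey, 0.0) + sim
    ranked = sorted(votes, key=lambda c: (-votes[c], -endorsement[c], c))
    ranked = ranked[: cfg.max_recommendations]
    return RecommendationList(
        focal_id=focal,
        ranked=[RecommendedPrey(c, votes[c], endorsement[c]) for c in ranked],
    )
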