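"""Leave-one-prey-out retrieval evaluation of the KNN recommender.

One trial removes a uniformly random prey from a focal species, asks for up
to ten recommendations against the reduced prey set, and records the rank
at which the removed prey reappears (or that it does not).  Distances are
computed once on the intact web and reused across trials and across all K
values for a given trait weight; an exact (slow) mode rebuilds the distance
matrix after each removal instead.

Aggregation reports top-1/5/10 success rates per (K, w_t) grid cell, and
top-1 rates stratified by the focal's intact prey count (bins: at most 10,
11-100, more than 100 preys).  Only species with at least 2 preys on the
intact web serve as focals; every species remains available as a neighbour
or candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import FoodWeb, SpeciesId
from .recommender import recommend
from .similarity import DistanceMatrix, RecommenderConfig, build_distance_matrix

DEFAULT_K_VALUES: tuple[int, ...] = tuple(range(1, 20, 2))
DEFAULT_WT_VALUES: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

PREY_COUNT_BINS: tuple[tuple[str, int, float], ...] = (
    ("<=10", 0, 10),
    ("11-100", 11, 100),
    (">100", 101, float("inf")),
)


def prey_count_bin(count: int) -> str:
    for label, lo, hi in PREY_COUNT_BINS:
        if lo <= count <= hi:
            return label
    raise ValueError(f"negative prey count {count}")  # pragma: no cover


@dataclass(frozen=True)
class TrialRecord:
    """One leave-one-prey-out attempt."""

    focal_id: SpeciesId
    removed_prey_id: SpeciesId
    retrieval_rank: Optional[int]  # 1..max_recommendations, or None if missed
    k: int
    w_t: float
    replicate: int
    seed: int
    intact_prey_count: int


def eligible_focals(web: FoodWeb) -> list[SpeciesId]:
    """Species with at least two preys on the intact web, sorted."""
    counts = {s: len(p) for s, p in web.prey_sets().items()}
    return sorted(s for s, c in counts.items() if c >= 2)


def trial_seed(master_seed: int, focal_index: int, replicate: int) -> int:
    """Per-trial seed: SeedSequence(master) spawned at key (focal, replicate).

    The removal draw therefore depends only on the focal and the replicate,
    never on K or w_t, so grid cells see identical removals.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(focal_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def run_trial(
    web: FoodWeb,
    dm: Optional[DistanceMatrix],
    focal: SpeciesId,
    cfg: RecommenderConfig,
    rng_seed: int,
    replicate: int = 0,
    recompute_distances: bool = False,
) -> TrialRecord:
    """Remove one random prey of ``focal``, recommend, record the rank.

    ``dm`` must be built on the intact web; with ``recompute_distances``
    the matrix is instead rebuilt on the reduced web for this trial (slow,
    has little effect on the results).  The web is restored before return.
    """
    preys = sorted(web.prey_set(focal))
    if len(preys) < 2:
        raise ValueError(
            f"focal {focal!r} has {len(preys)} prey(s); leave-one-out needs at least 2"
        )
    rng = np.random.default_rng(rng_seed)
    removed = preys[int(rng.integers(len(preys)))]
    web.interactions.remove((focal, removed))
    try:
        if recompute_distances:
            dm_used = build_distance_matrix(web, cfg.w_t)
        else:
            if dm is None:
                raise ValueError("a precomputed distance matrix is required unless recompute_distances=True")
            dm_used = dm
        recs = recommend(focal, web, dm_used, cfg)
    finally:
        web.interactions.add((focal, removed))
    return TrialRecord(
        focal_id=focal,
        removed_prey_id=removed,
        retrieval_rank=recs.rank_of(removed),
        k=cfg.k,
        w_t=cfg.w_t,
        replicate=replicate,
        seed=rng_seed,
        intact_prey_count=len(preys),
    )


@dataclass
class EvaluationReport:
    """All trials of a (K, w_t) grid run, with aggregation helpers."""

    trials: pd.DataFrame
    replicates: int
    master_seed: int

    def summary(self) -> pd.DataFrame:
        """Top-1/5/10 success rates and trial counts per (k, w_t) cell."""
        df = self.trials
        rows = []
        for (k, wt), grp in df.groupby(["k", "w_t"], sort=True):
            rank = grp["retrieval_rank"]
            rows.append(
                {
                    "k": k,
                    "w_t": wt,
                    "top1": float((rank <= 1).mean()),
                    "top5": float((rank <= 5).mean()),
                    "top10": float((rank <= 10).mean()),
                    "n_trials": int(len(grp)),
                }
            )
        return pd.DataFrame(rows).set_index(["k", "w_t"])

    def n_trials(self) -> int:
        return len(self.trials)


def run_grid(
    web: FoodWeb,
    k_values: Optional[Sequence[int]] = None,
    wt_values: Optional[Sequence[float]] = None,
    replicates: int = 10,
    master_seed: int = 0,
    max_recommendations: int = 10,
    recompute_distances: bool = False,
) -> EvaluationReport:
    """Leave-one-prey-out over the full (K, w_t) grid.

    Defaults follow the standard protocol: odd K from 1 to 19, trait weights
    {0, 0.2, 0.4, 0.6, 0.8, 1}, 10 replicates per focal.  One distance
    matrix is built per trait weight and shared across every K (distances do
    not depend on K).  Fully deterministic under ``master_seed``.
    """
    k_values = list(DEFAULT_K_VALUES if k_values is None else k_values)
    wt_values = list(DEFAULT_WT_VALUES if wt_values is None else wt_values)
    if not k_values or not wt_values:
        raise ValueError("k_values and wt_values must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    focals = eligible_focals(web)
    if not focals:
        raise ValueError("no species with at least 2 preys; nothing to evaluate")
    max_k = max(k_values)
    if max_k > web.n_species - 1:
        raise ValueError(f"k={max_k} exceeds the {web.n_species - 1} available neighbours")

    seeds = {
        (fi, rep): trial_seed(master_seed, fi, rep)
        for fi in range(len(focals))
        for rep in range(replicates)
    }
    records: list[TrialRecord] = []
    for wt in wt_values:
        dm = None if recompute_distances else build_distance_matrix(web, wt)
        for k in k_values:
            cfg = RecommenderConfig(k=k, w_t=wt, max_recommendations=max_recommendations)
            for fi, focal in enumerate(focals):
                for rep in range(replicates):
                    records.append(
                        run_trial(
                            web,
                            dm,
                            focal,
                            cfg,
                            rng_seed=seeds[(fi, rep)],
                            replicate=rep,
                            recompute_distances=recompute_distances,
                        )
                    )
    trials = pd.DataFrame(
        {
            "focal": [r.focal_id for r in records],
            "removed": [r.removed_prey_id for r in records],
            "retrieval_rank": [
                np.nan if r.retrieval_rank is None else float(r.retrieval_rank) for r in records
            ],
            "k": [r.k for r in records],
            "w_t": [r.w_t for r in records],
            "replicate": [r.replicate for r in records],
            "seed": [r.seed for r in records],
            "intact_prey_count": [r.intact_prey_count for r in records],
        }
    )
    return EvaluationReport(trials=trials, replicates=replicates, master_seed=master_seed)


def stratify_by_prey_count(report: EvaluationReport, web: Optional[FoodWeb] = None) -> pd.DataFrame:
    """Top-1 rates per (k, w_t) and intact-prey-count bin.

    Bin membership uses the focal's prey count on the intact (pre-removal)
    web.  Bins without any trial report NaN rate and n_trials = 0 rather
    than a zero rate.
    """
    df = report.trials.copy()
    if web is not None:
        counts = {s: len(p) for s, p in web.prey_sets().items()}
        df["intact_prey_count"] = df["focal"].map(counts)
    df["bin"] = df["intact_prey_count"].map(prey_count_bin)
    rows = []
    for (k, wt), grp in df.groupby(["k", "w_t"], sort=True):
        for label, _, _ in PREY_COUNT_BINS:
            sub = grp[grp["bin"] == label]
            rows.append(
                {
                    "k": k,
                    "w_t": wt,
                    "bin": label,
                    "top1": float((sub["retrieval_rank"] <= 1).mean()) if len(sub) else float("nan"),
                    "n_trials": int(len(sub)),
                }
            )
    return pd.DataFrame(rows).set_index(["k", "w_t", "bin"])
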