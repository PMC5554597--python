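"""Trait-only supervised baseline: random-forest interaction classification.

The matrix-completion framing: every ordered species pair (predator, prey)
is a row whose features are the predator's trait vector concatenated with
the prey's, and whose label is 1 if the pair is an observed interaction and
0 otherwise.  A stock random forest is fitted on most pairs and scored on a
small holdout.  Skill metrics:

    Score_y   = tp / (tp + fp)            precision on interactions
    Score_!y  = tn / (tn + fn)            precision on non-interactions
    Accuracy  = (Score_y * n_1 + Score_!y * n_0) / n^2
    TSS       = (tp*tn - fp*fn) / ((tp + fn) * (fp + tn))

where n_1 and n_0 count interactions and non-interactions in the full n-by-n
matrix.  The True Skill Statistic ranges from -1 to 1 and is insensitive to
the heavy class imbalance typical of food webs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, train_test_split

from .core import FoodWeb

CONTINUOUS_FEATURES = ("body_mass_log", "ph0", "ph1")

ID_COLUMNS = ("predator_id", "prey_id")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a pair table, in predator-then-prey order."""
    return [
        c for c in table.columns if c.startswith(("pred_", "prey_")) and c not in ID_COLUMNS
    ]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts: all nonnegative, summing to evaluated pairs."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def score_y(c: ConfusionCounts) -> float:
    """Precision on interactions: tp / (tp + fp)."""
    denom = c.tp + c.fp
    if denom == 0:
        raise ZeroDivisionError("Score_y undefined: no positive predictions (tp + fp = 0)")
    return c.tp / denom


def score_not_y(c: ConfusionCounts) -> float:
    """Precision on non-interactions: tn / (tn + fn)."""
    denom = c.tn + c.fn
    if denom == 0:
        raise ZeroDivisionError("Score_not_y undefined: no negative predictions (tn + fn = 0)")
    return c.tn / denom


def weighted_accuracy(c: ConfusionCounts, n_interactions: int, n_non: int, n_species: int) -> float:
    """Class-weighted accuracy over the full n_species^2 interaction matrix.

    (Score_y * n_interactions + Score_not_y * n_non) / n_species^2, which
    requires n_interactions + n_non == n_species^2.
    """
    if n_interactions + n_non != n_species**2:
        raise ValueError(
            f"count mismatch: {n_interactions} + {n_non} != {n_species}^2 = {n_species**2}"
        )
    return (score_y(c) * n_interactions + score_not_y(c) * n_non) / n_species**2


def tss(c: ConfusionCounts) -> float:
    """True Skill Statistic: (tp*tn - fp*fn) / ((tp + fn) * (fp + tn)), in [-1, 1]."""
    denom = (c.tp + c.fn) * (c.fp + c.tn)
    if denom == 0:
        raise ZeroDivisionError("TSS undefined: a true class is empty")
    return (c.tp * c.tn - c.fp * c.fn) / denom


def build_pair_table(
    web: FoodWeb,
    features: Optional[Sequence[str]] = None,
    include_self: bool = False,
) -> pd.DataFrame:
    """One row per ordered species pair with concatenated trait features.

    The feature vector is the predator's traits followed by the prey's, in a
    fixed documented order: the web vocabulary's binary labels as 0/1, then
    body_mass_log, ph0, ph1 — each prefixed ``pred_`` or ``prey_``.  The
    label is 1 iff the pair is in the interaction set, else 0 (unobserved
    pairs count as non-interactions under the matrix-completion framing).
    ``features`` restricts columns, e.g. ``["body_mass_log", "ph0", "ph1"]``
    for the continuous-only variant.  Self pairs are excluded unless
    ``include_self`` (include them for an exact n^2 matrix).
    """
    ids = web.species_ids
    vocab = list(web.vocabulary.labels) if web.vocabulary is not None else sorted(
        {t for r in web.species.values() for t in r.binary_traits}
    )
    if features is None:
        features = vocab + list(CONTINUOUS_FEATURES)
    else:
        features = list(features)
        unknown = [f for f in features if f not in vocab and f not in CONTINUOUS_FEATURES]
        if unknown:
            raise ValueError(f"unknown feature(s) {unknown}")

    n = len(ids)
    per_species = np.empty((n, len(features)), dtype=float)
    missing: list = []
    for i, sid in enumerate(ids):
        rec = web.species[sid]
        for j, feat in enumerate(features):
            if feat in CONTINUOUS_FEATURES:
                val = getattr(rec, feat)
                if val is None:
                    missing.append(sid)
                    val = np.nan
                per_species[i, j] = val
            else:
                per_species[i, j] = float(feat in rec.binary_traits)
    if missing:
        raise ValueError(
            f"{len(set(missing))} species lack continuous trait values, "
            f"e.g. {sorted(set(missing), key=str)[:5]}"
        )

    pred_idx, prey_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    pred_idx, prey_idx = pred_idx.ravel(), prey_idx.ravel()
    if not include_self:
        keep = pred_idx != prey_idx
        pred_idx, prey_idx = pred_idx[keep], prey_idx[keep]

    id_arr = np.array(ids, dtype=object)
    table = pd.DataFrame(
        np.hstack([per_species[pred_idx], per_species[prey_idx]]),
        columns=[f"pred_{f}" for f in features] + [f"prey_{f}" for f in features],
    )
    table.insert(0, "predator_id", id_arr[pred_idx])
    table.insert(1, "prey_id", id_arr[prey_idx])
    inter = web.interactions
    table["label"] = [
        1 if (p, q) in inter else 0 for p, q in zip(table["predator_id"], table["prey_id"])
    ]
    return table


@dataclass
class BaselineResult:
    """Holdout confusion counts and skill metrics of the trait-only forest."""

    counts: ConfusionCounts
    score_y: float
    score_not_y: float
    accuracy: float
    tss: float
    best_params: dict
    n_test: int

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "score_y": self.score_y,
            "score_not_y": self.score_not_y,
            "accuracy": self.accuracy,
            "tss": self.tss,
            "n_test": self.n_test,
            **{f"param_{k}": v for k, v in self.best_params.items()},
        }


DEFAULT_GRID = {"n_estimators": [200], "max_depth": [None]}


def train_and_score(
    table: pd.DataFrame,
    test_fraction: float = 0.05,
    seed: int = 0,
    grid: Optional[dict] = None,
    stratify: bool = False,
    class_weight: Optional[str] = None,
) -> BaselineResult:
    """Fit a random forest on the pair table and score a random holdout.

    Keeps ``test_fraction`` (default 5%) of the pairs for testing, grid
    searches forest hyperparameters on the rest (3-fold, skipped when the
    grid has a single point), and reports confusion counts plus all four
    skill metrics on the holdout.  Deterministic under ``seed``.  The split
    is uniform over pairs; ``stratify=True`` stratifies it by label instead.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    feat_cols = feature_columns(table)
    X = table[feat_cols].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y if stratify else None
    )
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set contains a single class; cannot fit a classifier")

    grid = DEFAULT_GRID if grid is None else grid
    n_points = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    base = RandomForestClassifier(random_state=seed, n_jobs=1, class_weight=class_weight)
    if n_points <= 1:
        params = {k: v[0] for k, v in grid.items()}
        model = base.set_params(**params)
        model.fit(X_tr, y_tr)
        best_params = params
    else:
        search = GridSearchCV(base, grid, cv=3, scoring="balanced_accuracy", n_jobs=1)
        search.fit(X_tr, y_tr)
        model = search.best_estimator_
        best_params = dict(search.best_params_)

    y_hat = model.predict(X_te)
    counts = ConfusionCounts(
        tp=int(np.sum((y_te == 1) & (y_hat == 1))),
        tn=int(np.sum((y_te == 0) & (y_hat == 0))),
        fp=int(np.sum((y_te == 0) & (y_hat == 1))),
        fn=int(np.sum((y_te == 1) & (y_hat == 0))),
    )
    s_y = score_y(counts)
    s_ny = score_not_y(counts)
    n_1 = int(table["label"].sum())
    n_0 = int(len(table) - n_1)
    # class-weighted accuracy over all pairs in the table (n^2 when the
    # diagonal is included, n^2 - n otherwise)
    accuracy = (s_y * n_1 + s_ny * n_0) / (n_1 + n_0)
    return BaselineResult(
        counts=counts,
        score_y=s_y,
        score_not_y=s_ny,
        accuracy=accuracy,
        tss=tss(counts),
        best_params=best_params,
        n_test=len(y_te),
    )
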