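"""Trait featurization: PCoA, unit-interval scaling, quartile binarization.

Three continuous attributes describe each species — log body mass and two
taxonomy-derived coordinates obtained by principal coordinates analysis
(classical multidimensional scaling) of a taxonomic distance matrix.  For
set-based (Tanimoto) similarity these have to become binary features: each
continuous variable is scaled to [0, 1) and split into four bins of (as
near as possible) equal size, yielding twelve extra binary trait labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import FoodWeb, SpeciesId, TraitVocabulary

#: Tolerance below which a PCoA eigenvalue counts as non-positive.
_EIG_TOL = 1e-9


def pcoa(dist, n_axes: int = 2) -> pd.DataFrame:
    """Principal coordinates analysis (classical MDS) of a distance matrix.

    Double-centers the squared distances, B = -1/2 * J D^(2) J with
    J = I - 11'/n, eigendecomposes B, and returns the eigenvectors scaled by
    the square roots of the (nonnegative-clamped) eigenvalues for the
    ``n_axes`` largest eigenvalues.  Axis k has non-increasing eigenvalue in
    k.  Negative eigenvalues — common for non-Euclidean taxonomic distances —
    are clamped to zero.  Each axis' sign is fixed by making its
    largest-magnitude loading positive, so output is reproducible.

    Parameters
    ----------
    dist : array-like or DataFrame
        Square symmetric matrix of nonnegative distances with zero diagonal.
        A DataFrame index labels the rows of the result.
    n_axes : int
        Number of leading coordinate axes to return.
    """
    if isinstance(dist, pd.DataFrame):
        ids: Sequence = list(dist.index)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        ids = list(range(D.shape[0]))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    if not (1 <= n_axes <= n):
        raise ValueError(f"n_axes must be in [1, {n}]")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")

    cols = [f"pcoa{k}" for k in range(n_axes)]
    if not np.any(D):
        # all points coincide: every coordinate is zero
        return pd.DataFrame(np.zeros((n, n_axes)), index=ids, columns=cols)

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if n_axes >= 2 and eigvals[1] <= _EIG_TOL:
        raise ValueError(
            "degenerate distance matrix: no positive eigenvalue beyond axis 0, "
            f"cannot extract {n_axes} axes"
        )
    lam = np.clip(eigvals[:n_axes], 0.0, None)
    coords = eigvecs[:, :n_axes] * np.sqrt(lam)
    # deterministic sign: largest-magnitude loading on each axis is positive
    for k in range(n_axes):
        col = coords[:, k]
        if np.any(col):
            pivot = np.argmax(np.abs(col))
            if col[pivot] < 0:
                coords[:, k] = -col
    return pd.DataFrame(coords, index=ids, columns=cols)


def read_distance_matrix(path) -> pd.DataFrame:
    """Read a square distance matrix CSV with species ids as header/index."""
    df = pd.read_csv(path, index_col=0)
    df.columns = df.index
    return df


def scale_unit_interval(values, eps: float = 1e-9) -> np.ndarray:
    """Affine map of ``values`` onto [0, 1): (v - min) / ((max - min)(1 + eps)).

    Order-preserving; the maximum lands strictly below 1.  A constant vector
    has no defined scale and raises.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        raise ValueError("cannot scale a constant vector to [0, 1)")
    return (v - lo) / ((hi - lo) * (1.0 + eps))


@dataclass
class BinnedFeatureSet:
    """Four equal-size binary bin labels for one continuous variable."""

    labels: list[str]
    assignment: dict[SpeciesId, str]
    bin_sizes: dict[str, int]

    def members(self, label: str) -> set[SpeciesId]:
        return {s for s, lab in self.assignment.items() if lab == label}


def quartile_binarize(values: Mapping[SpeciesId, float] | pd.Series, label_prefix: str) -> BinnedFeatureSet:
    """Split species into four bins of (near-)equal size by value rank.

    Species are stable-sorted ascending by (value, species_id); the sorted
    sequence is cut into four consecutive blocks whose sizes differ by at
    most one (the first ``n mod 4`` blocks take the extra member).  Each
    species receives exactly one of the labels ``{prefix}_q1 .. {prefix}_q4``.
    """
    if isinstance(values, pd.Series):
        items = list(values.items())
    else:
        items = list(values.items())
    n = len(items)
    if n < 4:
        raise ValueError(f"need at least 4 species to form quartile bins, got {n}")
    items.sort(key=lambda kv: (kv[1], kv[0]))
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    labels = [f"{label_prefix}_q{i + 1}" for i in range(4)]
    assignment: dict[SpeciesId, str] = {}
    pos = 0
    bin_sizes = {}
    for lab, size in zip(labels, sizes):
        for sid, _ in items[pos : pos + size]:
            assignment[sid] = lab
        bin_sizes[lab] = size
        pos += size
    return BinnedFeatureSet(labels=labels, assignment=assignment, bin_sizes=bin_sizes)


def featurize_web(
    web: FoodWeb,
    tax_distances: Optional[pd.DataFrame] = None,
    bin_prefixes: tuple[str, str, str] = ("M", "Ph0", "Ph1"),
) -> dict[str, BinnedFeatureSet]:
    """Run the full featurization pipeline on ``web`` in place.

    1. If ``tax_distances`` is given, set each species' ``ph0``/``ph1`` to
       its scores on the first two PCoA axes of the matrix.
    2. Scale body mass, ph0 and ph1 to [0, 1).
    3. Bin each scaled variable into four equal-size binary traits, added to
       each species' ``binary_traits`` and to the web vocabulary.

    Every species must carry all three continuous values (after step 1).
    Returns the three :class:`BinnedFeatureSet` objects keyed by prefix.
    """
    ids = web.species_ids
    if tax_distances is not None:
        missing = [s for s in ids if s not in set(tax_distances.index)]
        if missing:
            raise ValueError(f"taxonomic distance matrix lacks {len(missing)} web species, e.g. {missing[0]!r}")
        coords = pcoa(tax_distances.loc[ids, ids], n_axes=2)
        for sid in ids:
            web.species[sid].ph0 = float(coords.loc[sid, "pcoa0"])
            web.species[sid].ph1 = float(coords.loc[sid, "pcoa1"])

    series = {}
    for prefix, attr in zip(bin_prefixes, ("body_mass_log", "ph0", "ph1")):
        vals = {s: getattr(web.species[s], attr) for s in ids}
        absent = [s for s, v in vals.items() if v is None]
        if absent:
            raise ValueError(
                f"{len(absent)} species lack a value for {attr!r}, e.g. {absent[0]!r}"
            )
        series[prefix] = pd.Series(vals, dtype=float)

    out: dict[str, BinnedFeatureSet] = {}
    new_labels: list[str] = []
    for prefix, attr in zip(bin_prefixes, ("body_mass_log", "ph0", "ph1")):
        scaled = scale_unit_interval(series[prefix].to_numpy())
        for sid, v in zip(ids, scaled):
            setattr(web.species[sid], attr, float(v))
        binned = quartile_binarize(pd.Series(scaled, index=ids), prefix)
        for sid, lab in binned.assignment.items():
            web.species[sid].binary_traits.add(lab)
        out[prefix] = binned
        new_labels.extend(binned.labels)
    if web.vocabulary is None:
        web.vocabulary = TraitVocabulary(new_labels)
    else:
        web.vocabulary.extend(new_labels)
    return out
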