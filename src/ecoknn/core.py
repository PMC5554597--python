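"""Domain types and I/O for binary food webs and species trait tables.

A food web is a directed network whose arcs point from consumer (predator)
to resource (prey).  Interactions are positive-only evidence: an absent pair
is *unknown* unless it appears in the explicit non-interaction set (an
observed absence).  Species carry a set of binary trait labels plus three
continuous attributes: log body mass and two taxonomy-derived coordinates
(``ph0``, ``ph1``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SpeciesId = Hashable

#: The 25 binary trait labels of the soil food-web data set, with short
#: descriptions.  Guild membership (carnivore, detritivore, ...) and
#: morphology/behaviour flags.
SOIL_TRAITS: tuple[tuple[str, str], ...] = (
    ("AG", "lives above ground"),
    ("An", "phylum Annelida"),
    ("Ar", "phylum Arthropoda"),
    ("Bc", "domain Bacteria"),
    ("BG", "lives below ground"),
    ("Ca", "carnivore (eats other animals)"),
    ("Cr", "crawls"),
    ("Cy", "phylum Cyanobacteria"),
    ("De", "detritivore"),
    ("Ds", "is a detritus"),
    ("Fg", "fungivore"),
    ("Fu", "kingdom Fungi"),
    ("HS", "has a shell"),
    ("He", "herbivore"),
    ("Im", "immobile"),
    ("IH", "hard exterior without a shell"),
    ("Ju", "can jump"),
    ("LL", "long legs"),
    ("Mo", "phylum Mollusca"),
    ("Ne", "phylum Nematoda"),
    ("Pl", "kingdom Plantae"),
    ("Pr", "kingdom Protozoa"),
    ("SL", "short legs"),
    ("UP", "uses poison"),
    ("WB", "builds webs"),
)


class TraitVocabulary:
    """Ordered collection of binary trait labels.

    Order is stable across I/O round trips; labels are unique.
    """

    def __init__(self, labels: Iterable[str], descriptions: Optional[Mapping[str, str]] = None):
        labels = list(labels)
        if len(labels) != len(set(labels)):
            raise ValueError("trait labels must be unique")
        self.labels: list[str] = labels
        self.descriptions: dict[str, str] = dict(descriptions or {})

    def __contains__(self, label: str) -> bool:
        return label in set(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, TraitVocabulary) and self.labels == other.labels

    def extend(self, labels: Iterable[str]) -> None:
        """Append new labels, ignoring ones already present."""
        known = set(self.labels)
        for lab in labels:
            if lab not in known:
                self.labels.append(lab)
                known.add(lab)

    def __repr__(self) -> str:
        return f"TraitVocabulary({len(self.labels)} labels)"


def default_soil_vocabulary() -> TraitVocabulary:
    """The 25-label binary trait vocabulary of the soil food-web data."""
    return TraitVocabulary([a for a, _ in SOIL_TRAITS], dict(SOIL_TRAITS))


@dataclass
class SpeciesRecord:
    """One species: identifier, binary trait labels, continuous traits.

    ``body_mass_log`` is the natural log of body mass in grams; ``ph0`` and
    ``ph1`` are the species' scores on the first two principal-coordinate
    axes of a taxonomic distance matrix.  After featurization all three lie
    in [0, 1).
    """

    species_id: SpeciesId
    binary_traits: set[str] = field(default_factory=set)
    body_mass_log: Optional[float] = None
    ph0: Optional[float] = None
    ph1: Optional[float] = None

    def continuous(self) -> dict[str, Optional[float]]:
        return {"body_mass_log": self.body_mass_log, "ph0": self.ph0, "ph1": self.ph1}


class FoodWeb:
    """Species registry plus directed interaction set (predator -> prey).

    Both endpoints of every pair are registered species, and the interaction
    and non-interaction sets are disjoint.  Self-loops (cannibalism) are
    allowed.
    """

    def __init__(self, vocabulary: Optional[TraitVocabulary] = None):
        self.species: dict[SpeciesId, SpeciesRecord] = {}
        self.interactions: set[tuple[SpeciesId, SpeciesId]] = set()
        self.non_interactions: set[tuple[SpeciesId, SpeciesId]] = set()
        self.vocabulary = vocabulary
        self.metadata: dict = {}

    # -- registry -----------------------------------------------------------

    def add_species(self, record: SpeciesRecord) -> SpeciesRecord:
        if record.species_id in self.species:
            raise ValueError(f"species {record.species_id!r} already registered")
        if self.vocabulary is not None:
            unknown = record.binary_traits - set(self.vocabulary.labels)
            if unknown:
                raise ValueError(
                    f"species {record.species_id!r} carries traits outside the "
                    f"vocabulary: {sorted(unknown)}"
                )
        self.species[record.species_id] = record
        return record

    def ensure_species(self, species_id: SpeciesId) -> SpeciesRecord:
        """Return the record for ``species_id``, auto-registering if absent."""
        if species_id not in self.species:
            self.species[species_id] = SpeciesRecord(species_id)
        return self.species[species_id]

    @property
    def species_ids(self) -> list[SpeciesId]:
        return sorted(self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    # -- interactions -------------------------------------------------------

    def add_interaction(self, predator: SpeciesId, prey: SpeciesId) -> None:
        pair = (predator, prey)
        if pair in self.non_interactions:
            raise ValueError(f"pair {pair!r} recorded both as interaction and absence")
        self.ensure_species(predator)
        self.ensure_species(prey)
        self.interactions.add(pair)

    def add_non_interaction(self, predator: SpeciesId, prey: SpeciesId) -> None:
        pair = (predator, prey)
        if pair in self.interactions:
            raise ValueError(f"pair {pair!r} recorded both as interaction and absence")
        self.ensure_species(predator)
        self.ensure_species(prey)
        self.non_interactions.add(pair)

    def prey_set(self, species_id: SpeciesId) -> set[SpeciesId]:
        """Preys of ``species_id``: {q : (species_id, q) in interactions}."""
        if species_id not in self.species:
            raise KeyError(f"unknown species {species_id!r}")
        return {q for p, q in self.interactions if p == species_id}

    def prey_sets(self) -> dict[SpeciesId, set[SpeciesId]]:
        """All prey sets in one pass (cheaper than n calls to prey_set)."""
        out: dict[SpeciesId, set[SpeciesId]] = {s: set() for s in self.species}
        for p, q in self.interactions:
            out[p].add(q)
        return out

    def predators(self) -> list[SpeciesId]:
        """Species with at least one prey, in sorted order."""
        preying = {p for p, _ in self.interactions}
        return sorted(preying)

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        for pair in self.interactions | self.non_interactions:
            for end in pair:
                if end not in self.species:
                    raise ValueError(f"pair {pair!r} references unregistered species {end!r}")
        overlap = self.interactions & self.non_interactions
        if overlap:
            raise ValueError(f"{len(overlap)} pairs labelled both 1 and 0, e.g. {next(iter(overlap))!r}")

    def __repr__(self) -> str:
        return (
            f"FoodWeb({self.n_species} species, {len(self.interactions)} interactions, "
            f"{len(self.non_interactions)} observed absences)"
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path, sep: Optional[str]) -> pd.DataFrame:
    try:
        # sep=None sniffs comma vs tab
        return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path}: {exc}") from exc


def read_interactions(
    path,
    predator_col: str = "predator",
    prey_col: str = "prey",
    label_col: str = "label",
    sep: Optional[str] = None,
    web: Optional[FoodWeb] = None,
) -> FoodWeb:
    """Read an edge list (CSV/TSV) into a :class:`FoodWeb`.

    The file needs at least ``predator_col`` and ``prey_col``.  An optional
    ``label_col`` distinguishes interactions (1) from observed absences (0);
    without it every row is an interaction.  Duplicate rows are collapsed;
    a pair labelled both 1 and 0 is an error.
    """
    df = _read_table(path, sep)
    for col in (predator_col, prey_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    has_label = label_col in df.columns

    if web is None:
        web = FoodWeb()
    n_inter = n_absent = 0
    seen: dict[tuple, int] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        pred = getattr(row, predator_col)
        prey = getattr(row, prey_col)
        if pd.isna(pred) or pd.isna(prey):
            raise ValueError(f"{path}: malformed row at line {idx}: missing endpoint")
        if has_label:
            lab = getattr(row, label_col)
            if pd.isna(lab) or int(lab) not in (0, 1):
                raise ValueError(f"{path}: malformed row at line {idx}: label must be 0 or 1")
            lab = int(lab)
        else:
            lab = 1
        pair = (pred, prey)
        if pair in seen and seen[pair] != lab:
            raise ValueError(f"{path}: pair {pair!r} labelled both 1 and 0")
        seen[pair] = lab
        if lab == 1:
            if pair not in web.interactions:
                web.add_interaction(pred, prey)
                n_inter += 1
        else:
            if pair not in web.non_interactions:
                web.add_non_interaction(pred, prey)
                n_absent += 1
    web.metadata["parsed_interactions"] = n_inter
    web.metadata["parsed_non_interactions"] = n_absent
    logger.info("read %d interactions and %d observed absences from %s", n_inter, n_absent, path)
    return web


def read_traits(
    path,
    web: Optional[FoodWeb] = None,
    vocabulary: Optional[TraitVocabulary] = None,
    id_col: str = "id",
    mass_col: str = "body_mass_log",
    ph0_col: str = "ph0",
    ph1_col: str = "ph1",
    sep: Optional[str] = None,
) -> FoodWeb:
    """Read a species trait table (one row per species) into ``web``.

    Binary columns are the intersection of the header with ``vocabulary``
    (or, if no vocabulary is given, every column that is not the id or a
    continuous column).  Continuous columns are stored raw; featurization
    (scaling, binning) is a separate stage.  Species in the table that are
    not in the web are registered; a warning counts trait rows for species
    absent from an already-populated web.
    """
    df = _read_table(path, sep)
    if id_col not in df.columns:
        raise ValueError(f"{path}: missing id column {id_col!r}")
    continuous = {mass_col, ph0_col, ph1_col}
    if vocabulary is None:
        binary_cols = [c for c in df.columns if c != id_col and c not in continuous]
        vocabulary = TraitVocabulary(binary_cols)
    else:
        binary_cols = [c for c in vocabulary.labels if c in df.columns]

    if web is None:
        web = FoodWeb(vocabulary=vocabulary)
    if web.vocabulary is None:
        web.vocabulary = vocabulary
    else:
        web.vocabulary.extend(vocabulary.labels)

    had_interactions = bool(web.interactions)
    known = set(web.species)
    n_new = 0
    for idx, row in df.iterrows():
        sid = row[id_col]
        vals = row[binary_cols]
        bad = [c for c, v in vals.items() if v not in (0, 1)]
        if bad:
            raise ValueError(
                f"{path}: non-binary value in binary column(s) {bad} for species {sid!r}"
            )
        if sid not in known:
            n_new += 1
        rec = web.ensure_species(sid)
        rec.binary_traits = {c for c, v in vals.items() if v == 1}
        for col, attr in ((mass_col, "body_mass_log"), (ph0_col, "ph0"), (ph1_col, "ph1")):
            if col in df.columns and not pd.isna(row[col]):
                setattr(rec, attr, float(row[col]))
    if had_interactions and n_new:
        warnings.warn(
            f"{n_new} species in the trait table were absent from the web",
            stacklevel=2,
        )
    return web


def write_interactions(web: FoodWeb, path, include_absences: bool = True) -> None:
    """Write the edge list as CSV (predator, prey, label)."""
    rows = [(p, q, 1) for p, q in sorted(web.interactions)]
    if include_absences:
        rows += [(p, q, 0) for p, q in sorted(web.non_interactions)]
    pd.DataFrame(rows, columns=["predator", "prey", "label"]).to_csv(path, index=False)


def write_traits(web: FoodWeb, path, vocabulary: Optional[TraitVocabulary] = None) -> None:
    """Write the species trait table as CSV (0/1 columns + continuous)."""
    vocab = vocabulary or web.vocabulary
    if vocab is None:
        labels = sorted({t for rec in web.species.values() for t in rec.binary_traits})
        vocab = TraitVocabulary(labels)
    rows = []
    for sid in web.species_ids:
        rec = web.species[sid]
        row: dict = {"id": sid}
        for lab in vocab.labels:
            row[lab] = int(lab in rec.binary_traits)
        row["body_mass_log"] = rec.body_mass_log
        row["ph0"] = rec.ph0
        row["ph1"] = rec.ph1
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_adjacency(web: FoodWeb, path) -> None:
    """Write the web as a square 0/1 CSV matrix, rows=predators, cols=preys.

    Row and column order is sorted ``species_id``.
    """
    if web.n_species == 0:
        raise ValueError("cannot write adjacency of an empty web")
    ids = web.species_ids
    index = {s: i for i, s in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)), dtype=int)
    for p, q in web.interactions:
        mat[index[p], index[q]] = 1
    try:
        pd.DataFrame(mat, index=ids, columns=ids).to_csv(path)
    except OSError as exc:
        raise OSError(f"failed writing adjacency matrix to {path}: {exc}") from exc


def read_adjacency(path) -> FoodWeb:
    """Read a square 0/1 adjacency CSV written by :func:`write_adjacency`."""
    df = pd.read_csv(path, index_col=0)
    # column labels come back as strings; realign with the index dtype
    df.columns = df.index
    web = FoodWeb()
    for sid in df.index:
        web.ensure_species(sid)
    arr = df.to_numpy()
    ids = list(df.index)
    for i, j in zip(*np.nonzero(arr)):
        web.add_interaction(ids[i], ids[j])
    return web
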