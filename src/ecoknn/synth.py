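"""Synthetic food webs: niche-model generator, trait attachment, fixtures.

The niche model places every species at a uniform position on a
one-dimensional niche axis; each consumes every species falling inside a
contiguous diet interval.  The interval's width is the species' niche value
times a Beta(1, (1 - 2C)/(2C)) draw — which makes the expected fraction of
realized links equal the target connectance C — and its centre is uniform
between half the width and the species' own niche value, biasing diets
toward lower-niche (smaller) species.  The resulting webs are nested (diets
overlap hierarchically), which is exactly the structure the KNN recommender
exploits.

``attach_synthetic_traits`` decorates a niche web with traits correlated
with diet, so both the trait channel of the recommender and the trait-only
supervised baseline have learnable signal: log body mass is affine in the
niche value, the two taxonomy-like coordinates encode the diet interval's
centre and width, and four binary guild labels threshold the niche axis.
All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FoodWeb, SpeciesRecord, TraitVocabulary, default_soil_vocabulary

#: Affine map from niche value in [0, 1] to ln body mass in grams, spanning
#: roughly bacteria (~1e-13 g) to large soil macrofauna (~1 g).
MASS_LOG_RANGE = (-30.0, 0.0)

GUILD_LABELS = ("G1", "G2", "G3", "G4")


@dataclass(frozen=True)
class NicheParams:
    """Niche-model parameters: community size, target connectance, seed."""

    n_species: int
    connectance: float
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("n_species must be at least 4")
        if not (0.0 < self.connectance < 0.5):
            raise ValueError(f"connectance must lie in (0, 0.5), got {self.connectance}")


def generate_niche_web(params: NicheParams) -> FoodWeb:
    """Draw one binary niche-model food web.

    Species ids are 0..n-1 in niche order is *not* guaranteed; ids follow
    the draw order.  The niche value, diet-interval centre and width of each
    species are retained in ``web.metadata`` under ``"niche"``, ``"center"``
    and ``"range"`` so traits can later be attached.  Every diet is a
    contiguous interval of the niche axis; expected realized connectance
    approximates ``params.connectance``.
    """
    n, c = params.n_species, params.connectance
    rng = np.random.default_rng(params.seed)
    niche = rng.uniform(size=n)
    beta_b = (1.0 - 2.0 * c) / (2.0 * c)
    width = niche * rng.beta(1.0, beta_b, size=n)
    center = rng.uniform(width / 2.0, niche)

    web = FoodWeb()
    for i in range(n):
        web.add_species(SpeciesRecord(i))
    lo = center - width / 2.0
    hi = center + width / 2.0
    for i in range(n):
        for j in np.nonzero((niche >= lo[i]) & (niche <= hi[i]))[0]:
            web.add_interaction(i, int(j))
    web.metadata["niche"] = {i: float(niche[i]) for i in range(n)}
    web.metadata["center"] = {i: float(center[i]) for i in range(n)}
    web.metadata["range"] = {i: float(width[i]) for i in range(n)}
    web.metadata["params"] = params
    return web


def attach_synthetic_traits(web: FoodWeb, noise: float = 0.05, seed: int = 0) -> FoodWeb:
    """Attach diet-correlated traits to a niche web, in place.

    - ``body_mass_log``: affine in the niche value plus Gaussian noise with
      standard deviation ``noise`` on the niche scale.
    - ``ph0`` / ``ph1``: the diet interval's centre and width plus the same
      Gaussian noise — low-dimensional stand-ins for taxonomy coordinates.
    - binary guild labels G1..G4: which quarter of the niche axis the
      (noise-perturbed) niche value falls into.

    With ``noise = 0`` body mass is strictly monotone in the niche value and
    the interaction rule is an exact threshold on the traits; as noise grows
    the trait channels decouple from diet and trait-only prediction decays
    to chance.  Deterministic under ``seed``.
    """
    if noise < 0:
        raise ValueError("noise must be nonnegative")
    for key in ("niche", "center", "range"):
        if key not in web.metadata:
            raise ValueError("web lacks niche metadata; generate it with generate_niche_web")
    rng = np.random.default_rng(seed)
    ids = web.species_ids
    n = len(ids)
    niche = np.array([web.metadata["niche"][s] for s in ids])
    center = np.array([web.metadata["center"][s] for s in ids])
    width = np.array([web.metadata["range"][s] for s in ids])

    lo, hi = MASS_LOG_RANGE
    mass = lo + (hi - lo) * (niche + noise * rng.normal(size=n)).clip(0.0, 1.0)
    ph0 = (center + noise * rng.normal(size=n)).clip(0.0, 1.0 - 1e-9)
    ph1 = (width + noise * rng.normal(size=n)).clip(0.0, 1.0 - 1e-9)
    guild_basis = (niche + noise * rng.normal(size=n)).clip(0.0, 1.0)

    if web.vocabulary is None:
        web.vocabulary = TraitVocabulary(list(GUILD_LABELS))
    else:
        web.vocabulary.extend(GUILD_LABELS)
    for i, sid in enumerate(ids):
        rec = web.species[sid]
        rec.body_mass_log = float(mass[i])
        rec.ph0 = float(ph0[i])
        rec.ph1 = float(ph1[i])
        quarter = min(int(guild_basis[i] * 4), 3)
        rec.binary_traits.add(GUILD_LABELS[quarter])
    return web


def table3_microweb() -> FoodWeb:
    """The four-predator worked-example web used throughout the docs.

    Species 0, 6, 28 and 70 are predators with printed trait and prey sets;
    prey-only taxa (42, 47, 72, 812) are registered with empty trait sets so
    distance computations stay total.
    """
    web = FoodWeb(vocabulary=default_soil_vocabulary())
    predators = {
        0: ({"Ar", "Ca"}, {6, 42, 47}),
        6: ({"Ar", "Ca"}, {42, 47, 70, 72}),
        28: ({"Ar", "Ca"}, {42, 47, 70, 812}),
        70: ({"Ca"}, {42, 47, 812}),
    }
    for sid, (traits, _) in predators.items():
        web.add_species(SpeciesRecord(sid, binary_traits=set(traits)))
    for sid, (_, preys) in predators.items():
        for prey in preys:
            web.add_interaction(sid, prey)
    return web


def make_nested_web(
    n_predators: int = 300,
    n_preys: int = 300,
    seed: int = 0,
    size_mu: float = 2.5,
    size_sigma: float = 1.4,
    noise: float = 0.1,
) -> FoodWeb:
    """Subset-nested web: diets are noisy prefixes of one global prey order.

    Each predator draws a diet size from a lognormal (heavy-tailed, so the
    community holds many specialists and a few generalists, as in real soil
    webs) and consumes the first ``size`` preys of a fixed shuffled prey
    ordering — smaller diets are subsets of larger ones, the hierarchical
    overlap the KNN recommender exploits.  ``noise`` is the probability that
    each diet member is swapped for a uniformly random outside prey,
    degrading nestedness smoothly.  Predator ids are 0..n_predators-1, prey
    ids follow; deterministic under ``seed``.
    """
    if n_predators < 2 or n_preys < 2:
        raise ValueError("need at least 2 predators and 2 preys")
    if not (0.0 <= noise < 1.0):
        raise ValueError("noise must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sizes = np.clip(
        np.round(rng.lognormal(size_mu, size_sigma, size=n_predators)).astype(int), 2, n_preys
    )
    web = FoodWeb()
    for i in range(n_predators):
        web.add_species(SpeciesRecord(i))
    prey_ids = np.arange(n_predators, n_predators + n_preys)
    for j in prey_ids:
        web.add_species(SpeciesRecord(int(j)))
    order = prey_ids.copy()
    rng.shuffle(order)
    for i, s in enumerate(sizes):
        diet = set(int(p) for p in order[:s])
        if noise:
            outside = [int(p) for p in prey_ids if int(p) not in diet]
            for p in sorted(diet):
                if outside and rng.uniform() < noise:
                    diet.discard(p)
                    q = outside[int(rng.integers(len(outside)))]
                    diet.add(q)
                    outside.remove(q)
        for p in sorted(diet):
            web.add_interaction(i, p)
    return web


def make_mass_window_web(n_species: int = 200, window: float = 0.15, seed: int = 0) -> FoodWeb:
    """Web whose interactions follow a deterministic body-mass window rule.

    Every species draws a size uniformly on (0, 1); predator ``i`` consumes
    prey ``j`` exactly when ``0 < size_i - size_j <= window`` — a pure
    threshold rule on the body-mass difference, so trait-only classification
    is learnable by construction.  ``body_mass_log`` is the affine image of
    the size on the usual log-gram scale; ``ph0``/``ph1`` are independent
    uniform draws carrying no signal.  Deterministic under ``seed``.
    """
    if n_species < 4:
        raise ValueError("n_species must be at least 4")
    if not (0.0 < window < 1.0):
        raise ValueError("window must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    size = rng.uniform(size=n_species)
    lo, hi = MASS_LOG_RANGE
    web = FoodWeb()
    for i in range(n_species):
        web.add_species(
            SpeciesRecord(
                i,
                body_mass_log=float(lo + (hi - lo) * size[i]),
                ph0=float(rng.uniform()),
                ph1=float(rng.uniform()),
            )
        )
    diff = size[:, None] - size[None, :]
    for i, j in zip(*np.nonzero((diff > 0) & (diff <= window))):
        web.add_interaction(int(i), int(j))
    web.metadata["size"] = {i: float(size[i]) for i in range(n_species)}
    web.metadata["window"] = window
    return web


def make_clone_web(n_groups: int, group_size: int, diet_size: int, seed: int = 0) -> FoodWeb:
    """Web of predator groups with identical within-group, disjoint
    across-group diets — a nestedness stress fixture.

    With group size above K, leave-one-prey-out retrieval is perfect (the
    removed prey is always the unique novel candidate among the clones);
    with groups of one the diets are fully disjoint and retrieval is
    impossible.  Predator ids are 0..n_groups*group_size-1; prey ids follow.
    Total interactions = n_groups * group_size * diet_size.
    """
    if min(n_groups, group_size, diet_size) < 1:
        raise ValueError("n_groups, group_size and diet_size must all be >= 1")
    rng = np.random.default_rng(seed)
    n_pred = n_groups * group_size
    prey_pool = np.arange(n_pred, n_pred + n_groups * diet_size)
    rng.shuffle(prey_pool)
    web = FoodWeb()
    for sid in range(n_pred):
        web.add_species(SpeciesRecord(sid))
    for sid in prey_pool:
        web.add_species(SpeciesRecord(int(sid)))
    for g in range(n_groups):
        diet = prey_pool[g * diet_size : (g + 1) * diet_size]
        for member in range(g * group_size, (g + 1) * group_size):
            for prey in diet:
                web.add_interaction(member, int(prey))
    return web
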