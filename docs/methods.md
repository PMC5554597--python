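# Methods

## Model

`ecoknn` implements instance-based, positive-only link prediction for binary
directed food webs. No model is fitted: a focal species' candidate preys are
scored directly from the diets of its K nearest neighbours under the
trait-weighted Tanimoto distance

d(x, y; w_t) = w_t · (1 − |x_t ∩ y_t| / |x_t ∪ y_t|) + (1 − w_t) · (1 − |x_i ∩ y_i| / |x_i ∪ y_i|),

where x_t is the species' set of binary trait labels and x_i its prey set.
The method's core assumption is **nestedness**: that species cluster around
shared prey sets, so a focal's missing preys appear in the diets of similar
species. On webs where every predator has a unique diet the approach cannot
work, and the clone-web fixtures make both limits testable exactly (perfect
retrieval when clone groups exceed K; zero retrieval on disjoint diets).

Two conventions the distance needs to be total:

- two empty sets have Tanimoto similarity 1 (identical sets must have
  distance 0; the alternative would make every prey-only species maximally
  distant from every other, including its twins);
- `lookup(i, i) = 0` by convention; only the n(n−1)/2 off-diagonal distances
  are stored, in a packed triangular array, and neighbour search is an exact
  linear scan — at the package's intended scale (n ≲ 10³) an index structure
  buys nothing.

## Ranking and ties

Candidates are ranked by vote count (how many of the K neighbours eat them),
excluding the focal's current preys only — a neighbour can itself be a
candidate. Vote ties are broken by the summed similarity (1 − distance) of
the endorsing neighbours, then by ascending species id; ties at the K-th
neighbour distance break by ascending id. The endorsement rule is a
reconstruction: it is one of several orderings consistent with the worked
four-predator example (a most-similar-single-endorser rule agrees there
too), so rankings that straddle a vote tie carry that ambiguity.

## Featurization

Continuous attributes (log body mass and two taxonomy coordinates) enter the
set-based similarity as binary features:

1. **PCoA** (classical MDS) of a square taxonomic distance matrix:
   B = −½ J D⁽²⁾ J, eigendecomposition, coordinates = eigenvectors ×
   √eigenvalue for the leading axes. Negative eigenvalues — routine for
   non-Euclidean taxonomic distances — are clamped to zero. Axis signs are
   arbitrary in exact arithmetic, so each axis is flipped to make its
   largest-magnitude loading positive; sign cannot affect downstream bins.
   An all-zero distance matrix returns all-zero coordinates (coincident
   points); a nonzero matrix with no positive eigenvalue beyond the first is
   rejected when two axes are requested.
2. **Unit-interval scaling**: v ↦ (v − min) / ((max − min)(1 + ε)), ε = 1e−9,
   the simplest order-preserving map that keeps the maximum strictly below 1.
3. **Quartile binarization**: species are stable-sorted by (value, id) and
   cut into four consecutive blocks whose sizes differ by at most one (881
   species → 221/220/220/220); each species gains exactly one of four bin
   labels per variable, twelve new binary traits in all. Rank-based binning
   makes the raw-vs-scaled question moot: both orderings are identical.

## Evaluation protocol

One trial: pick a focal with ≥ 2 preys on the intact web, remove one prey
uniformly at random, recommend up to 10 preys against the reduced prey set,
record the rank of the removed prey (or non-retrieval beyond rank 10),
restore the web. Ten replicates per focal; K over the odd values 1–19 and
w_t over {0, 0.2, 0.4, 0.6, 0.8, 1} by default. Distances are computed once
per trait weight on the **intact** web and shared across all K — removal
happens after the matrix is built. An exact mode that rebuilds the matrix
per trial exists behind `recompute_distances=True`; it is much slower and
changes little, since a single removed edge barely moves any Jaccard value.

Seeding: the per-trial seed is `SeedSequence(master, spawn_key=(focal_index,
replicate))`, so every trial is independently reproducible and the removal
draw depends only on (focal, replicate) — never on K or w_t — making grid
cells directly comparable. Species with zero or one prey never serve as
focals but remain available as neighbours and candidates. Stratified rates
bin focals by intact diet size (≤ 10, 11–100, > 100); empty bins report NaN
with a zero trial count, not a zero rate.

## Supervised baseline

Each ordered pair (predator, prey) becomes a feature row: predator trait
vector concatenated with prey trait vector (binary labels as 0/1 plus the
three continuous traits per side). Concatenation is the minimal encoding
that lets a forest express size-ratio and guild rules; it is a
reconstruction, not a documented choice. Unobserved pairs are labelled 0
(matrix-completion framing); self pairs are excluded by default and
toggleable. A scikit-learn random forest is fitted on 95% of pairs
(unstratified uniform split by default, stratified and class-weighted modes
available) and scored on the 5% holdout; a 3-fold grid search runs when the
hyperparameter grid has more than one point. The four metrics are native:
interaction precision tp/(tp+fp), non-interaction precision tn/(tn+fn),
class-weighted accuracy (Score_y·n₁ + Score_¬y·n₀)/n² (the strict n² form
requires the diagonal; `train_and_score` uses the table's own pair count as
denominator), and TSS, which is prevalence-insensitive — the right summary
when non-interactions outnumber interactions twentyfold.

## Synthetic webs — what they emulate, and what not

All generators are pure functions of their seed.

- **Niche model** (`generate_niche_web`): niche value uniform on (0, 1);
  diet width = niche value × Beta(1, (1 − 2C)/(2C)), making the expected
  connectance C; diet centre uniform between half-width and the niche value.
  Diets are contiguous intervals; realized connectance is unbiased within
  Monte-Carlo error (checked at n = 200 over 50 seeds, tolerance ±0.02).
- **Synthetic traits** (`attach_synthetic_traits`): log body mass affine in
  the niche value over roughly e⁻³⁰–e⁰ grams (bacteria to macrofauna); the
  two taxonomy-like coordinates expose the diet interval's centre and width;
  four guild labels threshold the niche axis at quarters. Gaussian noise with
  a common standard deviation degrades all channels toward chance.
- **Nested web** (`make_nested_web`): diets are noisy prefixes of one global
  prey ordering with lognormal(2.5, 1.4) sizes — many specialists, few
  generalists, mirroring empirical diet-size distributions — and a 10%
  per-prey rewiring probability. Defaults chosen to populate all three
  diet-size strata at a few hundred predators.
- **Clone web** (`make_clone_web`) and **mass-window web**
  (`make_mass_window_web`): analytic fixtures — exact retrieval limits, and
  a deterministic threshold rule on the body-mass difference that a
  trait-only classifier can learn essentially perfectly.

A finding worth recording: niche-model webs **reverse** the empirical
diet-size gradient of retrieval success (generalists are retrieved better
than specialists), because interval diets give specialists no clone-like
redundancy — each specialist's 2-prey diet is its own. Subset-nested webs,
where many specialists share identical small diets, reproduce the empirical
direction (top-1 ≈ 0.83 for ≤ 10 preys vs ≈ 0.17 for > 100 at K = 7,
w_t = 0 on the 300-predator default). Passing tests on these generators
demonstrate the mechanics of the method under controlled structure; they do
not certify performance on real webs, whose nestedness, trait noise and
taxonomic bias the generators only caricature.

## Problem sizes and numerical choices

The test and acceptance suites run at n = 40–300 species (up to ~3,800
evaluation trials per grid cell and ~40,000 classifier pairs), sizes at
which every result above is stable across seeds. Distances are clipped to
[0, 1] after vectorized computation to absorb float round-off; the
unit-interval scaler refuses constant vectors (no defined scale); quartile
binning refuses n < 4. Web I/O is plain CSV/TSV (edge list, trait table,
square adjacency, square distance matrix); species ids may be integers or
strings but must be mutually comparable, since deterministic tie-breaking
sorts them.

## Known limitations

- Binary interactions only: no abundances, preferences or interaction
  strengths, and no indirect (hypergraph) effects.
- The distance is fixed, not learned; performance is bounded by how much
  diet overlap and the chosen traits actually encode.
- The supervised baseline ignores community context by construction — it
  sees only the pair's traits.
- Tie-breaking beyond vote counts is a documented reconstruction (above);
  alternative rules reorder candidates only within exact vote-and-similarity
  ties.
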