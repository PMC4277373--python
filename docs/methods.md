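# Methods

## Scope and data model

The package evaluates a DNA barcode reference library built from aligned COI
sequences with specimen metadata. Specimens carry a species / genus / family
taxonomy, a sampling region mapped onto two roles — *reference* (the library)
and *query* (the specimens to identify) — and optional distribution-category
and dispersal-class annotations. All analyses are distance-based; no trees
are built.

## Distances

Pairwise distances use the Kimura 2-parameter model. For each sequence pair,
sites where either base is not an unambiguous A/C/G/T are excluded
(*pairwise deletion*); among the n compared sites, P is the transition
proportion (A↔G, C↔T) and Q the transversion proportion, and

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q).

Two conventions matter downstream:

- A pair is **undefined** when n < `min_overlap` (default 100 sites) or when
  a logarithm argument is non-positive (saturation). Undefined pairs are
  recorded and excluded from all minima/maxima; clamping them to a large
  value would silently distort nearest-neighbour statistics.
- Distances are stored as proportions and reported as percentages.

K2P does not guarantee the triangle inequality; nothing here assumes it.
Inputs must be pre-aligned (COI barcodes are length-conserved in the groups
this targets); a strict length check replaces an alignment stage. The
all-pairs computation is exact, implemented with one-hot site indicators and
matrix products rather than a pair loop.

## Gap statistics and diagnosability

Per species: maximum and mean intraspecific distance, the nearest
heterospecific neighbour (NN) and its distance (minimum pairwise distance
between the species' specimens and any heterospecific specimen), and a
barcode-gap flag (NN distance > max intraspecific). Singletons contribute
max = mean = 0 and are flagged so users can exclude them. NN ties break to
the lexicographically smaller species name and are logged.

**Diagnosability** is operationalised as single-linkage isolation: a species
is diagnosable iff (a) no conspecific–heterospecific pair is at distance 0,
and (b) the largest edge of the minimum spanning tree over its own specimens
is strictly smaller than its minimum interspecific distance. This counts
deep intraspecific splits as diagnosable (the species still separates
cleanly at some threshold) while failing barcode sharing and intermingled
sequences, which is the behaviour the field means by "possesses a diagnostic
barcode".

Threshold censuses use strict inequality (a species at exactly 1.0 % is not
"<1 %"). The sample-size analysis regresses NN distance (%) on
log₁₀ of the harmonic mean H = 2·n₁·n₂/(n₁+n₂) of the species' and its
NN's sample sizes (OLS, two-sided t-test on the slope). Residual-based
comparisons regress max intraspecific distance on sample size; when every
species has the same n the slope is unidentifiable and the residuals fall
back to mean-centering.

The partition comparison recomputes the gap statistics on the
reference-region subset alone and on the pooled sample. Since pooling only
adds specimens, max_intra can only grow and NN distance can only shrink;
both invariants are asserted in tests for every species.

## Identification

Two criteria identify query-region specimens against the reference library:
pure nearest neighbour (assign the closest library specimen's species, no
threshold) and best close match (majority species among library specimens
within a threshold, default 2 %; none → no identification; tie →
ambiguous). Query species absent from the library are tallied separately
instead of being scored incorrect — that outcome measures library coverage,
not method failure. Identification success rates are reported even though
the underlying study design treats diagnosability as the headline number;
success against a distant reference library is the design's purpose.

## BIN-style clustering (RESL)

Sequences are pre-clustered by single linkage at 2.2 % (edges where
d < threshold; undefined pairs contribute no edge). Each pre-cluster is then
refined by Markov clustering on a similarity graph and the refinement is
accepted only if it improves the partition's mean silhouette.

Choices that the published sketch of RESL leaves open, all exposed in
`RESLConfig`:

- similarity transform `w = max(0, 1 − d/(s·t))` with threshold t and scale
  s = 1 (similarity reaches zero at the pre-clustering threshold). A gentler
  decay (e.g. zero at 2t) leaves so little contrast on a dense pre-cluster
  that the MCL flow matrix converges to its uniform fixed point and no split
  is ever proposed; s = 1 recovers genuine sub-structure.
- MCL: self-loops of weight 1, column-normalised, expansion 2, inflation 2.0
  (configurable), iterated to max-change < 1e−8 or 200 iterations;
  non-convergence keeps the pre-cluster unsplit with a warning. Clusters are
  the connected components of the converged flow's support, which handles
  the block-uniform limit states cleanly.
- silhouette: s(i) = (b−a)/max(a,b) with a = mean distance to own cluster,
  b = smallest mean distance to another cluster; singleton members score 0
  and a one-cluster partition is defined as 0, so "do not split" is the
  neutral reference. Acceptance requires mean silhouette > 0 (plus an
  optional margin), applied per pre-cluster.

The refinement can split but never merge across pre-clusters, so the final
partition is always a refinement of the single-linkage one. Cluster ids are
"C0001"-style, assigned in order of first member appearance; permuting the
input order relabels clusters but never changes the partition. Clustering is
local to the dataset — there is no global BIN registry, so cluster counts on
a public dataset need not match registry BIN counts.

**Concordance** classes per species: *match* (one cluster, unshared),
*merge* (one cluster shared with another species), *split* (≥2 clusters,
none shared), *mixture* (≥2 clusters, some shared). For splits, the regional
pattern is *between_regions* when the clusters segregate cleanly by region,
*within_region* when several clusters co-occur in one region, *both*
otherwise.

## Category models

Distribution categories are assigned from range data with precedence:
migratory → (gap > 500 km) disjunct → continuous (present in Germany, Czech
Republic, Poland, NW Russia and ≥2 of the three Baltic states, with ≥half
the provinces occupied in Germany and Poland) → fragmented. Only the 500 km
gap forces "disjunct"; country absences alone make a species fragmented, as
absence records are too uneven to be definitional.

The effect model is a Gaussian linear mixed model fitted by maximum
likelihood:

    y_s = μ + category_c(s) + γ·x_s + b_f(s) + ε_s,
    b_f ~ N(0, σ_f²),  ε_s ~ N(0, σ_c(s)²)

with a family-level random intercept and, when heteroscedastic, one residual
SD per category. Fixed effects are profiled out by GLS at each variance
configuration (Woodbury identities per family block), and the variance
parameters are maximised numerically (Nelder–Mead) from three fixed starting
points; the best likelihood wins, so fits are deterministic. With a single
family (or none) the random intercept is dropped, and the homoscedastic
model without covariate reduces exactly to one-way ANOVA — a closed-form
path also used for fast null simulations. The random effect is a family
intercept rather than genus-within-family nesting: at the sample sizes the
simulator produces, the genus level is weakly identified, and the family
intercept captures the phylogenetic correlation the model is there for;
genus nesting would be a config extension, not the default.

Likelihood-ratio tests compare nested fits; degrees of freedom count both
mean and variance parameters (a 4-level category against the null is 3 mean
contrasts + 3 variance ratios = 6 df). Pairwise category contrasts are Wald
z-tests on the GLS covariance, uncorrected. Responses: log₁₀ of
max-intraspecific / NN distance (species with zero or undefined NN are
excluded; species with max intra > NN excluded by a flag; zero max intra
either excluded or floored at half the smallest nonzero value — the
pipeline uses the floor, because dropping zero-divergence species would
selectively empty the least variable category), and max intraspecific
distance with sample size as covariate.

## Synthetic libraries

The generator emulates the two-region study design: `n_families ×
genera_per_family × species_per_genus` species (default 8×5×5 = 200), 3–4
reference and 1–2 query specimens each, nested taxonomy, categories
apportioned exactly to configured proportions (defaults 55 % continuous,
25 % fragmented, 18 % disjunct, 2 % migratory).

Sequences evolve under K80 with transition/transversion rate ratio κ = 4 by
exact per-branch site sampling: for a branch of expected length d
substitutions/site, each site changes with the exact K80 probabilities, so
consecutive branches compose correctly and measured K2P distances are
consistent with branch lengths up to estimator noise. Structure:

- per genus, a uniform-random ancestral sequence; each species' ancestor
  sits at branch `floor/2 + Exp((mean−floor)/2)` (defaults 3 % floor, 8 %
  mean between-species divergence within a genus). Between-family distances
  are unconstrained; NN structure comes from within-genus divergence only.
- within species, deterministic branch lengths: a regional split of 0.6·δ_c
  and tips of 0.2·δ_c, so the expected cross-region distance equals the
  category divergence δ_c (defaults: continuous 0.8 %, fragmented 1.1 %,
  disjunct 0.9 %, migratory 0.1 %). Branch lengths are deterministic because
  the substitution process at 658 sites already gives realised distances a
  large coefficient of variation; stacking exponential branch draws on top
  made the upper tail of max-intra unrealistically heavy.
- with probability `deep_split_fraction` (default 0.12) a non-migratory
  species gets an extra split of Uniform(2 %, 10 %) depth, placed between
  the regions with probability ½ and inside the reference region otherwise
  (one reference specimen moves to the deep lineage). Migratory species are
  excluded: their near-zero divergence is the category's defining feature.
- optional `n_noise_rate` replaces a fraction of emitted bases with N to
  exercise pairwise deletion; default 0. No indels, no among-site rate
  variation, no coalescent genealogies.

What the simulator does *not* emulate: real mitochondrial genealogies
(introgression, Wolbachia sweeps, incomplete lineage sorting), uneven
species richness per genus, misidentifications, or sequence-quality
artefacts. Tests passing on these libraries show the *pipeline* is correct
and well-calibrated under the stated model, not that any particular real
fauna behaves this way.

Scenario presets: `paper_like` (the defaults above), `no_structure` (0.3 %
intraspecific everywhere, 7 % interspecific floor, no deep splits — clusters
must equal species exactly), `heavy_splits` (50 % of species with a fixed
4 % split, 6 % floor — split detection must be near-perfect).

## Problem sizes and determinism

Default analyses run at 200 species / ~1000 specimens, where the full
pipeline completes in seconds; null-calibration simulations use 1000
replicates of the closed-form ANOVA path at n = 240. Every stochastic step
takes an explicit seed; reruns with the same config and seed are
byte-identical. `scripts/acceptance.py` recomputes all headline quantities
from a single seed.

## Known limitations

- Distance-based only: no monophyly or tree-based diagnosability.
- RESL here is a faithful re-implementation of the published *sketch*; the
  production BIN system clusters against a global registry and its exact
  parameters are unpublished, so cluster counts on shared datasets can
  differ legitimately.
- The heteroscedastic ML fit counts variance parameters in LRT df, which is
  standard but approximate in small samples; the type-I error calibration
  test covers the homoscedastic path at n = 240.
- `best_close_match` uses a simple majority among in-threshold candidates;
  no probabilistic assignment.
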