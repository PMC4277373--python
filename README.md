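# barcodegap

Evaluation toolkit for DNA barcode reference libraries.

DNA barcoding identifies animal specimens from a ~658 bp fragment of the
mitochondrial COI gene. Whether a barcode library actually works depends on
the *barcode gap*: for each species, the separation between its maximum
intraspecific K2P distance and the minimum distance to its nearest
heterospecific neighbour (NN). A recurring design question is whether a
library assembled in one region can identify specimens collected far away —
for example, a densely sampled national library (3–4 specimens per species)
used to identify single specimens from a site 1600 km distant.

`barcodegap` implements that evaluation end to end for people building or
auditing barcode libraries:

- **Distances** — pairwise Kimura 2-parameter distances with pairwise
  deletion of ambiguous/gapped sites:
  `d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`, where `P` and `Q` are the
  transition and transversion proportions among compared sites. Saturated
  or low-overlap pairs are *undefined*, never clamped.
- **Gap analysis** — per-species max/mean intraspecific distance, NN species
  and distance, barcode-gap and diagnosability calls (single-linkage
  isolation criterion), threshold censuses (<1 %, <2 %, …), NN distance vs.
  log₁₀ harmonic-mean sample size regression, and reference-region vs.
  pooled-sample comparisons.
- **Identification** — nearest-neighbour and best-close-match identification
  of query-region specimens against the reference library, with per-verdict
  rates.
- **BIN-style clustering** — Refined Single Linkage: 2.2 % single-linkage
  pre-clusters refined by Markov clustering, accepted on silhouette
  improvement; species×cluster concordance classes (match / merge / split /
  mixture) with regional split patterns.
- **Category models** — distribution-category rules (continuous, fragmented,
  disjunct, migratory) from range data, and Gaussian mixed models (family
  random intercept, per-category residual variances) with likelihood-ratio
  tests for category and dispersal effects on divergence.
- **Synthetic libraries** — a K80 sequence simulator that generates
  two-region libraries with configurable inter/intraspecific divergence,
  deep-split fraction and category structure, plus a ground-truth table, so
  the whole pipeline is testable without downloading anything.

## Worked example

```python
from barcodegap import (generate_library, get_preset, pairwise_matrix,
                        species_stats, library_test, assign_bins, concordance)
import numpy as np

ds, truth = generate_library(get_preset("paper_like", seed=1))
m = pairwise_matrix(ds)
stats = species_stats(m, ds)

mi = np.array([s.max_intra for s in stats])
nn = np.array([s.nn_dist for s in stats])
print(f"{len(stats)} species, {len(ds)} specimens")
print(f"mean max intraspecific distance: {mi.mean():.2f}%")
print(f"mean distance to nearest neighbour: {np.nanmean(nn):.2f}%")
print(f"species with a barcode gap: {np.mean([s.gap_present for s in stats]):.1%}")
print(f"diagnosable species: {np.mean([s.diagnosable for s in stats]):.1%}")

ident = library_test(ds, m, mode="nn")
print(f"query specimens identified correctly: {ident['rates']['correct']:.1%}")

records, agg = concordance(assign_bins(m, ds), ds)
print("species vs cluster concordance:", agg["by_class"])
```

prints

```
200 species, 1002 specimens
mean max intraspecific distance: 1.81%
mean distance to nearest neighbour: 6.88%
species with a barcode gap: 94.5%
diagnosable species: 94.5%
query specimens identified correctly: 100.0%
species vs cluster concordance: {'match': 173, 'merge': 0, 'split': 27, 'mixture': 0}
```

The NN distances (≈7 % on average) dwarf intraspecific variation (mostly
<1 %, with a ~12 % minority of deep splits >2 %), so the reference library
identifies every query specimen correctly even though the query "region" is
deliberately under-sampled. Deep-split species surface as `split`
concordance classes — candidate cryptic species — without hurting
identification.

The same analyses run on real data from the command line
(`barcodegap run --fasta lib.fasta --metadata meta.tsv --outdir out/`),
taking an aligned FASTA keyed by specimen id and a tab-separated metadata
table (`specimen_id`, `species`, `genus`, `family`, `region`, optional
`distribution_category` and `dispersal_class`). Individual stages are
available as subcommands (`simulate`, `distmat`, `gapstats`, `partition`,
`identify`, `cluster`, `concord`, `catfit`).

## Documentation

See `docs/methods.md` for the statistical model, the simulator's design and
its limitations, and the numerical conventions (tie-breaking, undefined
distances, degenerate fits).
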