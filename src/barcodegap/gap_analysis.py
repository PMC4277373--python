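"""Per-species barcode-gap statistics and partition comparisons.

The barcode gap of a species is the separation between its maximum
intraspecific distance and its minimum distance to the nearest heterospecific
neighbour (NN).  This module computes those statistics per species, calls
diagnosability, tallies threshold censuses (fraction of species below 1%, 2%,
...), quantifies sample-size effects on the NN distance, and compares a
reference-region-only partition against the pooled two-region sample.

All reported distances are percentages (K2P proportion x 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distances import DistanceMatrix
from .io_formats import SequenceDataset

logger = logging.getLogger("barcodegap")


@dataclass
class SpeciesGapStats:
    """Barcode-gap summary for one species (distances in %)."""

    species: str
    n_specimens: int
    max_intra: float
    mean_intra: float
    nn_species: str | None
    nn_dist: float  # NaN when no defined heterospecific distance exists
    gap_present: bool
    diagnosable: bool
    singleton: bool
    harmonic_n: float  # harmonic mean of own and NN-species sample sizes


@dataclass
class PartitionComparison:
    """Reference-only vs pooled statistics for one species (distances in %)."""

    species: str
    max_intra_ref: float
    max_intra_pooled: float
    nn_dist_ref: float
    nn_dist_pooled: float
    nn_species_ref: str | None
    nn_species_pooled: str | None
    nn_changed: bool
    nn_reduction_pct: float


def harmonic_mean(n1: int, n2: int) -> float:
    """Harmonic mean H = 2*n1*n2/(n1+n2) of two sample sizes."""
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    return 2.0 * n1 * n2 / (n1 + n2)


def _species_index(m: DistanceMatrix, ds: SequenceDataset) -> dict[str, np.ndarray]:
    """Map species -> row indices into the distance matrix."""
    by_sp: dict[str, list[int]] = {}
    for r in ds.records:
        by_sp.setdefault(r.species, []).append(m.index_of(r.specimen_id))
    return {sp: np.asarray(ix, dtype=int) for sp, ix in by_sp.items()}


def _min_between(m: DistanceMatrix, ix_a: np.ndarray, ix_b: np.ndarray) -> float:
    block = m.d[np.ix_(ix_a, ix_b)]
    if np.all(np.isnan(block)):
        return float("nan")
    return float(np.nanmin(block))


def species_stats(m: DistanceMatrix, ds: SequenceDataset) -> list[SpeciesGapStats]:
    """Compute per-species gap statistics from a distance matrix.

    Singletons get ``max_intra = mean_intra = 0`` with the singleton flag set.
    Undefined (NaN) pairs are ignored in minima and maxima.  When two species
    tie for nearest neighbour, the lexicographically smaller name wins and the
    tie is logged.
    """
    sp_ix = _species_index(m, ds)
    species = sorted(sp_ix)
    out: list[SpeciesGapStats] = []
    for sp in species:
        ix = sp_ix[sp]
        n = len(ix)
        if n == 1:
            max_intra = mean_intra = 0.0
            singleton = True
        else:
            singleton = False
            block = m.d[np.ix_(ix, ix)]
            vals = block[np.triu_indices(n, k=1)]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                max_intra = mean_intra = float("nan")
            else:
                max_intra = float(vals.max()) * 100.0
                mean_intra = float(vals.mean()) * 100.0

        nn_species: str | None = None
        nn_dist = float("nan")
        for other in species:
            if other == sp:
                continue
            dmin = _min_between(m, ix, sp_ix[other])
            if np.isnan(dmin):
                continue
            dmin *= 100.0
            if np.isnan(nn_dist) or dmin < nn_dist:
                nn_species, nn_dist = other, dmin
            elif dmin == nn_dist:
                # species are visited in lexicographic order, so the incumbent
                # is already the tie-break winner
                logger.info("NN tie for %s between %s and %s", sp, nn_species, other)

        if nn_species is None:
            gap = False
            h = float(n)
        else:
            gap = bool(nn_dist > max_intra)
            h = harmonic_mean(n, len(sp_ix[nn_species]))

        out.append(
            SpeciesGapStats(
                species=sp,
                n_specimens=n,
                max_intra=max_intra,
                mean_intra=mean_intra,
                nn_species=nn_species,
                nn_dist=nn_dist,
                gap_present=gap,
                diagnosable=diagnosable(sp, m, ds, _sp_ix=sp_ix),
                singleton=singleton,
                harmonic_n=h,
            )
        )
    return out


def _intra_mst_max_edge(m: DistanceMatrix, ix: np.ndarray) -> float:
    """Largest edge of the minimum spanning tree over one species' specimens.

    Prim's algorithm on the conspecific submatrix; undefined pairs are
    non-edges.  Returns inf when the specimens cannot be connected at all.
    """
    n = len(ix)
    if n == 1:
        return 0.0
    sub = m.d[np.ix_(ix, ix)].copy()
    sub[np.isnan(sub)] = np.inf
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = sub[0].copy()
    max_edge = 0.0
    for _ in range(n - 1):
        best[in_tree] = np.inf
        j = int(np.argmin(best))
        if not np.isfinite(best[j]):
            return float("inf")
        max_edge = max(max_edge, float(best[j]))
        in_tree[j] = True
        best = np.minimum(best, sub[j])
    return max_edge


def diagnosable(
    species: str,
    m: DistanceMatrix,
    ds: SequenceDataset,
    _sp_ix: dict[str, np.ndarray] | None = None,
) -> bool:
    """Whether a species has a diagnostic barcode.

    True iff (a) no conspecific/heterospecific pair is at distance zero, and
    (b) the largest edge of the minimum spanning tree connecting the species'
    own specimens is strictly smaller than its minimum interspecific distance.
    Condition (b) means single-linkage clustering at some threshold isolates
    the species exactly: deep intraspecific splits remain diagnosable as long
    as the intraspecific chain is tighter than the gap to the neighbour,
    whereas barcode sharing or intermingled sequences fail.
    """
    sp_ix = _species_index(m, ds) if _sp_ix is None else _sp_ix
    if species not in sp_ix:
        raise KeyError(f"species {species!r} not in dataset")
    ix = sp_ix[species]
    other_ix = np.concatenate([v for k, v in sp_ix.items() if k != species]) if len(sp_ix) > 1 else None
    if other_ix is None or other_ix.size == 0:
        return True
    inter = m.d[np.ix_(ix, other_ix)]
    if np.any(inter[~np.isnan(inter)] == 0.0):
        return False
    min_inter = np.nanmin(inter) if not np.all(np.isnan(inter)) else float("inf")
    return _intra_mst_max_edge(m, ix) < min_inter


def threshold_census(stats: list[SpeciesGapStats], thresholds: list[float]) -> dict:
    """Count species with max_intra strictly below each threshold (in %).

    Also reports the number of species with no intraspecific divergence at
    all (max_intra == 0) and the number at or above the top threshold.
    """
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    vals = np.array([s.max_intra for s in stats], dtype=float)
    n = len(vals)
    census: dict = {"n_species": n, "zero_divergence": int(np.sum(vals == 0.0))}
    for t in thresholds:
        c = int(np.sum(vals < t))
        census[f"lt_{t:g}"] = c
        census[f"lt_{t:g}_frac"] = c / n if n else 0.0
    if thresholds:
        top = thresholds[-1]
        census[f"ge_{top:g}"] = int(np.sum(vals >= top))
    return census


def nn_vs_samplesize_regression(stats: list[SpeciesGapStats]):
    """OLS of NN distance (%) on log10 of the harmonic-mean sample size.

    Returns (slope, intercept, p_value) with a two-sided t-test on the slope.
    Species without a defined NN distance are excluded.
    """
    pts = [(s.harmonic_n, s.nn_dist) for s in stats if np.isfinite(s.nn_dist)]
    if len(pts) < 3:
        raise ValueError("need at least 3 species with finite NN distance")
    x = np.log10([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in log10 harmonic-mean sample size")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def intra_vs_samplesize_residuals(stats: list[SpeciesGapStats]) -> pd.Series:
    """Residuals of max_intra (%) regressed on per-species sample size.

    Used to compare intraspecific divergence across families or categories
    while accounting for unequal sampling.  If every species has the same
    sample size the slope is unidentifiable and the residuals degrade
    gracefully to mean-centred max_intra values.
    """
    if len(stats) < 3:
        raise ValueError("need at least 3 species")
    x = np.array([s.n_specimens for s in stats], dtype=float)
    y = np.array([s.max_intra for s in stats], dtype=float)
    if np.ptp(x) == 0.0:
        resid = y - y.mean()
    else:
        res = sps.linregress(x, y)
        resid = y - (res.intercept + res.slope * x)
    return pd.Series(resid, index=[s.species for s in stats], name="residual_max_intra")


def partition_compare(m: DistanceMatrix, ds: SequenceDataset) -> list[PartitionComparison]:
    """Compare reference-region-only gap statistics with the pooled sample.

    Reference statistics are computed on the reference-region subset alone;
    pooled statistics on all specimens.  Only species with at least one
    reference specimen appear (others are logged and skipped).  Adding
    specimens can only raise a species' maximum intraspecific distance and
    lower its NN distance, so ``max_intra_pooled >= max_intra_ref`` and
    ``nn_dist_pooled <= nn_dist_ref`` hold for every species.
    """
    ref_ds = ds.by_region_role("reference")
    if len(ref_ds) == 0 or len(ref_ds) == len(ds):
        raise ValueError("partition comparison requires both regions to be present")
    ref_m = m.submatrix(ref_ds.specimen_ids)
    ref_stats = {s.species: s for s in species_stats(ref_m, ref_ds)}
    pooled_stats = {s.species: s for s in species_stats(m, ds)}

    skipped = [sp for sp in pooled_stats if sp not in ref_stats]
    if skipped:
        logger.info(
            "%d species with no reference-region specimen excluded from partition comparison",
            len(skipped),
        )

    out: list[PartitionComparison] = []
    for sp in sorted(ref_stats):
        r, p = ref_stats[sp], pooled_stats[sp]
        if np.isfinite(r.nn_dist) and r.nn_dist > 0 and np.isfinite(p.nn_dist):
            reduction = 100.0 * (r.nn_dist - p.nn_dist) / r.nn_dist
        else:
            reduction = float("nan")
        out.append(
            PartitionComparison(
                species=sp,
                max_intra_ref=r.max_intra,
                max_intra_pooled=p.max_intra,
                nn_dist_ref=r.nn_dist,
                nn_dist_pooled=p.nn_dist,
                nn_species_ref=r.nn_species,
                nn_species_pooled=p.nn_species,
                nn_changed=bool(r.nn_species != p.nn_species),
                nn_reduction_pct=reduction,
            )
        )
    return out
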