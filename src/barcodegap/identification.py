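"""Identification of query specimens against a reference library.

The central use case: a reference library densely sampled in one region, and
query specimens from a distant region identified against it.  Two criteria
are provided: pure nearest neighbour (assign the species of the closest
library specimen, no threshold) and best close match (majority species among
library specimens within a distance threshold; no candidate -> no
identification).

Success rates are first-class output — per-verdict counts, overall rates and
a per-family breakdown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .io_formats import SequenceDataset, SpecimenRecord

logger = logging.getLogger("barcodegap")

VERDICTS = ("correct", "incorrect", "no_id", "ambiguous")

DEFAULT_BCM_THRESHOLD = 2.0  # percent


@dataclass
class IdentificationResult:
    specimen_id: str
    true_species: str
    assigned_species: str | None
    verdict: str  # one of VERDICTS
    nn_distance: float  # % distance to the nearest library specimen (NaN if none)
    in_library: bool = True  # whether the true species occurs in the library


def _library_distances(
    query: SpecimenRecord, library: SequenceDataset, m: DistanceMatrix
) -> tuple[np.ndarray, list[str]]:
    qi = m.index_of(query.specimen_id)
    lib_ids = library.specimen_ids
    if query.specimen_id in lib_ids:
        raise ValueError(f"query specimen {query.specimen_id!r} is part of the library")
    li = np.array([m.index_of(s) for s in lib_ids], dtype=int)
    return m.d[qi, li] * 100.0, [r.species for r in library.records]


def identify_nn(
    query: SpecimenRecord, library: SequenceDataset, m: DistanceMatrix
) -> IdentificationResult:
    """Assign the species of the nearest library specimen (no threshold)."""
    dists, species = _library_distances(query, library, m)
    if np.all(np.isnan(dists)):
        return IdentificationResult(
            query.specimen_id, query.species, None, "no_id", float("nan"),
            in_library=query.species in species,
        )
    dmin = np.nanmin(dists)
    nearest = sorted({species[i] for i in np.where(dists == dmin)[0]})
    in_lib = query.species in species
    if len(nearest) > 1:
        logger.info(
            "NN tie for query %s at %.4f%% between %s", query.specimen_id, dmin, nearest
        )
        return IdentificationResult(
            query.specimen_id, query.species, None, "ambiguous", float(dmin), in_lib
        )
    assigned = nearest[0]
    verdict = "correct" if assigned == query.species else "incorrect"
    return IdentificationResult(
        query.specimen_id, query.species, assigned, verdict, float(dmin), in_lib
    )


def best_close_match(
    query: SpecimenRecord,
    library: SequenceDataset,
    m: DistanceMatrix,
    threshold: float = DEFAULT_BCM_THRESHOLD,
) -> IdentificationResult:
    """Majority species among library specimens within ``threshold`` percent.

    No candidate within the threshold -> ``no_id``; a majority tie between
    species -> ``ambiguous``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    dists, species = _library_distances(query, library, m)
    in_lib = query.species in species
    finite = np.isfinite(dists)
    if not finite.any():
        return IdentificationResult(
            query.specimen_id, query.species, None, "no_id", float("nan"), in_lib
        )
    dmin = float(np.nanmin(dists))
    cand = np.where(finite & (dists <= threshold))[0]
    if cand.size == 0:
        return IdentificationResult(
            query.specimen_id, query.species, None, "no_id", dmin, in_lib
        )
    counts: dict[str, int] = {}
    for i in cand:
        counts[species[i]] = counts.get(species[i], 0) + 1
    top = max(counts.values())
    winners = sorted(sp for sp, c in counts.items() if c == top)
    if len(winners) > 1:
        return IdentificationResult(
            query.specimen_id, query.species, None, "ambiguous", dmin, in_lib
        )
    assigned = winners[0]
    verdict = "correct" if assigned == query.species else "incorrect"
    return IdentificationResult(query.specimen_id, query.species, assigned, verdict, dmin, in_lib)


def library_test(
    ds: SequenceDataset,
    m: DistanceMatrix,
    mode: str = "nn",
    threshold: float = DEFAULT_BCM_THRESHOLD,
) -> dict:
    """Identify every query-region specimen against the reference library.

    ``mode`` is ``"nn"`` (pure nearest neighbour) or ``"bcm"`` (best close
    match).  Query specimens whose species is absent from the library are
    tallied separately under ``not_in_library`` and excluded from the verdict
    rates, which would otherwise conflate library gaps with method failures.
    """
    if mode not in ("nn", "bcm"):
        raise ValueError(f"unknown identification mode {mode!r}")
    library = ds.by_region_role("reference")
    queries = ds.by_region_role("query")
    if len(library) == 0 or len(queries) == 0:
        raise ValueError("library test requires specimens in both regions")

    results: list[IdentificationResult] = []
    for q in queries.records:
        if mode == "nn":
            results.append(identify_nn(q, library, m))
        else:
            results.append(best_close_match(q, library, m, threshold))

    scored = [r for r in results if r.in_library]
    unscored = [r for r in results if not r.in_library]
    counts = {v: sum(1 for r in scored if r.verdict == v) for v in VERDICTS}
    n = len(scored)
    per_family: dict[str, dict[str, int]] = {}
    fam_of = {r.specimen_id: r.family for r in queries.records}
    for r in scored:
        fam = fam_of[r.specimen_id]
        per_family.setdefault(fam, {v: 0 for v in VERDICTS})
        per_family[fam][r.verdict] += 1

    return {
        "mode": mode,
        "threshold_pct": threshold if mode == "bcm" else None,
        "n_queries": len(results),
        "n_scored": n,
        "not_in_library": len(unscored),
        "counts": counts,
        "rates": {v: (counts[v] / n if n else 0.0) for v in VERDICTS},
        "per_family": per_family,
        "results": results,
    }
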