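"""RESL-style clustering into BIN-like units and species/cluster concordance.

Refined Single Linkage (RESL) is the algorithm behind Barcode Index Numbers
(BINs): sequences are first pre-clustered by single linkage at a fixed
divergence threshold (2.2%), then each pre-cluster is refined by Markov
clustering (MCL) on a similarity graph, and a refinement is accepted only if
it improves the mean silhouette of the partition.  Clustering here is local
to the supplied dataset — there is no global registry — so cluster labels are
plain "C0001"-style strings assigned in order of first member appearance.

Concordance classifies each species against the resulting partition:

    match    — one cluster, not shared with any other species
    merge    — one cluster, shared (barcode sharing)
    split    — several clusters, none shared (deep intraspecific divergence)
    mixture  — several clusters, at least one shared

For splits, the regional pattern records whether the clusters segregate
between the two sampling regions or co-occur within one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .io_formats import SequenceDataset

logger = logging.getLogger("barcodegap")

CONCORDANCE_CLASSES = ("match", "merge", "split", "mixture")


@dataclass
class RESLConfig:
    """Tuning knobs for the RESL-style clustering.

    precluster_threshold is a percentage (2.2 = the BIN seed threshold);
    similarity edges are w = max(0, 1 - d / (similarity_scale * threshold)),
    decaying to zero at ``similarity_scale`` times the pre-clustering
    threshold.  The default scale of 1 gives the contrast Markov clustering
    needs: with a gentler decay the flow matrix converges to the uniform
    fixed point on every dense pre-cluster and no split is ever proposed.
    MCL uses expansion 2 with the given inflation, iterated to convergence.
    A refinement is accepted when it beats the unsplit pre-cluster's mean
    silhouette by more than silhouette_min_gain (an unsplit partition scores
    0 by convention).
    """

    precluster_threshold: float = 2.2
    similarity_scale: float = 1.0
    mcl_inflation: float = 2.0
    mcl_max_iter: int = 200
    mcl_tol: float = 1e-8
    silhouette_min_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.precluster_threshold <= 0:
            raise ValueError("precluster_threshold must be > 0")
        if self.mcl_inflation <= 1:
            raise ValueError("mcl_inflation must be > 1")


@dataclass
class ClusterAssignment:
    """A partition of specimens into clusters with stable string ids."""

    specimen_to_cluster: dict[str, str]
    clusters: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_labels(cls, ids: list[str], labels: np.ndarray) -> "ClusterAssignment":
        """Build from integer labels, naming clusters in order of first appearance."""
        name_of: dict[int, str] = {}
        mapping: dict[str, str] = {}
        clusters: dict[str, list[str]] = {}
        for sid, lab in zip(ids, labels):
            lab = int(lab)
            if lab not in name_of:
                name_of[lab] = f"C{len(name_of) + 1:04d}"
                clusters[name_of[lab]] = []
            cid = name_of[lab]
            mapping[sid] = cid
            clusters[cid].append(sid)
        return cls(specimen_to_cluster=mapping, clusters=clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def members(self, cluster_id: str) -> list[str]:
        return self.clusters[cluster_id]


@dataclass
class ConcordanceRecord:
    species: str
    n_clusters: int
    sharing: bool
    concordance_class: str  # one of CONCORDANCE_CLASSES
    split_regional_pattern: str | None  # between_regions | within_region | both | None


def single_linkage_preclusters(m: DistanceMatrix, threshold: float) -> ClusterAssignment:
    """Connected components of the graph with edges where d < threshold (%).

    Undefined pairs contribute no edge, so saturated comparisons can never
    join two pre-clusters.
    """
    thr = threshold / 100.0
    n = len(m.ids)
    adj = np.zeros((n, n), dtype=bool)
    finite = np.isfinite(m.d)
    adj[finite & (m.d < thr)] = True
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    return ClusterAssignment.from_labels(list(m.ids), labels)


def _mcl(sim: np.ndarray, inflation: float, max_iter: int, tol: float) -> np.ndarray | None:
    """Markov clustering on a symmetric similarity matrix with self-loops.

    Returns integer cluster labels, or None on non-convergence.  Nodes are
    assigned to the attractor (row with mass on its own diagonal) that gives
    them the largest probability; ties go to the lowest attractor index, so
    the result is deterministic.
    """
    n = sim.shape[0]
    M = sim.astype(float).copy()
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = M @ M
        inflated = np.power(expanded, inflation)
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        inflated /= colsum
        change = np.abs(inflated - M).max()
        M = inflated
        if change < tol:
            break
    else:
        return None
    # clusters = connected components of the surviving flow: robust to the
    # block-uniform limit states MCL reaches on dense similarity graphs
    support = (M > 1e-5) | (M.T > 1e-5)
    np.fill_diagonal(support, True)
    _, labels = connected_components(csr_matrix(support), directed=False)
    return labels


def mcl_refine(
    precluster_ids: list[str], m: DistanceMatrix, config: RESLConfig
) -> tuple[np.ndarray, bool]:
    """Markov clustering of one pre-cluster's similarity graph.

    Edge weights are max(0, 1 - d/(similarity_scale*threshold)); undefined
    distances get weight 0.  Returns (labels, converged); a non-converged
    run falls back to the unsplit pre-cluster with a warning.
    """
    sub = m.submatrix(precluster_ids)
    thr_sim = config.similarity_scale * config.precluster_threshold / 100.0
    d = sub.d.copy()
    d[np.isnan(d)] = np.inf
    sim = np.maximum(0.0, 1.0 - d / thr_sim)
    labels = _mcl(sim, config.mcl_inflation, config.mcl_max_iter, config.mcl_tol)
    if labels is None:
        logger.warning(
            "MCL did not converge on a pre-cluster of %d specimens; keeping it unsplit",
            len(precluster_ids),
        )
        return np.zeros(len(precluster_ids), dtype=int), False
    return labels, True


def silhouette_mean(labels: np.ndarray, d: np.ndarray) -> float:
    """Mean silhouette s(i) = (b(i)-a(i))/max(a(i),b(i)) over all points.

    a(i) is the mean distance to the point's own cluster, b(i) the smallest
    mean distance to another cluster.  Singleton-cluster members contribute
    s = 0, and a single-cluster partition is defined as 0, so "no split" is
    the neutral reference the refinement must beat.  Undefined distances are
    excluded from the means.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        return 0.0
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = (labels == labels[i])
        own[i] = False
        if not own.any():
            continue  # singleton: s = 0
        with np.errstate(invalid="ignore"):
            a = np.nanmean(d[i, own])
        b = np.inf
        for lab in uniq:
            if lab == labels[i]:
                continue
            vals = d[i, labels == lab]
            if np.all(np.isnan(vals)):
                continue
            b = min(b, float(np.nanmean(vals)))
        if not np.isfinite(b) or np.isnan(a):
            continue
        denom = max(a, b)
        s[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(s.mean())


def assign_bins(
    m: DistanceMatrix, ds: SequenceDataset, config: RESLConfig | None = None
) -> ClusterAssignment:
    """Full RESL-style assignment: pre-cluster, refine, accept by silhouette.

    Each pre-cluster is refined independently; the MCL partition replaces the
    pre-cluster only when its mean silhouette exceeds the unsplit score (0)
    by more than ``silhouette_min_gain``.  The output is always a refinement
    of the single-linkage pre-clusters — refinement can split but never merge
    across pre-cluster boundaries.
    """
    config = config or RESLConfig()
    pre = single_linkage_preclusters(m, config.precluster_threshold)
    final_labels = np.full(len(m.ids), -1, dtype=int)
    pos = {sid: i for i, sid in enumerate(m.ids)}
    next_label = 0
    # iterate pre-clusters in order of first member appearance (C0001, ...)
    for cid in sorted(pre.clusters, key=lambda c: int(c[1:])):
        members = pre.clusters[cid]
        if len(members) < 2:
            final_labels[[pos[s] for s in members]] = next_label
            next_label += 1
            continue
        labels, converged = mcl_refine(members, m, config)
        accepted = False
        if converged and len(np.unique(labels)) > 1:
            sub_d = m.submatrix(members).d
            gain = silhouette_mean(labels, sub_d) - 0.0
            accepted = gain > config.silhouette_min_gain
        if not accepted:
            labels = np.zeros(len(members), dtype=int)
        # relabel into the global sequence, keeping member order
        seen: dict[int, int] = {}
        for sid, lab in zip(members, labels):
            if int(lab) not in seen:
                seen[int(lab)] = next_label
                next_label += 1
            final_labels[pos[sid]] = seen[int(lab)]
    return ClusterAssignment.from_labels(list(m.ids), final_labels)


def concordance(
    assignment: ClusterAssignment, ds: SequenceDataset
) -> tuple[list[ConcordanceRecord], dict]:
    """Classify every species by its relation to the cluster partition.

    Also returns an aggregate table: species counts by (number of clusters,
    sharing) cell, the split regional patterns, and the same breakdown per
    distribution category where categories are annotated.
    """
    sp_clusters: dict[str, set[str]] = {}
    cluster_species: dict[str, set[str]] = {}
    sp_cluster_regions: dict[str, dict[str, set[str]]] = {}
    cat_of: dict[str, str | None] = {}
    for r in ds.records:
        cid = assignment.specimen_to_cluster[r.specimen_id]
        sp_clusters.setdefault(r.species, set()).add(cid)
        cluster_species.setdefault(cid, set()).add(r.species)
        sp_cluster_regions.setdefault(r.species, {}).setdefault(cid, set()).add(r.region_role)
        cat_of.setdefault(r.species, r.distribution_category)

    records: list[ConcordanceRecord] = []
    for sp in sorted(sp_clusters):
        clusters = sp_clusters[sp]
        k = len(clusters)
        sharing = any(len(cluster_species[c]) > 1 for c in clusters)
        if k == 1:
            cls = "merge" if sharing else "match"
            pattern = None
        else:
            cls = "mixture" if sharing else "split"
            pattern = _split_pattern(sp_cluster_regions[sp])
        records.append(ConcordanceRecord(sp, k, sharing, cls, pattern))

    agg: dict = {
        "n_species": len(records),
        "by_class": {c: sum(1 for r in records if r.concordance_class == c) for c in CONCORDANCE_CLASSES},
        "split_patterns": {
            p: sum(1 for r in records if r.split_regional_pattern == p)
            for p in ("between_regions", "within_region", "both")
        },
        "by_cell": {},
        "by_category": {},
    }
    for r in records:
        cell = f"k={min(r.n_clusters, 3)}{'+' if r.n_clusters > 3 else ''},shared={r.sharing}"
        agg["by_cell"][cell] = agg["by_cell"].get(cell, 0) + 1
    for r in records:
        cat = cat_of.get(r.species) or "unassigned"
        agg["by_category"].setdefault(cat, {c: 0 for c in CONCORDANCE_CLASSES})
        agg["by_category"][cat][r.concordance_class] += 1
    return records, agg


def _split_pattern(cluster_regions: dict[str, set[str]]) -> str:
    """Regional pattern of a species split across clusters.

    between_regions: each cluster's members of this species come from a
    single region and not all clusters are in the same region.
    within_region: at least two clusters co-occur in one region and the
    species does not also segregate clusters between regions.
    both: mixed evidence (some region holds several clusters while another
    cluster is exclusive to the other region, or clusters span regions).
    """
    region_lists = list(cluster_regions.values())
    all_single = all(len(rs) == 1 for rs in region_lists)
    regions_used = set().union(*region_lists)
    region_counts: dict[str, int] = {}
    for rs in region_lists:
        for reg in rs:
            region_counts[reg] = region_counts.get(reg, 0) + 1
    cooccur = any(c >= 2 for c in region_counts.values())
    between = all_single and len(regions_used) > 1
    # for >=2 clusters at least one of the two signatures always holds
    if between and not cooccur:
        return "between_regions"
    if cooccur and not between:
        return "within_region"
    return "both"
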