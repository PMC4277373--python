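"""Kimura 2-parameter distances with pairwise deletion.

For each specimen pair, sites where either sequence carries anything other
than an unambiguous A/C/G/T (ambiguity codes, gaps, missing data) are
excluded before counting differences ("pairwise deletion").  Among the
remaining compared sites, P is the proportion of transitions (A<->G, C<->T)
and Q the proportion of transversions, and the distance is

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

A pair is *undefined* when too few sites overlap (below ``min_overlap``) or
when either logarithm argument is non-positive (substitutional saturation).
Undefined pairs are recorded and excluded from downstream minima and maxima
rather than clamped to a large value, which would silently distort
nearest-neighbour statistics.

K2P is not guaranteed to satisfy the triangle inequality; no downstream code
relies on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SequenceDataset

DEFAULT_MIN_OVERLAP = 100

_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i


@dataclass(frozen=True)
class SitePairCounts:
    """Transition/transversion proportions for one aligned sequence pair."""

    P: float
    Q: float
    n_sites: int


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix in proportion units.

    ``d[i, j]`` is NaN for undefined pairs; ``n_sites[i, j]`` is the number of
    compared sites behind each entry.  Distances are stored as proportions
    (0.0717 = 7.17%); reporting code multiplies by 100.
    """

    ids: list[str]
    d: np.ndarray
    n_sites: np.ndarray
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self) -> None:
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def index_of(self, specimen_id: str) -> int:
        return self._index[specimen_id]

    @property
    def undefined_pairs(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.d[i, j]):
                    out.add((self.ids[i], self.ids[j]))
        return out

    def submatrix(self, specimen_ids: list[str]) -> "DistanceMatrix":
        idx = np.array([self._index[s] for s in specimen_ids], dtype=int)
        return DistanceMatrix(
            ids=list(specimen_ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            n_sites=self.n_sites[np.ix_(idx, idx)].copy(),
            min_overlap=self.min_overlap,
        )


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """Encode sequences as a uint8 matrix: A,C,G,T -> 0..3, anything else 4."""
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[arr].reshape(len(seqs), -1)


def count_site_pairs(a: str, b: str) -> SitePairCounts:
    """Count transitions and transversions between two aligned sequences.

    Sites where either base is not an unambiguous A/C/G/T are excluded
    (pairwise deletion).  Transitions are A<->G and C<->T; every other
    mismatch among compared sites is a transversion.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    x, y = encode_sequences([a, b])
    valid = (x < 4) & (y < 4)
    n = int(valid.sum())
    if n == 0:
        return SitePairCounts(P=0.0, Q=0.0, n_sites=0)
    diff = valid & (x != y)
    # purine<->purine (A=0,G=2) or pyrimidine<->pyrimidine (C=1,T=3): codes
    # differ by 2, i.e. same parity.
    transition = diff & ((x % 2) == (y % 2))
    ts = int(transition.sum())
    tv = int(diff.sum()) - ts
    return SitePairCounts(P=ts / n, Q=tv / n, n_sites=n)


def k2p(counts: SitePairCounts, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """K2P distance from site-pair counts; NaN when undefined.

    Undefined means insufficient overlap (n_sites < min_overlap) or
    saturation (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    if counts.n_sites < min_overlap:
        return float("nan")
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def pairwise_matrix(ds: SequenceDataset, min_overlap: int = DEFAULT_MIN_OVERLAP) -> DistanceMatrix:
    """All-pairs K2P distances for a dataset.

    Implemented with one-hot site indicators and matrix products, so the cost
    is a handful of (n x L) @ (L x n) multiplications rather than an explicit
    loop over the n(n-1)/2 pairs.
    """
    if len(ds) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    codes = encode_sequences([r.sequence for r in ds.records])
    n = codes.shape[0]

    onehot = [(codes == k).astype(np.float32) for k in range(4)]
    valid = (codes < 4).astype(np.float32)

    n_sites = valid @ valid.T
    matches = sum(h @ h.T for h in onehot)
    # transitions: A<->G (codes 0,2) and C<->T (codes 1,3)
    transitions = (
        onehot[0] @ onehot[2].T
        + onehot[2] @ onehot[0].T
        + onehot[1] @ onehot[3].T
        + onehot[3] @ onehot[1].T
    )
    transversions = n_sites - matches - transitions

    n_sites = np.rint(n_sites).astype(np.int64)
    ts = np.rint(transitions).astype(np.int64)
    tv = np.rint(transversions).astype(np.int64)

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n_sites.astype(float)
        P = np.where(n_sites > 0, ts / np.maximum(denom, 1), 0.0)
        Q = np.where(n_sites > 0, tv / np.maximum(denom, 1), 0.0)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(np.where(w1 > 0, w1, np.nan)) - 0.25 * np.log(
            np.where(w2 > 0, w2, np.nan)
        )
    d = np.where(n_sites >= min_overlap, d, np.nan)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # numerically symmetric
    return DistanceMatrix(ids=ds.specimen_ids, d=d, n_sites=n_sites, min_overlap=min_overlap)


def matrix_to_long_frame(m: DistanceMatrix):
    """Long-form table (id1, id2, d_percent, n_sites) over unordered pairs."""
    import pandas as pd

    rows = []
    n = len(m.ids)
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(
                {
                    "id1": m.ids[i],
                    "id2": m.ids[j],
                    "d_percent": 100.0 * m.d[i, j],
                    "n_sites": int(m.n_sites[i, j]),
                }
            )
    return pd.DataFrame(rows, columns=["id1", "id2", "d_percent", "n_sites"])


def write_phylip(m: DistanceMatrix, path) -> None:
    """Square PHYLIP distance matrix; undefined entries rendered as -1."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(m.ids)}\n")
        for i, sid in enumerate(m.ids):
            vals = " ".join(
                f"{v:.6f}" if np.isfinite(v) else "-1.000000" for v in m.d[i]
            )
            fh.write(f"{sid[:10]:<10} {vals}\n")
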