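"""Reading and writing barcode libraries.

A barcode library is a pair of files: an aligned FASTA whose record ids are
specimen ids, and a tab-separated metadata table keyed on those same ids that
carries taxonomy (species, genus, family), sampling region, and the optional
distribution-category / dispersal-class annotations used by the category
models.  The metadata table is the single source of truth for everything but
the sequence itself; FASTA headers are treated as bare specimen ids.

Region labels in the metadata are free strings (e.g. "FI", "AT") mapped onto
the two roles the analyses need: ``reference`` (the library being tested) and
``query`` (the specimens identified against it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("barcodegap")

#: region-label mapping used when none is supplied: Finland is the reference
#: library, Austria (Vorarlberg) the query set.
DEFAULT_REGION_ROLES: dict[str, str] = {"FI": "reference", "AT": "query"}

REQUIRED_METADATA_COLUMNS = ("specimen_id", "species", "genus", "family", "region")
OPTIONAL_METADATA_COLUMNS = ("distribution_category", "dispersal_class")

DISTRIBUTION_CATEGORIES = ("continuous", "fragmented", "disjunct", "migratory")
DISPERSAL_CLASSES = ("good", "poor")

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class SpecimenRecord:
    """One sequenced specimen with its aligned barcode and annotations.

    ``region`` is the raw label from the metadata; ``region_role`` is its
    resolved role, either ``"reference"`` or ``"query"``.
    ``effective_length`` counts unambiguous A/C/G/T positions and is the
    quantity length filters operate on.
    """

    specimen_id: str
    species: str
    genus: str
    family: str
    region: str
    sequence: str
    region_role: str = "reference"
    distribution_category: str | None = None
    dispersal_class: str | None = None

    @property
    def effective_length(self) -> int:
        return sum(1 for c in self.sequence.upper() if c in _UNAMBIGUOUS)


@dataclass
class SequenceDataset:
    """An ordered collection of specimens sharing one alignment length."""

    records: list[SpecimenRecord] = field(default_factory=list)
    alignment_length: int = 0

    def __post_init__(self) -> None:
        if self.records and self.alignment_length == 0:
            self.alignment_length = len(self.records[0].sequence)
        for r in self.records:
            if len(r.sequence) != self.alignment_length:
                raise ValueError(
                    f"record {r.specimen_id!r} has length {len(r.sequence)}, "
                    f"expected alignment length {self.alignment_length}"
                )
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def species_names(self) -> list[str]:
        return sorted({r.species for r in self.records})

    def subset(self, keep: Iterable[str]) -> "SequenceDataset":
        """Subset by specimen id, preserving input order."""
        keep = set(keep)
        return SequenceDataset(
            records=[r for r in self.records if r.specimen_id in keep],
            alignment_length=self.alignment_length,
        )

    def by_region_role(self, role: str) -> "SequenceDataset":
        return SequenceDataset(
            records=[r for r in self.records if r.region_role == role],
            alignment_length=self.alignment_length,
        )

    def to_metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": [r.specimen_id for r in self.records],
                "species": [r.species for r in self.records],
                "genus": [r.genus for r in self.records],
                "family": [r.family for r in self.records],
                "region": [r.region for r in self.records],
                "distribution_category": [r.distribution_category for r in self.records],
                "dispersal_class": [r.dispersal_class for r in self.records],
            }
        )


def read_dataset(
    fasta_path: str | Path,
    metadata_path: str | Path,
    region_roles: Mapping[str, str] | None = None,
) -> SequenceDataset:
    """Read an aligned FASTA plus metadata TSV into a :class:`SequenceDataset`.

    FASTA ids must resolve 1:1 against the ``specimen_id`` column of the
    metadata.  Records are returned in FASTA file order.  Sequences must all
    share one alignment length; the first offending record is named in the
    error.  IUPAC ambiguity codes and gaps are retained — non-comparable sites
    are excluded pair-by-pair at distance time, not stripped here.
    """
    region_roles = dict(DEFAULT_REGION_ROLES if region_roles is None else region_roles)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata is missing required column(s): {missing_cols}")
    if meta["specimen_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["specimen_id"].duplicated(), "specimen_id"])
        raise ValueError(f"duplicate specimen ids in metadata: {dupes}")
    meta_by_id = meta.set_index("specimen_id")

    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    seen: set[str] = set()
    for rec in seqs:
        if rec.id in seen:
            raise ValueError(f"duplicate specimen id in FASTA: {rec.id!r}")
        seen.add(rec.id)

    orphans = [rec.id for rec in seqs if rec.id not in meta_by_id.index]
    if orphans:
        raise ValueError(f"FASTA id(s) absent from metadata: {orphans}")
    unmatched_meta = sorted(set(meta_by_id.index) - seen)
    if unmatched_meta:
        logger.warning(
            "%d metadata row(s) have no sequence and are ignored: %s",
            len(unmatched_meta),
            unmatched_meta[:10],
        )

    if not seqs:
        return SequenceDataset(records=[], alignment_length=0)

    aln_len = len(seqs[0].seq)
    records: list[SpecimenRecord] = []
    for rec in seqs:
        seq = str(rec.seq).upper()
        if len(seq) != aln_len:
            raise ValueError(
                f"sequence length mismatch: record {rec.id!r} has {len(seq)} bp, "
                f"expected {aln_len} (inputs must be pre-aligned)"
            )
        row = meta_by_id.loc[rec.id]
        region = row["region"]
        cat = row.get("distribution_category", "") or None
        disp = row.get("dispersal_class", "") or None
        if cat is not None and cat not in DISTRIBUTION_CATEGORIES:
            raise ValueError(
                f"unknown distribution_category {cat!r} for {rec.id!r}; "
                f"expected one of {DISTRIBUTION_CATEGORIES}"
            )
        if disp is not None and disp not in DISPERSAL_CLASSES:
            raise ValueError(
                f"unknown dispersal_class {disp!r} for {rec.id!r}; "
                f"expected one of {DISPERSAL_CLASSES}"
            )
        records.append(
            SpecimenRecord(
                specimen_id=rec.id,
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                region=region,
                region_role=region_roles.get(region, "reference"),
                sequence=seq,
                distribution_category=cat,
                dispersal_class=disp,
            )
        )
    return SequenceDataset(records=records, alignment_length=aln_len)


def filter_by_length(ds: SequenceDataset, min_bp: int) -> SequenceDataset:
    """Retain records whose effective (unambiguous A/C/G/T) length is >= min_bp.

    Order is preserved. An empty result is allowed (logged as a warning) so
    that pipelines can decide how to proceed.
    """
    if min_bp < 0:
        raise ValueError("min_bp must be >= 0")
    kept = [r for r in ds.records if r.effective_length >= min_bp]
    removed = len(ds.records) - len(kept)
    logger.info("length filter (>=%d bp): retained %d, removed %d", min_bp, len(kept), removed)
    if not kept and ds.records:
        logger.warning("length filter removed every record (min_bp=%d)", min_bp)
    return SequenceDataset(records=kept, alignment_length=ds.alignment_length)


def write_fasta(ds: SequenceDataset, path: str | Path) -> None:
    """Write sequences as single-line FASTA with bare specimen-id headers."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in ds.records:
            fh.write(f">{r.specimen_id}\n{r.sequence}\n")


def write_metadata(ds: SequenceDataset, path: str | Path) -> None:
    df = ds.to_metadata_frame()
    df = df.fillna("")
    df.to_csv(path, sep="\t", index=False)


def write_table(rows, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write any tabular result as a UTF-8 TSV with a header.

    ``rows`` may be a DataFrame, a list of dataclasses, or a list of dicts.
    Floats are rendered with 6 decimals so that a read-back reproduces the
    values exactly at that precision.  An empty input yields a header-only
    file (``columns`` must then be given unless rows carry their own schema).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = list(rows)
        if rows and hasattr(rows[0], "__dataclass_fields__"):
            from dataclasses import asdict

            df = pd.DataFrame([asdict(r) for r in rows])
        else:
            df = pd.DataFrame(rows)
    if df.empty and columns is not None:
        df = pd.DataFrame(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
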