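import numpy as np
import pytest

from barcodegap import (
    DistanceMatrix,
    SequenceDataset,
    SpecimenRecord,
    generate_library,
    get_preset,
    pairwise_matrix,
    species_stats,
)

SIM_SEED = 42  # seed for the shared "paper_like" library used across tests


def make_records(rows, seq_length=8):
    """Build SpecimenRecords from (id, species, region_role[, sequence]) tuples.

    Sequences default to a constant placeholder; tests that construct a
    DistanceMatrix by hand only need consistent ids and labels.
    """
    out = []
    for row in rows:
        sid, species, role = row[:3]
        seq = row[3] if len(row) > 3 else "A" * seq_length
        genus = species.split()[0]
        out.append(
            SpecimenRecord(
                specimen_id=sid,
                species=species,
                genus=genus,
                family="TestFam",
                region="FI" if role == "reference" else "AT",
                region_role=role,
                sequence=seq,
            )
        )
    return out


def make_matrix(ids, pct_entries):
    """Symmetric DistanceMatrix from {(id_a, id_b): percent} entries."""
    n = len(ids)
    d = np.zeros((n, n))
    pos = {s: i for i, s in enumerate(ids)}
    for (a, b), v in pct_entries.items():
        d[pos[a], pos[b]] = d[pos[b], pos[a]] = v / 100.0
    return DistanceMatrix(ids=list(ids), d=d, n_sites=np.full((n, n), 658), min_overlap=0)


@pytest.fixture(scope="session")
def paper_like():
    """One shared paper-like simulated library with its ground truth."""
    return generate_library(get_preset("paper_like", seed=SIM_SEED))


@pytest.fixture(scope="session")
def paper_like_matrix(paper_like):
    ds, _ = paper_like
    return pairwise_matrix(ds)


@pytest.fixture(scope="session")
def paper_like_stats(paper_like, paper_like_matrix):
    ds, _ = paper_like
    return species_stats(paper_like_matrix, ds)


@pytest.fixture()
def random_sequences():
    def _make(n, length=658, seed=0):
        rng = np.random.default_rng(seed)
        return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]

    return _make
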