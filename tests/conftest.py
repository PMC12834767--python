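import numpy as np
import pytest
from hypothesis import settings

from torsionscan import (
    CorpusSpec,
    build_backbone_coordinates,
    build_index,
    compute_backbone_dihedrals,
    make_segments,
    sample_sequences,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def wrapped_diff(a: float, b: float) -> float:
    """Smallest angular difference in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def naive_scan(sequences: dict[str, str], kmer: str) -> list[tuple[str, int]]:
    """Independent brute-force substring scanner: (entry_id, start) pairs."""
    hits = []
    k = len(kmer)
    for eid in sorted(sequences):
        seq = sequences[eid]
        for start in range(len(seq) - k + 1):
            if seq[start : start + k] == kmer:
                hits.append((eid, start))
    return hits


@pytest.fixture(scope="session")
def iid_segments():
    """Small i.i.d. uniform corpus as in-memory torsion segments."""
    seqs, _ = sample_sequences(CorpusSpec(n_chains=30, chain_length=80, seed=11))
    return make_segments(seqs, seed=11)


@pytest.fixture(scope="session")
def iid_index(iid_segments):
    return build_index(iid_segments, [1, 2, 3, 4])


@pytest.fixture()
def helical_chain():
    """12-residue alpha-helical chain from the internal-coordinate builder."""
    n = 12
    torsions = [
        [None if i == 0 else -57.0, None if i == n - 1 else -47.0, None if i == 0 else 180.0]
        for i in range(n)
    ]
    return build_backbone_coordinates("ACDEFGHIKLMN", torsions), torsions


@pytest.fixture()
def helical_segments(helical_chain):
    chain, _ = helical_chain
    return compute_backbone_dihedrals(chain)
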