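import numpy as np
import pytest

from topsignal.annotation_io import LeaderModel
from topsignal.tss_profiles import TssProfile


def make_leader(sequence: str, gene_id: str = "gX", start: int = 0,
                strand: str = "+", chrom: str = "chr1") -> LeaderModel:
    """Leader model over a contiguous genomic block starting at ``start``.

    For '+' the sequence is read left-to-right from ``start``; for '-' the
    given sequence is still the leader 5'->3', so leader index 0 maps to the
    highest genomic coordinate of the block.
    """
    length = len(sequence)
    if strand == "+":
        positions = tuple(range(start, start + length))
    else:
        positions = tuple(range(start + length - 1, start - 1, -1))
    return LeaderModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        sequence=sequence, genomic_positions=positions,
    )


def random_profile(rng: np.random.Generator, leader_len: int,
                   max_sites: int = 8, max_count: int = 50) -> TssProfile:
    n_sites = int(rng.integers(1, min(max_sites, leader_len) + 1))
    indices = rng.choice(leader_len, size=n_sites, replace=False)
    return TssProfile(
        gene_id="gR",
        site_counts={int(i): int(rng.integers(1, max_count + 1)) for i in indices},
    )


def random_leader_sequence(rng: np.random.Generator, length: int,
                           pyr_prob: float = 0.5) -> str:
    bases = []
    for _ in range(length):
        if rng.random() < pyr_prob:
            bases.append("CT"[int(rng.integers(0, 2))])
        else:
            bases.append("AG"[int(rng.integers(0, 2))])
    return "".join(bases)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
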