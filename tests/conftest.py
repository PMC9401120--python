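"""Shared fixtures: compact clonotype factories and random instances.

Random instances for oracle tests use a tiny amino-acid alphabet, short
sequences and few V/J segments so that every similarity relation fires often
enough for a brute-force comparison to be informative.
"""
from __future__ import annotations

import numpy as np
import pytest

from repfrac.types import Clonotype, NucleotideVariant, Repertoire

# deterministic injective reverse-codon map for fixture building (one codon
# per amino acid, so distinct aa sequences get distinct nt sequences)
_FIX_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def make_clonotype(
    aa: str = "CASS",
    v: str = "TRBV1",
    j: str = "TRBJ1-1",
    cn: int = 2,
    variant_counts: tuple[int, ...] | None = None,
) -> Clonotype:
    """Clonotype with synthetic but valid nucleotide variants."""
    counts = variant_counts if variant_counts is not None else (cn,)
    assert sum(counts) == cn
    base = "".join(_FIX_CODON.get(ch, "GCT") for ch in aa)
    # distinct variants via last-position wobble (first variant = base itself)
    wobble = [b for b in "ACGT" if b != base[-1]]
    assert len(counts) <= 4, "fixture supports at most 4 variants"
    variants = tuple(
        NucleotideVariant(base[:-1] + wobble[i - 1] if i else base, c)
        for i, c in enumerate(counts)
    )
    return Clonotype(aa, v, j, cn, variants)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_clonotypes(
    rng: np.random.Generator,
    n: int,
    alphabet: str = "ACD",
    len_range: tuple[int, int] = (3, 6),
    n_v: int = 3,
    n_j: int = 2,
    max_cn: int = 6,
) -> list[Clonotype]:
    """Random clonotype list (duplicates allowed) for oracle comparisons."""
    out = []
    for _ in range(n):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        aa = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))
        k = int(rng.integers(1, 9))
        cn = int(rng.integers(max(2, k), max_cn + k))
        counts = np.ones(min(k, cn), dtype=int)
        counts[0] += cn - counts.sum()
        variants = tuple(
            NucleotideVariant("ACGT"[i % 4] * 3 + "A" * (3 * (i // 4)) + "TGC", int(c))
            for i, c in enumerate(counts)
        )
        out.append(
            Clonotype(
                aa,
                f"TRBV{int(rng.integers(1, n_v + 1))}",
                f"TRBJ1-{int(rng.integers(1, n_j + 1))}",
                cn,
                variants,
            )
        )
    return out


def random_repertoire(
    rng: np.random.Generator, n: int, sample_id: str = "r", max_cn: int = 2000
) -> Repertoire:
    """Repertoire with unique aa sequences and a broad copy-number range."""
    seen: set[str] = set()
    clonotypes = []
    while len(clonotypes) < n:
        length = int(rng.integers(6, 12))
        aa = "".join("ACDEFGHIKL"[i] for i in rng.integers(0, 10, length))
        if aa in seen:
            continue
        seen.add(aa)
        cn = int(rng.integers(2, max_cn + 1))
        clonotypes.append(make_clonotype(aa, f"TRBV{int(rng.integers(1, 6))}",
                                         f"TRBJ1-{int(rng.integers(1, 4))}", cn))
    return Repertoire(sample_id, clonotypes)
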