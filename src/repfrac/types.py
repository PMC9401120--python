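"""Core domain types for TCR-beta repertoire analysis.

A repertoire is a set of clonotypes; a clonotype is one CDR3beta amino-acid
sequence with an assigned V and J segment, a total copy number (summed read
count), and the nucleotide variants that encode it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class NucleotideVariant:
    """One CDR3beta nucleotide sequence and its read count."""

    nt_sequence: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError(f"read_count must be >= 1, got {self.read_count}")
        if not self.nt_sequence or not _DNA.issuperset(self.nt_sequence):
            raise ValueError(f"invalid nucleotide sequence {self.nt_sequence!r}")


@dataclass(frozen=True)
class Clonotype:
    """Set of T cells sharing one CDR3beta amino-acid sequence.

    The copy number (CN) is the summed read count over all nucleotide
    variants; V/J segments come from the variant with the highest read count.
    """

    cdr3_aa: str
    v_segment: str
    j_segment: str
    copy_number: int
    variants: tuple[NucleotideVariant, ...] = ()

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError(f"copy_number must be >= 1, got {self.copy_number}")
        if self.variants:
            total = sum(v.read_count for v in self.variants)
            if total != self.copy_number:
                raise ValueError(
                    f"copy_number {self.copy_number} != sum of variant reads {total}"
                )

    @property
    def n_variants(self) -> int:
        """Number of distinct nucleotide sequences coding for this clonotype."""
        return len(self.variants) if self.variants else 1


@dataclass
class Repertoire:
    """One animal's clonotype set plus sample metadata."""

    sample_id: str
    clonotypes: list[Clonotype]
    group_label: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for c in self.clonotypes:
            if c.cdr3_aa in seen:
                raise ValueError(f"duplicate cdr3_aa {c.cdr3_aa!r} in {self.sample_id}")
            seen.add(c.cdr3_aa)

    def __len__(self) -> int:
        return len(self.clonotypes)

    @property
    def total_reads(self) -> int:
        return sum(c.copy_number for c in self.clonotypes)

    def aa_set(self) -> set[str]:
        return {c.cdr3_aa for c in self.clonotypes}


@dataclass
class SubRepertoire:
    """Clonotypes of one repertoire restricted to a copy-number interval."""

    parent_id: str
    cn_condition: tuple[float, float]  # half-open interval (lo, hi]
    clonotypes: list[Clonotype]
    group_label: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.cn_condition
        for c in self.clonotypes:
            if not (lo < c.copy_number <= hi):
                raise ValueError(
                    f"clonotype CN {c.copy_number} outside ({lo}, {hi}]"
                )

    def __len__(self) -> int:
        return len(self.clonotypes)

    def aa_set(self) -> set[str]:
        return {c.cdr3_aa for c in self.clonotypes}


@dataclass(frozen=True)
class SimilarityRelation:
    """Named reflexive, symmetric predicate over clonotype pairs.

    ``kind`` tags relations with fast evaluation paths:

    * ``"equivalence"`` — the relation is x R y iff class_of(x) == class_of(y),
      so pair counts reduce to class-size combinatorics;
    * ``"ld"`` — CDR3 Levenshtein distance <= max_d (non-transitive);
    * ``"generic"`` — evaluated pairwise through ``predicate``.
    """

    name: str
    predicate: Callable[[Clonotype, Clonotype], bool]
    kind: str = "generic"
    class_of: Callable[[Clonotype], object] | None = None
    max_d: int = 1

    def __call__(self, a: Clonotype, b: Clonotype) -> bool:
        return bool(self.predicate(a, b))


@dataclass(frozen=True)
class DissimilaritySpec:
    """Weighted list of similarity relations defining d between repertoires."""

    relations: tuple[SimilarityRelation, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.relations) != len(self.weights):
            raise ValueError("relations and weights must have equal length")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if not math.isclose(sum(self.weights), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")


@dataclass(frozen=True)
class IndexValue:
    """Result of an index computation with an explicit undefined flag.

    Indices on fewer items than their formula supports (e.g. RHI on < 2
    clonotypes) carry ``defined=False`` and a NaN value rather than a silent
    zero, so group statistics can exclude them.
    """

    value: float
    n_items: int
    index_name: str
    defined: bool = True

    @staticmethod
    def undefined(index_name: str, n_items: int = 0) -> "IndexValue":
        return IndexValue(float("nan"), n_items, index_name, defined=False)


def as_clonotype_list(items: Repertoire | SubRepertoire | Sequence[Clonotype]) -> list[Clonotype]:
    """Accept repertoires, sub-repertoires or bare clonotype sequences."""
    if isinstance(items, (Repertoire, SubRepertoire)):
        return list(items.clonotypes)
    return list(items)
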