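"""Copy-number fractioning of repertoires.

Two published schemes plus custom intervals:

* tripartition — CN_low: CN = 2; CN_med: 2 < CN <= 500; CN_high: CN > 500
* log2 — ten fractions: fraction k (k = 1..9) holds 2^(k-1) < CN <= 2^k,
  fraction 10 holds CN > 512; fraction 1 equals CN_low.

Note the deliberate asymmetry inherited from the published boundaries:
clonotypes with 500 < CN <= 512 belong to CN_high but to log2 fraction 9.

Also defines the X_top (CN > 64) and X_bottom (CN <= 4) sub-repertoires used
for classification, and the distribution of an externally supplied clonotype
set over the log2 fractions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import Clonotype, Repertoire, SubRepertoire

N_LOG2_FRACTIONS = 10

#: half-open (lo, hi] intervals of the log2 scheme, fraction index 1..10
LOG2_INTERVALS: list[tuple[float, float]] = [
    (2 ** (k - 1), float(2**k)) for k in range(1, N_LOG2_FRACTIONS)
] + [(512, math.inf)]

TRIPARTITION_INTERVALS: dict[str, tuple[float, float]] = {
    "low": (1, 2),        # CN = 2
    "med": (2, 500),      # 2 < CN <= 500
    "high": (500, math.inf),
}

TOP_INTERVAL: tuple[float, float] = (64, math.inf)  # log2(CN) > 6
BOTTOM_INTERVAL: tuple[float, float] = (1, 4)       # log2(CN) <= 2, CN >= 2


@dataclass(frozen=True)
class FractionScheme:
    """Ordered, disjoint half-open copy-number intervals covering CN >= 2."""

    name: str
    boundaries: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_hi = None
        for lo, hi in self.boundaries:
            if hi <= lo:
                raise ValueError(f"empty interval ({lo}, {hi}]")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError("intervals must be contiguous and ordered")
            prev_hi = hi
        if self.boundaries[0][0] > 1:
            raise ValueError("scheme must cover CN = 2")
        if self.boundaries[-1][1] != math.inf:
            raise ValueError("last interval must be unbounded")

    def __len__(self) -> int:
        return len(self.boundaries)

    def index_of(self, cn: int) -> int:
        """1-based fraction index of a copy number."""
        if cn < 2:
            raise ValueError(f"copy number {cn} < 2 (singletons are removed upstream)")
        for i, (lo, hi) in enumerate(self.boundaries, start=1):
            if lo < cn <= hi:
                return i
        raise AssertionError("unreachable: scheme covers all CN >= 2")


LOG2_SCHEME = FractionScheme("log2", tuple(LOG2_INTERVALS))
TRIPARTITION_SCHEME = FractionScheme(
    "tripartition", tuple(TRIPARTITION_INTERVALS.values())
)


def log2_fraction_index(cn: int) -> int:
    """Log2 fraction (1..10) of a copy number: k iff 2^(k-1) < cn <= 2^k, 10 iff cn > 512."""
    if cn < 2:
        raise ValueError(f"copy number {cn} < 2 (singletons are removed upstream)")
    if cn > 512:
        return N_LOG2_FRACTIONS
    # ceil(log2(cn)) without float round-off: cn in (2^(k-1), 2^k]
    return (cn - 1).bit_length()


def split_by_scheme(rep: Repertoire, scheme: FractionScheme) -> list[SubRepertoire]:
    """Partition a preprocessed repertoire into the scheme's fractions."""
    buckets: list[list[Clonotype]] = [[] for _ in scheme.boundaries]
    for c in rep.clonotypes:
        buckets[scheme.index_of(c.copy_number) - 1].append(c)
    return [
        SubRepertoire(rep.sample_id, interval, bucket, rep.group_label, rep.timepoint)
        for interval, bucket in zip(scheme.boundaries, buckets)
    ]


def split_log2(rep: Repertoire) -> list[SubRepertoire]:
    """Split into the ten log2 copy-number fractions (empty fractions retained)."""
    return split_by_scheme(rep, LOG2_SCHEME)


def split_tripartition(
    rep: Repertoire,
) -> tuple[SubRepertoire, SubRepertoire, SubRepertoire]:
    """Split into (CN_low, CN_med, CN_high)."""
    low, med, high = split_by_scheme(rep, TRIPARTITION_SCHEME)
    return low, med, high


def sub_repertoire(rep: Repertoire, which: str) -> SubRepertoire:
    """Extract X_top (CN > 64) or X_bottom (CN <= 4)."""
    if which == "top":
        interval = TOP_INTERVAL
    elif which == "bottom":
        interval = BOTTOM_INTERVAL
    else:
        raise ValueError(f"which must be 'top' or 'bottom', got {which!r}")
    lo, hi = interval
    kept = [c for c in rep.clonotypes if lo < c.copy_number <= hi]
    return SubRepertoire(rep.sample_id, interval, kept, rep.group_label, rep.timepoint)


def custom_sub_repertoire(rep: Repertoire, cn_min: float, cn_max: float = math.inf) -> SubRepertoire:
    """Sub-repertoire with cn_min < CN <= cn_max (e.g. the log2(CN) > 8 variant)."""
    kept = [c for c in rep.clonotypes if cn_min < c.copy_number <= cn_max]
    return SubRepertoire(rep.sample_id, (cn_min, cn_max), kept, rep.group_label, rep.timepoint)


def distribute_clonotype_set(
    rep: Repertoire, aa_set: list[str] | set[str], scheme: FractionScheme = LOG2_SCHEME
) -> np.ndarray:
    """Count how many members of an amino-acid sequence set fall in each fraction.

    Set members absent from the repertoire contribute nothing; the result is
    a fixed-length integer vector (one entry per fraction of the scheme).
    """
    wanted = set(aa_set)
    counts = np.zeros(len(scheme), dtype=np.int64)
    for c in rep.clonotypes:
        if c.cdr3_aa in wanted:
            counts[scheme.index_of(c.copy_number) - 1] += 1
    return counts
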