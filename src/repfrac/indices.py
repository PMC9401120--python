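"""Generalized homogeneity and similarity indices for TCR repertoires.

For a repertoire X = {(x_i, v(x_i))} and a reflexive, symmetric similarity
relation R over clonotypes:

* RHI_R(X)  = #{unordered pairs i < j with x_i R x_j} / C(m, 2)
  — the probability that a randomly sampled clonotype pair is similar; a
  generalized Simpson index (diagonal excluded).
* D_NC(x)   = 1 - sum_i (v(x^(i)) / v(x))^2 over the nucleotide variants of x
  — the coding diversity of one clonotype.
* CDI(X)    = mean of D_NC over clonotypes.
* RSI_R(X,Y) = 2 * [sum_{i,j} 1(x_i R y_j) / (n m)]
               / [sum_{i,j} 1(x_i R x_j) / m^2 + sum_{i,j} 1(y_i R y_j) / n^2]
  — cross-repertoire similarity; the self sums run over ordered pairs
  including the diagonal. Under the identity relation RSI equals the Sorensen
  index; its copy-number-weighted analog equals Morisita-Horn.
* d_{alpha,R_1..R_k}(X,Y) = 1 - sum_i alpha_i * min(RSI_{R_i}(X,Y), 1)
  — the dissimilarity used for clustering and classification.

Relations with an equivalence structure (VJ, identity, variant-count classes)
are evaluated by class-size combinatorics; the LD <= 1 relation uses a
deletion-signature hash. Both fast paths are oracle-checked against the
O(n^2) double loop in the test suite.
"""
from __future__ import annotations

import itertools
from collections import Counter
from typing import Sequence

import edlib
import numpy as np

from .types import (
    Clonotype,
    DissimilaritySpec,
    IndexValue,
    Repertoire,
    SimilarityRelation,
    SubRepertoire,
    as_clonotype_list,
)

# ---------------------------------------------------------------------------
# Levenshtein distance and similarity relations


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution/insertion/deletion each cost 1)."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def relation_vj() -> SimilarityRelation:
    """Similar iff equal V- and J-segments were assigned."""
    return SimilarityRelation(
        "VJ",
        lambda x, y: x.v_segment == y.v_segment and x.j_segment == y.j_segment,
        kind="equivalence",
        class_of=lambda c: (c.v_segment, c.j_segment),
    )


def relation_v() -> SimilarityRelation:
    """Similar iff equal V-segment (one of the two d_V,J criteria)."""
    return SimilarityRelation(
        "V",
        lambda x, y: x.v_segment == y.v_segment,
        kind="equivalence",
        class_of=lambda c: c.v_segment,
    )


def relation_j() -> SimilarityRelation:
    """Similar iff equal J-segment."""
    return SimilarityRelation(
        "J",
        lambda x, y: x.j_segment == y.j_segment,
        kind="equivalence",
        class_of=lambda c: c.j_segment,
    )


def relation_ld(max_d: int = 1) -> SimilarityRelation:
    """Similar iff the CDR3 Levenshtein distance is at most ``max_d``.

    Short-circuits on the length difference before running the DP alignment.
    """

    def pred(x: Clonotype, y: Clonotype) -> bool:
        a, b = x.cdr3_aa, y.cdr3_aa
        if abs(len(a) - len(b)) > max_d:
            return False
        return levenshtein(a, b) <= max_d

    return SimilarityRelation("LD", pred, kind="ld" if max_d == 1 else "generic", max_d=max_d)


def relation_identity(strict: bool = False) -> SimilarityRelation:
    """Similar iff identical CDR3 amino-acid sequence.

    ``strict=True`` additionally requires equal V and J segments.
    """
    if strict:
        return SimilarityRelation(
            "identity_strict",
            lambda x, y: (x.cdr3_aa, x.v_segment, x.j_segment)
            == (y.cdr3_aa, y.v_segment, y.j_segment),
            kind="equivalence",
            class_of=lambda c: (c.cdr3_aa, c.v_segment, c.j_segment),
        )
    return SimilarityRelation(
        "identity",
        lambda x, y: x.cdr3_aa == y.cdr3_aa,
        kind="equivalence",
        class_of=lambda c: c.cdr3_aa,
    )


def relation_nc_count(threshold: int = 5) -> SimilarityRelation:
    """Similar iff variant counts coincide or exceed ``threshold`` for both.

    'Exceeds' is implemented strictly (> threshold); this merges all counts
    above the threshold into one class, so the relation is an equivalence.
    """

    def cls(c: Clonotype) -> int:
        n = c.n_variants
        return threshold + 1 if n > threshold else n

    return SimilarityRelation(
        f"NC>{threshold}",
        lambda x, y: cls(x) == cls(y),
        kind="equivalence",
        class_of=cls,
    )


# ---------------------------------------------------------------------------
# fast pair counting

def _ld1_keys(s: str):
    """Deletion signatures: two same-length strings differ by exactly one
    substitution iff they share a (position, deleted-string) signature."""
    for i in range(len(s)):
        yield (len(s), i, s[:i] + s[i + 1 :])


def _count_similar_pairs_ld1(seqs: Sequence[str]) -> int:
    """Number of unordered pairs (i < j) with Levenshtein distance <= 1."""
    n = len(seqs)
    value_counts = Counter(seqs)
    # identical pairs (LD = 0)
    pairs = sum(c * (c - 1) // 2 for c in value_counts.values())
    # substitution pairs: same length, differ at exactly one position.
    # Work on unique values, then multiply by multiplicities.
    sig: Counter = Counter()
    uniq = list(value_counts)
    for s in uniq:
        w = value_counts[s]
        for key in _ld1_keys(s):
            sig[key] += w
    # pairs sharing a signature = sub pairs + identical pairs counted len(s)
    # times each; remove the identical contribution per signature.
    sub_pairs = sum(c * (c - 1) // 2 for c in sig.values())
    sub_pairs -= sum(
        len(s) * (w * (w - 1) // 2) for s, w in value_counts.items()
    )
    pairs += sub_pairs
    # indel pairs: len(a) = len(b) + 1 and b is a deletion of a
    by_len: dict[int, Counter] = {}
    for s, w in value_counts.items():
        by_len.setdefault(len(s), Counter())[s] = w
    for s, w in value_counts.items():
        shorter = by_len.get(len(s) - 1)
        if not shorter:
            continue
        for d in {s[:i] + s[i + 1 :] for i in range(len(s))}:
            pairs += w * shorter.get(d, 0)
    return pairs


def _count_cross_ld1(xs: Sequence[str], ys: Sequence[str]) -> int:
    """Number of ordered cross pairs (x, y) with Levenshtein distance <= 1."""
    cx, cy = Counter(xs), Counter(ys)
    total = sum(w * cy.get(s, 0) for s, w in cx.items())  # LD = 0
    sig_y: Counter = Counter()
    for s, w in cy.items():
        for key in _ld1_keys(s):
            sig_y[key] += w
    for s, w in cx.items():
        shared = sum(sig_y.get(key, 0) for key in _ld1_keys(s))
        # equal strings share all len(s) signatures; remove that overcount
        shared -= len(s) * cy.get(s, 0)
        total += w * shared
    # indel pairs in both directions
    ylen: dict[int, Counter] = {}
    for s, w in cy.items():
        ylen.setdefault(len(s), Counter())[s] = w
    xlen: dict[int, Counter] = {}
    for s, w in cx.items():
        xlen.setdefault(len(s), Counter())[s] = w
    for s, w in cx.items():
        shorter = ylen.get(len(s) - 1)
        if shorter:
            for d in {s[:i] + s[i + 1 :] for i in range(len(s))}:
                total += w * shorter.get(d, 0)
    for s, w in cy.items():
        shorter = xlen.get(len(s) - 1)
        if shorter:
            for d in {s[:i] + s[i + 1 :] for i in range(len(s))}:
                total += w * shorter.get(d, 0)
    return total


def count_similar_pairs(
    items: Sequence[Clonotype], relation: SimilarityRelation
) -> int:
    """Unordered similar pairs i < j (diagonal excluded)."""
    if relation.kind == "equivalence" and relation.class_of is not None:
        classes = Counter(relation.class_of(c) for c in items)
        return sum(g * (g - 1) // 2 for g in classes.values())
    if relation.kind == "ld" and relation.max_d == 1:
        return _count_similar_pairs_ld1([c.cdr3_aa for c in items])
    return sum(
        1 for a, b in itertools.combinations(items, 2) if relation(a, b)
    )


def count_cross_pairs(
    xs: Sequence[Clonotype], ys: Sequence[Clonotype], relation: SimilarityRelation
) -> int:
    """Ordered similar cross pairs (x_i, y_j)."""
    if relation.kind == "equivalence" and relation.class_of is not None:
        cx = Counter(relation.class_of(c) for c in xs)
        cy = Counter(relation.class_of(c) for c in ys)
        return sum(w * cy.get(k, 0) for k, w in cx.items())
    if relation.kind == "ld" and relation.max_d == 1:
        return _count_cross_ld1([c.cdr3_aa for c in xs], [c.cdr3_aa for c in ys])
    return sum(1 for a in xs for b in ys if relation(a, b))


# ---------------------------------------------------------------------------
# indices


def rhi(items, relation: SimilarityRelation) -> IndexValue:
    """Repertoire Homogeneity Index: P(random clonotype pair is similar)."""
    cl = as_clonotype_list(items)
    m = len(cl)
    name = f"RHI_{relation.name}"
    if m < 2:
        return IndexValue.undefined(name, m)
    pairs = count_similar_pairs(cl, relation)
    return IndexValue(pairs / (m * (m - 1) / 2), m, name)


def rhi_weighted(items, relation: SimilarityRelation) -> IndexValue:
    """Copy-number-weighted RHI.

    Pair sampling is weighted by copy numbers over *distinct* clonotypes:
    sum_{i<j} v_i v_j 1(x_i R x_j) / sum_{i<j} v_i v_j. Equals the unweighted
    RHI when all copy numbers coincide; a dominant clonotype similar only to
    itself drives the value to 0 as its copy number grows.
    """
    cl = as_clonotype_list(items)
    m = len(cl)
    name = f"RHIw_{relation.name}"
    if m < 2:
        return IndexValue.undefined(name, m)
    v = np.array([c.copy_number for c in cl], dtype=np.float64)
    total = v.sum()
    denom = (total * total - (v * v).sum()) / 2.0
    if relation.kind == "equivalence" and relation.class_of is not None:
        sums: dict = {}
        sq: dict = {}
        for c, w in zip(cl, v):
            k = relation.class_of(c)
            sums[k] = sums.get(k, 0.0) + w
            sq[k] = sq.get(k, 0.0) + w * w
        num = sum((sums[k] ** 2 - sq[k]) / 2.0 for k in sums)
    else:
        num = sum(
            cl[i].copy_number * cl[j].copy_number
            for i, j in itertools.combinations(range(m), 2)
            if relation(cl[i], cl[j])
        )
    return IndexValue(num / denom, m, name)


def coding_diversity(clonotype: Clonotype) -> float:
    """D_NC: 1 minus the Simpson concentration of the variant read counts."""
    if clonotype.copy_number <= 0:
        raise ValueError("copy_number must be positive")
    if not clonotype.variants:
        return 0.0  # single (implicit) coding
    counts = np.array([v.read_count for v in clonotype.variants], dtype=np.float64)
    p = counts / clonotype.copy_number
    return float(1.0 - (p * p).sum())


def cdi(items) -> IndexValue:
    """Coding Diversity Index: mean D_NC over clonotypes."""
    cl = as_clonotype_list(items)
    if not cl:
        return IndexValue.undefined("CDI", 0)
    vals = [coding_diversity(c) for c in cl]
    return IndexValue(float(np.mean(vals)), len(cl), "CDI")


def jaccard(a, b) -> IndexValue:
    """Jaccard index over the CDR3 amino-acid sequence sets of two samples."""
    sa = a.aa_set() if hasattr(a, "aa_set") else {c.cdr3_aa for c in a}
    sb = b.aa_set() if hasattr(b, "aa_set") else {c.cdr3_aa for c in b}
    union = len(sa | sb)
    if union == 0:
        return IndexValue.undefined("Jaccard", 0)
    return IndexValue(len(sa & sb) / union, union, "Jaccard")


def _rsi_terms(xs, ys, relation: SimilarityRelation) -> tuple[float, float, float]:
    m, n = len(xs), len(ys)
    cross = count_cross_pairs(xs, ys, relation)
    # ordered self pairs including the diagonal (relation is reflexive)
    self_x = 2 * count_similar_pairs(xs, relation) + m
    self_y = 2 * count_similar_pairs(ys, relation) + n
    return cross / (n * m), self_x / (m * m), self_y / (n * n)


def rsi(x, y, relation: SimilarityRelation) -> IndexValue:
    """Repertoire Similarity Index between two samples under a relation.

    May exceed 1 for non-transitive relations; equals the Sorensen index
    under the identity relation.
    """
    xs, ys = as_clonotype_list(x), as_clonotype_list(y)
    name = f"RSI_{relation.name}"
    if not xs or not ys:
        return IndexValue.undefined(name, len(xs) + len(ys))
    cross, sx, sy = _rsi_terms(xs, ys, relation)
    return IndexValue(2.0 * cross / (sx + sy), len(xs) + len(ys), name)


def rsi_weighted(x, y, relation: SimilarityRelation) -> IndexValue:
    """Copy-number-weighted RSI.

    Read proportions p_i = v_X(x_i)/N_X and q_j = v_Y(y_j)/N_Y replace the
    uniform 1/m, 1/n weights in the RSI formula (self sums include the
    diagonal). Under the identity relation this equals the Morisita-Horn
    index of the two count vectors; under uniform counts it equals the
    unweighted RSI.
    """
    xs, ys = as_clonotype_list(x), as_clonotype_list(y)
    name = f"RSIw_{relation.name}"
    if not xs or not ys:
        return IndexValue.undefined(name, len(xs) + len(ys))
    px = np.array([c.copy_number for c in xs], dtype=np.float64)
    py = np.array([c.copy_number for c in ys], dtype=np.float64)
    px /= px.sum()
    py /= py.sum()

    if relation.kind == "equivalence" and relation.class_of is not None:
        wx: dict = {}
        wy: dict = {}
        sqx = 0.0
        sqy = 0.0
        for c, w in zip(xs, px):
            k = relation.class_of(c)
            wx[k] = wx.get(k, 0.0) + w
        for c, w in zip(ys, py):
            k = relation.class_of(c)
            wy[k] = wy.get(k, 0.0) + w
        cross = sum(w * wy.get(k, 0.0) for k, w in wx.items())
        sqx = sum(w * w for w in wx.values())
        sqy = sum(w * w for w in wy.values())
    else:
        cross = sum(
            float(px[i] * py[j])
            for i in range(len(xs))
            for j in range(len(ys))
            if relation(xs[i], ys[j])
        )
        sqx = sum(
            float(px[i] * px[j])
            for i in range(len(xs))
            for j in range(len(xs))
            if relation(xs[i], xs[j])
        )
        sqy = sum(
            float(py[i] * py[j])
            for i in range(len(ys))
            for j in range(len(ys))
            if relation(ys[i], ys[j])
        )
    return IndexValue(2.0 * cross / (sqx + sqy), len(xs) + len(ys), name)


def dissimilarity(x, y, spec: DissimilaritySpec, weighted: bool = False) -> float:
    """d_{alpha,R_1..R_k}(X, Y) = 1 - sum_i alpha_i * min(RSI_{R_i}(X, Y), 1).

    An undefined RSI (empty side) propagates as NaN.
    """
    fn = rsi_weighted if weighted else rsi
    total = 0.0
    for rel, alpha in zip(spec.relations, spec.weights):
        val = fn(x, y, rel)
        if not val.defined:
            return float("nan")
        total += alpha * min(val.value, 1.0)
    return 1.0 - total


def vj_dissimilarity_spec() -> DissimilaritySpec:
    """d_V,J: V and J identity as two independent, equally weighted criteria."""
    return DissimilaritySpec((relation_v(), relation_j()), (0.5, 0.5))


def nc_dissimilarity_spec(threshold: int = 5) -> DissimilaritySpec:
    """d_NC: the single variant-count relation."""
    return DissimilaritySpec((relation_nc_count(threshold),), (1.0,))


def summary_stats(items) -> tuple[int, float]:
    """(number of clonotypes, mean CDR3 amino-acid length); NaN length if empty."""
    cl = as_clonotype_list(items)
    if not cl:
        return 0, float("nan")
    return len(cl), float(np.mean([len(c.cdr3_aa) for c in cl]))
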