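"""Homogeneity/similarity indices against brute-force oracles and closed forms."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repfrac.indices import (
    cdi,
    coding_diversity,
    dissimilarity,
    jaccard,
    levenshtein,
    relation_identity,
    relation_j,
    relation_ld,
    relation_nc_count,
    relation_v,
    relation_vj,
    rhi,
    rhi_weighted,
    rsi,
    rsi_weighted,
    summary_stats,
    vj_dissimilarity_spec,
)
from repfrac.types import DissimilaritySpec, Repertoire

from conftest import make_clonotype, random_clonotypes
from _oracles import (
    brute_rhi,
    brute_rhi_weighted,
    brute_rsi,
    morisita_horn,
    naive_levenshtein,
    sorensen,
)

ALL_RELATIONS = [relation_vj(), relation_ld(1), relation_identity(), relation_nc_count(5)]


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,d",
        [("CASS", "CASS", 0), ("CASS", "CAST", 1), ("CASSLG", "CASSLA", 1),
         ("CASSLG", "CATT", 4), ("", "", 0), ("A", "", 1), ("AB", "BA", 2)],
    )
    def test_known_values(self, a, b, d):
        assert levenshtein(a, b) == d

    @settings(max_examples=300, derandomize=True)
    @given(st.text("ACDF", max_size=8), st.text("ACDF", max_size=8))
    def test_matches_naive_recursion(self, a, b):
        assert levenshtein(a, b) == naive_levenshtein(a, b)


class TestRelations:
    def test_vj_examples(self):
        x = make_clonotype("CA", "TRBV1", "TRBJ1-2")
        y = make_clonotype("CS", "TRBV1", "TRBJ1-2")
        z = make_clonotype("CT", "TRBV2", "TRBJ1-2")
        r = relation_vj()
        assert r(x, y) and not r(x, z)

    def test_ld_examples(self):
        r = relation_ld(1)
        assert r(make_clonotype("CASSLG"), make_clonotype("CASSLA"))
        assert not r(make_clonotype("CASSLG"), make_clonotype("CATT"))

    @pytest.mark.parametrize("ka,kb,similar", [(3, 3, True), (6, 8, True), (2, 4, False),
                                               (5, 5, True), (5, 6, False)])
    def test_nc_count_rule(self, ka, kb, similar):
        r = relation_nc_count(5)
        a = _with_k_variants("CA", ka)
        b = _with_k_variants("CS", kb)
        assert r(a, b) is similar

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_reflexive_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_clonotypes(rng, 2)
        for rel in ALL_RELATIONS:
            assert rel(a, a) and rel(b, b)
            assert rel(a, b) == rel(b, a)


def _with_k_variants(aa: str, k: int):
    from repfrac.types import Clonotype, NucleotideVariant
    variants = tuple(NucleotideVariant("ACGT"[i % 4] * 3 + "AAA" * (i // 4), 1)
                     for i in range(k))
    return Clonotype(aa, "TRBV1", "TRBJ1-1", k, variants)


class TestRHI:
    def test_no_similar_pairs_is_zero(self):
        items = [make_clonotype("CADDD", "TRBV1", "TRBJ1-1"),
                 make_clonotype("CWWWW", "TRBV2", "TRBJ1-2"),
                 make_clonotype("CKKKKKKK", "TRBV3", "TRBJ1-3")]
        assert rhi(items, relation_vj()).value == 0
        assert rhi(items, relation_ld(1)).value == 0

    def test_all_sharing_vj_is_one(self):
        items = [make_clonotype(aa, "TRBV1", "TRBJ1-1") for aa in ("CA", "CS", "CT", "CW")]
        assert rhi(items, relation_vj()).value == 1

    def test_ld_hand_example(self):
        items = [make_clonotype("CASSLG"), make_clonotype("CASSLA"), make_clonotype("CATT")]
        # only (CASSLG, CASSLA) of the 3 pairs has LD <= 1
        assert rhi(items, relation_ld(1)).value == pytest.approx(1 / 3)

    def test_undefined_below_two_items(self):
        iv = rhi([make_clonotype("CA")], relation_vj())
        assert not iv.defined and np.isnan(iv.value)

    @pytest.mark.parametrize("rel", ALL_RELATIONS, ids=lambda r: r.name)
    def test_oracle_equivalence(self, rng, rel):
        for _ in range(20):
            items = random_clonotypes(rng, int(rng.integers(5, 80)))
            assert rhi(items, rel).value == pytest.approx(brute_rhi(items, rel))

    def test_permutation_invariance(self, rng):
        items = random_clonotypes(rng, 40)
        perm = [items[i] for i in rng.permutation(40)]
        for rel in ALL_RELATIONS:
            assert rhi(items, rel).value == pytest.approx(rhi(perm, rel).value)


class TestRHIWeighted:
    def test_uniform_counts_collapse_to_unweighted(self, rng):
        items = random_clonotypes(rng, 30)
        items = [make_clonotype(c.cdr3_aa + str(i), c.v_segment, c.j_segment, cn=5)
                 for i, c in enumerate(items)]
        for rel in (relation_vj(), relation_ld(1)):
            assert rhi_weighted(items, rel).value == pytest.approx(rhi(items, rel).value)

    def test_dominant_self_only_clonotype_drives_to_zero(self):
        shared = [make_clonotype(aa, "TRBV1", "TRBJ1-1", cn=2) for aa in ("CAD", "CSD")]
        prev = 1.0
        for big_cn in (10, 100, 1000):
            items = shared + [make_clonotype("CW", "TRBV9", "TRBJ2-7", cn=big_cn)]
            val = rhi_weighted(items, relation_vj()).value
            assert val < prev
            prev = val
        assert prev < 0.01

    def test_expanded_multiset_oracle(self, rng):
        for _ in range(10):
            items = random_clonotypes(rng, int(rng.integers(5, 30)), max_cn=6)
            for rel in (relation_vj(), relation_identity()):
                assert rhi_weighted(items, rel).value == pytest.approx(
                    brute_rhi_weighted(items, rel)
                )


class TestCodingDiversity:
    def test_single_variant_is_zero(self):
        assert coding_diversity(make_clonotype("CA", cn=7)) == 0

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_equal_count_variants_closed_form(self, k):
        c = make_clonotype("CASS", cn=2 * k, variant_counts=(2,) * k)
        assert coding_diversity(c) == pytest.approx(1 - 1 / k)

    def test_counts_3_1(self):
        c = make_clonotype("CASS", cn=4, variant_counts=(3, 1))
        assert coding_diversity(c) == pytest.approx(0.375)


class TestCDI:
    def test_all_single_coded_is_zero(self):
        items = [make_clonotype(aa, cn=3) for aa in ("CA", "CS")]
        assert cdi(items).value == 0

    def test_mean_of_dnc(self):
        items = [make_clonotype("CA", cn=3),
                 make_clonotype("CASS", cn=4, variant_counts=(2, 2))]
        assert cdi(items).value == pytest.approx(0.25)

    def test_empty_undefined(self):
        assert not cdi([]).defined

    def test_matches_independent_recomputation(self, rng):
        items = random_clonotypes(rng, 60)
        expected = np.mean(
            [1 - sum((v.read_count / c.copy_number) ** 2 for v in c.variants)
             for c in items]
        )
        assert cdi(items).value == pytest.approx(expected)


class TestJaccard:
    def test_identical_sets(self):
        a = Repertoire("a", [make_clonotype("CA", cn=2), make_clonotype("CS", cn=9)])
        b = Repertoire("b", [make_clonotype("CA", cn=5), make_clonotype("CS", cn=2)])
        assert jaccard(a, b).value == 1

    def test_disjoint_sets(self):
        a = Repertoire("a", [make_clonotype("CA", cn=2)])
        b = Repertoire("b", [make_clonotype("CS", cn=2)])
        assert jaccard(a, b).value == 0

    def test_half_overlap(self):
        a = Repertoire("a", [make_clonotype(x, cn=2) for x in ("CA", "CB", "CC")])
        b = Repertoire("b", [make_clonotype(x, cn=2) for x in ("CB", "CC", "CD")])
        assert jaccard(a, b).value == pytest.approx(0.5)

    def test_both_empty_undefined(self):
        assert not jaccard(Repertoire("a", []), Repertoire("b", [])).defined


class TestRSI:
    def test_identity_relation_is_sorensen(self):
        xs = [make_clonotype(x, cn=2) for x in ("CA", "CB", "CC")]
        ys = [make_clonotype(x, cn=2) for x in ("CB", "CC", "CD")]
        assert rsi(xs, ys, relation_identity()).value == pytest.approx(2 / 3)

    def test_self_comparison_duplicate_free(self, rng):
        xs = random_clonotypes(rng, 20)
        uniq = {c.cdr3_aa: c for c in xs}
        xs = list(uniq.values())
        assert rsi(xs, xs, relation_identity()).value == pytest.approx(1.0)

    def test_sorensen_on_random_sets(self, rng):
        for _ in range(20):
            names = [f"C{i}" for i in range(30)]
            sa = set(rng.choice(names, size=int(rng.integers(3, 20)), replace=False))
            sb = set(rng.choice(names, size=int(rng.integers(3, 20)), replace=False))
            xs = [make_clonotype(a, cn=2) for a in sa]
            ys = [make_clonotype(b, cn=2) for b in sb]
            assert rsi(xs, ys, relation_identity()).value == pytest.approx(sorensen(sa, sb))

    @pytest.mark.parametrize("rel", ALL_RELATIONS, ids=lambda r: r.name)
    def test_oracle_equivalence(self, rng, rel):
        for _ in range(10):
            xs = random_clonotypes(rng, int(rng.integers(5, 40)))
            ys = random_clonotypes(rng, int(rng.integers(5, 40)))
            assert rsi(xs, ys, rel).value == pytest.approx(brute_rsi(xs, ys, rel))

    def test_symmetry(self, rng):
        xs, ys = random_clonotypes(rng, 25), random_clonotypes(rng, 30)
        for rel in ALL_RELATIONS:
            assert rsi(xs, ys, rel).value == pytest.approx(rsi(ys, xs, rel).value)

    def test_empty_side_undefined(self):
        assert not rsi([], [make_clonotype("CA")], relation_vj()).defined


class TestRSIWeighted:
    def test_identical_repertoires_identity_is_one(self):
        xs = [make_clonotype("CA", cn=5), make_clonotype("CS", cn=3)]
        assert rsi_weighted(xs, xs, relation_identity()).value == pytest.approx(1.0)

    def test_identity_equals_morisita_horn(self, rng):
        for _ in range(20):
            names = [f"C{i}" for i in range(12)]
            cx = rng.integers(0, 9, size=12)
            cy = rng.integers(0, 9, size=12)
            cx[0] = max(cx[0], 2)
            cy[1] = max(cy[1], 2)
            xs = [make_clonotype(n, cn=int(c) + 1) for n, c in zip(names, cx) if c > 0]
            ys = [make_clonotype(n, cn=int(c) + 1) for n, c in zip(names, cy) if c > 0]
            # align count vectors over the union for the textbook oracle
            union = sorted({c.cdr3_aa for c in xs} | {c.cdr3_aa for c in ys})
            vx = np.array([next((c.copy_number for c in xs if c.cdr3_aa == n), 0) for n in union])
            vy = np.array([next((c.copy_number for c in ys if c.cdr3_aa == n), 0) for n in union])
            assert rsi_weighted(xs, ys, relation_identity()).value == pytest.approx(
                morisita_horn(vx, vy)
            )

    def test_uniform_counts_collapse_to_unweighted(self, rng):
        xs = [make_clonotype(f"CA{i}", f"TRBV{i % 3 + 1}", "TRBJ1-1", cn=4) for i in range(10)]
        ys = [make_clonotype(f"CB{i}", f"TRBV{i % 4 + 1}", "TRBJ1-1", cn=4) for i in range(8)]
        for rel in (relation_v(), relation_vj()):
            assert rsi_weighted(xs, ys, rel).value == pytest.approx(rsi(xs, ys, rel).value)


class TestDissimilarity:
    def test_self_distance_zero_identity(self):
        xs = [make_clonotype("CA", cn=2), make_clonotype("CS", cn=3)]
        spec = DissimilaritySpec((relation_identity(),), (1.0,))
        assert dissimilarity(xs, xs, spec) == pytest.approx(0.0)

    def test_all_rsi_zero_gives_one(self):
        xs = [make_clonotype("CA", "TRBV1", "TRBJ1-1", cn=2)]
        ys = [make_clonotype("CB", "TRBV2", "TRBJ1-2", cn=2)]
        assert dissimilarity(xs, ys, vj_dissimilarity_spec()) == pytest.approx(1.0)

    def test_vj_spec_composes_oracle_rsi(self, rng):
        xs = random_clonotypes(rng, 20)
        ys = random_clonotypes(rng, 25)
        expected = 1 - 0.5 * (
            min(brute_rsi(xs, ys, relation_v()), 1.0)
            + min(brute_rsi(xs, ys, relation_j()), 1.0)
        )
        assert dissimilarity(xs, ys, vj_dissimilarity_spec()) == pytest.approx(expected)

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            DissimilaritySpec((relation_v(), relation_j()), (0.7, 0.7))


class TestSummaryStats:
    def test_count_and_mean_length(self):
        n, ml = summary_stats([make_clonotype("CASS", cn=2), make_clonotype("CASSLG", cn=2)])
        assert n == 2 and ml == pytest.approx(5.0)

    def test_empty(self):
        n, ml = summary_stats([])
        assert n == 0 and np.isnan(ml)
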