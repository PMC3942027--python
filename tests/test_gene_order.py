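"""Core gene-order mathematics: adjacencies, GOC/GOL, breakpoint and DCJ."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitorder.errors import ContentMismatchError, DuplicateGeneError, \
    UndefinedInputError
from mitorder.gene_order import (
    GeneOrder,
    adjacency_set,
    breakpoint_distance,
    dcj_distance,
    goc_gol,
    shared_gene_set,
)

from .conftest import random_signed_circular
from .dcj_oracle import bfs_dcj_distance


def order(seq, genome_id="g", circular=True):
    return GeneOrder(
        genome_id,
        tuple((s.lstrip("-"), -1 if s.startswith("-") else 1) for s in seq),
        circular=circular,
    )


def adj(*pairs):
    return frozenset(frozenset(p) for p in pairs)


class TestGeneOrder:
    def test_duplicate_symbols_rejected(self):
        with pytest.raises(DuplicateGeneError):
            order(["A", "B", "A"])

    def test_empty_rejected(self):
        with pytest.raises(UndefinedInputError):
            GeneOrder("g", ())

    def test_restrict_deletes_and_joins(self):
        g = order(["A", "B", "C", "F", "D", "E"])
        assert g.restrict(set("ABCDE")).symbols == tuple("ABCDE")


class TestAdjacencies:
    def test_circular_full(self, abcde):
        assert adjacency_set(abcde) == adj("AB", "BC", "CD", "DE", "EA")

    def test_delete_and_join(self):
        g = order(["A", "B", "C", "F", "D", "E"])
        assert adjacency_set(g, restrict_to=set("ABCDE")) == adj(
            "AB", "BC", "CD", "DE", "EA"
        )

    def test_linear_no_wrap(self):
        g = order(["A", "B", "C"], circular=False)
        assert adjacency_set(g) == adj("AB", "BC")

    def test_too_small(self):
        g = order(["A", "B"])
        with pytest.raises(UndefinedInputError):
            adjacency_set(g, restrict_to={"A"})

    @pytest.mark.parametrize("n", [3, 5, 8, 13])
    def test_circular_count_equals_gene_count(self, n, rng):
        g = random_signed_circular(n, rng)
        assert len(adjacency_set(g)) == n


class TestSharedGenes:
    def test_partial_overlap(self):
        g1 = order(list("ABCDE"))
        g2 = order(["A", "B", "C", "F", "G"])
        assert shared_gene_set(g1, g2) == set("ABC")

    def test_disjoint(self):
        assert shared_gene_set(order(list("ABC")), order(list("XYZ"))) == set()


class TestGOC:
    def test_identical_orders(self, abcde):
        goc, gol = goc_gol(abcde, order(list("ABCDE"), "other"))
        assert goc == 1.0 and gol == 0.0

    def test_one_transposition(self, abcde):
        # (A,B,C,D,E) vs (A,B,D,C,E): shared adjacencies AB, CD, EA
        goc, gol = goc_gol(abcde, order(["A", "B", "D", "C", "E"]))
        assert goc == pytest.approx(0.6)
        assert gol == pytest.approx(0.4)

    def test_restriction_recovers_identity(self, abcde):
        g2 = order(["A", "B", "C", "F", "D", "E"])
        goc, _ = goc_gol(abcde, g2)
        assert goc == 1.0

    def test_too_few_shared_genes(self):
        with pytest.raises(UndefinedInputError):
            goc_gol(order(list("ABX")), order(list("ABY")))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_range_and_self(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        g1 = random_signed_circular(n, rng, "a")
        g2 = random_signed_circular(n, rng, "b")
        goc12, gol12 = goc_gol(g1, g2)
        goc21, _ = goc_gol(g2, g1)
        assert goc12 == goc21
        assert 0.0 <= goc12 <= 1.0
        assert goc12 + gol12 == pytest.approx(1.0)
        assert goc_gol(g1, g1)[0] == 1.0

    @given(st.integers(0, 2**32 - 1), st.integers(1, 11))
    @settings(max_examples=25, deadline=None)
    def test_rotation_and_reflection_invariance(self, seed, k):
        import numpy as np

        rng = np.random.default_rng(seed)
        g1 = random_signed_circular(8, rng, "a")
        g2 = random_signed_circular(8, rng, "b")
        base = goc_gol(g1, g2)[0]
        assert goc_gol(g1.rotate(k), g2)[0] == base
        assert goc_gol(g1.reverse(), g2)[0] == base


class TestBreakpointDistance:
    def test_identical(self, abcde):
        assert breakpoint_distance(abcde, order(list("ABCDE"), "o")) == 0

    def test_one_transposition(self, abcde):
        assert breakpoint_distance(abcde, order(["A", "B", "D", "C", "E"])) == 2

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_equals_m_times_gol(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        g1 = random_signed_circular(n, rng, "a")
        g2 = random_signed_circular(n, rng, "b")
        goc, gol = goc_gol(g1, g2)
        assert breakpoint_distance(g1, g2) == pytest.approx(n * gol)


class TestDCJ:
    def test_identical(self, abcde):
        assert dcj_distance(abcde, order(list("ABCDE"), "o")) == 0

    def test_rotation_and_reflection_are_free(self, abcde):
        assert dcj_distance(abcde, abcde.rotate(2)) == 0
        assert dcj_distance(abcde, abcde.reverse()) == 0

    def test_single_inversion(self, abcde):
        g2 = order(["A", "-C", "-B", "D", "E"])
        assert dcj_distance(abcde, g2) == 1

    def test_two_inversions(self):
        g1 = order(list("ABCD"))
        g2 = order(["A", "-B", "-C", "D"])
        assert dcj_distance(g1, g2) == 2

    def test_content_mismatch_refused(self):
        with pytest.raises(ContentMismatchError):
            dcj_distance(order(list("ABC")), order(list("ABD")))

    def test_never_exceeds_signed_breakpoints(self, rng):
        # each conserved signed adjacency closes its own cycle, so the
        # sign-aware breakpoint count bounds the DCJ distance from above
        for _ in range(50):
            n = int(rng.integers(4, 10))
            g1 = random_signed_circular(n, rng, "a")
            g2 = random_signed_circular(n, rng, "b")
            assert dcj_distance(g1, g2) <= breakpoint_distance(
                g1, g2, signed=True
            )

    def test_metric_properties(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 8))
            g1 = random_signed_circular(n, rng, "a")
            g2 = random_signed_circular(n, rng, "b")
            g3 = random_signed_circular(n, rng, "c")
            d12 = dcj_distance(g1, g2)
            assert d12 == dcj_distance(g2, g1)
            assert dcj_distance(g1, g1) == 0
            assert d12 <= dcj_distance(g1, g3) + dcj_distance(g3, g2)
            if d12 == 0:
                # zero iff equal up to rotation / reflection-with-sign-flip
                variants = {g2.rotate(k).genes for k in range(n)}
                variants |= {g2.reverse().rotate(k).genes for k in range(n)}
                assert g1.genes in variants

    @pytest.mark.parametrize("n", [3, 4])
    def test_bfs_oracle_exhaustive(self, n):
        from .conftest import all_signed_circular_orders

        symbols = [f"g{i + 1}" for i in range(n)]
        identity = GeneOrder("id", tuple((s, 1) for s in symbols))
        for target in all_signed_circular_orders(symbols):
            assert dcj_distance(identity, target) == bfs_dcj_distance(
                identity, target
            )

    def test_bfs_oracle_sampled(self, rng):
        for n in (5, 6):
            for _ in range(8):
                g1 = random_signed_circular(n, rng, "a")
                g2 = random_signed_circular(n, rng, "b")
                assert dcj_distance(g1, g2) == bfs_dcj_distance(g1, g2)
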