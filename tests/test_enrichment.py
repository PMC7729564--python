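"""Hypergeometric enrichment statistics and catalog handling."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from quiescreen.enrichment import (CategoryCatalog, cluster_enrichment,
                                   fold_enrichment, hypergeom_point,
                                   hypergeom_tail, read_catalog)


def exact_point(k, n, K, N):
    """Exact rational hypergeometric point mass via integer combinatorics."""
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


class TestFoldEnrichment:
    def test_saga_in_entry_defect_cluster(self):
        # 3 of the 15 genes in the G0-entry-defect cluster are SAGA subunits;
        # 9 SAGA deletions among 684 analyzed strains
        assert fold_enrichment(3, 15, 9, 684) == pytest.approx(15.2)

    def test_rits_in_viability_cluster(self):
        assert fold_enrichment(2, 108, 2, 684) == pytest.approx(6.3333, abs=1e-3)

    def test_whole_background_in_one_cluster_is_unity(self):
        assert fold_enrichment(9, 684, 9, 684) == pytest.approx(1.0)

    def test_proportional_representation_is_unity(self):
        # k/n == K/N exactly
        assert fold_enrichment(3, 30, 10, 100) == pytest.approx(1.0)

    def test_zero_cluster_or_category_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(0, 0, 5, 100)
        with pytest.raises(ValueError):
            fold_enrichment(0, 5, 0, 100)


class TestHypergeometric:
    def test_rits_point_probability(self):
        assert hypergeom_point(2, 108, 2, 684) == pytest.approx(0.024737,
                                                                abs=1e-5)

    def test_point_edge_cases(self):
        assert hypergeom_point(0, 0, 5, 10) == 1.0
        assert hypergeom_tail(0, 20, 5, 100) == 1.0

    def test_small_case_by_enumeration_of_subsets(self):
        # all 6 two-element subsets of {1,2,3,4} with K=2 marked:
        # 1 subset has both marks, 4 have one, 1 has none
        assert hypergeom_point(1, 2, 2, 4) == pytest.approx(2 / 3)
        assert hypergeom_tail(1, 2, 2, 4) == pytest.approx(5 / 6)

    def test_tail_dominates_point(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(2, 200))
            n = int(rng.integers(0, N + 1))
            K = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            assert hypergeom_tail(k, n, K, N) >= hypergeom_point(k, n, K, N) - 1e-12

    def test_pmf_sums_to_one_over_support(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            N = int(rng.integers(2, 200))
            n = int(rng.integers(0, N + 1))
            K = int(rng.integers(0, N + 1))
            total = sum(hypergeom_point(k, n, K, N)
                        for k in range(max(0, n + K - N), min(n, K) + 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            hypergeom_point(6, 5, 10, 100)
        with pytest.raises(ValueError, match="inconsistent"):
            hypergeom_tail(1, 5, 200, 100)


class TestCatalog:
    def test_members_must_be_in_background(self):
        with pytest.raises(ValueError, match="outside the background"):
            CategoryCatalog({"c": frozenset({"g1", "gX"})},
                            frozenset({"g1", "g2"}))

    def test_read_two_column_and_gmt(self, tmp_path):
        tsv = tmp_path / "cat.tsv"
        tsv.write_text("SAGA\tgcn5\nSAGA\tada2\nDASH\task1\n")
        bg = tmp_path / "bg.txt"
        bg.write_text("gcn5\nada2\nask1\nspare\n")
        cat = read_catalog(tsv, bg)
        assert cat.categories["SAGA"] == {"gcn5", "ada2"}
        assert len(cat.background) == 4

        gmt = tmp_path / "cat.gmt"
        gmt.write_text("SAGA\tdesc\tgcn5\tada2\nDASH\tdesc\task1\n")
        cat2 = read_catalog(gmt, bg)
        assert cat2.categories == cat.categories


class TestClusterEnrichment:
    def _setup(self):
        background = [f"g{i}" for i in range(200)]
        category = set(background[:10])
        assignments = {g: (1 if i < 20 else 2) for i, g in enumerate(background)}
        catalog = CategoryCatalog({"cplx": frozenset(category)},
                                  frozenset(background))
        return assignments, catalog

    def test_fully_contained_category(self):
        assignments, catalog = self._setup()
        table = cluster_enrichment(assignments, catalog)
        row = table[(table.cluster == 1) & (table.category == "cplx")].iloc[0]
        assert row.fold == pytest.approx(10.0)
        # oracle: brute-force exact rational tail
        want = float(sum(exact_point(k, 20, 10, 200) for k in range(10, 11)))
        assert row.p_tail == pytest.approx(want, rel=1e-9)
        assert row.p_point == pytest.approx(want, rel=1e-9)

    def test_absent_category_not_reported(self):
        assignments, catalog = self._setup()
        table = cluster_enrichment(assignments, catalog)
        assert not ((table.cluster == 2) & (table.category == "cplx")).any()

    def test_ino80_counts_reproduce_printed_fold(self):
        background = [f"g{i}" for i in range(684)]
        ino80 = frozenset(background[:10])
        assignments = {}
        # cluster 1 of 108 genes containing 5 Ino80 members
        for g in background[:5] + background[10:113]:
            assignments[g] = 1
        for g in background[5:10] + background[113:]:
            assignments[g] = 2
        catalog = CategoryCatalog({"Ino80": ino80}, frozenset(background))
        table = cluster_enrichment(assignments, catalog)
        row = table[table.cluster == 1].iloc[0]
        assert (row.k, row.n, row.K, row.N) == (5, 108, 10, 684)
        assert row.fold == pytest.approx(3.17, abs=0.01)

    def test_unknown_genes_rejected_with_ids(self):
        assignments, catalog = self._setup()
        assignments["mystery"] = 1
        with pytest.raises(ValueError, match="mystery"):
            cluster_enrichment(assignments, catalog)

    def test_sorted_by_point_probability_with_bh_column(self):
        rng = np.random.default_rng(2)
        background = [f"g{i}" for i in range(100)]
        cats = {f"c{j}": frozenset(rng.choice(background, 8, replace=False))
                for j in range(5)}
        assignments = {g: int(rng.integers(1, 4)) for g in background}
        table = cluster_enrichment(assignments,
                                   CategoryCatalog(cats, frozenset(background)))
        assert (table.p_point.diff().dropna() >= -1e-15).all()
        assert ((table.p_bh >= table.p_tail - 1e-12) | (table.p_bh == 1)).all()
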