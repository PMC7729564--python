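"""Phenotype standardization, Ward clustering, CCC and control comparison."""

import numpy as np
import pandas as pd
import pytest

from quiescreen.clustering import (build_phenotype_matrix, compare_to_control,
                                   compute_ccc, cut_assignments,
                                   cluster_phenotypes, partition_r2,
                                   standardize_features, ward_cluster)
from quiescreen.simulate import simulate_phenotype_archetypes


# --- independent O(n^3) Ward reference --------------------------------------

def brute_force_ward(X):
    """Greedy Ward agglomeration from first principles.

    At each step merge the pair of clusters with the smallest increase in
    total within-cluster sum of squares; report scipy-compatible heights
    sqrt(2 * deltaESS) and the member sets merged.
    """
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                ca, cb = X[clusters[a]].mean(0), X[clusters[b]].mean(0)
                na, nb = len(clusters[a]), len(clusters[b])
                cost = na * nb / (na + nb) * float(np.sum((ca - cb) ** 2))
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        cost, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]),
                       np.sqrt(2 * cost)))
        clusters[a] = clusters[a] + clusters.pop(b)
    return merges


def linkage_to_merges(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_i, (a, b, h, _) in enumerate(Z):
        fa, fb = members[int(a)], members[int(b)]
        out.append((fa, fb, h))
        members[n + row_i] = fa | fb
    return out


class TestWardCluster:
    @pytest.mark.parametrize("n,p,seed", [(6, 2, 0), (9, 3, 1), (12, 5, 2),
                                          (12, 2, 3)])
    def test_agreement_with_brute_force_reference(self, n, p, seed):
        X = np.random.default_rng(seed).standard_normal((n, p))
        Z = ward_cluster(X)
        got = linkage_to_merges(Z, n)
        want = brute_force_ward(X)
        for (ga, gb, gh), (wa, wb, wh) in zip(got, want):
            assert {ga, gb} == {wa, wb}
            assert gh == pytest.approx(wh, abs=1e-9)

    def test_identical_points_merge_at_height_zero(self):
        X = np.ones((8, 3))
        Z = ward_cluster(X)
        assert np.allclose(Z[:, 2], 0)

    def test_two_separated_blobs_dominate_final_merge(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.standard_normal((20, 3)),
                       rng.standard_normal((20, 3)) + 10.0])
        Z = ward_cluster(X)
        assert Z[-1, 2] >= 5 * Z[:-1, 2].max()

    def test_heights_nondecreasing(self):
        X = np.random.default_rng(7).standard_normal((30, 4))
        Z = ward_cluster(X)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_cuts_are_nested(self):
        X = np.random.default_rng(8).standard_normal((25, 3))
        Z = ward_cluster(X)
        for k in range(2, 10):
            coarse = cut_assignments(Z, k)
            fine = cut_assignments(Z, k + 1)
            # every fine cluster maps into exactly one coarse cluster
            for lab in np.unique(fine):
                assert len(np.unique(coarse[fine == lab])) == 1

    def test_row_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((40, 5))
        perm = rng.permutation(40)
        Z1, Z2 = ward_cluster(X), ward_cluster(X[perm])
        for k in (2, 4, 7):
            a = cut_assignments(Z1, k)[perm]
            b = cut_assignments(Z2, k)
            # identical partitions: co-membership matrices agree
            assert (np.equal.outer(a, a) == np.equal.outer(b, b)).all()


class TestStandardize:
    def test_two_point_feature_sample_sd(self):
        Z, flags = standardize_features(np.array([[0.0], [10.0]]))
        # sample sd (n-1) is 7.0711, so z = +/- 0.70711
        assert Z[:, 0] == pytest.approx([-0.7071067811865475, 0.7071067811865475])
        assert not flags[0]

    def test_columns_centered_and_unit_variance(self):
        X = np.random.default_rng(3).uniform(0, 50, (30, 5))
        Z, _ = standardize_features(X)
        assert np.allclose(Z.mean(0), 0, atol=1e-9)
        assert np.allclose(Z.var(0, ddof=1), 1, atol=1e-9)

    def test_constant_column_zeroed_and_flagged(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        Z, flags = standardize_features(X)
        assert (Z[:, 1] == 0).all() and flags[1] and not flags[0]

    def test_idempotence(self):
        X = np.random.default_rng(6).standard_normal((20, 3)) * 7 + 2
        Z1, _ = standardize_features(X)
        Z2, _ = standardize_features(Z1)
        assert np.allclose(Z1, Z2, atol=1e-12)


class TestCCC:
    def test_r2_nondecreasing_in_k(self):
        X = np.random.default_rng(10).standard_normal((50, 5))
        Z = ward_cluster(X)
        r2s = [partition_r2(X, cut_assignments(Z, k)) for k in range(2, 15)]
        assert (np.diff(r2s) >= -1e-12).all()

    def test_three_planted_clusters_selected(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            means = rng.standard_normal((3, 5))
            dmin = min(np.linalg.norm(means[i] - means[j])
                       for i in range(3) for j in range(i + 1, 3))
            means = means / dmin * 8.0
            X = np.vstack([m + rng.standard_normal((50, 5)) for m in means])
            _, chosen = compute_ccc(X, ward_cluster(X), range(2, 16))
            hits += (chosen == 3)
        assert hits >= 20  # >= 80% of replicates

    def test_single_blob_shows_no_structure(self):
        X = np.random.default_rng(123).standard_normal((150, 5))
        ccc, _ = compute_ccc(X, ward_cluster(X), range(2, 16))
        assert max(ccc.values()) < 2

    def test_perfect_partition_gets_infinite_marker(self):
        X = np.repeat(np.eye(3), 4, axis=0)  # three exact point masses
        ccc, chosen = compute_ccc(X, ward_cluster(X), range(2, 5))
        assert ccc[3] == np.inf and chosen == 3


class TestPhenotypeMatrix:
    def _tables(self):
        fits = pd.DataFrame({
            "strain_id": ["a", "b", "c"],
            "t50": [10.0, 1000.0, 20.0], "t25": [5.0, 1000.0, 9.0],
            "t50_censored": [False, True, False],
            "t25_censored": [False, True, False]})
        rows = []
        for sid in ["a", "b"]:
            for day in [0, 1, 7]:
                rows.append({"strain_id": sid, "day": day, "g0_pct": 50.0,
                             "g2_pct": 30.0, "qc_pass": True})
        # strain c misses day 7
        for day in [0, 1]:
            rows.append({"strain_id": "c", "day": day, "g0_pct": 50.0,
                         "g2_pct": 30.0, "qc_pass": True})
        return fits, pd.DataFrame(rows)

    def test_censored_strain_kept_at_horizon_with_flag(self):
        fits, summaries = self._tables()
        records, excl = build_phenotype_matrix(fits, summaries)
        by_id = {r.strain_id: r for r in records}
        assert by_id["b"].censored_t50 and by_id["b"].t50 == 1000.0

    def test_incomplete_strain_excluded_with_reason(self):
        fits, summaries = self._tables()
        records, excl = build_phenotype_matrix(fits, summaries)
        assert "c" in excl and "incomplete" in excl["c"]
        assert {r.strain_id for r in records} == {"a", "b"}

    def test_exclude_policy_drops_censored(self):
        fits, summaries = self._tables()
        records, excl = build_phenotype_matrix(fits, summaries,
                                               censored_policy="exclude")
        assert {r.strain_id for r in records} == {"a"}
        assert "censored" in excl["b"]


def test_archetype_recovery_end_to_end():
    """Planted 7-archetype phenotype screen: CCC finds k=7 and the Ward
    partition matches the planted labels almost perfectly."""
    from scipy.optimize import linear_sum_assignment

    X, labels = simulate_phenotype_archetypes(20, separation=6.0, seed=1)
    Xz, _ = standardize_features(X)
    Z = ward_cluster(Xz)
    _, chosen = compute_ccc(Xz, Z, range(2, 16))
    assert chosen == 7
    pred = cut_assignments(Z, 7)
    m = np.zeros((7, 7))
    for t, p in zip(labels, pred):
        m[t, p - 1] += 1
    r, c = linear_sum_assignment(-m)
    assert m[r, c].sum() / len(labels) >= 0.9


class TestCompareToControl:
    def test_identical_samples(self):
        t, p = compare_to_control([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_shifted_samples_match_closed_form(self):
        t, p = compare_to_control([1, 2, 3], [11, 12, 13])
        assert abs(t) == pytest.approx(12.247448, abs=1e-5)
        assert p < 0.001

    def test_swapping_groups_negates_t(self):
        t1, p1 = compare_to_control([1, 2, 4], [5, 7, 8])
        t2, p2 = compare_to_control([5, 7, 8], [1, 2, 4])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            compare_to_control([1], [1, 2])
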