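"""Isoelectric points, rank-sum/Fisher tests, clustering, Mantel test."""

import itertools
import math
import random
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from halochic.simulate import random_protein
from halochic.stats import (
    EMBOSS,
    IPC_PROTEIN,
    PkaSet,
    assign_family_cog,
    compare_distributions,
    enrichment_test,
    family_identity_summary,
    isoelectric_point,
    jaccard_linkage,
    mantel_test,
    net_charge,
)

from conftest import make_hit


class TestIsoelectricPoint:
    def test_two_group_peptide_matches_closed_form(self):
        pka = PkaSet("lehninger-termini", n_term=9.60, c_term=2.34,
                     D=3.9, E=4.1, C=8.5, Y=10.1, H=6.5, K=10.8, R=12.5)
        # glycylglycine: only the two termini ionize
        assert isoelectric_point("GG", pka) == pytest.approx(
            (9.60 + 2.34) / 2, abs=1e-3
        )

    def test_acidic_residue_lowers_pi(self):
        assert isoelectric_point("GGDGG") < isoelectric_point("GGGGG")

    def test_basic_residue_raises_pi(self):
        assert isoelectric_point("GGKGG") > isoelectric_point("GGGGG")

    def test_composition_only_invariance(self):
        rng = np.random.default_rng(4)
        seq = random_protein(120, rng)
        shuffled = "".join(rng.permutation(list(seq)))
        assert isoelectric_point(seq) == pytest.approx(
            isoelectric_point(shuffled), abs=1e-6
        )

    @pytest.mark.parametrize("pka", [IPC_PROTEIN, EMBOSS], ids=lambda p: p.name)
    def test_bisection_matches_fine_grid_oracle(self, pka):
        rng = np.random.default_rng(12)
        grid = np.arange(0.0, 14.0005, 0.001)
        for _ in range(20):
            seq = random_protein(200, rng)
            charges = np.array([net_charge(seq, ph, pka) for ph in grid])
            oracle = grid[np.argmin(np.abs(charges))]
            assert isoelectric_point(seq, pka) == pytest.approx(oracle, abs=0.01)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            isoelectric_point("")

    def test_pka_values_validated(self):
        with pytest.raises(ValueError):
            PkaSet("bad", n_term=15.0, c_term=2.0, D=3.9, E=4.1, C=8.5,
                   Y=10.1, H=6.5, K=10.8, R=12.5)


def _rank_sum_enumeration_oracle(a, b, alternative):
    """Exact p by enumerating all rank assignments (ties not supported)."""
    combined = sorted(a + b)
    ranks_a = sum(combined.index(v) + 1 for v in a)
    n, m = len(a), len(b)
    u_obs = ranks_a - n * (n + 1) / 2  # U of the first sample
    count_le = count_ge = total = 0
    for subset in itertools.combinations(range(1, n + m + 1), n):
        u = sum(subset) - n * (n + 1) / 2
        total += 1
        count_le += u <= u_obs
        count_ge += u >= u_obs
    if alternative == "less":
        return count_le / total
    if alternative == "greater":
        return count_ge / total
    return min(1.0, 2 * min(count_le, count_ge) / total)


class TestCompareDistributions:
    def test_fully_separated_small_groups(self):
        _u, p = compare_distributions([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(1 / math.comb(6, 3))

    def test_identical_multisets_two_sided(self):
        _u, p = compare_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_all_equal_values_degenerate(self):
        _u, p = compare_distributions([5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0

    def test_exact_path_matches_enumeration_oracle(self):
        rng = random.Random(77)
        for _ in range(40):
            n = rng.randint(1, 6)
            m = rng.randint(1, 6)
            values = rng.sample(range(1000), n + m)
            a, b = values[:n], values[n:]
            for alt in ("less", "greater", "two-sided"):
                _u, p = compare_distributions(a, b, alternative=alt)
                assert p == pytest.approx(
                    _rank_sum_enumeration_oracle(a, b, alt), abs=1e-12
                )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])


def _fisher_enumeration_oracle(k, K, n, N):
    """Upper-tail hypergeometric probability with exact rational arithmetic."""
    total = Fraction(math.comb(N, n))
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i))
    return float(acc / total)


class TestEnrichment:
    def test_fully_concentrated_table(self):
        assert enrichment_test(3, 3, 3, 6) == pytest.approx(0.05)

    def test_zero_successes_gives_one(self):
        assert enrichment_test(0, 5, 3, 10) == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        rng = random.Random(3)
        for _ in range(60):
            N = rng.randint(2, 15)
            K = rng.randint(0, N)
            n = rng.randint(0, N)
            k_lo = max(0, n - (N - K))
            k = rng.randint(k_lo, min(K, n))
            assert enrichment_test(k, n, K, N) == pytest.approx(
                _fisher_enumeration_oracle(k, K, n, N), abs=1e-12
            )

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(5, 3, 5, 10)


def _complete_linkage_oracle(dist):
    """Naive O(n^3) complete-linkage agglomeration; returns merge heights."""
    n = dist.shape[0]
    clusters = {i: {i} for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        for i in clusters:
            for j in clusters:
                if i < j:
                    d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                    if best is None or d < best[0]:
                        best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return sorted(heights)


class TestJaccardLinkage:
    def test_simple_distance_values(self):
        mat = pd.DataFrame(
            {"f1": [1, 1], "f2": [0, 0], "f3": [1, 0]}, index=["g1", "g2"]
        ).T
        # profiles 101 and 100 over three genomes... here columns are genomes
        from scipy.spatial.distance import jaccard

        assert jaccard([1, 0, 1], [1, 0, 0]) == pytest.approx(0.5)

    def test_identical_profiles_merge_at_zero(self):
        mat = pd.DataFrame(
            [[1, 0, 1], [1, 0, 1], [0, 1, 0]],
            index=["g1", "g2", "g3"],
            columns=["f1", "f2", "f3"],
        )
        Z, labels = jaccard_linkage(mat, axis="rows")
        assert Z[0, 2] == pytest.approx(0.0)

    def test_all_zero_profiles_have_zero_distance(self):
        mat = pd.DataFrame(
            [[0, 0, 0], [0, 0, 0], [1, 1, 0]],
            index=["g1", "g2", "g3"],
            columns=["f1", "f2", "f3"],
        )
        Z, _ = jaccard_linkage(mat, axis="rows")
        assert Z[0, 2] == pytest.approx(0.0)

    def test_merge_heights_match_naive_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(4, 16))
            mat = pd.DataFrame(
                rng.integers(0, 2, size=(n, 12)),
                index=[f"g{i}" for i in range(n)],
            )
            Z, _ = jaccard_linkage(mat, axis="rows")
            from scipy.spatial.distance import pdist, squareform

            dist = squareform(np.nan_to_num(pdist(mat.values.astype(float),
                                                  metric="jaccard")))
            assert np.allclose(sorted(Z[:, 2]), _complete_linkage_oracle(dist),
                               atol=1e-12)

    def test_matches_scipy_when_distances_are_distinct(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(2)
        data = rng.normal(size=(12, 6))  # continuous: ties have measure zero
        mat = pd.DataFrame(data, index=[f"g{i}" for i in range(12)])
        Z, _ = jaccard_linkage(mat, axis="rows", metric="euclidean")
        ref = linkage(pdist(data), method="complete")
        assert np.allclose(sorted(Z[:, 2]), sorted(ref[:, 2]), atol=1e-10)


class TestMantel:
    @staticmethod
    def _random_distance(n, rng):
        m = rng.uniform(0.1, 1.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return m

    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        a = self._random_distance(6, rng)
        r, p = mantel_test(a, a, n_permutations=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_constant_matrix_rejected(self):
        a = np.ones((4, 4)) - np.eye(4)
        b = self._random_distance(4, np.random.default_rng(1))
        with pytest.raises(ValueError, match="degenerate"):
            mantel_test(b, a)

    def test_asymmetric_input_rejected(self):
        a = self._random_distance(4, np.random.default_rng(2))
        bad = a.copy()
        bad[0, 1] += 1
        with pytest.raises(ValueError):
            mantel_test(a, bad)

    def test_small_case_close_to_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        a = self._random_distance(4, rng)
        b = self._random_distance(4, rng)
        iu = np.triu_indices(4, 1)
        va = a[iu]
        r_obs = np.corrcoef(va, b[iu])[0, 1]
        count = 0
        perms = list(itertools.permutations(range(4)))
        for perm in perms:
            perm = np.array(perm)
            vp = b[perm[iu[0]], perm[iu[1]]]
            if np.corrcoef(va, vp)[0, 1] >= r_obs - 1e-12:
                count += 1
        exact_p = count / len(perms)
        _r, p = mantel_test(a, b, n_permutations=23, seed=3)
        assert abs(p - exact_p) <= 1 / 24 + 1e-9

    def test_agrees_with_scikit_bio_r_statistic(self):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        rng = np.random.default_rng(21)
        a = self._random_distance(8, rng)
        b = self._random_distance(8, rng)
        r_ours, _ = mantel_test(a, b, n_permutations=9, seed=0)
        r_ref, _p, _n = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b), permutations=0
        )
        assert r_ours == pytest.approx(float(r_ref), abs=1e-10)


class TestFamilySummaries:
    def test_single_pair_mean(self):
        hits = [make_hit(q="a", s="b", identity=80.0)]
        out = family_identity_summary(["a", "b"], hits)
        assert out["mean_identity"] == pytest.approx(80.0)
        assert out["n_missing_pairs"] == 0

    def test_three_member_mean_and_missing_pairs(self):
        hits = [
            make_hit(q="a", s="b", identity=60.0),
            make_hit(q="a", s="c", identity=70.0),
            make_hit(q="b", s="c", identity=80.0),
        ]
        out = family_identity_summary(["a", "b", "c"], hits)
        assert out["mean_identity"] == pytest.approx(70.0)
        out2 = family_identity_summary(["a", "b", "c"], hits[:2])
        assert out2["n_missing_pairs"] == 1

    def test_best_hit_per_pair_is_used(self):
        hits = [
            make_hit(q="a", s="b", identity=40.0),
            make_hit(q="b", s="a", identity=55.0),
        ]
        out = family_identity_summary(["a", "b"], hits)
        assert out["mean_identity"] == pytest.approx(55.0)


class TestCogAssignment:
    def test_majority_above_threshold_wins(self):
        members = ["a", "b", "c", "d", "e"]
        ann = {m: "G" for m in members[:4]}
        assert assign_family_cog(members, ann) == "G"

    def test_exact_sixty_percent_is_not_enough(self):
        members = ["a", "b", "c", "d", "e"]
        ann = {"a": "G", "b": "G", "c": "G", "d": "K", "e": "K"}
        assert assign_family_cog(members, ann) == "unknown"

    def test_unannotated_members_dilute(self):
        members = ["a", "b", "c"]
        assert assign_family_cog(members, {"a": "G"}) == "unknown"
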