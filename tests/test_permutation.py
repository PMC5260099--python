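"""The capped, max-over-clusters permutation test and its exact oracle."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from _utils import counts_from_frame, identity_alignment, linear_chain

from mut3d.clustering import build_clusters
from mut3d.mapping import ResidueMutationCounts
from mut3d.permutation import (
    ExactEnumerationError,
    apply_cap,
    exact_pvalue,
    permutation_pvalue,
    sample_decoy,
)
from mut3d.permutation import test_structure as run_chain_test
from mut3d.structure_io import compute_contact_map


def chain_setup(n, spacing=3.8, gene="G1"):
    chain = linear_chain(n, spacing=spacing)
    cmap = compute_contact_map(chain)
    clusters = build_clusters(cmap, set(range(n)), gene=gene)
    return chain, cmap, clusters


def make_counts(counts, n, gene="G1"):
    return ResidueMutationCounts(
        gene=gene, counts=counts, aligned_positions=set(range(1, n + 1))
    )


class TestApplyCap:
    def test_truncates_dominant_count(self):
        assert apply_cap({1: 30, 5: 2, 6: 2, 7: 2}, 2) == {1: 2, 5: 2, 6: 2, 7: 2}

    def test_identity_when_counts_at_or_below_cap(self):
        counts = {1: 2, 3: 1}
        assert apply_cap(counts, 2) == counts
        assert apply_cap(counts, max(counts.values())) == counts

    def test_cap_below_one_rejected(self):
        with pytest.raises(ValueError):
            apply_cap({1: 2}, 0)


class TestSampleDecoy:
    def test_multiset_conserved(self):
        rng = np.random.default_rng(0)
        counts = {2: 3, 5: 1, 6: 1}
        for _ in range(50):
            decoy = sample_decoy(counts, range(1, 11), rng)
            assert Counter(decoy.counts.values()) == Counter(counts.values())
            assert set(decoy.counts) <= set(range(1, 11))

    def test_identical_seed_identical_decoy(self):
        a = sample_decoy({1: 2}, range(1, 5), np.random.default_rng(42))
        b = sample_decoy({1: 2}, range(1, 5), np.random.default_rng(42))
        assert a.counts == b.counts

    def test_placement_is_uniform(self):
        # count 2 on 4 positions: each position should receive it w.p. 1/4
        rng = np.random.default_rng(123)
        n_draws = 10_000
        landings = Counter()
        for _ in range(n_draws):
            decoy = sample_decoy({1: 2}, range(1, 5), rng)
            (pos,) = decoy.counts
            landings[pos] += 1
        observed = [landings[p] for p in range(1, 5)]
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 1e-4

    def test_support_outside_alignment_rejected(self):
        with pytest.raises(ValueError):
            sample_decoy({99: 1}, range(1, 5), np.random.default_rng(0))


class TestExactPvalue:
    def test_window_cluster_on_six_chain(self):
        _, _, clusters = chain_setup(6)
        counts = make_counts({2: 2, 3: 2}, 6)
        cluster = next(c for c in clusters if c.center == 2)  # seq {2,3,4}
        assert exact_pvalue(cluster, counts, clusters) == pytest.approx(9 / 15)

    def test_all_positions_equally_mutated(self):
        _, _, clusters = chain_setup(5)
        counts = make_counts({p: 1 for p in range(1, 6)}, 5)
        cluster = clusters[2]
        assert exact_pvalue(cluster, counts, clusters) == 1.0

    def test_single_mutated_residue(self):
        _, _, clusters = chain_setup(5)
        counts = make_counts({3: 1}, 5)
        for cluster in clusters:
            if any(counts.counts.get(p, 0) for p in cluster.seq_members):
                assert exact_pvalue(cluster, counts, clusters) == 1.0

    def test_refuses_above_combinatorial_bound(self):
        _, _, clusters = chain_setup(8)
        counts = make_counts({1: 1, 2: 2, 3: 3, 4: 4}, 8)
        with pytest.raises(ExactEnumerationError):
            exact_pvalue(clusters[0], counts, clusters, max_placements=10)


class TestPermutationPvalue:
    def test_fully_connected_chain_gives_p_one(self):
        # every cluster contains all residues: any shuffle conserves the
        # total, so the inclusive comparison must fire on every decoy
        chain, cmap, clusters = chain_setup(4, spacing=1.0)
        assert all(c.members == frozenset(range(4)) for c in clusters)
        counts = make_counts({1: 2, 3: 1}, 4)
        r = permutation_pvalue(clusters[0], counts, clusters, n_decoys=500, seed=0)
        assert r.p_value == 1.0

    def test_single_mutated_residue_gives_p_one_everywhere(self):
        _, _, clusters = chain_setup(6)
        counts = make_counts({4: 3}, 6)
        for cluster in clusters:
            if 4 in cluster.seq_members:
                r = permutation_pvalue(cluster, counts, clusters, n_decoys=500, seed=1)
                assert r.p_value == 1.0

    def test_monte_carlo_matches_exact_enumeration(self):
        _, _, clusters = chain_setup(6)
        counts = make_counts({2: 2, 3: 2}, 6)
        cluster = next(c for c in clusters if c.center == 2)
        p_exact = exact_pvalue(cluster, counts, clusters)
        n = 100_000
        r = permutation_pvalue(cluster, counts, clusters, n_decoys=n, seed=7)
        tol = 4 * math.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(r.p_value - p_exact) <= tol
        assert r.observed == 4 and r.cap == 2

    def test_result_bookkeeping(self):
        _, _, clusters = chain_setup(6)
        counts = make_counts({2: 2, 3: 2}, 6)
        cluster = next(c for c in clusters if c.center == 2)
        r = permutation_pvalue(cluster, counts, clusters, n_decoys=1000, seed=3)
        assert r.p_value == r.n_exceed / r.n_decoys
        assert r.member_counts == {2: 2, 3: 2}
        assert not r.below_resolution

    def test_untestable_cluster_rejected(self):
        _, _, clusters = chain_setup(6)
        counts = make_counts({6: 1}, 6)
        empty = next(c for c in clusters if 6 not in c.seq_members)
        with pytest.raises(ValueError):
            permutation_pvalue(empty, counts, clusters, n_decoys=10, seed=0)

    def test_invalid_n_decoys(self):
        _, _, clusters = chain_setup(6)
        counts = make_counts({2: 2}, 6)
        with pytest.raises(ValueError):
            permutation_pvalue(clusters[1], counts, clusters, n_decoys=0, seed=0)

    def test_cap_rule_unmasks_modest_cluster(self):
        # dominant residue (count 30) far from a modest adjacent triple
        _, _, clusters = chain_setup(30)
        counts = make_counts({5: 30, 15: 2, 16: 2, 17: 2}, 30)
        cluster = next(
            c for c in clusters if sorted(c.seq_members) == [15, 16, 17]
        )
        capped = permutation_pvalue(cluster, counts, clusters, n_decoys=20_000, seed=5)
        uncapped = permutation_pvalue(
            cluster, counts, clusters, n_decoys=20_000, seed=5, use_cap=False
        )
        assert capped.p_value <= uncapped.p_value
        assert capped.p_value < 0.05
        assert uncapped.p_value >= 0.05

    def test_oracle_equivalence_on_random_small_fixtures(self):
        rng = np.random.default_rng(2024)
        n_decoys = 20_000
        for _ in range(8):
            n = int(rng.integers(4, 9))
            _, _, clusters = chain_setup(n)
            k = int(rng.integers(1, min(4, n)))
            positions = rng.choice(np.arange(1, n + 1), size=k, replace=False)
            counts = make_counts(
                {int(p): int(rng.integers(1, 4)) for p in positions}, n
            )
            cluster = next(
                c for c in clusters
                if any(counts.counts.get(p, 0) for p in c.seq_members)
            )
            p_exact = exact_pvalue(cluster, counts, clusters)
            r = permutation_pvalue(
                cluster, counts, clusters, n_decoys=n_decoys,
                seed=int(rng.integers(2**31)),
            )
            tol = 4 * math.sqrt(max(p_exact * (1 - p_exact), 1e-9) / n_decoys) + 1e-9
            assert abs(r.p_value - p_exact) <= tol


class TestTestStructure:
    def test_deterministic_with_fixed_seed(self):
        chain, _, _ = chain_setup(10)
        aln = identity_alignment("G1", 10)
        counts = make_counts({3: 2, 4: 1, 8: 1}, 10)
        a = run_chain_test(chain, aln, counts, n_decoys=2000, seed=9)
        b = run_chain_test(chain, aln, counts, n_decoys=2000, seed=9)
        assert [(r.observed, r.n_exceed, r.p_value) for r in a] == [
            (r.observed, r.n_exceed, r.p_value) for r in b
        ]

    def test_no_mutated_residue_gives_empty_list(self):
        chain, _, _ = chain_setup(6)
        counts = make_counts({}, 6)
        assert run_chain_test(chain, identity_alignment("G1", 6), counts) == []

    def test_all_pvalues_finite_under_scattered_null(self):
        chain, _, _ = chain_setup(20)
        counts = make_counts({2: 1, 7: 1, 13: 1, 19: 1}, 20)
        results = run_chain_test(
            chain, identity_alignment("G1", 20), counts, n_decoys=2000, seed=4
        )
        assert results
        for r in results:
            assert 0.0 <= r.p_value <= 1.0 and not math.isnan(r.p_value)

    def test_injected_cluster_beats_background(self):
        # adjacent triple with 2 mutated samples each vs isolated singles
        chain, _, clusters = chain_setup(12)
        counts = make_counts({5: 2, 6: 2, 7: 2, 1: 1, 11: 1}, 12)
        results = run_chain_test(
            chain, identity_alignment("G1", 12), counts, n_decoys=5000, seed=6
        )
        injected = min(
            (r for r in results if {5, 6, 7} <= set(r.cluster.seq_members)),
            key=lambda r: r.p_value,
        )
        background = [
            r for r in results
            if not ({5, 6, 7} & set(r.cluster.seq_members))
        ]
        assert all(injected.p_value < r.p_value for r in background)
        cluster = next(c for c in clusters if sorted(c.seq_members) == [5, 6, 7])
        p_exact = exact_pvalue(cluster, counts, clusters)
        assert abs(injected.p_value - p_exact) <= 4 * math.sqrt(
            p_exact * (1 - p_exact) / 5000
        ) + 1e-9

    def test_clusters_sharing_cap_share_decoy_stream(self):
        chain, _, _ = chain_setup(10)
        counts = make_counts({2: 1, 8: 1}, 10)
        results = run_chain_test(
            chain, identity_alignment("G1", 10), counts, n_decoys=2000, seed=11
        )
        same_obs = [r for r in results if r.observed == 1 and r.cap == 1]
        assert len({r.n_exceed for r in same_obs}) == 1
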