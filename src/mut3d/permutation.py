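"""Permutation test for significantly mutated 3D clusters.

The null model shuffles the observed per-residue mutated-sample counts
uniformly over the aligned region of the structure chain (a random
bijection of the count multiset onto the aligned positions).  For a
cluster with observed score s, the p-value is the fraction of decoy
patterns in which *any* cluster of the chain scores >= s — a max
statistic, family-wise over the clusters of one chain.

Before shuffling, counts are truncated to the largest count found
inside the assessed cluster (the cap rule).  A dominant single-residue
hotspot elsewhere in the gene would otherwise land in some cluster of
nearly every decoy and mask modest clusters; capping removes its
excess recurrence while leaving the assessed cluster's own counts
unchanged.  The observed score itself is computed on uncapped counts,
which is self-consistent because the cap equals the assessed cluster's
maximum member count.

An exact-enumeration oracle over all distinct placements of the count
multiset is provided for small problems; the Monte Carlo estimate must
agree with it within binomial error.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .clustering import Cluster, cluster_score
from .mapping import ResidueMutationCounts, SequenceStructureAlignment
from .structure_io import DEFAULT_CONTACT_CUTOFF, StructureChain, compute_contact_map

DEFAULT_N_DECOYS = 100_000
DEFAULT_MAX_PLACEMENTS = 1_000_000

_DECOY_CHUNK = 20_000  # decoys per vectorized block; memory/speed trade-off


class ExactEnumerationError(ValueError):
    """Raised when the number of distinct placements exceeds the bound."""


@dataclass(frozen=True)
class DecoyPattern:
    """One shuffled mutational pattern: capped counts reassigned to
    aligned positions; the count multiset is conserved."""

    counts: Mapping[int, int]
    provenance: str = ""


@dataclass
class ClusterTestResult:
    """Outcome of the permutation test for one cluster."""

    cluster: Cluster
    observed: int
    cap: int
    n_decoys: int
    n_exceed: int
    p_value: float
    below_resolution: bool = False  # no decoy reached the observed score
    seed: int | None = None
    member_counts: dict[int, int] | None = None  # seq position -> samples

    def __post_init__(self) -> None:
        if not (0 <= self.n_exceed <= self.n_decoys):
            raise ValueError("n_exceed must lie in [0, n_decoys]")


def apply_cap(counts: Mapping[int, int], cap: int) -> dict[int, int]:
    """Truncate every per-residue count above ``cap`` down to ``cap``."""
    if cap < 1:
        raise ValueError("cap must be >= 1 (a testable cluster has a mutation)")
    return {pos: min(n, cap) for pos, n in counts.items()}


def sample_decoy(
    capped_counts: Mapping[int, int],
    aligned_positions: Iterable[int],
    rng: np.random.Generator,
) -> DecoyPattern:
    """Draw one decoy: a uniformly random bijection of the count
    multiset (zeros included) onto the aligned positions."""
    positions = sorted(aligned_positions)
    support = set(capped_counts)
    if not support <= set(positions):
        raise ValueError("counts present outside the aligned region")
    values = np.array([capped_counts.get(p, 0) for p in positions], dtype=np.int64)
    shuffled = rng.permutation(values)
    return DecoyPattern(
        counts={p: int(v) for p, v in zip(positions, shuffled) if v > 0},
        provenance=type(rng.bit_generator).__name__,
    )


def _membership_matrix(
    clusters: Sequence[Cluster], positions: Sequence[int]
) -> np.ndarray:
    """Boolean (n_clusters x n_positions) matrix of seq-position membership."""
    index = {p: i for i, p in enumerate(positions)}
    mat = np.zeros((len(clusters), len(positions)), dtype=np.int64)
    for ci, cl in enumerate(clusters):
        for pos in cl.seq_members:
            mat[ci, index[pos]] = 1
    return mat


def _decoy_max_scores(
    values: np.ndarray,
    membership: np.ndarray,
    n_decoys: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Max cluster score of each decoy; vectorized in blocks."""
    maxes = np.empty(n_decoys, dtype=np.int64)
    done = 0
    mt = membership.T
    while done < n_decoys:
        m = min(_DECOY_CHUNK, n_decoys - done)
        block = np.tile(values, (m, 1))
        block = rng.permuted(block, axis=1)
        maxes[done : done + m] = (block @ mt).max(axis=1)
        done += m
    return maxes


def _observed_and_cap(
    cluster: Cluster, counts: ResidueMutationCounts
) -> tuple[int, int, dict[int, int]]:
    member_counts = {
        p: counts.counts.get(p, 0) for p in cluster.seq_members
    }
    observed = sum(member_counts.values())
    cap = max(member_counts.values(), default=0)
    return observed, cap, {p: n for p, n in member_counts.items() if n > 0}


def permutation_pvalue(
    cluster: Cluster,
    counts: ResidueMutationCounts,
    all_clusters: Sequence[Cluster],
    n_decoys: int = DEFAULT_N_DECOYS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    use_cap: bool = True,
) -> ClusterTestResult:
    """Monte Carlo p-value of one cluster under the shuffle null.

    ``use_cap=False`` disables the cap rule (for diagnostics only); the
    default reproduces the method's definition.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    observed, cap, member_counts = _observed_and_cap(cluster, counts)
    if observed < 1:
        raise ValueError("cluster has no observed mutation; not testable")
    if rng is None:
        rng = np.random.default_rng(seed)

    positions = sorted(counts.aligned_positions)
    aligned = counts.aligned_counts()
    working = apply_cap(aligned, cap) if use_cap else dict(aligned)
    values = np.array([working.get(p, 0) for p in positions], dtype=np.int64)
    membership = _membership_matrix(list(all_clusters), positions)

    maxes = _decoy_max_scores(values, membership, n_decoys, rng)
    n_exceed = int((maxes >= observed).sum())
    return ClusterTestResult(
        cluster=cluster,
        observed=observed,
        cap=cap,
        n_decoys=n_decoys,
        n_exceed=n_exceed,
        p_value=n_exceed / n_decoys,
        below_resolution=(n_exceed == 0),
        seed=seed,
        member_counts=member_counts,
    )


def _n_distinct_placements(values: Sequence[int]) -> int:
    n = math.factorial(len(values))
    for v in set(values):
        n //= math.factorial(list(values).count(v))
    return n


def exact_pvalue(
    cluster: Cluster,
    counts: ResidueMutationCounts,
    all_clusters: Sequence[Cluster],
    max_placements: int = DEFAULT_MAX_PLACEMENTS,
    use_cap: bool = True,
) -> float:
    """Exact null exceedance probability by multiset enumeration.

    Enumerates every distinct placement of the capped count multiset on
    the aligned positions and returns the fraction in which some
    cluster scores >= the assessed cluster's observed score.  Refuses
    (raises :class:`ExactEnumerationError`) if the number of distinct
    placements exceeds ``max_placements``; callers then fall back to
    Monte Carlo.
    """
    observed, cap, _ = _observed_and_cap(cluster, counts)
    if observed < 1:
        raise ValueError("cluster has no observed mutation; not testable")
    positions = sorted(counts.aligned_positions)
    aligned = counts.aligned_counts()
    working = apply_cap(aligned, cap) if use_cap else dict(aligned)
    values = [working.get(p, 0) for p in positions]

    n_place = _n_distinct_placements(values)
    if n_place > max_placements:
        raise ExactEnumerationError(
            f"{n_place} distinct placements exceed the bound {max_placements}"
        )
    membership = _membership_matrix(list(all_clusters), positions)
    n_exceed = 0
    for placement in multiset_permutations(values):
        scores = membership @ np.asarray(placement, dtype=np.int64)
        if scores.max() >= observed:
            n_exceed += 1
    return n_exceed / n_place


def _gene_hash(gene: str) -> int:
    return zlib.crc32(gene.encode("utf-8")) & 0x7FFFFFFF


def decoy_rng(seed: int, gene: str, cap: int) -> np.random.Generator:
    """Decoy stream keyed by (seed, gene, cap) so that results do not
    depend on the order in which genes or clusters are processed."""
    ss = np.random.SeedSequence(seed, spawn_key=(_gene_hash(gene), cap))
    return np.random.default_rng(ss)


def test_structure(
    chain: StructureChain,
    alignment: SequenceStructureAlignment,
    counts: ResidueMutationCounts,
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int = 0,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[ClusterTestResult]:
    """Test every mutated cluster of one structure chain.

    Builds the contact map and the per-residue clusters over the
    aligned region, then runs the permutation test for each cluster
    with at least one observed mutation.  Clusters sharing a cap value
    share one decoy stream (the capped null is identical for them);
    distinct caps get independent streams keyed by (seed, gene, cap).
    """
    from .clustering import build_clusters  # local to avoid cycle at import

    cmap = compute_contact_map(chain, cutoff=cutoff)
    ordinal_to_seq = {
        o: p for o, p in alignment.ordinal_to_seq.items() if o < len(chain)
    }
    aligned_ordinals = set(ordinal_to_seq)
    if not aligned_ordinals:
        return []
    # restrict the shuffle domain to positions actually on this chain
    counts = ResidueMutationCounts(
        gene=counts.gene,
        counts=dict(counts.counts),
        aligned_positions=set(ordinal_to_seq.values()),
    )
    clusters = build_clusters(
        cmap, aligned_ordinals, ordinal_to_seq, gene=alignment.gene
    )

    testable: list[tuple[Cluster, int, int, dict[int, int]]] = []
    for cl in clusters:
        observed, cap, member_counts = _observed_and_cap(cl, counts)
        if observed >= 1:
            testable.append((cl, observed, cap, member_counts))
    if not testable:
        return []

    positions = sorted(counts.aligned_positions)
    aligned_counts = counts.aligned_counts()
    membership = _membership_matrix(clusters, positions)

    maxes_by_cap: dict[int, np.ndarray] = {}
    for cap in sorted({cap for _, _, cap, _ in testable}):
        values = np.array(
            [apply_cap(aligned_counts, cap).get(p, 0) for p in positions],
            dtype=np.int64,
        )
        rng = decoy_rng(seed, alignment.gene, cap)
        maxes_by_cap[cap] = _decoy_max_scores(values, membership, n_decoys, rng)

    results = []
    for cl, observed, cap, member_counts in testable:
        n_exceed = int((maxes_by_cap[cap] >= observed).sum())
        results.append(
            ClusterTestResult(
                cluster=cl,
                observed=observed,
                cap=cap,
                n_decoys=n_decoys,
                n_exceed=n_exceed,
                p_value=n_exceed / n_decoys,
                below_resolution=(n_exceed == 0),
                seed=seed,
                member_counts=member_counts,
            )
        )
    results.sort(key=lambda r: r.cluster.center)
    return results
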