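"""Construction, scoring, and deduplication of 3D residue clusters.

Every aligned residue of a chain defines one cluster: itself (the
center) plus its contact neighbors restricted to the aligned region.
Clusters are never merged, so a residue generally belongs to several
clusters.  Clusters from different structures with the same set of
sequence positions are counted as one unique cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .mapping import ResidueMutationCounts
from .structure_io import ContactMap


@dataclass(frozen=True)
class Cluster:
    """A central residue and its aligned contact neighbors on one chain.

    ``members`` are 0-based chain ordinals; ``seq_members`` the
    corresponding 1-based sequence positions under the alignment.
    """

    gene: str
    structure_id: str
    chain_id: str
    center: int
    members: frozenset
    seq_members: frozenset

    def __post_init__(self) -> None:
        if self.center not in self.members:
            raise ValueError("cluster center must be a member")
        if len(self.members) != len(self.seq_members):
            raise ValueError("members and seq_members must correspond one-to-one")


@dataclass
class UniqueCluster:
    """A deduplicated cluster: one (gene, sequence-residue-set) key with
    the provenance of every structure chain that produced it."""

    gene: str
    seq_members: frozenset
    provenance: list[tuple[str, str]] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, frozenset]:
        return (self.gene, self.seq_members)


def build_clusters(
    cmap: ContactMap,
    aligned: set[int],
    ordinal_to_seq: Mapping[int, int] | None = None,
    gene: str = "",
) -> list[Cluster]:
    """Build one cluster per aligned residue of a contact map.

    Neighbors falling outside the aligned region are excluded: the
    permutation null shuffles counts only over aligned positions, so
    unshuffleable residues must not contribute to cluster scores.

    Parameters
    ----------
    cmap
        Residue contact map of the chain.
    aligned
        0-based chain ordinals covered by the sequence alignment.
    ordinal_to_seq
        Maps chain ordinal -> 1-based sequence position.  Defaults to
        the identity mapping ordinal i -> position i + 1.
    """
    if not aligned:
        raise ValueError("aligned residue set is empty")
    bad = [i for i in aligned if not (0 <= i < cmap.n_residues)]
    if bad:
        raise IndexError(f"aligned ordinals out of range: {sorted(bad)}")
    if ordinal_to_seq is None:
        ordinal_to_seq = {i: i + 1 for i in aligned}

    clusters = []
    for center in sorted(aligned):
        members = (cmap.neighbors(center) & aligned) | {center}
        clusters.append(
            Cluster(
                gene=gene,
                structure_id=cmap.structure_id,
                chain_id=cmap.chain_id,
                center=center,
                members=frozenset(members),
                seq_members=frozenset(ordinal_to_seq[m] for m in members),
            )
        )
    return clusters


def cluster_score(cluster: Cluster, counts: ResidueMutationCounts) -> int:
    """Total mutated-sample count over the cluster's residues."""
    return sum(counts.counts.get(pos, 0) for pos in cluster.seq_members)


def dedupe_unique_clusters(
    clusters: Iterable[Cluster | UniqueCluster],
) -> list[UniqueCluster]:
    """Collapse clusters with identical (gene, sequence members) keys.

    Provenance lists of all contributing structure chains are merged
    and sorted; the operation is idempotent.
    """
    by_key: dict[tuple[str, frozenset], UniqueCluster] = {}
    for c in clusters:
        if isinstance(c, UniqueCluster):
            key, prov = c.key, list(c.provenance)
        else:
            key, prov = (c.gene, c.seq_members), [(c.structure_id, c.chain_id)]
        uc = by_key.get(key)
        if uc is None:
            uc = UniqueCluster(gene=key[0], seq_members=key[1])
            by_key[key] = uc
        uc.provenance.extend(prov)
    out = []
    for key in sorted(by_key, key=lambda k: (k[0], sorted(k[1]))):
        uc = by_key[key]
        uc.provenance = sorted(set(uc.provenance))
        out.append(uc)
    return out
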