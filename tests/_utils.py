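"""Shared helpers for the test suite: in-memory chains and count tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from mut3d.mapping import ResidueMutationCounts
from mut3d.structure_io import Atom, Residue, StructureChain


def chain_from_coords(
    coords, structure_id: str = "SYN", chain_id: str = "A"
) -> StructureChain:
    """Build a CA-only chain directly from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    residues = [
        Residue(
            chain_id=chain_id,
            auth_number=i + 1,
            insertion_code="",
            name="ALA",
            atoms=[Atom(name="CA", coords=xyz)],
        )
        for i, xyz in enumerate(coords)
    ]
    return StructureChain(structure_id=structure_id, chain_id=chain_id, residues=residues)


def linear_chain(n: int, spacing: float = 3.8) -> StructureChain:
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    return chain_from_coords(coords)


def brute_force_edges(chain: StructureChain, cutoff: float) -> set[tuple[int, int]]:
    """Exhaustive all-atom-pair contact computation (test oracle)."""
    edges = set()
    for i, ri in enumerate(chain.residues):
        for j in range(i + 1, len(chain.residues)):
            rj = chain.residues[j]
            dmin = min(
                float(np.linalg.norm(a.coords - b.coords))
                for a in ri.atoms
                for b in rj.atoms
            )
            if dmin <= cutoff:
                edges.add((i, j))
    return edges


def counts_from_frame(df: pd.DataFrame, gene: str, n_positions: int) -> ResidueMutationCounts:
    """Per-residue distinct-sample counts from a fixture mutation table."""
    by_pos: dict[int, set[str]] = {}
    for row in df.itertuples(index=False):
        if row.gene == gene and row.variant_class == "missense":
            by_pos.setdefault(int(row.protein_position), set()).add(row.sample_id)
    return ResidueMutationCounts(
        gene=gene,
        counts={p: len(s) for p, s in by_pos.items()},
        aligned_positions=set(range(1, n_positions + 1)),
    )


def identity_alignment(gene: str, n: int, structure_id: str = "SYN1", chain_id: str = "A"):
    from mut3d.mapping import SequenceStructureAlignment

    return SequenceStructureAlignment(
        gene=gene,
        structure_id=structure_id,
        chain_id=chain_id,
        identity=1.0,
        pairs=[(i + 1, i) for i in range(n)],
    )
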