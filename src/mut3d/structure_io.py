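"""Reading protein structures and computing residue contact maps.

A residue contact map is the adjacency relation underlying 3D cluster
construction: two residues of a chain are in contact when any pair of
their atoms lies within a distance cutoff (default 5.0 angstroms,
inclusive).  Contacts are computed per chain; inter-chain contacts are
out of scope.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 5.0  # angstroms, any-atom, inclusive


class PdbFormatError(ValueError):
    """Raised when a PDB input cannot be parsed into any polypeptide chain."""


@dataclass(frozen=True)
class Atom:
    """A single atom: name, Cartesian coordinates in angstroms, altloc tag."""

    name: str
    coords: np.ndarray
    altloc: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name!r}: coords must be 3 finite numbers")
        object.__setattr__(self, "coords", c)


@dataclass
class Residue:
    """An amino-acid residue with author numbering and its atoms."""

    chain_id: str
    auth_number: int
    insertion_code: str
    name: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("residue must have at least one atom")

    @property
    def auth_label(self) -> str:
        """Author residue number with insertion code, e.g. ``'100A'``."""
        return f"{self.auth_number}{self.insertion_code}".strip()


@dataclass
class StructureChain:
    """One polypeptide chain of a structure; residues in file order.

    Contact-map and cluster indices are 0-based ordinal positions along
    ``residues``; author numbering is kept only for I/O.
    """

    structure_id: str
    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        keys = [(r.auth_number, r.insertion_code) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(
                f"chain {self.chain_id}: duplicate (auth_number, insertion_code)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ContactMap:
    """Symmetric, irreflexive residue adjacency at an any-atom cutoff.

    ``edges`` stores unordered pairs as (i, j) with i < j, in 0-based
    residue ordinals of the source chain.
    """

    structure_id: str
    chain_id: str
    n_residues: int
    cutoff: float
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("contact map must be irreflexive")
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues):
                raise ValueError("edge index out of range")

    def neighbors(self, residue_index: int) -> set[int]:
        """All residues in contact with ``residue_index`` (never itself)."""
        if not (0 <= residue_index < self.n_residues):
            raise IndexError(
                f"residue index {residue_index} out of range [0, {self.n_residues})"
            )
        out: set[int] = set()
        for i, j in self.edges:
            if i == residue_index:
                out.add(j)
            elif j == residue_index:
                out.add(i)
        return out


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Residue | None:
    # altloc policy: first-listed conformer per atom name, deterministically
    atoms: list[Atom] = []
    seen: set[str] = set()
    for a in res:
        if a.name in seen:
            continue
        seen.add(a.name)
        altloc = a.altloc if a.altloc not in ("\0", "") else ""
        atoms.append(
            Atom(name=a.name, coords=np.array([a.pos.x, a.pos.y, a.pos.z]), altloc=altloc)
        )
    if not atoms:
        return None
    icode = res.seqid.icode.strip()
    return Residue(
        chain_id=chain_id,
        auth_number=res.seqid.num,
        insertion_code=icode,
        name=res.name,
        atoms=atoms,
    )


def read_pdb(source: str | Path) -> list[StructureChain]:
    """Parse PDB text or a PDB file into polypeptide chains.

    Only the first MODEL is used.  Waters and non-amino-acid
    heteroatoms are dropped; a chain left without amino-acid residues is
    omitted with a warning.  For alternate locations only the
    first-listed conformer of each atom is kept.

    Parameters
    ----------
    source
        Path to a PDB file, or the PDB text itself (detected by the
        presence of a newline).

    Raises
    ------
    PdbFormatError
        If the input yields no chain with at least one amino-acid atom.
    """
    text_input = isinstance(source, str) and "\n" in source
    try:
        if text_input:
            st = gemmi.read_pdb_string(source)
        else:
            if not os.path.exists(source):
                raise PdbFormatError(f"no such file: {source}")
            st = gemmi.read_pdb(str(source))
    except PdbFormatError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError variants
        raise PdbFormatError(f"cannot parse PDB input: {exc}") from exc

    if len(st) == 0:
        raise PdbFormatError("PDB input contains no model/ATOM records")
    structure_id = st.name.strip() or "UNKNOWN"
    model = st[0]

    chains: list[StructureChain] = []
    for ch in model:
        residues = []
        for res in ch:
            if not _is_amino_acid(res.name):
                continue
            conv = _convert_residue(ch.name, res)
            if conv is not None:
                residues.append(conv)
        if not residues:
            logger.warning(
                "structure %s chain %s has no amino-acid residues; omitted",
                structure_id,
                ch.name,
            )
            continue
        chains.append(
            StructureChain(structure_id=structure_id, chain_id=ch.name, residues=residues)
        )
    if not chains:
        raise PdbFormatError("PDB input contains no polypeptide chain")
    return chains


def compute_contact_map(
    chain: StructureChain, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> ContactMap:
    """Compute the any-atom residue contact map of one chain.

    Residues i != j are in contact iff the minimum over their atom
    pairs of the Euclidean distance is <= ``cutoff`` (inclusive).
    """
    if len(chain) == 0:
        raise ValueError("chain is empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    coords = []
    owner = []
    for idx, res in enumerate(chain.residues):
        for atom in res.atoms:
            coords.append(atom.coords)
            owner.append(idx)
    pts = np.asarray(coords)
    owner_arr = np.asarray(owner)

    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")  # distance <= cutoff
    edges: set[tuple[int, int]] = set()
    if len(pairs):
        ri = owner_arr[pairs[:, 0]]
        rj = owner_arr[pairs[:, 1]]
        mask = ri != rj
        lo = np.minimum(ri[mask], rj[mask])
        hi = np.maximum(ri[mask], rj[mask])
        edges = {(int(a), int(b)) for a, b in zip(lo, hi)}
    return ContactMap(
        structure_id=chain.structure_id,
        chain_id=chain.chain_id,
        n_residues=len(chain),
        cutoff=float(cutoff),
        edges=frozenset(edges),
    )


def neighbors(cmap: ContactMap, residue_index: int) -> set[int]:
    """Module-level convenience wrapper for :meth:`ContactMap.neighbors`."""
    return cmap.neighbors(residue_index)
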