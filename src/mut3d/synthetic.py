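"""Synthetic structures, alignments, and mutation tables with known truth.

Fixtures are CA-only traces (a linear chain at fixed spacing or an
ideal alpha-helix); the any-atom contact rule makes a single atom per
residue sufficient for exercising every pipeline stage, at the cost of
side-chain realism.  Mutation tables place injected cluster mutations
in distinct samples and scatter background mutations uniformly, so the
ground truth of every fixture is known exactly.

Helix constants are fixed: rise 1.5 A/residue, 100 degrees/residue,
radius 2.3 A.  They give the familiar i+/-3, i+/-4 contact pattern at
the 5 A cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .structure_io import StructureChain, read_pdb

HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # A

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
# one-letter -> three-letter, for writing CA records with plausible names
AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic test case."""

    n_residues: int
    geometry: str = "linear"  # linear | helix | custom
    spacing: float = 3.8  # A between consecutive CA atoms (linear)
    coords: np.ndarray | None = None  # (n, 3), geometry == "custom"
    injected: list[tuple[tuple[int, ...], int]] = field(default_factory=list)
    background: int = 0  # number of background missense events
    seed: int = 0
    gene: str = "GENE1"
    structure_id: str = "SYN1"
    chain_id: str = "A"
    cancer_type: str = "SYNTH"

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        for positions, count in self.injected:
            if count < 1:
                raise ValueError("injected counts must be >= 1")
            for p in positions:
                if not (1 <= p <= self.n_residues):
                    raise ValueError(f"injected position {p} outside [1, n_residues]")

    @property
    def injected_positions(self) -> set[int]:
        return {p for positions, _ in self.injected for p in positions}


def ref_aa_at(position: int) -> str:
    """Deterministic reference amino acid of a fixture position."""
    return AA_ORDER[(position - 1) % len(AA_ORDER)]


def _alt_aa_at(position: int) -> str:
    return AA_ORDER[position % len(AA_ORDER)]


def fixture_coordinates(spec: FixtureSpec) -> np.ndarray:
    """CA coordinates of the fixture, shape (n_residues, 3)."""
    n = spec.n_residues
    if spec.geometry == "linear":
        coords = np.zeros((n, 3))
        coords[:, 0] = spec.spacing * np.arange(n)
        return coords
    if spec.geometry == "helix":
        i = np.arange(n)
        theta = np.deg2rad(HELIX_TWIST) * i
        return np.column_stack(
            [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
        )
    if spec.geometry == "custom":
        coords = np.asarray(spec.coords, dtype=float)
        if coords.shape != (n, 3):
            raise ValueError("custom geometry requires coords of shape (n_residues, 3)")
        return coords
    raise ValueError(f"unknown geometry {spec.geometry!r}")


def write_fixture_pdb(spec: FixtureSpec, path: str | Path) -> Path:
    """Write the fixture as a CA-only PDB file readable by read_pdb."""
    coords = fixture_coordinates(spec)
    st = gemmi.Structure()
    st.name = spec.structure_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(spec.chain_id)
    for i, xyz in enumerate(coords):
        res = gemmi.Residue()
        res.name = AA3[ref_aa_at(i + 1)]
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path))
    return path


def make_structure(spec: FixtureSpec, path: str | Path) -> StructureChain:
    """Write the fixture PDB and return the re-parsed chain (round-trip)."""
    write_fixture_pdb(spec, path)
    chains = read_pdb(Path(path))
    return chains[0]


def identity_alignment_frame(spec: FixtureSpec) -> pd.DataFrame:
    """Trivial alignment: sequence position i <-> chain ordinal i-1, identity 1."""
    return pd.DataFrame(
        {
            "gene": spec.gene,
            "structure_id": spec.structure_id,
            "chain_id": spec.chain_id,
            "identity": 1.0,
            "seq_pos": np.arange(1, spec.n_residues + 1),
            "chain_ordinal": np.arange(spec.n_residues),
        }
    )


def mutation_frame(
    spec: FixtureSpec, n_samples: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate the fixture's mutation table as a DataFrame.

    Injected positions receive `count` missense records each, every
    record in a distinct sample; `spec.background` events are then
    placed uniformly at random (with replacement) over the remaining
    positions, also in distinct samples, so per-residue counts equal
    event counts.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_injected = sum(len(positions) * count for positions, count in spec.injected)
    total = n_injected + spec.background
    if total > n_samples:
        raise ValueError(
            f"{total} mutation records need {total} distinct samples; "
            f"only {n_samples} available"
        )

    rows = []
    sample_no = 0
    for positions, count in spec.injected:
        for p in positions:
            for _ in range(count):
                sample_no += 1
                rows.append((f"S{sample_no:04d}", p))
    remaining = sorted(set(range(1, spec.n_residues + 1)) - spec.injected_positions)
    if spec.background:
        if not remaining:
            raise ValueError("no positions left for background mutations")
        for p in rng.choice(remaining, size=spec.background, replace=True):
            sample_no += 1
            rows.append((f"S{sample_no:04d}", int(p)))

    return pd.DataFrame(
        {
            "sample_id": [s for s, _ in rows],
            "gene": spec.gene,
            "protein_position": [p for _, p in rows],
            "ref_aa": [ref_aa_at(p) for _, p in rows],
            "alt_aa": [_alt_aa_at(p) for _, p in rows],
            "variant_class": "missense",
            "cancer_type": spec.cancer_type,
        }
    )


def make_mutations(
    spec: FixtureSpec,
    n_samples: int,
    mutations_path: str | Path,
    alignment_path: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[Path, Path]:
    """Write the fixture's mutation TSV and identity alignment TSV."""
    mut = mutation_frame(spec, n_samples, rng=rng)
    aln = identity_alignment_frame(spec)
    mutations_path = Path(mutations_path)
    alignment_path = Path(alignment_path)
    mutations_path.parent.mkdir(parents=True, exist_ok=True)
    alignment_path.parent.mkdir(parents=True, exist_ok=True)
    mut.to_csv(mutations_path, sep="\t", index=False)
    aln.to_csv(alignment_path, sep="\t", index=False)
    return mutations_path, alignment_path


def null_batch(
    spec: FixtureSpec, n_replicates: int, rng: np.random.Generator
) -> list[pd.DataFrame]:
    """Independent uniform background placements for calibration runs.

    Requires a spec without injected clusters; each replicate is an
    independent uniform placement of ``spec.background`` events.
    """
    if spec.injected:
        raise ValueError("null_batch requires a spec without injected clusters")
    n_samples = spec.background
    return [
        mutation_frame(spec, n_samples, rng=rng) for _ in range(n_replicates)
    ]
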