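"""Mutation tables, sequence-to-structure alignments, and cohort filters.

Inputs are protein-level somatic mutation calls (MAF-like TSV), residue
level alignments between canonical protein sequences and structure
chains, optional germline-variant blacklists, and an optional gene x
sample TPM expression matrix.  The module's output is the per-residue
count of mutated tumor samples on the aligned region of a chain — the
object that the permutation null shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Iterable, Mapping, Sequence

import pandas as pd

MIN_ALIGNMENT_IDENTITY = 0.90
LOW_EXPRESSION_TPM = 0.1
LOW_EXPRESSION_TYPE_FRACTION = 0.90  # >= : covered cancer types
LOW_EXPRESSION_GLOBAL_FRACTION = 0.95  # > : fallback over all tumors

#: accepted values for the ``variant_class`` column (case-insensitive)
VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "silent", "splice", "frameshift", "inframe", "other"}
)

MUTATION_COLUMNS = (
    "sample_id",
    "gene",
    "protein_position",
    "ref_aa",
    "alt_aa",
    "variant_class",
    "cancer_type",
)

ALIGNMENT_COLUMNS = (
    "gene",
    "structure_id",
    "chain_id",
    "identity",
    "seq_pos",
    "chain_ordinal",
)


class MutationTableError(ValueError):
    """Schema or row-level error in a mutation table."""


class AlignmentError(ValueError):
    """Malformed sequence-to-structure alignment."""


@dataclass(frozen=True)
class MutationRecord:
    """One protein-level somatic mutation call in one tumor sample."""

    sample_id: str
    gene: str
    protein_position: int
    ref_aa: str
    alt_aa: str
    variant_class: str
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise ValueError("protein_position must be >= 1")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        """Identity used for blacklist matching: (gene, pos, ref, alt)."""
        return (self.gene, self.protein_position, self.ref_aa, self.alt_aa)


@dataclass
class SequenceStructureAlignment:
    """One-to-one residue mapping between a canonical protein sequence
    and a structure chain.

    ``pairs`` maps 1-based sequence positions to 0-based residue
    ordinals along the parsed chain.
    """

    gene: str
    structure_id: str
    chain_id: str
    identity: float
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise AlignmentError("identity must lie in [0, 1]")
        seq = [p for p, _ in self.pairs]
        ords = [o for _, o in self.pairs]
        if len(set(seq)) != len(seq) or len(set(ords)) != len(ords):
            raise AlignmentError(
                f"{self.gene}/{self.structure_id}:{self.chain_id}: "
                "alignment pairs must be one-to-one in both coordinates"
            )

    @property
    def seq_to_ordinal(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def ordinal_to_seq(self) -> dict[int, int]:
        return {o: p for p, o in self.pairs}

    @property
    def seq_positions(self) -> set[int]:
        return {p for p, _ in self.pairs}

    @property
    def ordinals(self) -> set[int]:
        return {o for _, o in self.pairs}


@dataclass
class ResidueMutationCounts:
    """Number of distinct mutated samples per sequence position of a gene.

    ``counts`` covers every position with at least one missense sample,
    aligned or not; ``aligned_positions`` is the alignment's coverage and
    defines the shuffle domain of the permutation null.
    """

    gene: str
    counts: dict[int, int] = field(default_factory=dict)
    aligned_positions: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pos, n in self.counts.items():
            if n < 1:
                raise ValueError(f"count at position {pos} must be >= 1")

    def aligned_counts(self) -> dict[int, int]:
        """Counts restricted to the aligned region."""
        return {p: n for p, n in self.counts.items() if p in self.aligned_positions}

    def total(self) -> int:
        return sum(self.counts.values())


def load_mutations(source: str | Path) -> list[MutationRecord]:
    """Read a MAF-like tab-separated mutation table.

    Required columns: sample_id, gene, protein_position, ref_aa, alt_aa,
    variant_class, cancer_type.  Rows with a non-integer position (e.g.
    indel ranges like ``12_13``) or an unknown variant class are
    rejected with a row-numbered error.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise MutationTableError(f"missing required column(s): {', '.join(missing)}")

    records: list[MutationRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        raw_pos = str(row.protein_position).strip()
        try:
            if not raw_pos.isdigit():  # rejects ranges like "12_13" and signs
                raise ValueError
            pos = int(raw_pos)
        except ValueError:
            raise MutationTableError(
                f"row {row_no}: protein_position {raw_pos!r} is not an integer "
                "(indels/ranges are unsupported)"
            ) from None
        vclass = str(row.variant_class).strip().lower()
        if vclass not in VARIANT_CLASSES:
            raise MutationTableError(
                f"row {row_no}: unknown variant_class {row.variant_class!r}"
            )
        try:
            records.append(
                MutationRecord(
                    sample_id=str(row.sample_id),
                    gene=str(row.gene),
                    protein_position=pos,
                    ref_aa=str(row.ref_aa),
                    alt_aa=str(row.alt_aa),
                    variant_class=vclass,
                    cancer_type=str(row.cancer_type),
                )
            )
        except ValueError as exc:
            raise MutationTableError(f"row {row_no}: {exc}") from None
    return records


def load_alignments(source: str | Path) -> list[SequenceStructureAlignment]:
    """Read residue alignments from TSV (one row per aligned residue pair)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise AlignmentError(f"missing required column(s): {', '.join(missing)}")
    out: list[SequenceStructureAlignment] = []
    for (gene, sid, cid, ident), grp in df.groupby(
        ["gene", "structure_id", "chain_id", "identity"], sort=True
    ):
        pairs = sorted(
            (int(r.seq_pos), int(r.chain_ordinal)) for r in grp.itertuples(index=False)
        )
        out.append(
            SequenceStructureAlignment(
                gene=gene,
                structure_id=sid,
                chain_id=cid,
                identity=float(ident),
                pairs=pairs,
            )
        )
    return out


def filter_alignments(
    alignments: Iterable[SequenceStructureAlignment],
    min_identity: float = MIN_ALIGNMENT_IDENTITY,
) -> list[SequenceStructureAlignment]:
    """Keep alignments whose sequence identity is >= ``min_identity``."""
    return [a for a in alignments if a.identity >= min_identity]


def load_blacklist(source: str | Path) -> dict[tuple[str, int, str, str], int]:
    """Read a germline-variant blacklist TSV.

    Columns: gene, position, ref, alt, n_samples.  Returns the mapping
    variant key -> number of carrier samples in the population panel.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    required = ("gene", "position", "ref", "alt", "n_samples")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MutationTableError(f"blacklist missing column(s): {', '.join(missing)}")
    return {
        (r.gene, int(r.position), r.ref, r.alt): int(r.n_samples)
        for r in df.itertuples(index=False)
    }


def filter_germline(
    mutations: Iterable[MutationRecord],
    thousand_genomes: Mapping[tuple[str, int, str, str], int],
    esp: Collection[tuple[str, int, str, str]],
) -> list[MutationRecord]:
    """Remove likely germline variants misreported as somatic.

    A mutation is dropped when its variant key is present in both the
    1000 Genomes panel and the ESP panel, or when it is present in the
    1000 Genomes panel in two or more samples.
    """
    esp_keys = set(esp)
    kept = []
    for m in mutations:
        k = m.variant_key
        in_1kg = k in thousand_genomes
        if in_1kg and k in esp_keys:
            continue
        if in_1kg and thousand_genomes[k] >= 2:
            continue
        kept.append(m)
    return kept


def low_expression_genes(
    expression: pd.DataFrame,
    sample_types: Mapping[str, str],
    covered_types: Collection[str] | None = None,
) -> tuple[dict[str, set[str]], set[str], set[str]]:
    """Identify genes that are essentially unexpressed.

    Parameters
    ----------
    expression
        Genes (rows) x samples (columns) TPM matrix.
    sample_types
        Maps each expression-matrix sample to its cancer type.
    covered_types
        Cancer types considered to have expression data; defaults to
        all types appearing among the matrix's samples.

    Returns
    -------
    per_type, global_low, covered
        ``per_type[type]`` = genes with TPM < 0.1 in >= 90% of that
        type's tumors; ``global_low`` = genes with TPM < 0.1 in > 95%
        of all tumors (the fallback for uncovered types).
    """
    cols = [c for c in expression.columns if c in sample_types]
    if covered_types is None:
        covered_types = {sample_types[c] for c in cols}
    covered = set(covered_types)
    low = expression[cols] < LOW_EXPRESSION_TPM

    per_type: dict[str, set[str]] = {}
    for t in covered:
        t_cols = [c for c in cols if sample_types[c] == t]
        if not t_cols:
            per_type[t] = set()
            continue
        frac = low[t_cols].mean(axis=1)
        per_type[t] = set(frac.index[frac >= LOW_EXPRESSION_TYPE_FRACTION])
    global_frac = low.mean(axis=1)
    global_low = set(global_frac.index[global_frac > LOW_EXPRESSION_GLOBAL_FRACTION])
    return per_type, global_low, covered


def filter_expression(
    mutations: Iterable[MutationRecord],
    expression: pd.DataFrame,
    sample_types: Mapping[str, str],
    covered_types: Collection[str] | None = None,
) -> list[MutationRecord]:
    """Drop mutations in genes not expressed in the relevant tumors.

    For a mutation whose cancer type has expression data, the gene must
    not have TPM < 0.1 in >= 90% of that type's tumors.  For cancer
    types without expression data the fallback applies: the gene is
    dropped if more than 95% of all tumors have TPM < 0.1.
    """
    per_type, global_low, covered = low_expression_genes(
        expression, sample_types, covered_types
    )
    kept = []
    for m in mutations:
        if m.cancer_type in covered:
            if m.gene in per_type.get(m.cancer_type, ()):
                continue
        elif m.gene in global_low:
            continue
        kept.append(m)
    return kept


def residue_counts(
    mutations: Iterable[MutationRecord],
    gene: str,
    alignment: SequenceStructureAlignment,
) -> ResidueMutationCounts:
    """Count distinct mutated samples per protein position of ``gene``.

    Only missense records contribute; several missense alleles of one
    sample at one position count once (per-sample counting).  Positions
    outside the alignment remain in ``counts`` but are excluded from
    ``aligned_positions``.
    """
    if alignment.gene != gene:
        raise AlignmentError(
            f"alignment is for gene {alignment.gene!r}, expected {gene!r}"
        )
    samples_by_pos: dict[int, set[str]] = {}
    for m in mutations:
        if m.gene != gene or m.variant_class != "missense":
            continue
        samples_by_pos.setdefault(m.protein_position, set()).add(m.sample_id)
    counts = {pos: len(samples) for pos, samples in samples_by_pos.items()}
    return ResidueMutationCounts(
        gene=gene, counts=counts, aligned_positions=alignment.seq_positions
    )
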