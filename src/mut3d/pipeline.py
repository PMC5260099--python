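"""End-to-end run configuration and orchestration.

The pipeline wires together the stages: load mutations, apply germline
and expression filters, load and filter alignments, compute per-chain
contact maps and clusters, run the permutation test, and assemble and
export the catalog.  A run report records the counts at every stage
and the seed, so runs are auditable and reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import catalog as catalog_mod
from . import mapping as mapping_mod
from .mapping import MIN_ALIGNMENT_IDENTITY
from .permutation import DEFAULT_N_DECOYS, test_structure
from .structure_io import DEFAULT_CONTACT_CUTOFF, PdbFormatError, read_pdb

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A required input is missing or unreadable."""


@dataclass
class RunConfig:
    """All parameters and paths of an end-to-end detection run."""

    mutations: str = ""
    alignments: str = ""
    structures_dir: str = ""
    out_dir: str = "mut3d-out"
    blacklist_1kg: str | None = None
    blacklist_esp: str | None = None
    expression: str | None = None
    sample_types: str | None = None
    hotspots: str | None = None
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    min_identity: float = MIN_ALIGNMENT_IDENTITY
    n_decoys: int = DEFAULT_N_DECOYS
    alpha: float = catalog_mod.DEFAULT_ALPHA
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cutoff):
            raise ConfigurationError("cutoff must be positive")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ConfigurationError("min_identity must lie in [0, 1]")
        if self.n_decoys < 1:
            raise ConfigurationError("n_decoys must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _load_hotspots(path: str | Path) -> set[tuple[str, int]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "position"):
        if col not in df.columns:
            raise ConfigurationError(f"hotspot list missing column {col!r}")
    return {(r.gene, int(r.position)) for r in df.itertuples(index=False)}


def _require(path: str | None, label: str) -> Path:
    if not path:
        raise ConfigurationError(f"configuration is missing the {label} path")
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"{label} path does not exist: {p}")
    return p


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the full detection workflow and write catalog + report.

    Returns the run report (also written as ``report.json``).  Failures
    on individual structures are logged and skipped; the run continues.
    """
    import pandas as pd

    mut_path = _require(config.mutations, "mutations")
    aln_path = _require(config.alignments, "alignments")
    struct_dir = _require(config.structures_dir, "structures_dir")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    mutations = mapping_mod.load_mutations(mut_path)
    n_loaded = len(mutations)

    n_germline = 0
    if config.blacklist_1kg or config.blacklist_esp:
        kg = mapping_mod.load_blacklist(_require(config.blacklist_1kg, "blacklist_1kg"))
        esp = set(
            mapping_mod.load_blacklist(_require(config.blacklist_esp, "blacklist_esp"))
        )
        before = len(mutations)
        mutations = mapping_mod.filter_germline(mutations, kg, esp)
        n_germline = before - len(mutations)

    n_expression = 0
    if config.expression:
        expr = pd.read_csv(
            _require(config.expression, "expression"), sep="\t", index_col=0
        )
        types_df = pd.read_csv(
            _require(config.sample_types, "sample_types"),
            sep="\t", dtype=str, keep_default_na=False,
        )
        sample_types = dict(zip(types_df["sample_id"], types_df["cancer_type"]))
        before = len(mutations)
        mutations = mapping_mod.filter_expression(mutations, expr, sample_types)
        n_expression = before - len(mutations)

    alignments = mapping_mod.load_alignments(aln_path)
    n_aln = len(alignments)
    alignments = mapping_mod.filter_alignments(alignments, config.min_identity)

    all_results = []
    n_chains = 0
    chain_cache: dict[str, dict[str, object]] = {}
    for aln in sorted(alignments, key=lambda a: (a.gene, a.structure_id, a.chain_id)):
        pdb_path = Path(struct_dir) / f"{aln.structure_id}.pdb"
        if aln.structure_id not in chain_cache:
            try:
                chain_cache[aln.structure_id] = {
                    ch.chain_id: ch for ch in read_pdb(pdb_path)
                }
            except (PdbFormatError, OSError) as exc:
                logger.warning("skipping structure %s: %s", aln.structure_id, exc)
                chain_cache[aln.structure_id] = {}
        chain = chain_cache[aln.structure_id].get(aln.chain_id)
        if chain is None:
            logger.warning(
                "chain %s not found in structure %s; skipped",
                aln.chain_id, aln.structure_id,
            )
            continue
        counts = mapping_mod.residue_counts(mutations, aln.gene, aln)
        results = test_structure(
            chain, aln, counts,
            n_decoys=config.n_decoys, seed=config.seed, cutoff=config.cutoff,
        )
        n_chains += 1
        all_results.extend(results)

    entries = catalog_mod.significant_clusters(all_results, alpha=config.alpha)
    if config.hotspots:
        entries = catalog_mod.classify_residues(
            entries, _load_hotspots(_require(config.hotspots, "hotspots"))
        )

    ref_aa = {(m.gene, m.protein_position): m.ref_aa for m in mutations}
    files = catalog_mod.export(entries, "tsv", out_dir / "catalog", ref_aa=ref_aa)
    files += catalog_mod.export(entries, "json", out_dir / "catalog.json", ref_aa=ref_aa)

    report = {
        "n_mutations_loaded": n_loaded,
        "n_removed_germline": n_germline,
        "n_removed_expression": n_expression,
        "n_mutations_final": len(mutations),
        "n_alignments_loaded": n_aln,
        "n_alignments_pass_identity": len(alignments),
        "n_chains_tested": n_chains,
        "n_clusters_tested": len(all_results),
        "n_significant_unique_clusters": len(entries),
        "parameters": asdict(RunConfig(**asdict(config))),
        "outputs": [str(f) for f in files],
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
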