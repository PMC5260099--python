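"""Catalog assembly: significant clusters, residue categories, summaries.

Significant clusters are deduplicated across structures by their set of
sequence residues, keeping the minimum p-value.  Residues are then
placed into three categories relative to an externally supplied list of
single-residue hotspots:

1. the residue is itself a single-residue hotspot,
2. a rarely mutated residue sharing a significant cluster with a
   hotspot (in any of its clusters — ties resolve toward category 2),
3. a rarely mutated residue clustering only with other rare residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mapping import MutationRecord
from .permutation import ClusterTestResult

DEFAULT_ALPHA = 0.05

HOTSPOT = 1
RARE_COUPLED = 2
RARE_ONLY = 3

CATEGORY_NAMES = {HOTSPOT: "hotspot", RARE_COUPLED: "rare_coupled", RARE_ONLY: "rare_only"}


@dataclass
class CatalogEntry:
    """One unique significant cluster."""

    gene: str
    seq_members: frozenset
    p_value: float
    structures: list[tuple[str, str]] = field(default_factory=list)
    member_counts: dict[int, int] = field(default_factory=dict)
    categories: dict[int, int] | None = None
    cancer_types: dict[str, int] | None = None

    @property
    def key(self) -> tuple[str, frozenset]:
        return (self.gene, self.seq_members)


def significant_clusters(
    results: Iterable[ClusterTestResult], alpha: float = DEFAULT_ALPHA
) -> list[CatalogEntry]:
    """Filter test results at ``p <= alpha`` and deduplicate.

    Clusters with the same (gene, sequence-residue-set) key collapse to
    one entry keeping the minimum p-value; provenance is merged.
    """
    by_key: dict[tuple[str, frozenset], CatalogEntry] = {}
    for r in sorted(
        results,
        key=lambda r: (r.cluster.gene, sorted(r.cluster.seq_members),
                       r.cluster.structure_id, r.cluster.chain_id),
    ):
        if r.p_value > alpha:
            continue
        key = (r.cluster.gene, r.cluster.seq_members)
        prov = (r.cluster.structure_id, r.cluster.chain_id)
        entry = by_key.get(key)
        if entry is None:
            by_key[key] = CatalogEntry(
                gene=r.cluster.gene,
                seq_members=r.cluster.seq_members,
                p_value=r.p_value,
                structures=[prov],
                member_counts=dict(r.member_counts or {}),
            )
        else:
            entry.p_value = min(entry.p_value, r.p_value)
            if prov not in entry.structures:
                entry.structures.append(prov)
            for pos, n in (r.member_counts or {}).items():
                entry.member_counts[pos] = max(entry.member_counts.get(pos, 0), n)
    return [
        by_key[k] for k in sorted(by_key, key=lambda k: (k[0], sorted(k[1])))
    ]


def classify_residues(
    catalog: Sequence[CatalogEntry],
    hotspot_list: Iterable[tuple[str, int]],
) -> list[CatalogEntry]:
    """Assign residue categories 1/2/3 across the whole catalog.

    A residue appearing in several clusters takes the lowest applicable
    category: hotspot membership anywhere makes it category 1; sharing
    *any* significant cluster with a hotspot makes it category 2.
    """
    hotspots = set(hotspot_list)
    coupled: set[tuple[str, int]] = set()
    for entry in catalog:
        if any((entry.gene, p) in hotspots for p in entry.seq_members):
            coupled.update((entry.gene, p) for p in entry.seq_members)

    out = []
    for entry in catalog:
        cats = {}
        for p in sorted(entry.seq_members):
            key = (entry.gene, p)
            if key in hotspots:
                cats[p] = HOTSPOT
            elif key in coupled:
                cats[p] = RARE_COUPLED
            else:
                cats[p] = RARE_ONLY
        out.append(replace(entry, categories=cats))
    return out


def residue_table(catalog: Sequence[CatalogEntry]) -> pd.DataFrame:
    """One row per catalog residue: gene, position, category, samples."""
    rows: dict[tuple[str, int], dict] = {}
    for entry in catalog:
        for p in sorted(entry.seq_members):
            key = (entry.gene, p)
            cat = (entry.categories or {}).get(p)
            n = entry.member_counts.get(p, 0)
            if key not in rows:
                rows[key] = {"gene": entry.gene, "position": p,
                             "category": cat, "n_samples": n}
            else:
                prev = rows[key]
                if cat is not None and (prev["category"] is None or cat < prev["category"]):
                    prev["category"] = cat
                prev["n_samples"] = max(prev["n_samples"], n)
    return pd.DataFrame(
        [rows[k] for k in sorted(rows)],
        columns=["gene", "position", "category", "n_samples"],
    )


def summarize(
    catalog: Sequence[CatalogEntry],
    mutations: Iterable[MutationRecord],
) -> dict:
    """Per-gene and per-sample summaries of the classified catalog.

    Returns a dict with:

    - ``gene_summary``: DataFrame with the number of cluster residues
      per gene and the fraction of samples carrying >= 1 missense
      mutation at a cluster residue of that gene;
    - ``sample_categories``: Series sample -> lowest category among its
      cluster mutations;
    - ``overall_prevalence``: fraction of all samples with >= 1 cluster
      mutation.
    """
    muts = [m for m in mutations if m.variant_class == "missense"]
    all_samples = {m.sample_id for m in muts}

    res_tab = residue_table(catalog)
    cluster_residues: dict[str, set[int]] = {}
    category_of: dict[tuple[str, int], int] = {}
    for row in res_tab.itertuples(index=False):
        cluster_residues.setdefault(row.gene, set()).add(row.position)
        if row.category is not None:
            category_of[(row.gene, row.position)] = int(row.category)

    gene_rows = []
    samples_by_gene: dict[str, set[str]] = {g: set() for g in cluster_residues}
    sample_cat: dict[str, int] = {}
    for m in muts:
        if m.protein_position in cluster_residues.get(m.gene, ()):
            samples_by_gene[m.gene].add(m.sample_id)
            cat = category_of.get((m.gene, m.protein_position))
            if cat is not None:
                prev = sample_cat.get(m.sample_id)
                sample_cat[m.sample_id] = cat if prev is None else min(prev, cat)

    n_total = len(all_samples)
    for gene in sorted(cluster_residues):
        n_mut = len(samples_by_gene[gene])
        gene_rows.append(
            {
                "gene": gene,
                "n_cluster_residues": len(cluster_residues[gene]),
                "n_samples": n_mut,
                "prevalence": n_mut / n_total if n_total else 0.0,
            }
        )
    gene_summary = pd.DataFrame(
        gene_rows, columns=["gene", "n_cluster_residues", "n_samples", "prevalence"]
    ).sort_values(["n_cluster_residues", "gene"], ascending=[False, True]).reset_index(drop=True)

    covered = set()
    for g, residues in cluster_residues.items():
        covered |= samples_by_gene[g]
    return {
        "gene_summary": gene_summary,
        "sample_categories": pd.Series(sample_cat, dtype="Int64").sort_index(),
        "overall_prevalence": len(covered) / n_total if n_total else 0.0,
    }


def format_member(position: int, n_samples: int, ref_aa: str = "") -> str:
    """Render one cluster member as e.g. ``P250(1)``."""
    return f"{ref_aa}{position}({n_samples})"


def _entry_to_dict(entry: CatalogEntry, ref_aa: Mapping[tuple[str, int], str]) -> dict:
    members = sorted(entry.seq_members)
    return {
        "gene": entry.gene,
        "members": members,
        "ref_aa": {str(p): ref_aa.get((entry.gene, p), "") for p in members},
        "member_counts": {str(p): entry.member_counts.get(p, 0) for p in members},
        "categories": {str(p): (entry.categories or {}).get(p) for p in members},
        "p_value": entry.p_value,
        "structures": [list(s) for s in entry.structures],
        "cancer_types": entry.cancer_types,
    }


def export(
    catalog: Sequence[CatalogEntry],
    format: str,
    path: str | Path,
    ref_aa: Mapping[tuple[str, int], str] | None = None,
) -> list[Path]:
    """Write the catalog as TSV (cluster + residue tables) or JSON.

    For ``format='tsv'``, ``path`` is a prefix: ``<path>.clusters.tsv``
    and ``<path>.residues.tsv`` are written.  For ``format='json'`` a
    single file at ``path`` holds the full content and round-trips via
    :func:`import_json`.
    """
    ref_aa = dict(ref_aa or {})
    path = Path(path)
    if format == "json":
        payload = [_entry_to_dict(e, ref_aa) for e in catalog]
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return [path]
    if format != "tsv":
        raise ValueError(f"unknown export format {format!r}")

    cluster_rows = []
    for e in catalog:
        members = " ".join(
            format_member(p, e.member_counts.get(p, 0), ref_aa.get((e.gene, p), ""))
            for p in sorted(e.seq_members)
        )
        cluster_rows.append(
            {
                "gene": e.gene,
                "members": members,
                "n_residues": len(e.seq_members),
                "p_value": e.p_value,
                "structures": ",".join(f"{s}:{c}" for s, c in e.structures),
            }
        )
    cluster_df = pd.DataFrame(
        cluster_rows,
        columns=["gene", "members", "n_residues", "p_value", "structures"],
    )
    res_df = residue_table(catalog)
    res_df.insert(
        2, "ref_aa",
        [ref_aa.get((g, p), "") for g, p in zip(res_df["gene"], res_df["position"])],
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    p1 = path.with_name(path.name + ".clusters.tsv")
    p2 = path.with_name(path.name + ".residues.tsv")
    cluster_df.to_csv(p1, sep="\t", index=False)
    res_df.to_csv(p2, sep="\t", index=False)
    return [p1, p2]


def import_json(path: str | Path) -> list[CatalogEntry]:
    """Re-read a JSON export into catalog entries."""
    payload = json.loads(Path(path).read_text())
    entries = []
    for d in payload:
        cats = {
            int(p): int(c) for p, c in (d.get("categories") or {}).items()
            if c is not None
        }
        entries.append(
            CatalogEntry(
                gene=d["gene"],
                seq_members=frozenset(d["members"]),
                p_value=float(d["p_value"]),
                structures=[tuple(s) for s in d["structures"]],
                member_counts={int(p): int(n) for p, n in d["member_counts"].items()},
                categories=cats or None,
                cancer_types=d.get("cancer_types"),
            )
        )
    return entries
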