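# mut3d

Detection of **significantly mutated 3D clusters** of somatic missense
mutations on protein structures.

Most somatic missense mutations found in tumor sequencing are rare:
they occur once or twice in a cohort and cannot be separated from
passenger events by positional recurrence alone. Many functional
mutations, however, sit close together *in space* — near a recurrent
hotspot or near other rare mutations — on the folded protein. `mut3d`
finds such mutations by testing, for every residue of a structure
chain, whether the residue and its 3D contact neighbors are more
heavily mutated than expected under a permutation null. It is aimed at
cancer-genomics analysts who have protein-level mutation calls and
want to prioritize rare candidate driver alleles using structures.

## Method

For each structure chain, a residue **contact map** is computed: two
residues are in contact if any pair of their atoms lies within 5 Å
(inclusive). Every aligned residue *c* defines one **3D cluster**
`C(c) = {c} ∪ neighbors(c)`; clusters are never merged, so a residue
belongs to several clusters. Mutations are mapped through a
sequence-to-structure alignment (kept only if identity ≥ 90%), and
each residue *i* gets a count `n_i` = number of distinct tumor samples
with a missense mutation there. The observed score of a cluster is
`s(C) = Σ_{i∈C} n_i`.

Significance is assessed with a **capped, max-over-clusters
permutation test**. Decoy patterns are drawn by shuffling the counts
`(n_i)` uniformly over the aligned positions (a random bijection of
the count multiset). Before shuffling, every count is truncated to
`cap = max_{i∈C} n_i` of the assessed cluster, so a dominant
single-residue hotspot elsewhere in the gene (think BRAF V600) cannot
mask modest clusters. The p-value of cluster *C* with observed score
*s* is

```
p(C) = (# decoys in which ANY cluster scores ≥ s) / (# decoys)
```

with 10⁵ decoys by default. The max-over-clusters form makes the
p-value family-wise across the clusters of a chain; a single mutated
residue alone always yields p = 1, so pure single-site recurrence is
never called a 3D cluster. An exact enumeration oracle over all
distinct placements of the count multiset is included for small cases
and used throughout the tests.

Significant clusters (default α = 0.05, configurable) are deduplicated
across structures by their residue set, and residues are categorized
against an external single-residue hotspot list: **1** hotspot,
**2** rare residue sharing a cluster with a hotspot, **3** rare
residue clustering only with other rare residues.

## Worked example

Generate a synthetic fixture with a known planted cluster and run the
full pipeline on it:

```sh
mut3d simulate --n-residues 40 --geometry linear --inject "20,21,22:3" \
    --background 5 --n-samples 100 --seed 3 --out-dir fixture
mut3d detect --mutations fixture/mutations.tsv \
    --alignments fixture/alignments.tsv --structures-dir fixture \
    --out-dir out --n-decoys 10000 --seed 17
```

which prints:

```
tested 16 clusters on 1 chains; 1 unique significant clusters (seed 17)
```

`out/catalog.clusters.tsv` then contains (members rendered as
`<ref><position>(<samples>)`, as in per-cluster mutation tables):

```
gene	members	n_residues	p_value	structures
GENE1	Y20(3) A21(3) C22(3)	3	0.0035	SYN1:A
```

The planted triple 20–22 (three mutated samples per residue, observed
cluster score 9) is recovered at p = 0.0035: only 35 of the 10 000
decoy shuffles produced any cluster scoring ≥ 9 once counts were
capped at the cluster's maximum of 3. The 16 tested clusters are the
windows around each mutated residue; the background positions, mutated
once each, stay near p = 1 and are filtered out at α = 0.05.

Per-gene tests are also available directly: `mut3d test-gene GENE1
--pdb fixture/SYN1.pdb --alignments fixture/alignments.tsv --mutations
fixture/mutations.tsv` prints one row per cluster with observed score,
cap, and p-value.

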