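# Methods

## Model

`mut3d` treats a protein structure chain as a contact graph. Residues
*i* and *j* are adjacent when the minimum distance over their atom
pairs is at most a cutoff (default **5.0 Å, inclusive**). Each residue
aligned to the canonical protein sequence defines one cluster — the
residue plus its aligned contact neighbors — so a chain with *L*
aligned residues yields exactly *L* clusters, and a residue's cluster
multiplicity is one plus its contact degree. Clusters are deliberately
not merged: overlapping clusters are tested independently, and
clusters from different structures with the same set of sequence
positions are collapsed to one unique cluster after testing (keeping
the minimum p-value).

Mutation input is protein-level: each record is (sample, gene, 1-based
position, ref/alt amino acid, variant class, cancer type). Only
missense records are scored, and the per-residue statistic is the
number of **distinct mutated samples**, so two different alleles in
one sample at one residue count once. The analysis assumes annotation
to canonical isoforms has already happened upstream; genome
coordinates, VEP annotation, and liftover are out of scope.

## Null model and test

Let `n_i` be the count at aligned position *i* and `s(C) = Σ_{i∈C} n_i`
the observed score of cluster *C*. The null hypothesis is that the
observed counts are exchangeable across the aligned region: a decoy is
a uniformly random bijection of the multiset `{n_i}` (zeros included)
onto the aligned positions. For the assessed cluster, all counts are
first truncated to `cap = max_{i∈C} n_i` (the cap rule). Since the cap
equals the assessed cluster's own maximum, capping never changes that
cluster's observed score — only the influence of dominant residues
elsewhere in the gene. The p-value is the fraction of decoys in which
**any** cluster of the chain reaches the observed score (inclusive
comparison), estimated over `n_decoys` shuffles.

Properties that follow from this construction, all exercised by tests:

- the comparison is family-wise over clusters, so under the null the
  chance that any cluster reaches p ≤ α is at most α (empirically much
  lower, because the count distribution is discrete);
- a single mutated residue always gives p = 1: every decoy places its
  count inside some residue's own cluster;
- a fully connected chain gives p = 1 for every cluster: shuffles
  conserve the total.

The exact oracle enumerates all distinct placements of the count
multiset (`L! / Π mult!` of them) and computes the same exceedance
fraction exactly; it refuses above a configurable bound (default 10⁶
placements) and exists to validate the Monte Carlo path, never to
replace it.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 5.0 Å | any-atom contact distance, inclusive |
| `min_identity` | 0.90 | minimum sequence identity of an alignment |
| `n_decoys` | 100 000 | decoy patterns per cap value |
| `alpha` | 0.05 | significance threshold for the catalog |
| TPM threshold | 0.1 | "unexpressed" cutoff for the expression filter |
| type fraction | ≥ 0.90 | unexpressed-tumor fraction within a cancer type |
| global fraction | > 0.95 | fallback fraction over all tumors |

The significance threshold is an explicit configuration value rather
than a constant: published per-cluster p-values around 0.009–0.05 (and
one illustrative cluster at 0.085) show that the cutoff choice is a
judgment call, so it is surfaced in `RunConfig` and recorded in the
run report. The 1000 Genomes/ESP germline filter removes variants
present in both panels, plus variants seen twice or more in 1000
Genomes; matching is by (gene, position, ref, alt) at protein level,
a simplification consistent with the package's protein-level inputs.

## Numerical and design choices

- **Boundary**: "within 5 Å" is implemented as ≤ 5.0. The boundary
  case is tested explicitly at exactly 5.0 Å.
- **Altlocs / models**: only the first-listed alternate location of
  each atom and only the first MODEL are used, keeping parsing
  deterministic; occupancy-based selection was rejected.
- **Neighbors outside the aligned region are excluded from clusters.**
  The null shuffles only aligned positions; residues that cannot
  receive shuffled counts would deflate p-values if allowed to
  contribute observed counts.
- **Observed scores are uncapped**; capping applies to decoys only.
  This is self-consistent (see above) and matches the rule's purpose.
- **Decoy streams are keyed by (seed, gene, cap)** via a hash-derived
  `SeedSequence`, so results are independent of the order in which
  genes, structures, or clusters are processed, and clusters sharing a
  cap share one decoy stream (statistically identical, and it saves a
  factor of roughly the cluster count).
- **Zero exceedances** are reported as p = 0 with a
  `below_resolution` flag meaning "p < 1/n_decoys"; no add-one
  smoothing is applied, so reported p-values are the raw decoy
  fractions.
- **Ties in categories**: a residue in one cluster with a hotspot and
  another without is category 2; per-sample summaries take the lowest
  category among the sample's cluster mutations.
- Decoy scoring is vectorized: a block of shuffled count vectors is
  multiplied against the cluster membership matrix, and the max over
  clusters is compared to the observed score.

## Synthetic fixtures

The generator emulates the pipeline's inputs, not protein physics:
CA-only traces (linear chains at 3.8 Å spacing, or an ideal helix with
rise 1.5 Å/residue, 100°/residue, radius 2.3 Å), identity alignments,
and mutation tables where every record is a distinct sample — injected
cluster positions with fixed per-residue counts, background events
placed uniformly. With these helix constants a CA-only trace has i±1
contacts at 5 Å (the i±3 CA–CA distance is 5.05 Å, just outside the
cutoff; i±4 is geometrically out of reach without side chains), so
fixtures exercising 3D adjacency beyond the sequence neighbors use
custom coordinates. What fixtures do **not** model: side-chain
geometry, domain architecture, per-gene mutation-rate heterogeneity,
alignment gaps and errors, or sample-level mutation burden variation —
passing tests demonstrate the statistical machinery is correct under
exchangeability, not that real cohorts satisfy it.

Simulation sizes used by the tests and the acceptance script — 500
null replicates on a 50-residue helix with 20 background events at
10⁴ decoys, 100 power replicates on a 100-residue helix, 10⁵ decoys
for oracle-agreement checks — were chosen so the binomial error of
each estimate is small relative to the bound being checked.

## Limitations

- Per-chain analysis only: no inter-chain or interface clusters.
- Power depends directly on cohort size; clusters whose member counts
  are all 1 cannot reach small p-values on short aligned regions.
- The permutation null treats all aligned positions as exchangeable;
  real mutational processes (CpG context, replication timing) violate
  this, and the method inherits any such bias from its inputs.
- The catalog's composition is sensitive to `alpha` and to the
  structure/alignment coverage supplied; identical mutations can yield
  different clusters on different template structures, which is why
  unique-cluster deduplication is applied across structures.
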