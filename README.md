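# dloopkin

Maternal-lineage kinship analysis of mitochondrial D-loop (control-region)
haplotypes in livestock, built for the question of how sheep breeds — for
example the Egyptian thin- and fat-tailed breeds — relate through their
maternal gene pools.

Domestic sheep mtDNA falls into five deep maternal clades, the haplogroups
A–E. Classical distance statistics between breeds (Nei's or Reynolds'
distances, FST) are dominated by haplogroup composition, which blurs recent
maternal exchange. This package implements a tree-topology statistic that is
independent of haplogroup frequencies: counting, on a phylogenetic tree of
individual haplotypes, the **type-1 connections** (two tips that are strictly
sister — a *cherry*) and **type-2 connections** (a tip whose sister clade is
a cherry, linked to each cherry tip) between breeds. Breeds that exchanged
females recently accumulate cross-breed sister configurations regardless of
which haplogroup the lineages belong to.

Around that core the package provides the full analysis chain:

- **io_formats** — FASTA/TSV I/O, within-breed deduplication of identical
  haplotypes, candidate-pool filtering by near-identity (≤ 2 mismatches,
  ≥ 2 occurrences per breed);
- **alignment_qc** — end trimming to reference coverage, a Gblocks-style
  conserved-block mask, and the > 5 %-missing locus filter;
- **tree_model** — Newick I/O (external ML trees plug in directly), K2P
  distances, an internal neighbour-joining builder, outgroup rooting, and
  haplogroup assignment by clade placement among labelled references;
- **kinship_core** — type-1/type-2 connection matrices, breed partner
  profiles with regional grouping and retention truncation, profile
  dissimilarities;
- **popgen_fst** — pairwise ΦST via AMOVA on pairwise sequence differences
  (with the < 3-individuals population filter) and permutation tests;
- **ordination** — non-metric multidimensional scaling (Kruskal stress-1,
  isotonic regression, best-of-restarts) and UPGMA dendrograms;
- **synthetic_data** — a structured-coalescent generator with deep
  haplogroup clades, breed-level substructure and discrete introgression
  pulses, which makes every stage testable without downloading sequences;
- **pipeline / cli** — end-to-end orchestration (`dloopkin run --config
  pipeline.yaml`) plus thin subcommands (`qc`, `tree`, `haplogroups`,
  `connections`, `fst`, `ordinate`, `simulate`).

## The statistics, briefly

For two populations with d(i,j) the count of differing resolved sites,
AMOVA partitions ΣΣ d²/2N into within- and among-population sums of squares;
with σ²w = SSD_w/(N−P) and σ²a = (SSD_a/(P−1) − σ²w)/n̄,

    ΦST = σ²a / (σ²a + σ²w).

Distances for the internal tree builder use Kimura's two-parameter model,
d = ½ ln 1/(1−2P−Q) + ¼ ln 1/(1−2Q), with P and Q the transition and
transversion proportions. NMDS minimizes Kruskal's stress-1,
√(Σ(d̂−d)²/Σd²), with d̂ the isotonic fit of embedded to observed
dissimilarities.

## Worked example

`python examples/02_connection_counting.py` counts connections on a toy
tree of Egyptian-breed haplotypes:

```
cherries (type 1): [('Saidi1', 'Sohagi1'), ('Fallahi1', 'Sohagi3'), ('Barki1', 'Merino1')]
tip-plus-cherry (type 2): [('Sohagi2', 'Fallahi1', 'Sohagi3')]

type-2 connection matrix (diagonal = within-breed links):
      BARK  FALL  MERI  SAID  SOHA
BARK     0     0     0     0     0
FALL     0     0     0     0     1
MERI     0     0     0     0     0
SAID     0     0     0     0     0
SOHA     0     1     0     0     1

Sohagi partner profile (count, percent of all its links):
  FALL: 1 (100%)
```

The single type-2 configuration (Sohagi2 sister to the Fallahi1/Sohagi3
cherry) contributes one Sohagi–Fallahi link and one within-Sohagi link
(the diagonal); the cherry's own Fallahi–Sohagi pair would be counted by
type 1, not re-counted here. `examples/01_simulate_and_run_pipeline.py`
runs the whole pipeline on a simulated four-breed dataset and
`examples/03_phist_and_ordination.py` shows ΦST, its permutation test and
the NMDS embedding.

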