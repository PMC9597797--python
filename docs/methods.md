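# Methods

## Problem setting

Mitochondrial D-loop haplotypes are maternally inherited and fall, in
domestic sheep, into five deep haplogroups (A–E). Breed-level affinity
measured on haplotype trees separates two signals: haplogroup composition
(deep, ancient structure) and the fine placement of individual lineages
(recent maternal exchange). The package's central statistic — type-1 and
type-2 connection counting — targets the second signal; ΦST and its
ordination capture the first. This note records the models, the defaults
and the design choices behind both, and what the synthetic tests do and do
not demonstrate.

## Connection counting

The statistic is read off a rooted haplotype tree exactly as exported by
the tree-building program:

* type 1 — every internal node whose two children are both tips (a cherry)
  yields one link between the two tips' breeds;
* type 2 — every internal node with exactly two children, one a tip *t*
  and the other a cherry {x, y}, yields the two links t–x and t–y. The
  x–y pair inside the cherry is counted only by type 1, so the two
  matrices are independently interpretable and nothing is double-counted.

Counts accumulate into a symmetric breed × breed integer matrix; links
between two haplotypes of the same breed land on the diagonal. Row totals
("how connected is breed F?") exclude the diagonal by default because
within-breed links answer a different question; an `include_self` switch
exposes them. Ladderization and any rotation of children leave the counts
unchanged, and the totals satisfy two accounting identities used as test
invariants: the type-1 total equals the number of cherries, and the grand
sum of the type-2 matrix plus its trace equals four times the number of
tip-plus-cherry configurations (each configuration carries two links, and
each link increments either two symmetric cells or the diagonal once).

Maximum-likelihood trees are binary; should a polytomy appear, a polytomy
with m ≥ 2 tip children emits all C(m, 2) pairs as type-1 links. This
generalization is logged loudly whenever it fires.

Breed profiles express one focal breed's row as percentages over all its
partners, optionally merging partners into regional groups; partners are
then ranked by count and retained greedily until a chosen fraction of the
links (default 0.75) is covered — the form in which repertoires of related
breeds are compared. Profile dissimilarities for clustering come in two
variants: 1 − Pearson correlation between two breeds' rows (both self-cells
excluded pairwise; an undefined correlation from a constant row is reported
as distance 1 with a warning) and the user-similarity transform
1 − count/max(count).

## ΦST by AMOVA on pairwise differences

Sequence distance is the count of differing positions where both sequences
are resolved (pairwise deletion over gaps, N and ?; the Arlequin convention
for DNA haplotypes). For populations of sizes n_p (total N, P populations):

    SSD_total  = Σ_ordered d²/(2N)
    SSD_within = Σ_p Σ_ordered-within d²/(2 n_p)
    σ²w = SSD_within/(N−P)
    σ²a = (SSD_among/(P−1) − σ²w)/n̄,   n̄ = (N − Σ n_p²/N)/(P−1)
    ΦST = σ²a/(σ²a + σ²w)

Zero total variance (identical monomorphic populations) is reported as
ΦST = 0 with a warning. Negative estimates — finite-sample noise — are
preserved rather than clamped so that downstream ordination sees the
faithful matrix; a clamp flag exists, and the pipeline clamps at 0 only
when feeding NMDS, which requires non-negative dissimilarities. The
permutation test shuffles individuals between the two populations and
reports (b+1)/(n_perm+1).

Before the matrix is computed, populations with fewer than 3 individuals
are dropped, then loci (columns) with more than 5 % missing data — in that
order, since removing populations changes the missing fractions.

## Trees

dendropy is the tree backbone (Newick parsing/writing, traversal,
rerooting). The internal tree builder is Saitou–Nei neighbour joining on
K2P distances — a deliberate desk-scale surrogate for an external
maximum-likelihood search; a supplied ML tree always takes precedence in
the pipeline. NJ ties in the Q criterion break on the smallest
taxon-index pair, so results are reproducible across runs and platforms.
K2P distances use pairwise deletion; pairs sharing fewer than 50 resolved
sites are rejected when building matrices (partial GenBank fragments with
near-disjoint coverage otherwise produce meaningless distances), while the
bare two-sequence function imposes no such floor. Outgroup rooting places
the root on the branch separating the outgroup tip set, splitting its
length evenly, and errors with the offending tips when no edge induces
that bipartition.

Haplogroup assignment walks from each query tip toward the root until the
clade contains at least one reference; a unanimous clade decides
("clade" support), a mosaic clade falls back to the patristic-nearest
reference ("nearest" support). The clade rule comes first because
assignment on real data is read off tree structure; distance only breaks
ties. Missing branch lengths count as 0 in patristic distances;
a tree with no lengths at all errors only if the fallback is actually
needed.

## Alignment cleaning

Three column-deleting operations (order of retained columns always
preserved): trimming to the span jointly covered by designated reference
sequences; a conserved-block mask; and the missing-data locus filter.
The block mask is a faithful-in-spirit re-implementation of the published
Gblocks defaults — majority threshold floor(n/2)+1, flank threshold
ceil(0.85 n), non-conserved runs capped at 8, minimum block length 10,
no gap columns — not a byte-compatible clone; parameters are exposed.
Internally coordinates are 0-based half-open; reports are 1-based
inclusive, matching alignment viewers.

## Ordination and clustering

NMDS minimizes Kruskal stress-1 with disparities from
pool-adjacent-violators isotonic regression. The optimisation (SMACOF,
scikit-learn) is non-convex, so the embedding runs from a classical-scaling
(Torgerson) start plus random restarts (default 20) derived
deterministically from the seed, and the configuration with the lowest
stress-1 — recomputed independently of the optimiser's internal criterion —
is kept, centered at the origin. An all-zero matrix returns coincident
points and stress 0 with a warning. UPGMA is implemented directly so that
ties break on the smallest index pair; merge heights are half the merge
distance, which reproduces ultrametric inputs exactly, and dendrograms are
exported as Newick with heights as branch lengths. scipy's average-linkage
clustering serves as an independent cross-check in the tests, never as the
implementation.

## The synthetic-data generator

The generator emulates the statistical structure of a worldwide D-loop
database: deep maternal clades, breed-labelled samples, within-breed
coalescent structure, and optional introgression. Time is in coalescent
units; there is no explicit Ne or per-year rate, keeping expectations
closed-form.

* Within each (breed, haplogroup) group, lineages coalesce under a Kingman
  coalescent with timescale `within_depth` (default 1), capped at
  `split_depth` (default 5), when survivors enter the haplogroup's
  ancestral population and coalesce at rate 1.
* Haplogroup ancestors join along a fixed pectinate spine at intervals of
  `spine_spacing` (default 5), so clade identity is unambiguous across
  seeds.
* Mutations: per-site rate multipliers from Gamma(shape, 1/shape)
  (default shape 0.5, typical of control-region rate heterogeneity);
  events Poisson on branches at per-locus rate θ/2 per unit time, so a
  lineage pair with E(T₂) = 1 expects θ differences (default θ = 5 over
  789 sites, within the range of within-breed control-region diversity in
  sheep); an HKY one-step kernel with κ = 10 (transition-heavy, as in
  mammalian mtDNA) and AT-rich stationary frequencies (0.32/0.24/0.14/0.30).
  This is a uniform-event-rate jump-chain scheme: the per-site event rate
  does not depend on the current base, which keeps E(π) = θ exact at the
  mutation-event level.
* Introgression is a discrete pulse: a stated fraction of a recipient
  breed's lineages (rounded, at least one if the fraction is positive,
  never the whole breed) is re-assigned to coalesce within the donor
  breed, with haplogroup drawn from the donor's mixture. This yields an
  exact per-lineage truth table, unlike a migration-rate model. A pulse of
  fraction 0 consumes no randomness, so it is byte-identical to no pulse.

Random streams are split (assignment / pulses / coalescence) from a single
seed via SeedSequence spawning, and the sequence-evolution seed derives
from the same root, so every artifact is reproducible from one integer.

What the generator does *not* emulate: recombination (mtDNA is clonal),
selection, demographic growth, sequencing error, and the ragged coverage
of real GenBank fragments (sequences are complete over the locus). Passing
tests therefore demonstrate correctness of the statistics and the
qualitative detectability of structure, not calibration against real
archives.

## Problem sizes used in the checks

The oracle and recovery checks run at sizes chosen to exercise the
algorithms thoroughly while staying desk-scale: 100 random trees up to 200
tips for connection-counting equivalence; 50 random two-population
datasets (n ≤ 10 each) for ΦST at 1e-10; haplogroup recovery pooled over
5 simulated datasets of 10 breeds × 10 individuals with split depth 4
(deep clades, references one true member per haplogroup), requiring ≥ 99 %
accuracy; introgression detectability over 50 paired replicates of a
3 × 10 design with a 0.5 pulse (one-sided sign test); and the
related-breeds end-to-end check over 100 replicates of a 3 × 15 design
whose related pair splits at depth 0.05 — effectively a single maternal
pool recently subdivided, which is the scenario the check is about.

## Known limitations

* The Gblocks-style mask will not reproduce the exact column set of the
  Gblocks program on real alignments; only the rule family is shared.
* The NJ surrogate is not an ML tree; analyses of real data should supply
  the external ML topology, which the pipeline prefers automatically.
* Haplogroup assignment needs user-supplied reference labels; no built-in
  reference panel ships with the package.
* ΦST uses plain difference counts (no substitution-model correction or
  gamma weighting), matching the default treatment of haplotype data.
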