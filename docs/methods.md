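# Methods

This note documents the models and procedures implemented in `pangtm`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Family clustering

Genes are grouped into families by filtering an all-vs-all protein
similarity search and clustering the resulting graph with the Markov
Cluster Algorithm (MCL).

**Similarity filter.** A hit passes when percent identity ≥ 50 and
e-value ≤ 1e-4 (both configurable). Self-hits are removed during
filtering; self-loops are reintroduced only inside MCL, keeping data
cleaning separate from algorithm internals. No alignment-coverage
threshold is applied by default (none is part of the family definition
used here); one can be imposed by pre-filtering records.

**Internal identity path.** When no BLAST table is supplied, percent
identity is computed directly: a global alignment with identity scoring
(match 1, mismatch 0, linear gap penalty −1) and
identity = 100·matches/alignment length. For equal-length sequences the
optimal alignment under this scoring is ungapped, so the bulk all-vs-all
path compares columns directly (vectorised) and reserves the aligner for
unequal lengths. E-values are reported as 0 on this path — filtering then
rests on identity alone. BLAST's e-value statistics are deliberately not
reimplemented.

**Graph.** Undirected, over *all* input genes (isolated genes persist and
become singleton families). Reciprocal hits collapse to one edge weighted
by the larger bitscore, falling back to percent identity when bitscores
are absent.

**MCL.** Per connected component (a random walk cannot cross components,
so this is exact, not an approximation): add self-loops equal to each
node's maximum incident weight (the canonical stabiliser), normalise
columns, then iterate expansion (matrix squaring), inflation (elementwise
power 2.5, column renormalisation) and pruning (entries < 1e-5 dropped,
columns renormalised) until the maximum absolute change falls below 1e-6,
capped at 200 iterations (failure raises, naming the cap and residual).
Clusters are read off the limit matrix as attractor systems; a node
reachable from several systems is assigned to the one with the larger
total steady-state (diagonal) mass, ties resolving to the system with the
smallest member, and family labels are assigned by each family's smallest
gene id — every tie-break is deterministic.

**Single-copy filter.** For phylogeny, families are kept only when they
have exactly one member in every genome under consideration (presence in
all genomes *and* copy number one everywhere).

## Pan-genome analysis

The presence/absence matrix holds occurrence counts (paralogues count;
the binary view is count > 0). Partitioning: core = present in every
genome; unique = present in exactly one (attributed to that genome);
shared dispensable = the rest. Reports follow the convention that the
"variable" or "dispensable genome" total aggregates all non-core families,
with the three-way split always available.

**Accumulation curves.** For each genome ordering, pan(N) = families seen
in the first N genomes and core(N) = families present in all of the first
N. When G! ≤ 5040 (G ≤ 7) all orderings are enumerated exactly;
otherwise a seeded sample (default 100 permutations) is used. Means are
fitted by least squares with a Heaps-type power law κ·N^γ for the pan
curve and Ω + A·e^(−N/τ) for the core curve — standard pan-genomics
functional forms consistent with the asymptotic trends these curves show;
Ω estimates the asymptotic core size. With fewer than three genomes the
fits are skipped with a warning. The new-family rate over additions
[from, to] is the mean of successive differences of the permutation-mean
pan curve.

**Genome summaries.** Means with *population* standard deviation
(divisor n, matching how ± figures are conventionally printed for a fixed
strain panel rather than a sample), rounded half-up: ORF counts to
integers, GC to two decimals, sizes to two decimals in Mbp. The bundled
table of 20 *B. longum* APC/DPC isolates serves as the worked example.

**Heatmap export.** Genomes are clustered by average linkage on Jaccard
distance between binary family profiles; columns are pre-sorted by genome
id so leaf order is deterministic. The reordered matrix and a Newick
rendering of the dendrogram are exported for external plotting.

## Core-gene supertree

Per single-copy family: p-distances (proportion of differing sites,
masking positions where either sequence has an ambiguity or gap
character) → Saitou–Nei neighbor joining. NJ resolves Q-matrix ties to
the lowest-index pair and clamps negative branch lengths to zero, moving
the deficit to the sister branch so path lengths are conserved.

The supertree is the strict majority-rule consensus: exactly the
bipartitions occurring in more than half of the family trees (supports =
percent of trees; consensus branch lengths = mean over supporting trees,
0 where absent). An extended majority-rule variant (greedily adding
remaining compatible splits in frequency order) is available behind a
flag; strict is the default since the plain rule is the conservative
reading of "majority rule". The consensus is rooted at the midpoint of
the outgroup's branch. Families lacking the outgroup are skipped with a
warning; zero usable families is an error.

NJ with p-distances stands in for maximum-likelihood tree inference: at
the scale this package targets the signal of interest is topological,
the simulator emits exactly aligned sequences, and NJ on near-additive
distances is consistent for topology. This is a design choice of the
package, not a claim of equivalence to ML inference.

## Growth phenotyping

Calls are made from the 12-h OD600 (configurable timepoint). Two schemes
coexist: the three-way category (good > 0.5, moderate in [0.4, 0.5],
none < 0.4) and the binary matching call (0 below 0.3, 1 above 0.4). The
binary scheme leaves [0.3, 0.4] unassigned; rather than guessing, such
readings become INDETERMINATE and the matching stage chooses a policy:
default "as_zero" (count the position with the call treated as 0, report
the count), or "strict" (drop the position from numerator and
denominator). No negative-control OD subtraction is applied; the raw
12-h reading is used. A lactose row is flagged as the positive control
and excluded from matching. Only carbohydrates with a differential
profile (at least one 0 and one 1, indeterminate ignored) enter matching.

## Gene-trait matching

The genotype matrix drops core families (present in all strains — no
contrast) and families whose representative annotation contains any
exclusion keyword, case-insensitively: transposase, integrase, phage,
prophage, restriction, methyltransferase, CRISPR, mobile element
(configurable; the list covers mobile and defence elements unrelated to
carbon utilization). A family's representative annotation is its most
frequent member annotation, ties broken lexicographically; families with
no annotation at all are retained and flagged. Families with identical
occurrence vectors collapse into one pattern row.

Matching is position-wise equality between a pattern row and a phenotype
row — both 1–1 and 0–0 positions count as agreement, since shared absence
of gene and growth is equally informative under this model. Hits are
cells strictly above the 95% threshold (at 20 strains only 20/20
qualifies; 19/20 = 95% is excluded — this sensitivity is asserted in the
tests). Partial matches above 50% are reported separately, ranked, for
manual inspection. Only direct matches (presence ↔ growth) are scored;
an inverse-match report can be derived but is never mixed into hits.
No statistical association testing (Fisher, phylogenetically corrected
methods) is performed: the method is exact pattern matching.

## Synthetic pan-genome generator

The simulator emulates the statistical structure the analysis assumes,
with full ground truth:

- a species tree over N strains plus an outgroup (random joins, edge
  lengths uniform(0.4, 0.6), globally rescaled so the maximum
  leaf-to-leaf path equals `divergence_within_family`);
- a fixed core (every strain and the outgroup), dispensable families
  carried per-strain with probability drawn uniform from
  `occurrence_prob_range` (redrawn when carriage would be empty or
  complete, so dispensable families are strictly partial);
- K planted trait clusters, each a set of families whose carriage equals
  the cluster's carrier strain set exactly; the carrier set (size =
  round(`carrier_fraction`·N)) determines the noiseless phenotype of one
  carbohydrate;
- strain-unique genes; a configurable fraction of dispensable families
  annotated from the exclusion vocabulary so GTM filtering is exercised;
- sequences generated *pre-aligned*: one random ancestral protein per
  family (pairwise ancestral identity capped by an enforced dissimilarity
  floor), mutated site-wise along the species tree with per-edge
  substitution probability equal to branch length. Equal lengths and
  substitution-only evolution make p-distances and identities exact
  without an aligner.

Defaults describe the study conditions: 20 strains, 400 core + 600
dispensable families, 4 planted clusters of 4–10 families,
carrier fraction 0.5, phenotype noise 0, protein length 200, maximum
within-family divergence 0.25 (keeping within-family identity ≥ 70%,
comfortably above the 55% = threshold + 5-point margin the clustering
stage needs; configurations that would break the margin are rejected
with an explanation), between-family dissimilarity floor 0.60
(ancestral identity ≤ 40% = threshold − 10 points, enforced, not
assumed), OD noise sd 0.02, grower 12-h OD in (0.6, 1.1), non-grower in
(0.05, 0.2). Growth curves follow fixed monotone profiles scaled to the
drawn 12-h OD over timepoints {0, 6, 9, 12, 24} h, with truncated
Gaussian noise; a lactose column of all growers is always emitted.
Phenotype noise flips the binary grower/non-grower call, not the OD
value, so assay noise and biological noise stay separable and the flip
events can be replayed exactly from the seeded stream.

Randomness is organised as one child stream per output (tree, ancestors,
carriage, planted, unique, annotations, phenotype noise, growth), spawned
from the seed in a fixed documented order: identical configurations give
byte-identical files, and individual outputs can be regenerated or
replayed without the others.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: insertions/deletions and alignment uncertainty,
within-genome paralogues, rate variation across sites and lineages,
horizontal transfer correlated with phylogeny, assembly artefacts,
annotation errors, and phenotypes driven by regulation rather than gene
presence. Recovery results on simulated data bound the pipeline's
correctness, not its real-data sensitivity.

## Problem sizes and numerical choices

Tests run the full pipeline at two scales: a small configuration
(8 strains, 30 core + 40 dispensable families) wherever all-vs-all
sequence comparison is involved (quadratic in gene count), and the
default 20-strain configuration for presence/absence-level analyses
(GTM recovery, accumulation fits, supertrees over 25 core families).
These sizes were chosen as the smallest at which each property is
non-trivially exercised. Clustering equivalence uses ≥ 20 seeded random
graphs of up to 30 nodes against an independently written dense reference
MCL kept in the test tree. Convergence/pruning tolerances (1e-6 / 1e-5),
the exhaustive-permutation bound (7!), and all tie-break rules are as
stated above; rounding is half-up at the stated precisions everywhere a
figure is reported.

## Known limitations

- The internal identity path reports no e-values, so the e-value filter
  is only meaningful for imported BLAST tables.
- The consensus builder guarantees split compatibility only for
  thresholds ≥ 0.5, so thresholds below 0.5 are rejected.
- Accumulation-curve fits are descriptive; no open/closed pan-genome
  hypothesis test is attached to γ.
- The GTM stage treats annotations as given text; it does not reconstruct
  genomic neighbourhoods of hit clusters, only member listings.
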