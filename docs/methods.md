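# Methods

## Scope and design

The package decomposes a core-genome phylogenomics study of a bacterial
species complex into nine testable stages: sequence/table IO, synthetic
data generation, ortholog clustering with core-gene filters, alignment and
supermatrix assembly, distance-based tree inference with two resampling
support procedures, fragment-ANI species delimitation with dereplication,
group-specific gene detection, annotation summarisation, and an HGT
screen. External tools used in the original workflow (ortholog inference,
aligners, trimmers, ML tree programs, ANI and dereplication engines,
enrichment and HGT pipelines) are replaced by self-contained, deterministic
algorithms behind the same interfaces; each algorithm is simple enough to
verify against closed forms or brute-force oracles, and the interfaces are
pluggable so heavier engines can be substituted.

## Synthetic communities

The generator is the package's instrument for validating every downstream
claim; it emulates the statistical structure of the real data set rather
than any particular genome.

**Species tree.** Seven ingroup groups with sizes 3/45/4/1/3/2/17 (the
group sizes of the study's 75 ingroup genomes) plus one outgroup. The
first group diverges earliest; the rest form a balanced subtree. Branch
lengths are set so sister groups sit exactly `between_group_divergence`
apart leaf-to-leaf (default 0.18 substitutions/site), deeper pairs
slightly more via internal edges of 0.25 × that value, members of a group
`within_group_divergence` apart (default 0.02), and the outgroup 1.2 ×
the between-group divergence away. Within-group topology is a star:
resolutions of those polytomies by an inferred binary tree are arbitrary
by construction, which the scoring must (and does) tolerate.

**Sequence evolution.** Genes are random stop-free codon sequences
(length ~ N(180, 36) codons, floored at 60) evolved down the tree under a
uniform nucleotide model: the number of events on a branch is
Poisson(rate × branch length × sites); each event hits a uniform site and
substitutes a uniform alternative base, so expected identity at divergence
d has the closed form 1/4 + 3/4·e^(−4d/3) (97.06% at d = 0.03), which the
tests verify to 0.5 percentage points. Substitutions creating in-frame
stops are redrawn. Indels are codon multiples (1–2 codons,
insertion/deletion balanced) at `indel_rate` = 0.001 events/site.

**Purifying selection.** Conserved families accept a proposed
nonsynonymous substitution with probability `nonsyn_acceptance` = 0.1
(rejected proposals are redrawn, so the realized nucleotide substitution
count keeps its Poisson law while events concentrate on synonymous
sites). This mirrors the empirical fact that core genes of congeneric
bacteria retain high protein identity (here ~0.88 between groups, ~0.79
to the outgroup) while their nucleotide identity spans the species
boundary; without it, uniform mutation at the ANI-calibrated divergences
would push protein identity far below anything real core genes show, and
the homogeneity filters would sit exactly at their thresholds instead of
cleanly separating conserved from fast-evolving families.

**Planted features and their rationale.**

* *Hypervariable families* (10% of core-sized families, ceiling) evolve at
  5 × the nucleotide rate with 3 × the indel rate and the same selection.
  At the default divergences their between-group protein identity falls to
  ~0.35–0.55, below the clustering floor, so they fragment into per-group
  clusters and fail core selection on occupancy; their within-group
  alignments also exercise the trimmer. (A family that both stays
  connected at ≥ 0.6 identity and scores below 0.8 functional homogeneity
  over this group-size distribution is mathematically nearly impossible —
  the homogeneity examples are therefore unit-tested on constructed
  alignments.)
* *Paralogs* (10%): one random ingroup genome receives a second, 1%-
  diverged copy — rejected from the core by the single-copy filter.
* *Specific families*: two per group, one shared by the first two groups,
  one shared by all ingroup groups; each evolved only on its group-set's
  subtree. A fraction (1 − `specific_occupancy`, default 20%) of the
  copies is "annotation-missed": present in the proteome files (the
  enrichment pool) but withheld from the clustering input, so candidate
  detection sees partial occupancy and only enrichment can complete the
  group.
* *Clones* (2): near-copies (0.2% divergence) of members of the largest
  group, giving the dereplication step genuine ≥ 99% ANI clusters.
* *HGT events* (3): a recipient's copy of a clean-core family is replaced
  by a donor copy from another group, mutated under selection and redrawn
  until protein identity to the donor stays ≥ 98.5% (the planted-truth
  contract is ≥ 98%).

**What the generator does not model:** codon usage, rate heterogeneity
across sites beyond the fast class, rearrangements, realistic intergenic
content (spacers are shared random sequence evolved like neutral DNA),
contamination or assembly fragmentation. Passing tests therefore show the
algorithms recover planted structure under the stated regimes, not that
they are robust to assembly noise or annotation error beyond the modelled
withholding.

## Ortholog clustering and core-gene filters

All-vs-all protein comparison is prefiltered by shared amino-acid 5-mers;
surviving pairs are scored with global edit-distance identity
(1 − distance / max length, computed with edlib) and single-linkage
clustered at `min_identity` = 0.6. The floor is the one free parameter of
this stage: random same-length proteins score ≤ ~0.27 under this identity,
conserved families stay ≥ ~0.79 even to the outgroup, and fast-evolving
families (0.35–0.55) deliberately fragment. Clustering is deterministic:
cluster ids follow first-appearance order of the sorted (genome, sequence)
entries.

Core selection keeps clusters that are present in 100% of the taxa,
single-copy everywhere, and score ≥ 0.8 on both homogeneity indices:

* geometric = 1 − (column, pair) incidences where exactly one of the pair
  is gapped, over columns × pairs;
* functional = fraction of both-residue incidences whose residues share a
  biochemical class ({AVLIMC}, {FWYH}, {STNQ}, {KR}, {DE}, {G}, {P};
  anything else is its own class).

Both indices are invariant to row and column permutations. At threshold
0.8 they correspond literally to "less than 20% discordant gap insertions"
and "less than 20% cross-class substitutions".

## Alignment, trimming, supermatrix

Families are aligned progressively: a UPGMA guide tree on 3-mer distances
orders profile merges; each merge aligns the two profiles' column
consensuses with an affine-gap pairwise aligner (BLOSUM62, open −11,
extend −1 for protein; +1/−1, open −6 for DNA) and projects the gaps into
all rows. On low-divergence families this consensus-merge strategy is
indistinguishable from full profile-profile alignment and it keeps every
pairwise step in C-speed code; the pairwise optimum is verified against
brute-force enumeration of all alignments on short strings.

Conserved-site selection keeps columns with gap fraction ≤ 0.2 and
normalised Shannon entropy ≤ 0.5 (base-2 over non-gap residues, divided
by log2 of the alphabet size; both cutoffs inclusive, which the 50/50 DNA
column at exactly 0.5 pins down). Trimming is idempotent.

Back-translation maps each aligned residue onto its codon ('-' → '---'),
tolerating exactly one trailing stop codon. Concatenation fills absent
taxa with '?', which is the only character counted by `missing_fraction`
(alignment gaps are not missing). Coordinates are 0-based half-open
internally; the RAxML-style partition file is 1-based inclusive.

## Trees and support

Distances: Poisson-corrected −ln(1 − p) for protein (p clamped at 0.95)
and Kimura two-parameter for DNA, both over shared non-gap, non-missing
sites. Neighbor joining follows the Saitou–Nei Q criterion with
lexicographic tie-breaking and zero-floored branch lengths; on additive
matrices it provably recovers the generating topology, which the tests
confirm against exhaustive topology enumeration with a four-point-
condition oracle on up to six taxa.

Bootstrap: columns resampled with replacement to full length, one NJ tree
per replicate, bipartition percentages mapped onto the full-data tree.
Gene jackknife: per replicate, genes (canonically sorted by id) are drawn
uniformly without replacement until the cumulative trimmed length first
reaches the target (default 80% of the total, the analogue of ~70,000 of
85,654 positions); the replicate trees are summarised by extended
(greedy) majority-rule consensus with occurrence percentages as support.
Bipartitions are encoded everywhere as the frozen leaf-set on the side
excluding the lexicographically smallest taxon.

Topology agreement with the generating tree is scored by a
polytomy-tolerant distance: generating-tree bipartitions missing from the
inference plus inferred bipartitions incompatible with the generating
tree. This equals Robinson–Foulds on binary trees and scores 0 for any
resolution of the planted within-group stars; clone leaves (grafted after
tree construction) are pruned before comparison. The outgroup-removal and
dereplication controls compare the reduced inferences against the
generating structure restricted to the surviving taxa.

## ANI and dereplication

A query is cut into non-overlapping 1 kb fragments. Each fragment is
seeded onto the reference by exact 16-mers (sampled every 16 bp, with an
exhaustive retry before declaring failure, both strands), the modal
seeding diagonal defines a padded window, and the fragment is aligned
into the window with edlib (infix mode); identity = 1 − edit distance /
fragment length. ANI is the mean identity of mapped fragments, undefined
if none maps; the matrix is symmetrised by the mean of the two
directions. The estimator lands within 0.15 percentage points of the
Jukes–Cantor expectation at planted divergences 0.01–0.13. At the
default regimes within-group ANI is ≥ 96%, between-group ≤ 84%, and
outgroup pairs mostly fail to seed — which is itself informative, as
sub-80% ANI estimates are unreliable for any fragment-mapping method.

Species blocks are connected components of the ≥ 95% graph; raising the
threshold can only refine blocks. Dereplication single-links at 99% and
keeps the genome maximising completeness − 5 × contamination +
0.5 log₁₀ N50 (ties: lexicographic accession) — a reduced form of the
standard dereplication score using exactly the metadata the study's
Table provides.

## Specific genes

Candidates for a genome set must occur in ≥ ⌈0.6 × set size⌉ members
(ceiling, so 3 of 5 qualifies) and in zero study genomes outside the set
(outgroup included). Enrichment adds a pool sequence when its best hit
among family members reaches 0.4 identity over 0.5 length-coverage and —
when the annotated study proteomes are supplied — its best study-wide hit
is itself a family member. Confirmation requires all members present and
still no study outsiders; additionally, any annotated study sequence from
outside the set matching the family at the enrichment gate disqualifies
it (the cross-group homology control — this is what stops per-group
fragments of fast-evolving families from masquerading as specific genes).
The scan covers single groups, all pairs, the all-groups union and every
internal clade of the species tree, deduplicated by genome set; a family
confirmed for nested sets is reported for the smallest (then
lexicographic name). Breadth classification counts non-study member
genomes: none = unique, one = shared with one other, else shared with
many.

## HGT screen

For each protein, the best hit in any genome of a different taxon is a
candidate when identity ≥ 98% and the shorter/longer length ratio ≥ 0.95
(global alignment covers both sequences end to end). On synthetic truth
the screen recovers every planted transfer; hits mirrored by the donor's
group-mates against the transferred copy are counted as the same event,
not false positives. The gene-tree check midpoint-roots the family tree:
focal-taxon monophyly = congruent; a smallest focal-spanning clade
admixing exactly one other taxon names that taxon; two-taxon trees — and
spanning clades crossing several taxa — are indeterminate, matching the
cases a manual species-tree comparison cannot call.

## Annotation statistics

Quartiles use linear interpolation at positions 1 + p(n − 1) (the numpy
default) — the one convention that reproduces the printed interquartile
ranges (46 on the 37 unannotated lengths, 202.25 on the 70 annotated
ones) — and "above 100 aa" is implemented inclusively (≥ 100), the only
reading consistent with the printed count of six. The source table's one
ambiguous row (no mapping tool, category "Function unknown") is loaded as
a database hit with unspecified tool; only blank-tool/"Unknown" rows
count as unseen in databases, which reproduces the printed 37.

## Problem sizes and determinism

The full-scale validation community holds 78 genomes (76 mirroring the
study plus two clones) of ~48 genes each; one end-to-end run with 100
bootstrap and 100 jackknife replicates takes a few minutes on one CPU.
The multi-seed robustness sweep uses a reduced community (3 groups,
10 ingroup genomes, 12 core-sized families, 10 + 10 replicates) across
ten seeds; all discrete recovery properties (partition, topology, core,
specific genes, HGT) hold at both scales. Every stage draws randomness
from a sub-seed derived from the global seed and the stage name, so
results are bit-reproducible and stages can be rerun in isolation.

## Known limitations

* Edit-distance identity undercounts identity for indel-rich pairs; the
  clustering floor and enrichment gate were chosen with that bias in
  mind.
* NJ on corrected distances replaces ML inference; claims exercised here
  are topology-level. Branch lengths are distance-scale, not
  substitutions/site under a named model.
* The ANI estimator is not calibrated against reference implementations
  on real genomes; its contract is accuracy under the uniform-substitution
  model, verified against the closed form.
* The specific-gene enrichment cannot detect homology below ~30% identity
  (the random-score floor of edit-distance identity); truly unrecognisable
  homologs would be reported as specific, exactly as database searches in
  real pipelines report them as unknowns.
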