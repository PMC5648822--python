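# Methods

This note documents the models and algorithms implemented in
`syntelog-phylo`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that make
runs reproducible.

## Coordinates and ranks

Internal genomic coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted at the I/O boundary and converted back on write, so printed
coordinates round-trip exactly. The synteny coordinate of a gene is its
*rank* — the 0-based order index along its chromosome, assigned by start
coordinate with ties broken lexicographically by gene id. Rank-space
chaining mirrors gene-order-based synteny tools and makes the gap parameter
independent of intergenic distances.

## Synteny: anchors, chaining, quota, syntelogs

Homology hits (BLAST outfmt 6) are thresholded at `max_evalue` (default
1e−5) and `min_identity_pct` (default 85); the best-bitscore hit per gene
pair becomes an *anchor*. Per chromosome pair and orientation, the best
chain is found by dynamic programming over anchors sorted by `(rank_a,
rank_b)`: an anchor may extend a chain iff both rank gaps lie in
`[1, max_gap_ranks]` (default 20) in the orientation's direction. Chains are
scored by anchor count (no gap penalty). Blocks are extracted greedily —
best chain first, its anchors removed, repeat — until the best remaining
chain is shorter than `min_anchors_per_block` (default 5). The count/gap
defaults follow common collinearity-tool practice; both are configurable.

Equal-count chains are disambiguated first by total anchor bitscore, then by
smaller start rank. The bitscore tie-break matters when a diverged paralog
copy sits one rank away from the true gene: both candidate anchors would
support chains of equal length, and preferring the higher-bitscore (less
diverged) anchor resolves the tie toward the true ortholog instead of
leaving the outcome to input order.

The 1:1 quota filter accepts blocks in decreasing score order and rejects
any candidate whose rank span overlaps an accepted block's span — same
chromosome, either genome — by more than `overlap_tolerance` (default 0).
This greedy rule approximates the exact integer-programming formulation of
quota-constrained alignment; it is deterministic and sufficient for the
1:1 case. Quotas other than 1:1 are explicitly unimplemented.

Finally, anchor pairs of the accepted blocks become syntelog candidates, and
any gene appearing in more than one candidate pair causes removal of *all*
pairs containing it. The output therefore satisfies a strict 1:1 invariant
by construction.

## Transcript assignment

Transcript-vs-reference hits pass the same E-value/identity thresholds
(85% / 1e−5 by default; for taxonomically broader data sets the looser
1e−4 / 75% is available as plain parameters), then each transcript is
reduced to its single best-scoring reference gene so one transcript can
never populate two groups. The multi-mapping discard rule then applies per
(reference gene, species): exactly one mapped transcript becomes the
member; two or more distinct transcripts remove the species from that gene
entirely. The rule deliberately sacrifices completeness for purity — the
multi-mapped case is exactly where assembly redundancy or recent
duplication makes the orthology call unsafe. Isoforms must be collapsed
upstream (e.g. keep one transcript per assembled component).

Occupancy is computed against the *configured species roster*, not the
species observed in hits, so a taxon that dropped out entirely still counts
against every gene. The occupancy filter runs in exactly one of two modes:
fraction (`occupancy >= f`, default 0.90, boundary inclusive within 1e−12)
or minimum species count (full-matrix analyses use `min_species =
n_species`).

## Matrices and the internal tree engine

Genes are concatenated in lexicographic gene-id order; missing species are
gap-filled and a 1-based inclusive partition table is emitted (RAxML-style
`name = start-end` lines). The internal engine is distance-based:
p-distances with pairwise deletion of gap sites (pairs with zero comparable
sites are flagged missing and rejected by the tree builder), neighbor
joining (scikit-bio's implementation, negative branch lengths clamped to
zero), and a column-resampling bootstrap whose per-branch support is the
percentage of replicates containing the same bipartition. The engine exists
so the pipeline is self-contained and fast; it is *not* a substitute for
maximum-likelihood or quartet-based inference on real data, and adapter
hooks accept a mafft-compatible aligner or external tree tools where those
are wanted. Bootstrap default is 100 replicates, seeded from the
configuration.

## Tree comparison

A bipartition is stored canonically as the leaf set on the side not
containing the lexicographically smallest taxon, so equal splits compare
equal regardless of rooting. RF distance is the symmetric difference of
nontrivial split sets after pruning both trees to their shared leaves
(pairs sharing fewer than 4 leaves are undefined and skipped by callers);
normalised RF divides by 2(n−3), the binary-tree maximum. Polytomous trees
divide by the same constant, keeping values in [0, 1] as an upper-bounded
fraction. Two splits are compatible iff one of their four pairwise
side-intersections is empty.

Topology binning prunes all trees to the common taxon set, takes each
tree's splits at the support cutoff (default 100, i.e. only maximally
supported branches constrain), and greedily assigns trees in sorted-id order
to the first bin whose combined split set is compatible; since all splits
live on one taxon set, pairwise compatibility of the union guarantees the
bin stays jointly compatible. Greedy first-fit in canonical order is
deterministic but order-sensitive in principle; the number of bins on real
data should be read as a reproducible summary, not a uniquely defined
statistic. A branch with no recorded support fails any explicit cutoff (it
cannot certify the cutoff), which matches engines that always emit supports.

Bins can be labelled against named reference topologies (split sets): a bin
matches iff it contains every reference split and contradicts none;
references must be mutually exclusive, and unconstrained bins report
`unresolved`.

## Block-coherence permutation test

Per block, the statistic is the mean (optionally median) pairwise normalised
RF among its gene trees. The null re-assigns the pooled trees to blocks
uniformly at random, preserving block sizes (a permutation of the label
vector), recomputing every block's statistic per permutation; the default is
80,000 permutations. The p-value is one-sided lower-tail with the +1
correction, p = (1 + #{perm ≤ obs}) / (1 + n_perm), so p ∈ [1/(n_perm+1), 1]
and a degenerate pool (all trees identical) yields p = 1 everywhere.
Comparisons with fewer than 4 shared taxa contribute no value in either the
observed or the permuted statistic, so skipping cannot bias the test. The
mean was chosen as the simplest location summary of a distance
distribution; the median is offered because heavy-tailed distance sets can
occur with very discordant pools. Genes are canonicalised by sorted id
before any randomness, making p-values independent of input order and
bitwise reproducible for a given seed. Internally the pairwise RF matrix is
computed once and permutations are evaluated by vectorised indexing, so
80,000 permutations over tens of blocks take seconds.

Significance stars follow the ladder *** < 0.001, ** < 0.01, * < 0.05.

## Benchmark comparison

The benchmark set is built from pairwise 1:1 syntelog tables keyed by a
pivot genome; a group is the pivot gene plus its partner in every genome
whose table contains it (groups of size ≥ 2 kept). Any gene appearing in
two groups is an integrity error, so membership lookup is a function. A
predicted group agrees when its benchmark-resident genes all map to one
benchmark group and — in the default strict mode — that group holds no
conflicting member for any genome the prediction covers; the relaxed
`membership` mode drops the second clause. Groups with fewer than two
resident genes are unjudgeable: the benchmark can say nothing about genes
it does not contain, so they count as non-agreeing in the all-groups
denominator, are excluded from the in-benchmark denominator, and are
tallied separately. Note that the excluding-denominator percentage is *not*
guaranteed to dominate the all-groups percentage.

## Synthetic data generator

The generator defines the package's study conditions.

* **Genome pair** — genome B is genome A's gene order transformed by
  losses, inversions, translocations, and tandem/dispersed duplications.
  Rearranged segments default to 45–80 genes: long enough that a single
  anchor inside an inverted segment cannot "bridge" the forward chain
  across it at the default gap window (a bridge makes the flanking block's
  span swallow the inversion and the 1:1 quota then discards the true
  inverted block — with shorter segments the truth becomes unrecoverable
  for any span-based quota filter). Tens-of-genes inversions are also the
  realistic scale for the grass genomes this design emulates. Duplicate
  copies are registered as paralog decoys; their hit identities are drawn
  around 80% (sd 3), straddling the 85% cutoff so that a handful survive
  hit filtering and must be rejected by chaining/quota rather than by the
  identity threshold alone. Ortholog hits are drawn around 92% (sd 1.5).
* **Gene trees** — the standard multispecies coalescent with one haploid
  sample per species: within every species-tree branch, k lineages coalesce
  with Exponential(k(k−1)/2) waiting times in coalescent units; root
  lineages coalesce freely. Block-coherent discordance: each block may name
  an alternative species topology and a coherence γ, and every gene of the
  block draws its genealogy from the alternative with probability γ. The
  rooted-triplet discordance probability (2/3)e^(−t) and the Exp(1)
  pairwise coalescence time are verified against simulation in the test
  suite.
* **Sequences** — JC69 on nucleotides, root uniform, per-branch
  substitution probability (3/4)(1 − e^(−4d/3)); richer substitution models
  would add nothing to what the pipeline tests, which only consumes
  distances and identities. The default rate scaling (0.002 substitutions
  per site per coalescent unit) with species-tree increments of 5 units
  keeps transcript identities near 92%, comfortably above the default 85%
  cutoff, while giving concatenated matrices ample signal.
* **Hit tables** — E-values and bitscores are monotone deterministic maps of
  identity and length, not Karlin–Altschul statistics; the pipeline only
  thresholds and ranks them. Identities derive from the simulated p-distance
  plus Gaussian noise.

What the generator does **not** emulate: assembly artifacts and isoform
structure, amino-acid (vs nucleotide) identity as in real protein-level
BLAST, rate variation across sites and lineages, tandem arrays larger than
one copy, and base-pair-resolution breakpoints. Passing tests therefore
demonstrate the pipeline's algorithmic correctness and statistical
calibration under its stated model, not robustness to assembly noise.

## Problem sizes and numerical conventions

The test and acceptance workloads run at deliberately moderate scale —
anchor genomes of 3×400 genes, 10 species × 300 genes end to end,
permutation calibration over 200 simulated data sets at 2,000 permutations
and power at 10,000 — sizes at which every statistical check retains its
meaning while the whole suite completes in about a minute. All randomness
flows from explicit seeds (`numpy.random.default_rng`; the acceptance
script derives per-component seeds from one `SeedSequence`); identical
seeds give byte-identical outputs, including file artifacts. Newick support
values on [0, 1] are rescaled to [0, 100] when all supports are ≤ 1; branch
lengths and supports are printed with `%.6g`. Floating-point boundary cases
are handled inclusively (occupancy at exactly the threshold passes;
permutation counting uses a 1e−12 tolerance so exact ties count as ≤).

## Known limitations

* The greedy quota filter can differ from the exact optimum on adversarial
  overlap patterns; for 1:1 screening of real genome pairs the difference is
  immaterial, but exact quota optimisation is out of scope.
* Only the 1:1 quota is supported; polyploid-aware quotas (2:1, 2:2) are
  rejected explicitly.
* The internal NJ engine is a stand-in for likelihood-based inference in
  self-contained runs; branch supports from 100 bootstrap replicates on
  short genes are coarse.
* Binning implements the compatibility partition, not balanced
  graph-coloring binning with per-bin weighting.
* Rooting of gene trees is left to the user; all comparisons here are on
  unrooted topologies.
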