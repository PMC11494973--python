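# Methods

This note records the models, defaults and design choices behind
nano16s, and what the synthetic-data tests do and do not demonstrate
about real sequencing data.

## Amplicon model and simulator

A barcoded amplicon is
`fwd_bc (12 bp) + fwd_primer + insert + rc(rev_primer) + rc(rev_bc)`.
With the default full-length 16S primer pair (27F/1492R, 20 + 19 bp,
degenerate positions resolved to one concrete base per synthesised
oligo) and a 1,500-bp insert this gives a 1,563-bp molecule, matching
the ~1.6 kb fragments such protocols target. In 1BC mode the same
barcode flanks both ends; in 2BC mode combinatorial (fwd, rev) pairs
multiplex up to `n_barcodes²` samples per native pool. Native-pool
demultiplexing (the ONT library barcode) is modelled as the per-pool
input file, not re-implemented.

The read channel applies, per template position, one of
{delete, substitute, pass} and then an optional single-base insertion
after each retained base; a read is reverse-complemented with
probability `flip_prob`. Defaults — `sub = 0.02`, `ins = 0.01`,
`del = 0.01`, `flip = 0.5`, qualities ~ N(14, 3) clipped to [1, 50] —
emulate recent-chemistry simplex nanopore data (mean read quality near
Q14, per-base error around 4 %). Deviations from real nanopore data,
deliberate for tractability:

* errors are i.i.d. per base — no homopolymer or k-mer context effects;
* quality strings are drawn independently of the introduced errors, so
  qualities carry the correct marginal distribution but no per-base
  error information (the filter only uses the marginal);
* no chimeras by default (`chimera_rate` exists for adversarial
  fixtures) and no duplex read pairs.

Consequently, passing tests show the pipeline's logic is correct under
a rate-faithful error model; they do not certify yields on real
flow-cell data, where context-dependent errors make primer and barcode
survival correlated.

Synthetic reference databases are star phylogenies: one uniform random
ancestor, each taxon substituted per site at rate `divergence`
(default 0.1, roughly genus-level 16S spread). Barcode sets are drawn
with pairwise Hamming distance ≥ 6 so that the barcode-call tolerance
(≤ 2 mismatches) cannot produce collisions.

## Filtering

Reads are kept when `1300 ≤ length ≤ 1800` and the
error-probability-averaged quality `−10·log10(mean 10^(−q/10))`
is **strictly greater than** 9. Error-probability averaging matches
long-read filtering practice (one low-quality stretch dominates); the
strict inequality follows the threshold's usual phrasing ("quality
score > 9") and is configurable to ≥ for compatibility with tools that
use a closed bound.

## Demultiplexing

Primer localisation is an ungapped IUPAC-aware sliding scan: forward
orientation over the first 100 bp, reverse-complement orientation over
the last 100 bp; best hit wins, ties prefer the forward strand and the
smaller offset. A read-side `N` matches only a pattern `N` — an N
basecall is no evidence for any base. Defaults `max_primer_mismatch = 3`
(of 20) and `max_bc_mismatch = 2` (of 12) are choices, not measured
constants: they make noiseless recovery exact and, with barcode
separation ≥ 6, make cross-assignment impossible for barcode errors
alone.

Barcode calls are ungapped Hamming comparisons at the fixed 12-bp
window anchored by the primer hit; indel tolerance lives entirely in
the primer anchor. This keeps barcode calling O(#barcodes) and is the
reason demultiplexed yield drops at high indel rates (an indel inside
the barcode window defeats an ungapped comparison) while *soundness* —
no read assigned to the wrong sample — is preserved, which is the
property the acceptance suite asserts.

In 1BC mode the reverse barcode is not required, but when the reverse
window is readable and calls a *different* barcode uniquely within
tolerance, the read is discarded as `conflicting` (purity over yield).
One consequence: assigned counts are provably monotone in
`max_bc_mismatch` in 2BC mode, but in 1BC mode a larger tolerance can
surface a contradicting reverse call and discard a previously assigned
read; the monotonicity property is therefore asserted for 2BC.

Reads barcoded 1BC demultiplex identically in 2BC mode, since the
identical pair is one point of the combinatorial space — this
equivalence is tested on noiseless reads.

## EM annotation

`score_reads` aligns each read (both strands, best kept) as an infix of
each reference with edlib and scores
`L = p_err^(mismatches+indels) · (1−p_err)^matches`, `p_err = 0.1`
fixed — a fixed error rate keeps the toy likelihood identifiable.
References whose best alignment matches < 80 % of the read's bases are
non-candidates: edit-distance alignments of unrelated random DNA cannot
match much above the longest-common-subsequence fraction (~0.65 for
4-letter alphabets), while genuine templates at simulated error rates
sit above 0.9, so the threshold separates cleanly. Likelihoods are
computed in log space and rescaled per read before exponentiation; EM
is invariant to per-read scaling and 1.5-kb reads would otherwise
underflow.

EM initialises uniformly over supported taxa, iterates to
`tol = 1e-6` on the max abundance change (cap 100 iterations), drops
taxa below `min_abundance = 1e-4` and renormalises. Estimated read
counts are `f_t · n` over reads with a non-empty candidate set; reads
with empty candidate sets count toward `total_reads` but not the
mixture. The per-iteration log-likelihood history is exposed and
asserted non-decreasing in tests. This module reproduces the *role* of
EM-based 16S profilers (correct species, calibrated proportions at desk
scale), not any specific tool's probability model or database.

## Metrics

* Pool efficiency: reads assigned a PCR barcode (pair) / total reads in
  the native pool.
* Isolate gates: depth ≥ 10 reads, purity ≥ 0.90 (abundance of the top
  species); both configurable. Note the asymmetry with consensus bins,
  which require **> 10** reads — each rule follows its own convention.
* PPV = TP/(TP+FP); sensitivity/specificity are not computable without
  true negatives and are not reported.
* Cramér's V uses the Pearson χ² without continuity or bias correction
  (the common default in association-analysis packages); zero marginal
  rows/columns are dropped first. Theil's U uses natural-log entropies
  and takes an explicit `direction` argument rather than guessing a
  conditioning order.
* Alpha diversity: richness, Shannon in nats (`−Σ p ln p`),
  Berger-Parker (max p). An empty profile reports (0, 0, 0) by
  convention, documented rather than raised, so batch reports stay
  total.
* Bray-Curtis on relative abundances: `1 − Σ min(p, q)` over the union
  of taxa. Symmetry, range and identity-of-indiscernibles are asserted;
  it is a dissimilarity, not a metric.
* PERMANOVA: standard one-way pseudo-F on squared distances with
  seeded label permutations and `p = (1 + #{F* ≥ F}) / (1 + n_perm)`.
  Permutation comparisons are made on SS_within (F is monotone
  decreasing in it and SS_total is permutation-invariant), which keeps
  the test defined when observed within-group scatter is zero. The
  implementation is cross-checked against scikit-bio's in tests.
* Rarefaction: one multivariate-hypergeometric draw (seeded), i.e.
  subsampling without replacement.

## Consensus and phylogeny

Greedy clustering processes reads longest-first (ties by read id) and
joins the first bin whose centroid identity
(matches / alignment columns, global alignment) reaches the threshold
(default 0.97 — within-species nanopore reads clear it, 10 %-diverged
templates do not). Bins of ≤ 10 reads are discarded. Consensus is a
per-column majority vote against the centroid, ties keeping the
centroid base; insertions are kept only where > 50 % of members carry
one. This replaces neural polishing with a transparent, dependency-free
scheme adequate at these error rates (tests require the consensus
within 1 edit of the truth at 3 % substitutions, 30 reads).

Distances between consensus sequences are `1 − identity` with identity
= matches / alignment length including gap columns (pinned for
reproducibility; a matches/shorter-length variant would differ on
length-heterogeneous inputs). Neighbor joining is the canonical
Q-matrix algorithm with the standard branch-length formulas; negative
lengths are clamped to zero with the deficit moved to the sibling edge,
and Q-ties break on the lexicographically smallest leaf-label pair.
NJ is exact on additive matrices, which the test suite exploits as an
oracle (random additive trees, n ≤ 8, topology and all path lengths
recovered to 1e-9); topology is also cross-checked against
scikit-bio's NJ.

Bootstraps resample columns of a star alignment (every sequence
projected onto the longest one; insertions relative to the reference
dropped). A star alignment is cruder than a progressive MSA, but it
yields the fixed column set bootstrap needs and is deterministic.
Supports are the fraction of replicates containing each internal
bipartition and are serialised as internal node labels in newick.

## Problem sizes

Simulated studies use 8-sample pools at 100 reads/sample (~1.6-kb
reads), 600-read EM mixtures, 200-replicate PERMANOVA null calibrations
at 199 permutations, and 1,000-column bootstrap alignments at 100
replicates — sizes at which every property under test is already
exercised end-to-end while the full suite runs in well under a minute.

## Known limitations

* Ungapped barcode matching caps demultiplexed yield at high indel
  rates; real pipelines recover some of these reads with gapped barcode
  alignment.
* The EM likelihood ignores base qualities and alignment positions.
* The star-alignment bootstrap underestimates alignment uncertainty
  relative to a progressive MSA.
* Native-barcode (library-level) demultiplexing, basecalling and signal
  processing are entirely out of scope.
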