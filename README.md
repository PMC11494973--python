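# nano16s

A toolkit for barcoded full-length 16S rRNA amplicon sequencing on
nanopore platforms. It covers the complete desk-side analysis path for
runs in which each sample's 16S amplicon carries a 12-bp PCR barcode on
one or both primers (the single-barcode **1BC** and double-barcode
**2BC** layouts), pools of barcoded amplicons share a native library
barcode, and species-level identification is obtained by aligning reads
against a 16S reference database.

It is written for microbiologists and bioinformaticians who need to:

* **simulate** barcoded amplicon pools with a ground-truth sidecar
  (read layout `barcode + primer + 16S insert + rc(primer) + rc(barcode)`,
  ~1.6 kb, configurable substitution/insertion/deletion error channel);
* **filter** reads by length (default 1,300–1,800 bp) and
  error-probability-averaged quality (default mean Q > 9);
* **demultiplex** each native pool by PCR barcode (pair), with IUPAC-aware
  primer anchoring, strand canonicalisation and primer/barcode trimming;
* **annotate** each demultiplexed sample with species-level relative
  abundances by expectation-maximization over read-to-reference
  alignment likelihoods;
* **evaluate** runs: pool demultiplexing efficiency, depth (≥ 10 reads)
  and purity (≥ 90 %) gates for isolate calls, PPV / Cramér's V /
  Theil's U concordance with an orthogonal method, alpha diversity
  (richness, Shannon, Berger-Parker), Bray-Curtis beta diversity,
  PERMANOVA and rarefaction;
* **build consensus sequences and trees**: greedy centroid clustering,
  majority-vote consensus per read bin (> 10 reads), pairwise
  alignment-identity distances, neighbor joining with bootstrap supports,
  newick output.

## The core model

Demultiplexing assigns a read to sample *s* when both primers are found
(ungapped IUPAC-aware scan, ≤ 3 mismatches within a 100-bp end window)
and the 12-mers flanking them match barcodes *(b_f, b_r)* with Hamming
distance ≤ 2, uniquely at the minimal distance, with
*(pool, b_f, b_r) → s* in the scheme layout.

Annotation treats the sample composition **f** as mixture weights: read
*r* has likelihood `L[r,t] = p_err^errors · (1−p_err)^matches` under
taxon *t* (best-strand alignment; `p_err = 0.1`), and EM iterates

```
P(t|r) ∝ f_t · L[r,t]          (E-step)
f_t    = mean_r P(t|r)         (M-step)
```

until the abundances stabilise; the observed-data log-likelihood is
non-decreasing at every step. References matching < 80 % of a read's
bases are excluded from its candidate set.

## Worked example

```python
import nano16s as n16

scheme = n16.make_scheme(8, mode="2BC", seed=11)
db = n16.make_reference_db(8, seq_length=1500, divergence=0.1, seed=12)
model = n16.ErrorModel(sub_rate=0.02, ins_rate=0.01, del_rate=0.01, flip_prob=0.5)

records, truth = n16.simulate_pool(scheme, db, 100, model, seed=13)
kept, rejected = n16.filter_reads(records)
table, by_sample = n16.demultiplex_pool(kept, scheme, "pool01")
print(n16.pool_efficiency(table, "pool01").efficiency)
```

Running `python examples/01_simulate_and_demultiplex.py` prints:

```
simulated 800 reads across 8 samples
filter: kept 800, rejected 0 (length 1300-1800 bp, mean Q > 9)
demultiplexed 280/800 reads (pool efficiency 0.35)
cross-assigned reads vs ground truth: 0
```

800 simulated reads all pass the length/quality filter; at a 4 % total
error rate 280 still carry two intact primers and a recognisable
barcode pair (efficiency 0.35), and — the property that matters — none
of the assigned reads lands in the wrong sample. The EM example
(`examples/02_em_annotation.py`) recovers a 0.6/0.3/0.1 three-species
mixture to three decimals:

```
EM converged in 2 iterations over 600 reads
  tax001: estimated 0.600 (truth 0.6, ~360 reads)
  tax002: estimated 0.300 (truth 0.3, ~180 reads)
  tax003: estimated 0.100 (truth 0.1, ~60 reads)
```

The remaining examples cover isolate gating and concordance statistics
(`03`), community diversity and PERMANOVA (`04`) and consensus/tree
building (`05`). A thin CLI mirrors the pipeline stages:
`nano16s simulate | filter | demux | annotate | metrics | consensus | tree`
(see `nano16s --help`).

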