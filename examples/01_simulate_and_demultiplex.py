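"""Simulate a barcoded 16S amplicon pool and demultiplex it.

Builds an 8-sample double-barcode (2BC) scheme, simulates 100 nanopore-
style reads per sample at realistic error rates, filters by length and
quality, then demultiplexes by PCR barcode pair and checks the result
against the simulator's ground truth.
"""

import nano16s as n16

scheme = n16.make_scheme(8, mode="2BC", seed=11)
db = n16.make_reference_db(8, seq_length=1500, divergence=0.1, seed=12)
model = n16.ErrorModel(sub_rate=0.02, ins_rate=0.01, del_rate=0.01, flip_prob=0.5)

records, truth = n16.simulate_pool(scheme, db, 100, model, seed=13)
print(f"simulated {len(records)} reads across {len(scheme.samples_in_pool('pool01'))} samples")

kept, rejected = n16.filter_reads(records, n16.FilterParams())
print(f"filter: kept {len(kept)}, rejected {len(rejected)} (length 1300-1800 bp, mean Q > 9)")

table, by_sample = n16.demultiplex_pool(kept, scheme, "pool01")
stats = n16.pool_efficiency(table, "pool01")
print(f"demultiplexed {stats.n_pcr_demuxed}/{stats.n_total} reads (pool efficiency {stats.efficiency:.2f})")

wrong = sum(
    truth.entries[r.read_id][1] != sample for sample, recs in by_sample.items() for r in recs
)
print(f"cross-assigned reads vs ground truth: {wrong}")
print("every assigned read carries both primers and a recognisable barcode pair;")
print("unassigned reads lost a primer or barcode to simulated sequencing errors.")
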