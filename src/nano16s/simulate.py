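"""Synthetic barcoded-amplicon read generation with ground truth.

Every downstream stage of the toolkit (filtering, demultiplexing, EM
annotation, consensus building) is exercised against reads produced here.
An amplicon follows the dual-flanking layout of PCR-barcoded full-length
16S products:

    [fwd barcode][fwd primer][16S insert][revcomp(rev primer)][revcomp(rev barcode)]

so a 12-base barcode sits immediately 5' of each primer binding site on
both strands. Reads are the amplicon passed through a simple per-base
substitution/insertion/deletion channel, emitted on either strand, with
Gaussian per-base Phred qualities. A truth sidecar records, for every
read, its native pool, sample, template taxon and strand.

Default error rates emulate recent-chemistry nanopore simplex data: mean
read quality around Q14 (per-base error ~4%) split across substitutions
and indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    Barcode,
    BarcodeScheme,
    PrimerPair,
    ReferenceTaxon,
    SeqRecord,
    reverse_complement,
    IUPAC_BITS,
)

__all__ = [
    "ErrorModel",
    "SimTruth",
    "make_reference_db",
    "make_barcodes",
    "make_scheme",
    "resolve_degenerate",
    "construct_amplicon",
    "simulate_reads",
    "simulate_pool",
]

_BASES = np.array(list("ACGT"))

#: concrete bases encoded by each IUPAC letter
_IUPAC_SETS = {
    code: [b for i, b in enumerate("ACGT") if IUPAC_BITS[code] >> i & 1]
    for code in IUPAC_BITS
}

# Standard full-length 16S primer pair (27F / 1492R), degenerate positions
# included; used as the default primer pair for simulated schemes.
DEFAULT_FWD_PRIMER = "AGRGTTYGATYMTGGCTCAG"
DEFAULT_REV_PRIMER = "RGYTACCTTGTTACGACTT"


@dataclass
class ErrorModel:
    """Per-base read error channel plus quality-string distribution.

    Rates are fractions per base; ``flip_prob`` is the probability a read
    is emitted reverse-complemented (library molecules are sequenced from
    either strand). Quality strings are drawn independently of the
    introduced errors — the filter stage only needs the marginal Q
    distribution.
    """

    sub_rate: float = 0.02
    ins_rate: float = 0.01
    del_rate: float = 0.01
    mean_quality: float = 14.0
    quality_sd: float = 3.0
    flip_prob: float = 0.5
    chimera_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("flip_prob", "chimera_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ValueError("sub_rate + ins_rate + del_rate must be < 1")

    @classmethod
    def noiseless(cls) -> "ErrorModel":
        return cls(sub_rate=0.0, ins_rate=0.0, del_rate=0.0, flip_prob=0.0)


@dataclass
class SimTruth:
    """Ground-truth sidecar: read_id -> (native pool, sample, taxon, strand)."""

    entries: dict[str, tuple[str, str, str, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"read_id": rid, "native_pool": p, "sample": s, "taxon": t, "strand": st}
            for rid, (p, s, t, st) in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=["read_id", "native_pool", "sample", "taxon", "strand"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            {
                r["read_id"]: (r["native_pool"], r["sample"], r["taxon"], r["strand"])
                for _, r in df.iterrows()
            }
        )


def make_reference_db(
    n_taxa: int,
    seq_length: int = 1500,
    divergence: float = 0.1,
    seed: int | None = None,
) -> list[ReferenceTaxon]:
    """Generate a toy 16S reference database by star-shaped divergence.

    One random ancestor sequence is drawn uniformly over A/C/G/T; each
    taxon substitutes every site independently with probability
    ``divergence`` (to one of the three other bases). Two taxa therefore
    differ at a site with probability ``2d(1-d) + d^2 * 2/3``.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not (0.0 < divergence <= 0.5):
        raise ValueError("divergence must be in (0, 0.5]")
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=seq_length)
    taxa = []
    for i in range(n_taxa):
        mutate = rng.random(seq_length) < divergence
        shift = rng.integers(1, 4, size=seq_length)
        derived = np.where(mutate, (ancestor + shift) % 4, ancestor)
        seq = "".join(_BASES[derived])
        tid = f"tax{i + 1:03d}"
        taxa.append(ReferenceTaxon(tid, f"Synthetica species{i + 1}", ["Bacteria", "Synthetica"], seq))
    return taxa


def make_barcodes(n: int, seed: int | None = None, min_hamming: int = 6) -> list[Barcode]:
    """Draw ``n`` random 12-mer barcodes with pairwise Hamming distance >= ``min_hamming``.

    Rejection sampling; 12-mers at distance >= 6 are plentiful, so this
    terminates quickly for the pool sizes used in practice (<= ~100).
    """
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not generate enough well-separated barcodes")
        cand = rng.integers(0, 4, size=12)
        if all(int((cand != c).sum()) >= min_hamming for c in chosen):
            chosen.append(cand)
    return [Barcode(f"BC{i + 1:02d}", "".join(_BASES[c])) for i, c in enumerate(chosen)]


def make_scheme(
    n_samples: int,
    mode: str = "2BC",
    n_pools: int = 1,
    seed: int | None = None,
    primers: PrimerPair | None = None,
) -> BarcodeScheme:
    """Build a simulated barcode scheme covering ``n_samples`` per native pool.

    1BC assigns one barcode per sample (same barcode on both primers);
    2BC walks combinatorial (fwd, rev) pairs row-by-row, mirroring a
    plate layout where each column shares a native pool.
    """
    if primers is None:
        primers = PrimerPair("A", DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER)
    if mode == "1BC":
        n_bc = n_samples
    else:
        n_bc = int(np.ceil(np.sqrt(n_samples)))
        while n_bc * n_bc < n_samples:
            n_bc += 1
    barcodes = make_barcodes(n_bc, seed=seed)
    layout: dict[tuple[str, str, str], str] = {}
    for p in range(n_pools):
        pool = f"pool{p + 1:02d}"
        for s in range(n_samples):
            if mode == "1BC":
                f = r = barcodes[s].bc_id
            else:
                f = barcodes[s // n_bc].bc_id
                r = barcodes[s % n_bc].bc_id
            layout[(pool, f, r)] = f"{pool}_s{s + 1:02d}"
    return BarcodeScheme(barcodes, primers, mode, layout)


def resolve_degenerate(primer: str, rng: np.random.Generator) -> str:
    """Replace each IUPAC degenerate position by one concrete base (sampled)."""
    out = []
    for b in primer.upper():
        options = _IUPAC_SETS.get(b)
        if options is None:
            raise ValueError(f"non-IUPAC base {b!r} in primer")
        out.append(options[0] if len(options) == 1 else options[int(rng.integers(len(options)))])
    return "".join(out)


def construct_amplicon(
    template: ReferenceTaxon,
    scheme: BarcodeScheme,
    fwd_bc: str,
    rev_bc: str,
    seed: int | None = None,
) -> str:
    """Assemble the barcoded amplicon for one template and barcode pair.

    Layout: ``fwd_bc + fwd_primer + insert + revcomp(rev_primer) + revcomp(rev_bc)``.
    Degenerate primer positions are resolved to one concrete base each
    (the synthesised oligo is a specific molecule); for synthetic
    templates the insert is the whole template sequence.
    """
    bc_map = scheme.barcode_map
    if fwd_bc not in bc_map or rev_bc not in bc_map:
        raise KeyError(f"unknown barcode id: {fwd_bc!r} or {rev_bc!r}")
    rng = np.random.default_rng(seed)
    fwd_primer = resolve_degenerate(scheme.primers.fwd, rng)
    rev_primer = resolve_degenerate(scheme.primers.rev, rng)
    return (
        bc_map[fwd_bc].seq
        + fwd_primer
        + template.seq
        + reverse_complement(rev_primer)
        + reverse_complement(bc_map[rev_bc].seq)
    )


def _apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Per-position channel: delete / substitute / pass, then insert after retained bases."""
    if model.sub_rate == 0 and model.ins_rate == 0 and model.del_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.size
    u = rng.random(n)
    deleted = u < model.del_rate
    substituted = (~deleted) & (u < model.del_rate + model.sub_rate)
    # map A/C/G/T -> 0..3 for substitution; other symbols pass through
    lut = np.full(128, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[arr]
    shift = rng.integers(1, 4, size=n).astype(np.uint8)
    sub_codes = (codes + shift) % 4
    bases_u8 = np.frombuffer(b"ACGT", dtype=np.uint8)
    out_codes = np.where(substituted & (codes != 255), sub_codes, codes)
    pieces: list[str] = []
    insert_after = rng.random(n) < model.ins_rate
    ins_bases = _BASES[rng.integers(0, 4, size=n)]
    for i in range(n):
        if deleted[i]:
            continue
        c = out_codes[i]
        pieces.append(chr(bases_u8[c]) if c != 255 else chr(arr[i]))
        if insert_after[i]:
            pieces.append(ins_bases[i])
    return "".join(pieces)


def simulate_reads(
    amplicons: list[tuple[str, tuple[str, str, str]]],
    n_reads_per_sample: int,
    model: ErrorModel,
    seed: int | None = None,
) -> tuple[list[SeqRecord], SimTruth]:
    """Emit noisy reads from labelled amplicons.

    ``amplicons`` is a list of ``(amplicon_seq, (native_pool, sample, taxon))``;
    each contributes ``n_reads_per_sample`` reads. Errors, strand flips and
    qualities are all drawn from one seeded generator, so output is fully
    deterministic given the seed.
    """
    if n_reads_per_sample < 0:
        raise ValueError("n_reads_per_sample must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[SeqRecord] = []
    truth: dict[str, tuple[str, str, str, str]] = {}
    idx = 0
    for amp, (pool, sample, taxon) in amplicons:
        for _ in range(n_reads_per_sample):
            seq = _apply_errors(amp, model, rng)
            strand = "-" if rng.random() < model.flip_prob else "+"
            if strand == "-":
                seq = reverse_complement(seq)
            quals = np.clip(
                np.rint(rng.normal(model.mean_quality, model.quality_sd, size=len(seq))),
                1,
                50,
            ).astype(int)
            rid = f"read{idx:06d}"
            idx += 1
            records.append(SeqRecord(rid, seq, quals.tolist()))
            truth[rid] = (pool, sample, taxon, strand)
    return records, SimTruth(truth)


def simulate_pool(
    scheme: BarcodeScheme,
    db: list[ReferenceTaxon],
    n_reads_per_sample: int,
    model: ErrorModel | None = None,
    pool_id: str | None = None,
    seed: int | None = None,
    taxon_choice: dict[str, str] | None = None,
) -> tuple[list[SeqRecord], SimTruth]:
    """Simulate one native pool end-to-end from a scheme and reference db.

    Each sample in the pool gets one template taxon (cycled through the
    database unless ``taxon_choice`` maps sample_id -> taxon_id) and
    ``n_reads_per_sample`` reads.
    """
    if model is None:
        model = ErrorModel()
    if pool_id is None:
        pool_id = scheme.pools()[0]
    rng = np.random.default_rng(seed)
    by_id = {t.taxon_id: t for t in db}
    amplicons = []
    pairs = scheme.samples_in_pool(pool_id)
    if not pairs:
        raise ValueError(f"scheme layout has no samples for pool {pool_id!r}")
    for i, ((f, r), sample) in enumerate(sorted(pairs.items(), key=lambda kv: kv[1])):
        if taxon_choice and sample in taxon_choice:
            taxon = by_id[taxon_choice[sample]]
        else:
            taxon = db[i % len(db)]
        amp = construct_amplicon(taxon, scheme, f, r, seed=int(rng.integers(2**31)))
        amplicons.append((amp, (pool_id, sample, taxon.taxon_id)))
    return simulate_reads(
        amplicons, n_reads_per_sample, model, seed=int(rng.integers(2**31))
    )
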