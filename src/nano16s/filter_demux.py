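"""Read filtering and PCR-barcode demultiplexing (1BC / 2BC).

The demultiplexer works per native pool (one FASTQ per pool, the native
ONT barcode split having happened upstream). Each read is:

1. oriented — the forward primer is searched on both strands and the
   read is reverse-complemented into canonical (+) orientation if needed;
2. anchored — both primers must be found (the reverse primer as its
   reverse complement near the 3' end), else the read is unassignable;
3. barcode-called — the 12 bases immediately 5' of the forward primer
   are scored by Hamming distance against every scheme barcode; in 2BC
   mode the 12 bases 3' of the reverse-primer hit are scored against the
   reverse-complemented barcodes. In 1BC mode the reverse barcode is not
   required, but when it is readable and calls a different barcode the
   read is discarded as conflicting;
4. trimmed — the retained sequence is the insert strictly between the
   two primer hits, barcodes and primers removed, forward orientation.

Barcode matching is ungapped at a fixed 12-base window: indel tolerance
is delegated to primer localisation, which anchors the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .core_io import (
    BarcodeScheme,
    SeqRecord,
    encode_pattern,
    encode_read,
    mean_read_quality,
    reverse_complement,
    write_fastq,
)

__all__ = [
    "FilterParams",
    "PrimerHit",
    "DemuxAssignment",
    "filter_reads",
    "locate_primer",
    "demultiplex_read",
    "demultiplex_pool",
    "ASSIGNMENT_COLUMNS",
]


@dataclass
class FilterParams:
    """Length window and minimum mean read quality for the pre-demux filter.

    Defaults target full-length 16S amplicons (about 1.6 kb with barcodes
    and primers): 1,300-1,800 bp and mean quality strictly greater than
    Q9. The quality comparison is strict by default; set
    ``strict_quality=False`` for a >= comparison.
    """

    min_len: int = 1300
    max_len: int = 1800
    min_q: float = 9.0
    strict_quality: bool = True

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_q < 0:
            raise ValueError("min_q must be >= 0")


def filter_reads(
    records: Iterable[SeqRecord], params: FilterParams | None = None
) -> tuple[list[SeqRecord], list[tuple[SeqRecord, str]]]:
    """Partition reads into (kept, rejected-with-reason), order preserved.

    A read is kept iff its length lies in ``[min_len, max_len]`` and its
    error-probability-averaged quality exceeds ``min_q``.
    """
    if params is None:
        params = FilterParams()
    kept: list[SeqRecord] = []
    rejected: list[tuple[SeqRecord, str]] = []
    for rec in records:
        if len(rec) < params.min_len:
            rejected.append((rec, "too_short"))
        elif len(rec) > params.max_len:
            rejected.append((rec, "too_long"))
        else:
            q = mean_read_quality(rec.quals)
            ok = q > params.min_q if params.strict_quality else q >= params.min_q
            if ok:
                kept.append(rec)
            else:
                rejected.append((rec, "low_quality"))
    return kept, rejected


class PrimerHit(NamedTuple):
    offset: int  # start of the hit in the read, read coordinates
    strand: str  # '+': primer as given; '-': reverse complement of primer
    mismatches: int


def _scan(read_bits: np.ndarray, pattern_bits: np.ndarray, start: int, stop: int) -> tuple[int, int] | None:
    """Best ungapped IUPAC-aware hit of pattern in read[start:stop]; ties -> smaller offset."""
    p = len(pattern_bits)
    if stop - start < p:
        return None
    window = np.lib.stride_tricks.sliding_window_view(read_bits[start:stop], p)
    mism = ((window & pattern_bits) == 0).sum(axis=1)
    i = int(np.argmin(mism))
    return start + i, int(mism[i])


def locate_primer(
    read_seq: str,
    primer: str,
    max_mismatch: int = 3,
    search_window: int = 100,
) -> PrimerHit | None:
    """Locate a primer in a read, checking both orientations.

    The forward orientation is scanned over the first ``search_window``
    bases; the reverse-complement orientation over the last
    ``search_window`` bases (primers sit at read ends in intact
    amplicons). Returns the lowest-mismatch hit with
    ``mismatches <= max_mismatch``; ties prefer the '+' orientation and
    the smaller offset. ``None`` means absence, which is a value, not an
    error.
    """
    if search_window < len(primer):
        raise ValueError("search_window must be >= primer length")
    read_bits = encode_read(read_seq)
    fwd_bits = encode_pattern(primer)
    rc_bits = encode_pattern(reverse_complement(primer))
    n = len(read_seq)
    hits: list[PrimerHit] = []
    got = _scan(read_bits, fwd_bits, 0, min(search_window, n))
    if got is not None and got[1] <= max_mismatch:
        hits.append(PrimerHit(got[0], "+", got[1]))
    got = _scan(read_bits, rc_bits, max(0, n - search_window), n)
    if got is not None and got[1] <= max_mismatch:
        hits.append(PrimerHit(got[0], "-", got[1]))
    if not hits:
        return None
    return min(hits, key=lambda h: (h.mismatches, 0 if h.strand == "+" else 1, h.offset))


@dataclass
class DemuxAssignment:
    """Outcome of demultiplexing one read."""

    read_id: str
    status: str  # assigned | no_primer | no_barcode | ambiguous | conflicting
    sample_id: str | None = None
    fwd_bc: str | None = None
    rev_bc: str | None = None
    fwd_mm: int | None = None
    rev_mm: int | None = None
    reason: str = ""
    trimmed: SeqRecord | None = None


def _hamming_calls(
    window_bits: np.ndarray, candidates: dict[str, np.ndarray], max_mm: int
) -> tuple[list[str], int]:
    """Barcode ids at the minimal Hamming distance within tolerance."""
    best: list[str] = []
    best_d = max_mm + 1
    for bc_id, bits in candidates.items():
        d = int(((window_bits & bits) == 0).sum())
        if d < best_d:
            best, best_d = [bc_id], d
        elif d == best_d:
            best.append(bc_id)
    return best, best_d


def demultiplex_read(
    read: SeqRecord,
    scheme: BarcodeScheme,
    pool_id: str,
    max_bc_mismatch: int = 2,
    max_primer_mismatch: int = 3,
    search_window: int = 100,
    mode: str | None = None,
) -> DemuxAssignment:
    """Assign one quality-filtered read to a sample via its PCR barcode(s).

    ``mode`` overrides the scheme's barcoding mode: reads barcoded with a
    single barcode (1BC) can also be demultiplexed in 2BC mode, since the
    identical barcode pair is just one point in the combinatorial space.
    """
    mode = mode or scheme.mode
    fwd_primer = scheme.primers.fwd
    rev_primer = scheme.primers.rev

    # (i) orient by the forward primer
    hit_f = locate_primer(read.seq, fwd_primer, max_primer_mismatch, search_window)
    if hit_f is None:
        return DemuxAssignment(read.read_id, "no_primer", reason="fwd_primer_not_found")
    canon = read if hit_f.strand == "+" else read.reverse_complement()
    if hit_f.strand == "-":
        hit_f = locate_primer(canon.seq, fwd_primer, max_primer_mismatch, search_window)
        if hit_f is None or hit_f.strand != "+":  # pragma: no cover - defensive
            return DemuxAssignment(read.read_id, "no_primer", reason="orientation_failed")

    # (ii) reverse primer as reverse complement near the 3' end
    hit_r = locate_primer(canon.seq, rev_primer, max_primer_mismatch, search_window)
    if hit_r is None or hit_r.strand != "-" or hit_r.offset <= hit_f.offset:
        return DemuxAssignment(read.read_id, "no_primer", reason="rev_primer_not_found")

    canon_bits = encode_read(canon.seq)
    bc_map = scheme.barcode_map
    fwd_cands = {b: encode_pattern(bc_map[b].seq) for b in bc_map}
    rev_cands = {b: encode_pattern(reverse_complement(bc_map[b].seq)) for b in bc_map}

    # (iii) forward barcode: 12 bases immediately 5' of the forward primer
    f_start = hit_f.offset - 12
    if f_start < 0:
        return DemuxAssignment(read.read_id, "no_barcode", reason="fwd_bc_window_truncated")
    f_calls, f_d = _hamming_calls(canon_bits[f_start : hit_f.offset], fwd_cands, max_bc_mismatch)
    if f_d > max_bc_mismatch:
        return DemuxAssignment(read.read_id, "no_barcode", reason="fwd_bc_no_match")
    if len(f_calls) > 1:
        return DemuxAssignment(read.read_id, "ambiguous", reason="fwd_bc_tie", fwd_mm=f_d)
    fwd_call = f_calls[0]

    # reverse barcode window: 12 bases immediately 3' of the reverse-primer hit
    r_end_primer = hit_r.offset + len(rev_primer)
    r_window = canon_bits[r_end_primer : r_end_primer + 12]
    rev_readable = len(r_window) == 12

    rev_call: str | None = None
    r_d: int | None = None
    if rev_readable:
        r_calls, r_d_best = _hamming_calls(r_window, rev_cands, max_bc_mismatch)
        if r_d_best <= max_bc_mismatch:
            if len(r_calls) > 1:
                if mode == "2BC":
                    return DemuxAssignment(
                        read.read_id, "ambiguous", reason="rev_bc_tie", fwd_bc=fwd_call
                    )
                r_calls = []  # 1BC: an ambiguous reverse window is no evidence
            else:
                rev_call, r_d = r_calls[0], r_d_best

    # (iv) resolve to a sample
    if mode == "2BC":
        if rev_call is None:
            return DemuxAssignment(
                read.read_id, "no_barcode", reason="rev_bc_no_match", fwd_bc=fwd_call
            )
    else:  # 1BC: the forward call decides; a readable contradiction discards
        if rev_call is not None and rev_call != fwd_call:
            return DemuxAssignment(
                read.read_id,
                "conflicting",
                reason="rev_bc_contradicts_fwd",
                fwd_bc=fwd_call,
                rev_bc=rev_call,
                fwd_mm=f_d,
                rev_mm=r_d,
            )
        rev_call, r_d = fwd_call, r_d if rev_call == fwd_call else None

    sample = scheme.layout.get((pool_id, fwd_call, rev_call))
    if sample is None:
        return DemuxAssignment(
            read.read_id,
            "no_barcode",
            reason="bc_pair_not_in_layout",
            fwd_bc=fwd_call,
            rev_bc=rev_call,
            fwd_mm=f_d,
            rev_mm=r_d,
        )

    # (v) trim to the insert strictly between the primer hits
    ins_start = hit_f.offset + len(fwd_primer)
    trimmed = SeqRecord(
        canon.read_id,
        canon.seq[ins_start : hit_r.offset],
        canon.quals[ins_start : hit_r.offset],
        {"sample": sample, "fwd_bc": fwd_call, "rev_bc": rev_call},
    )
    return DemuxAssignment(
        read.read_id, "assigned", sample, fwd_call, rev_call, f_d, r_d, "", trimmed
    )


ASSIGNMENT_COLUMNS = ["read_id", "status", "sample", "fwd_bc", "rev_bc", "fwd_mm", "rev_mm", "reason"]


def demultiplex_pool(
    records: Iterable[SeqRecord],
    scheme: BarcodeScheme,
    pool_id: str,
    max_bc_mismatch: int = 2,
    max_primer_mismatch: int = 3,
    search_window: int = 100,
    mode: str | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, list[SeqRecord]]]:
    """Demultiplex one native pool into per-sample trimmed reads.

    Returns the assignment table (one row per input read, statuses
    partitioning the input) and a dict sample_id -> trimmed reads. When
    ``out_dir`` is given, one FASTQ per sample plus ``assignments.tsv``
    are written there; every sample in the pool layout gets a file, even
    if empty.
    """
    pairs = scheme.samples_in_pool(pool_id)
    if not pairs:
        raise ValueError(f"scheme layout does not cover pool {pool_id!r}")
    rows = []
    by_sample: dict[str, list[SeqRecord]] = {s: [] for s in sorted(pairs.values())}
    for rec in records:
        a = demultiplex_read(
            rec, scheme, pool_id, max_bc_mismatch, max_primer_mismatch, search_window, mode
        )
        rows.append(
            {
                "read_id": a.read_id,
                "status": a.status,
                "sample": a.sample_id,
                "fwd_bc": a.fwd_bc,
                "rev_bc": a.rev_bc,
                "fwd_mm": a.fwd_mm,
                "rev_mm": a.rev_mm,
                "reason": a.reason,
            }
        )
        if a.status == "assigned":
            by_sample[a.sample_id].append(a.trimmed)
    table = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample, recs in by_sample.items():
            write_fastq(recs, out_dir / f"{sample}.fastq")
        table.to_csv(out_dir / "assignments.tsv", sep="\t", index=False)
    return table, by_sample
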