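"""Domain types, sequence primitives and text-format I/O.

The toolkit operates on nanopore-style full-length 16S amplicon reads.
Everything downstream (filtering, demultiplexing, annotation, phylogeny)
is expressed in terms of the small set of containers defined here:
reads with per-base Phred qualities, barcode/primer schemes, reference
taxa, relative-abundance profiles and contingency tables.

File formats are plain text: FASTQ (Sanger/Phred+33), FASTA, a taxonomy
TSV (``tax_id  species  lineage``), an abundance TSV
(``tax_id  species  abundance  est_reads``) and a YAML scheme config.
Gzipped variants of the sequence formats are handled transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SeqRecord",
    "Barcode",
    "PrimerPair",
    "BarcodeScheme",
    "ReferenceTaxon",
    "AbundanceProfile",
    "ContingencyTable",
    "ParseError",
    "reverse_complement",
    "iupac_match",
    "mean_read_quality",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "write_taxonomy",
    "read_reference_db",
    "write_reference_db",
    "read_abundance",
    "write_abundance",
    "read_scheme",
    "write_scheme",
]

# --------------------------------------------------------------------------
# IUPAC machinery
# --------------------------------------------------------------------------

IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: bitmask encoding of the IUPAC alphabet: A=1, C=2, G=4, T=8
IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

# Read-side encoding: an 'N' basecall carries no information, so it gets a
# private bit that only the pattern 'N' can see.  Pattern 'N' additionally
# matches every concrete base.
_READ_N_BIT = 16
_READ_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": _READ_N_BIT}
_PATTERN_BITS = {k: (v | _READ_N_BIT if k == "N" else v) for k, v in IUPAC_BITS.items()}

_READ_LUT = np.zeros(128, dtype=np.uint8)
for _b, _v in _READ_BITS.items():
    _READ_LUT[ord(_b)] = _v
_PATTERN_LUT = np.zeros(128, dtype=np.uint8)
for _b, _v in _PATTERN_BITS.items():
    _PATTERN_LUT[ord(_b)] = _v


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (degenerate codes mapped)."""
    try:
        return "".join(IUPAC_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in sequence: {exc.args[0]!r}") from None


def iupac_match(pattern_base: str, base: str) -> bool:
    """Does read ``base`` fall in the set encoded by IUPAC ``pattern_base``?

    A read-side ``N`` matches only a pattern ``N``: an N basecall carries no
    evidence for any concrete base, so it must not count as a barcode or
    primer match.
    """
    p = _PATTERN_BITS.get(pattern_base.upper())
    if p is None:
        raise ValueError(f"invalid IUPAC pattern base: {pattern_base!r}")
    b = _READ_BITS.get(base.upper())
    if b is None:
        raise ValueError(f"invalid read base: {base!r}")
    return bool(p & b)


def encode_read(seq: str) -> np.ndarray:
    """Encode a read sequence (A/C/G/T/N) as a bitmask vector."""
    arr = _READ_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        bad = seq[int(np.argmax(arr == 0))]
        raise ValueError(f"invalid read base: {bad!r}")
    return arr


def encode_pattern(seq: str) -> np.ndarray:
    """Encode an IUPAC pattern (primer/barcode) as a bitmask vector."""
    arr = _PATTERN_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        bad = seq[int(np.argmax(arr == 0))]
        raise ValueError(f"invalid IUPAC pattern base: {bad!r}")
    return arr


def mean_read_quality(quals: Iterable[int]) -> float:
    """Error-probability-averaged read quality.

    Q = -10 * log10( mean_i 10^(-q_i / 10) ).  This is the quality notion
    used by long-read filtering tools: one low-quality stretch drags the
    read average down much more than an arithmetic mean of Phred scores
    would, because error probabilities, not scores, are averaged.
    """
    q = np.asarray(list(quals) if not isinstance(quals, np.ndarray) else quals, dtype=float)
    if q.size == 0:
        raise ValueError("mean_read_quality of an empty quality list is undefined")
    return float(-10.0 * np.log10(np.mean(np.power(10.0, -q / 10.0))))


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


class ParseError(ValueError):
    """Raised for malformed records in text inputs."""


@dataclass
class SeqRecord:
    """A single read: id, DNA sequence and per-base Phred qualities."""

    read_id: str
    seq: str
    quals: list[int]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"record {self.read_id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.seq)}"
            )
        if any(q < 0 or q > 93 for q in self.quals):
            raise ValueError(f"record {self.read_id!r}: Phred quality outside [0, 93]")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_quality(self) -> float:
        return mean_read_quality(self.quals)

    def reverse_complement(self) -> "SeqRecord":
        return SeqRecord(
            self.read_id,
            reverse_complement(self.seq),
            list(reversed(self.quals)),
            dict(self.annotations),
        )


@dataclass(frozen=True)
class Barcode:
    """A 12-base non-degenerate PCR barcode embedded 5' of the primer."""

    bc_id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != 12:
            raise ValueError(f"barcode {self.bc_id!r}: length must be 12, got {len(self.seq)}")
        if any(b not in "ACGT" for b in self.seq):
            raise ValueError(f"barcode {self.bc_id!r}: barcodes must be over A/C/G/T only")


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse amplification primers; may contain IUPAC degenerate bases."""

    name: str
    fwd: str
    rev: str

    def __post_init__(self) -> None:
        for label, seq in (("fwd", self.fwd), ("rev", self.rev)):
            if not seq:
                raise ValueError(f"primer pair {self.name!r}: empty {label} primer")
            for b in seq:
                if b.upper() not in IUPAC_BITS:
                    raise ValueError(
                        f"primer pair {self.name!r}: non-IUPAC base {b!r} in {label} primer"
                    )


@dataclass
class BarcodeScheme:
    """Barcodes, primer pair, barcoding mode and the pool layout.

    ``layout`` maps ``(native_pool_id, fwd_bc_id, rev_bc_id) -> sample_id``.
    In single-barcode (1BC) mode the same barcode sits on both primers, so
    every layout key has ``fwd_bc_id == rev_bc_id``; double-barcode (2BC)
    mode uses combinatorial pairs for higher multiplexing.
    """

    barcodes: list[Barcode]
    primers: PrimerPair
    mode: str  # "1BC" or "2BC"
    layout: dict[tuple[str, str, str], str]

    def __post_init__(self) -> None:
        if self.mode not in ("1BC", "2BC"):
            raise ValueError(f"mode must be '1BC' or '2BC', got {self.mode!r}")
        ids = {b.bc_id for b in self.barcodes}
        if len(ids) != len(self.barcodes):
            raise ValueError("duplicate barcode ids in scheme")
        seen_pairs: dict[str, set[tuple[str, str]]] = {}
        for (pool, f, r), sample in self.layout.items():
            if f not in ids or r not in ids:
                raise ValueError(f"layout for sample {sample!r} references unknown barcode")
            if self.mode == "1BC" and f != r:
                raise ValueError(
                    f"1BC layout requires fwd == rev barcode, got ({f}, {r}) for {sample!r}"
                )
            pairs = seen_pairs.setdefault(pool, set())
            if (f, r) in pairs:
                raise ValueError(f"barcode pair ({f}, {r}) reused within pool {pool!r}")
            pairs.add((f, r))

    @property
    def barcode_map(self) -> dict[str, Barcode]:
        return {b.bc_id: b for b in self.barcodes}

    def pools(self) -> list[str]:
        return sorted({pool for pool, _, _ in self.layout})

    def samples_in_pool(self, pool_id: str) -> dict[tuple[str, str], str]:
        """Map (fwd_bc_id, rev_bc_id) -> sample_id for one native pool."""
        return {
            (f, r): sample
            for (pool, f, r), sample in self.layout.items()
            if pool == pool_id
        }


@dataclass
class ReferenceTaxon:
    """One reference 16S sequence with its species name and lineage."""

    taxon_id: str
    species_name: str
    lineage: list[str]
    seq: str

    def validate_length(self, min_len: int = 1200, max_len: int = 1900) -> None:
        if not (min_len <= len(self.seq) <= max_len):
            raise ValueError(
                f"taxon {self.taxon_id!r}: 16S length {len(self.seq)} outside "
                f"[{min_len}, {max_len}]"
            )


@dataclass
class AbundanceProfile:
    """Per-sample relative species abundances with estimated read counts."""

    sample_id: str
    entries: dict[str, tuple[float, float]]  # taxon_id -> (abundance, est_reads)
    total_reads: int
    species_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entries:
            total = sum(a for a, _ in self.entries.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"profile {self.sample_id!r}: abundances sum to {total}, not 1"
                )
            if any(a < 0 or a > 1 for a, _ in self.entries.values()):
                raise ValueError(f"profile {self.sample_id!r}: abundance outside [0, 1]")

    @property
    def abundances(self) -> dict[str, float]:
        return {t: a for t, (a, _) in self.entries.items()}

    def as_series(self) -> pd.Series:
        return pd.Series(self.abundances, name=self.sample_id, dtype=float)


@dataclass
class ContingencyTable:
    """An r x c table of non-negative integer counts for association statistics."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ContingencyTable":
        """Cross-tabulate (row_label, col_label) observation pairs."""
        df = pd.DataFrame(list(pairs), columns=["row", "col"])
        tab = pd.crosstab(df["row"], df["col"])
        return cls(list(tab.index), list(tab.columns), tab.to_numpy())

    def drop_zero_marginals(self) -> "ContingencyTable":
        keep_r = self.counts.sum(axis=1) > 0
        keep_c = self.counts.sum(axis=0) > 0
        return ContingencyTable(
            [l for l, k in zip(self.row_labels, keep_r) if k],
            [l for l, k in zip(self.col_labels, keep_c) if k],
            self.counts[np.ix_(keep_r, keep_c)],
        )


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[SeqRecord]:
    """Parse a 4-line FASTQ file (Sanger/Phred+33 qualities) into records.

    Malformed records raise :class:`ParseError` naming the 0-based record
    index at which parsing failed.
    """
    records: list[SeqRecord] = []
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(f"malformed FASTQ record at index {len(records)}: {exc}") from exc
            if len(seq) != len(qual):
                raise ParseError(
                    f"malformed FASTQ record at index {len(records)}: "
                    f"sequence/quality length mismatch"
                )
            records.append(
                SeqRecord(title.split()[0], seq.upper(), [ord(c) - 33 for c in qual])
            )
    return records


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.quals)
            fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{qual}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, sequence) tuples; ids are the first header token."""
    with _open_text(path) as fh:
        return [(title.split()[0], seq.upper()) for title, seq in SimpleFastaParser(fh)]


def write_fasta(entries: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_taxonomy(path) -> pd.DataFrame:
    """Read the taxonomy TSV (``tax_id  species  lineage``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tax_id", "species", "lineage"}
    if not required.issubset(df.columns):
        raise ParseError(f"taxonomy TSV must have columns {sorted(required)}")
    return df


def write_taxonomy(taxa: Iterable[ReferenceTaxon], path) -> None:
    rows = [
        {"tax_id": t.taxon_id, "species": t.species_name, "lineage": ";".join(t.lineage)}
        for t in taxa
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reference_db(fasta_path, taxonomy_path) -> list[ReferenceTaxon]:
    """Assemble a reference database from a 16S FASTA plus taxonomy TSV."""
    seqs = dict(read_fasta(fasta_path))
    tax = read_taxonomy(taxonomy_path)
    taxa = []
    for _, row in tax.iterrows():
        tid = row["tax_id"]
        if tid not in seqs:
            raise ParseError(f"taxonomy references tax_id {tid!r} absent from FASTA")
        lineage = row["lineage"].split(";") if isinstance(row["lineage"], str) else []
        taxa.append(ReferenceTaxon(tid, row["species"], lineage, seqs[tid]))
    return taxa


def write_reference_db(taxa: Iterable[ReferenceTaxon], fasta_path, taxonomy_path) -> None:
    taxa = list(taxa)
    write_fasta([(t.taxon_id, t.seq) for t in taxa], fasta_path)
    write_taxonomy(taxa, taxonomy_path)


ABUNDANCE_COLUMNS = ["tax_id", "species", "abundance", "est_reads"]


def read_abundance(path, sample_id: str | None = None) -> AbundanceProfile:
    """Read an abundance TSV (``tax_id  species  abundance  est_reads``)."""
    df = pd.read_csv(path, sep="\t", dtype={"tax_id": str, "species": str})
    if list(df.columns[:4]) != ABUNDANCE_COLUMNS:
        raise ParseError(f"abundance TSV must have columns {ABUNDANCE_COLUMNS}")
    total = int(round(df["est_reads"].sum())) if len(df) else 0
    entries = {
        row["tax_id"]: (float(row["abundance"]), float(row["est_reads"]))
        for _, row in df.iterrows()
    }
    names = {row["tax_id"]: row["species"] for _, row in df.iterrows()}
    sid = sample_id if sample_id is not None else Path(path).stem
    return AbundanceProfile(sid, entries, total, names)


def write_abundance(profile: AbundanceProfile, path) -> None:
    rows = [
        {
            "tax_id": t,
            "species": profile.species_names.get(t, t),
            "abundance": a,
            "est_reads": er,
        }
        for t, (a, er) in sorted(
            profile.entries.items(), key=lambda kv: (-kv[1][0], kv[0])
        )
    ]
    pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scheme(path) -> BarcodeScheme:
    """Load a barcode scheme config (YAML).

    Expected keys::

        mode: 1BC | 2BC
        fwd_primer: AGRGTTYGATYMTGGCTCAG
        rev_primer: RGYTACCTTGTTACGACTT
        primer_name: A
        barcodes: {BC01: ACGT..., ...}
        layout:
          - {pool: pool01, fwd: BC01, rev: BC01, sample: s01}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("mode", "fwd_primer", "rev_primer", "barcodes", "layout"):
        if key not in cfg:
            raise ParseError(f"scheme config missing key {key!r}")
    barcodes = [Barcode(bc_id, seq) for bc_id, seq in cfg["barcodes"].items()]
    primers = PrimerPair(cfg.get("primer_name", "A"), cfg["fwd_primer"], cfg["rev_primer"])
    layout = {
        (row["pool"], row["fwd"], row["rev"]): row["sample"] for row in cfg["layout"]
    }
    return BarcodeScheme(barcodes, primers, cfg["mode"], layout)


def write_scheme(scheme: BarcodeScheme, path) -> None:
    cfg = {
        "mode": scheme.mode,
        "primer_name": scheme.primers.name,
        "fwd_primer": scheme.primers.fwd,
        "rev_primer": scheme.primers.rev,
        "barcodes": {b.bc_id: b.seq for b in scheme.barcodes},
        "layout": [
            {"pool": pool, "fwd": f, "rev": r, "sample": sample}
            for (pool, f, r), sample in sorted(scheme.layout.items())
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
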