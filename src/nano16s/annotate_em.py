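"""Species-level abundance estimation by expectation-maximization.

Long 16S reads are individually noisy, so a read often aligns acceptably
to several related reference sequences. Rather than assigning each read
to its single best hit, the sample composition ``f`` is treated as the
mixing weights of a mixture model: read ``r`` arises from taxon ``t``
with probability ``f_t``, and is then observed through an error channel
whose likelihood ``L[r, t]`` is scored from the read-to-reference
alignment. EM alternates read responsibilities
``P(t | r) ∝ f_t · L[r, t]`` with re-estimated weights
``f_t = mean_r P(t | r)`` until the abundances stabilise. This is the
standard long-read 16S profiling approach; the implementation here is a
deliberately small one: ungapped-penalty edit-distance alignment
(via edlib) and a fixed per-base error rate in the likelihood.

Likelihoods are computed in log space and rescaled per read before
exponentiation; EM is invariant to per-read scaling, and full-length
reads would otherwise underflow double precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .core_io import (
    AbundanceProfile,
    ReferenceTaxon,
    SeqRecord,
    read_fastq,
    reverse_complement,
)

__all__ = [
    "EMConfig",
    "ReadTaxonLikelihoods",
    "EMResult",
    "score_reads",
    "em_abundance",
    "annotate_sample",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class EMConfig:
    """Convergence and reporting knobs for the EM estimator.

    ``tol`` bounds the max absolute abundance change between iterations;
    ``min_abundance`` is a reporting floor below which taxa are dropped
    (the remainder is renormalised), mirroring the floors typical of
    taxonomic profilers.
    """

    tol: float = 1e-6
    max_iter: int = 100
    min_abundance: float = 1e-4

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ReadTaxonLikelihoods:
    """Per-read, per-taxon likelihoods (scaled per read; zeros = non-candidates)."""

    read_ids: list[str]
    taxon_ids: list[str]
    matrix: np.ndarray  # shape (n_reads, n_taxa), non-negative

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.read_ids), len(self.taxon_ids)):
            raise ValueError("likelihood matrix shape does not match labels")
        if not np.isfinite(self.matrix).all() or (self.matrix < 0).any():
            raise ValueError("likelihoods must be finite and non-negative")

    def candidates(self, r: int) -> list[str]:
        return [t for t, v in zip(self.taxon_ids, self.matrix[r]) if v > 0]


def _alignment_counts(query: str, target: str) -> tuple[int, int] | None:
    """(matches, errors) of the best infix alignment of query in target."""
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or res["cigar"] is None:
        return None
    matches = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        if op == "=":
            matches += int(num)
    return matches, res["editDistance"]


def score_reads(
    reads: list[SeqRecord],
    db: list[ReferenceTaxon],
    p_err: float = 0.1,
    min_coverage: float = 0.8,
) -> ReadTaxonLikelihoods:
    """Alignment likelihoods of each read against each reference taxon.

    Each read is aligned (both strands, best kept) as an infix of each
    reference; the likelihood is
    ``p_err^(mismatches + indels) · (1 - p_err)^matches``. References
    whose best alignment matches fewer than ``min_coverage`` of the read
    bases are not candidates for that read (likelihood 0) — unrelated
    sequences align with match fractions well below 0.8, real 16S
    templates well above it.
    """
    if not db:
        raise ValueError("reference database is empty")
    if not (0 < p_err < 1):
        raise ValueError("p_err must be in (0, 1)")
    n_r, n_t = len(reads), len(db)
    loglik = np.full((n_r, n_t), -np.inf)
    lp, lq = np.log(p_err), np.log1p(-p_err)
    for i, rec in enumerate(reads):
        rc = reverse_complement(rec.seq)
        for j, taxon in enumerate(db):
            best: tuple[int, int] | None = None
            for q in (rec.seq, rc):
                got = _alignment_counts(q, taxon.seq)
                if got is not None and (best is None or got[1] < best[1]):
                    best = got
            if best is None:
                continue
            matches, errors = best
            if len(rec.seq) > 0 and matches / len(rec.seq) >= min_coverage:
                loglik[i, j] = errors * lp + matches * lq
    # rescale per read: EM only sees likelihood ratios within a read
    with np.errstate(invalid="ignore"):
        shift = np.max(loglik, axis=1, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    matrix = np.exp(loglik - shift)
    matrix[~np.isfinite(loglik)] = 0.0
    return ReadTaxonLikelihoods(
        [r.read_id for r in reads], [t.taxon_id for t in db], matrix
    )


@dataclass
class EMResult:
    """Abundance profile plus EM diagnostics (per-iteration log-likelihood)."""

    profile: AbundanceProfile
    loglik_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def em_abundance(
    likelihoods: ReadTaxonLikelihoods,
    cfg: EMConfig | None = None,
    sample_id: str = "sample",
    species_names: dict[str, str] | None = None,
) -> EMResult:
    """Mixture EM over read-to-taxon likelihoods.

    Initialises uniformly over taxa with any support, iterates
    E-step/M-step to ``cfg.tol`` or ``cfg.max_iter``, drops taxa below
    ``cfg.min_abundance`` and renormalises. Estimated read counts are
    ``f_t · n_reads`` over the reads that had at least one candidate.
    The recorded log-likelihood history is non-decreasing (a standard EM
    guarantee, up to floating-point noise).
    """
    if cfg is None:
        cfg = EMConfig()
    L = likelihoods.matrix
    n_total = L.shape[0]
    usable = L.sum(axis=1) > 0
    L = L[usable]
    n = L.shape[0]
    if n == 0:
        return EMResult(AbundanceProfile(sample_id, {}, n_total), [], 0, True)

    support = L.sum(axis=0) > 0
    f = support.astype(float)
    f /= f.sum()
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        mix = L @ f  # per-read mixture likelihood (scaled)
        history.append(float(np.sum(np.log(mix))))
        resp = (L * f) / mix[:, None]  # E-step: P(t | r)
        f_new = resp.mean(axis=0)  # M-step
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < cfg.tol:
            converged = True
            break
    history.append(float(np.sum(np.log(L @ f))))

    keep = f >= cfg.min_abundance
    if not keep.any():
        keep = f == f.max()
    f_rep = np.where(keep, f, 0.0)
    f_rep /= f_rep.sum()
    entries = {
        t: (float(a), float(a * n))
        for t, a, k in zip(likelihoods.taxon_ids, f_rep, keep)
        if k
    }
    names = {t: species_names[t] for t in entries} if species_names else {}
    return EMResult(AbundanceProfile(sample_id, entries, n_total, names), history, it, converged)


def annotate_sample(
    reads: list[SeqRecord] | str | Path,
    db: list[ReferenceTaxon],
    cfg: EMConfig | None = None,
    sample_id: str | None = None,
    p_err: float = 0.1,
    min_coverage: float = 0.8,
) -> EMResult:
    """Full annotation of one demultiplexed sample: score then EM.

    ``reads`` may be a list of records or a FASTQ path. Deterministic for
    a fixed input; permuting read order leaves the profile unchanged.
    """
    if isinstance(reads, (str, Path)):
        if sample_id is None:
            sample_id = Path(reads).stem
        reads = read_fastq(reads)
    if sample_id is None:
        sample_id = "sample"
    if not reads:
        return EMResult(AbundanceProfile(sample_id, {}, 0), [], 0, True)
    likelihoods = score_reads(reads, db, p_err=p_err, min_coverage=min_coverage)
    names = {t.taxon_id: t.species_name for t in db}
    return em_abundance(likelihoods, cfg, sample_id=sample_id, species_names=names)
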