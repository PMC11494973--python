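"""Run-level, sample-level and community-level metrics.

Covers three layers of evaluation used around barcoded 16S runs:

* sequencing performance — PCR-barcode demultiplexing efficiency per
  native pool, and per-sample depth/purity gates for isolate calls;
* concordance with an orthogonal identification method — positive
  predictive value plus Cramér's V (chi-squared based, symmetric) and
  Theil's U (entropy based, directional) on the species contingency
  table;
* community ecology — alpha diversity (richness, Shannon in nats,
  Berger-Parker dominance), Bray-Curtis dissimilarity, one-way
  PERMANOVA on a distance matrix, paired-versus-unpaired dissimilarity
  comparisons across techniques, and seeded rarefaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from skbio import DistanceMatrix

from .core_io import AbundanceProfile, ContingencyTable

__all__ = [
    "PoolStats",
    "SampleCall",
    "pool_efficiency",
    "call_sample",
    "ppv",
    "cramers_v",
    "theils_u",
    "alpha_diversity",
    "bray_curtis",
    "profiles_to_matrix",
    "permanova",
    "PermanovaResult",
    "paired_dissimilarity_report",
    "rarefy",
]


# --------------------------------------------------------------------------
# sequencing performance
# --------------------------------------------------------------------------


@dataclass
class PoolStats:
    """Demultiplexing efficiency of one native pool: assigned / total reads."""

    native_pool_id: str
    n_total: int
    n_pcr_demuxed: int

    @property
    def efficiency(self) -> float:
        return self.n_pcr_demuxed / self.n_total if self.n_total else 0.0


def pool_efficiency(assignments: pd.DataFrame, pool_id: str) -> PoolStats:
    """PCR-barcode efficiency of a native pool from its assignment table.

    Efficiency is the number of reads assigned a PCR barcode (pair)
    divided by the total reads carrying that native barcode — i.e. all
    reads in the pool's table.
    """
    if "status" not in assignments.columns:
        raise ValueError("assignment table must have a 'status' column")
    if "native_pool" in assignments.columns:
        sub = assignments[assignments["native_pool"] == pool_id]
        if sub.empty:
            raise KeyError(f"no reads for native pool {pool_id!r}")
    else:
        sub = assignments
    n_total = len(sub)
    n_assigned = int((sub["status"] == "assigned").sum())
    return PoolStats(pool_id, n_total, n_assigned)


@dataclass
class SampleCall:
    """Isolate-level identification call with depth and purity gates."""

    sample_id: str
    top_species: str | None
    purity: float
    n_reads: int
    passes_depth: bool
    passes_purity: bool


def call_sample(
    profile: AbundanceProfile,
    purity_cutoff: float = 0.90,
    depth_cutoff: int = 10,
) -> SampleCall:
    """Call the dominant species of a sample and apply the QC gates.

    Purity is the relative abundance of the most abundant taxon; the
    sample passes if purity >= ``purity_cutoff`` (at least 90% of reads
    on one species by default) and its read count >= ``depth_cutoff``.
    Argmax ties break lexicographically by taxon_id for determinism.
    """
    if not profile.entries:
        return SampleCall(profile.sample_id, None, 0.0, profile.total_reads, False, False)
    top_taxon = min(profile.entries, key=lambda t: (-profile.entries[t][0], t))
    purity = profile.entries[top_taxon][0]
    species = profile.species_names.get(top_taxon, top_taxon)
    return SampleCall(
        profile.sample_id,
        species,
        purity,
        profile.total_reads,
        profile.total_reads >= depth_cutoff,
        purity >= purity_cutoff,
    )


def ppv(tp: int, fp: int) -> float:
    """Positive predictive value TP / (TP + FP)."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise ValueError("PPV undefined for tp + fp == 0")
    return tp / (tp + fp)


# --------------------------------------------------------------------------
# concordance statistics
# --------------------------------------------------------------------------


def cramers_v(table: ContingencyTable) -> float:
    """Cramér's V = sqrt(chi2 / (N * (min(r, c) - 1))), no continuity correction.

    Zero marginal rows/columns are dropped first; the reduced table must
    remain at least 2x2.
    """
    t = table.drop_zero_marginals()
    r, c = t.counts.shape
    if r < 2 or c < 2:
        raise ValueError("Cramér's V requires at least a 2x2 table after dropping zero marginals")
    n = t.total
    if n == 0:
        raise ValueError("Cramér's V undefined for an empty table")
    chi2 = chi2_contingency(t.counts, correction=False)[0]
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def theils_u(table: ContingencyTable, direction: str = "row|col") -> float:
    """Uncertainty coefficient U with natural-log entropies.

    ``U(row|col) = (H(row) - H(row|col)) / H(row)``: the fraction of the
    row variable's entropy explained by knowing the column variable.
    Asymmetric — the ``direction`` argument ("row|col" or "col|row")
    selects which variable is conditioned on which.
    """
    if direction not in ("row|col", "col|row"):
        raise ValueError("direction must be 'row|col' or 'col|row'")
    counts = table.counts.astype(float)
    if direction == "col|row":
        counts = counts.T
    n = counts.sum()
    if n == 0:
        raise ValueError("Theil's U undefined for an empty table")
    p_row = counts.sum(axis=1) / n
    h_row = _entropy(p_row)
    if h_row == 0:
        raise ValueError("Theil's U undefined when the conditioned variable has zero entropy")
    p_col = counts.sum(axis=0) / n
    h_row_given_col = 0.0
    for j in range(counts.shape[1]):
        col_total = counts[:, j].sum()
        if col_total > 0:
            h_row_given_col += (col_total / n) * _entropy(counts[:, j] / col_total)
    return float((h_row - h_row_given_col) / h_row)


# --------------------------------------------------------------------------
# diversity
# --------------------------------------------------------------------------


def alpha_diversity(profile: AbundanceProfile) -> tuple[int, float, float]:
    """(richness, Shannon diversity in nats, Berger-Parker dominance).

    Richness counts taxa with positive abundance; Shannon is
    ``-sum p ln p``; Berger-Parker is the abundance of the dominant
    taxon. An empty profile reports (0, 0.0, 0.0) — an explicit
    convention so batch reports need no special-casing.
    """
    p = np.array([a for a, _ in profile.entries.values() if a > 0])
    if p.size == 0:
        return 0, 0.0, 0.0
    return int(p.size), _entropy(p), float(p.max())


def bray_curtis(p: AbundanceProfile | Mapping[str, float], q: AbundanceProfile | Mapping[str, float]) -> float:
    """Bray-Curtis dissimilarity 1 - sum_t min(p_t, q_t) on relative abundances.

    Profiles are placed on the union of their taxa (missing = 0). For
    relative abundances this equals the standard count formulation under
    equal totals: 0 for identical profiles, 1 for disjoint supports.
    """
    pa = p.abundances if isinstance(p, AbundanceProfile) else dict(p)
    qa = q.abundances if isinstance(q, AbundanceProfile) else dict(q)
    if not pa and not qa:
        raise ValueError("Bray-Curtis undefined for two empty profiles")
    taxa = set(pa) | set(qa)
    shared = sum(min(pa.get(t, 0.0), qa.get(t, 0.0)) for t in taxa)
    return float(1.0 - shared)


def profiles_to_matrix(profiles: Sequence[AbundanceProfile]) -> DistanceMatrix:
    """Pairwise Bray-Curtis distance matrix over a set of profiles."""
    ids = [p.sample_id for p in profiles]
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(profiles[i], profiles[j])
    return DistanceMatrix(d, ids)


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    f_stat: float
    r2: float
    p_value: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    dist: DistanceMatrix | np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
    ids: Sequence[str] | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F statistic partitions the sum of squared distances into
    among- and within-group components; the p-value is
    ``(1 + #{permuted F >= observed F}) / (1 + n_perm)`` under seeded
    label permutations. ``R^2 = SS_among / SS_total`` is the fraction of
    distance variability explained by the grouping.
    """
    if isinstance(dist, DistanceMatrix):
        d = dist.data
    else:
        d = np.asarray(dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
    labels = np.asarray(groups)
    if labels.size != d.shape[0]:
        raise ValueError("groups length must match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or (counts < 2).any():
        raise ValueError("PERMANOVA needs >= 2 groups with >= 2 members each")
    n, g = labels.size, uniq.size
    d2 = d**2
    ss_total, ss_within = _permanova_ss(d2, labels)
    ss_among = ss_total - ss_within

    def f_of(ssw: float) -> float:
        if ssw == 0:
            return np.inf
        return ((ss_total - ssw) / (g - 1)) / (ssw / (n - g))

    f_obs = f_of(ss_within)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, ssw = _permanova_ss(d2, perm)
        # F is monotone decreasing in SS_within (SS_total is fixed under
        # label permutation), so compare on SS_within to keep the test
        # well-defined when the observed within-group scatter is zero
        if ssw <= ss_within + 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


# --------------------------------------------------------------------------
# paired vs unpaired dissimilarity
# --------------------------------------------------------------------------


def paired_dissimilarity_report(
    profiles_a: Mapping[str, AbundanceProfile],
    profiles_b: Mapping[str, AbundanceProfile],
    pairing: Mapping[str, str],
) -> pd.DataFrame:
    """Bray-Curtis of paired samples across two techniques vs all unpaired pairs.

    ``pairing`` maps sample ids of technique A to their counterparts in
    technique B. Returns a tidy frame with columns ``kind``
    ("paired"/"unpaired"), ``sample_a``, ``sample_b`` and
    ``bray_curtis``; the unpaired set is every cross-technique
    combination that is not a designated pair (empty for a single pair).
    """
    missing = [a for a in pairing if a not in profiles_a] + [
        b for b in pairing.values() if b not in profiles_b
    ]
    if missing:
        raise KeyError(f"pairing references unknown sample ids: {sorted(set(missing))}")
    rows = []
    for a, b in pairing.items():
        rows.append(
            {
                "kind": "paired",
                "sample_a": a,
                "sample_b": b,
                "bray_curtis": bray_curtis(profiles_a[a], profiles_b[b]),
            }
        )
    for a in profiles_a:
        for b in profiles_b:
            if pairing.get(a) == b:
                continue
            rows.append(
                {
                    "kind": "unpaired",
                    "sample_a": a,
                    "sample_b": b,
                    "bray_curtis": bray_curtis(profiles_a[a], profiles_b[b]),
                }
            )
    return pd.DataFrame(rows, columns=["kind", "sample_a", "sample_b", "bray_curtis"])


# --------------------------------------------------------------------------
# rarefaction
# --------------------------------------------------------------------------


def rarefy(counts: Mapping[str, int], depth: int, seed: int | None = None) -> dict[str, int]:
    """Subsample a taxon count vector to exactly ``depth`` reads without replacement.

    Multivariate hypergeometric draw (seeded); ``depth`` must not exceed
    the total count.
    """
    taxa = sorted(counts)
    vec = np.array([counts[t] for t in taxa], dtype=np.int64)
    if (vec < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(vec.sum())
    if depth < 0 or depth > total:
        raise ValueError(f"depth must be in [0, {total}], got {depth}")
    rng = np.random.default_rng(seed)
    draw = rng.multivariate_hypergeometric(vec, depth)
    return {t: int(c) for t, c in zip(taxa, draw)}
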