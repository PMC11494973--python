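"""Read binning, consensus building and neighbor-joining phylogenetics.

Per-sample reads are clustered greedily against centroid sequences (the
vsearch-style "cluster by identity to the first compatible centroid"
strategy), small bins are discarded, and each surviving bin is collapsed
to a majority-vote consensus against its centroid. Consensus sequences
are then related by a distance matrix of pairwise global-alignment
identities and a neighbor-joining tree, with bootstrap supports computed
by resampling columns of a star multiple alignment.

Majority-vote consensus is a deliberately simple polisher: at the toy
error rates used here it recovers templates to within a base or two,
which is all the downstream tree needs. Trees are
:class:`skbio.TreeNode` objects, so newick serialisation, traversal and
comparison come from scikit-bio.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
from skbio import DistanceMatrix, TreeNode

from .core_io import SeqRecord

__all__ = [
    "ReadBin",
    "align_stats",
    "greedy_cluster",
    "filter_bins",
    "consensus",
    "distance_matrix",
    "nj_tree",
    "bipartitions",
    "star_alignment",
    "alignment_distance_matrix",
    "bootstrap_support",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_ops(cigar: str):
    for num, op in _CIGAR_RE.findall(cigar):
        yield int(num), op


def align_stats(query: str, target: str) -> tuple[int, int, str]:
    """(matches, alignment_columns, cigar) of the global alignment query vs target."""
    res = edlib.align(query, target, mode="NW", task="path")
    matches = 0
    cols = 0
    for num, op in _cigar_ops(res["cigar"]):
        cols += num
        if op == "=":
            matches += num
    return matches, cols, res["cigar"]


def global_identity(a: str, b: str) -> float:
    """Matches / alignment length (gap columns included) from global alignment."""
    if not a or not b:
        return 0.0
    matches, cols, _ = align_stats(a, b)
    return matches / cols


@dataclass
class ReadBin:
    """A cluster of reads represented by a centroid (itself a member)."""

    bin_id: str
    centroid: str
    members: list[SeqRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def greedy_cluster(reads: list[SeqRecord], identity_threshold: float = 0.97) -> list[ReadBin]:
    """Greedy centroid clustering by global-alignment identity.

    Reads are processed in decreasing length order (ties by read_id);
    each read joins the first existing bin whose centroid identity
    reaches the threshold, otherwise it seeds a new bin with itself as
    centroid. Longest-first processing makes centroids full-length
    representatives, as in standard amplicon clustering.
    """
    if not reads:
        raise ValueError("greedy_cluster needs at least one read")
    ordered = sorted(reads, key=lambda r: (-len(r.seq), r.read_id))
    bins: list[ReadBin] = []
    for rec in ordered:
        for b in bins:
            if global_identity(rec.seq, b.centroid) >= identity_threshold:
                b.members.append(rec)
                break
        else:
            bins.append(ReadBin(f"bin{len(bins) + 1:03d}", rec.seq, [rec]))
    return bins


def filter_bins(bins: list[ReadBin], min_size: int = 10) -> list[ReadBin]:
    """Keep only bins with strictly more than ``min_size`` reads."""
    return [b for b in bins if b.size > min_size]


def consensus(bin_: ReadBin) -> str:
    """Majority-vote consensus of a bin against its centroid.

    Every member is globally aligned to the centroid. Per centroid
    column the majority symbol (base or gap) wins, ties keeping the
    centroid base; insertions relative to the centroid are retained only
    where more than half the members carry one (the most common inserted
    string, ties broken lexicographically).
    """
    if bin_.size < 1:
        raise ValueError("consensus of an empty bin is undefined")
    L = len(bin_.centroid)
    column_votes: list[Counter] = [Counter() for _ in range(L)]
    insert_votes: list[Counter] = [Counter() for _ in range(L + 1)]  # before column i
    for rec in bin_.members:
        res = edlib.align(rec.seq, bin_.centroid, mode="NW", task="path")
        qi = 0  # position in member
        ti = 0  # position in centroid
        pending_ins: list[str] = []
        for num, op in _cigar_ops(res["cigar"]):
            if op in "=X":
                if pending_ins:
                    insert_votes[ti][("".join(pending_ins))] += 1
                    pending_ins = []
                for _ in range(num):
                    column_votes[ti][rec.seq[qi]] += 1
                    qi += 1
                    ti += 1
            elif op == "I":  # consumes query only: insertion relative to centroid
                pending_ins.append(rec.seq[qi : qi + num])
                qi += num
            elif op == "D":  # consumes centroid only: member has a gap
                if pending_ins:
                    insert_votes[ti][("".join(pending_ins))] += 1
                    pending_ins = []
                for _ in range(num):
                    column_votes[ti]["-"] += 1
                    ti += 1
        if pending_ins:
            insert_votes[ti][("".join(pending_ins))] += 1
    n = bin_.size
    out: list[str] = []
    for i in range(L + 1):
        ins_count = sum(insert_votes[i].values())
        if ins_count * 2 > n:
            best = min(insert_votes[i].items(), key=lambda kv: (-kv[1], kv[0]))
            out.append(best[0])
        if i < L:
            votes = column_votes[i]
            centroid_base = bin_.centroid[i]
            top = max(votes.values()) if votes else 0
            winners = [b for b, c in votes.items() if c == top]
            base = centroid_base if centroid_base in winners or not winners else winners[0]
            if len(winners) > 1:
                base = centroid_base if centroid_base in winners else sorted(winners)[0]
            if base != "-":
                out.append(base)
    return "".join(out)


def distance_matrix(seqs: list[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise distance matrix d = 1 - identity from global alignments."""
    if len(seqs) < 2:
        raise ValueError("distance_matrix needs at least 2 sequences")
    names = [n for n, _ in seqs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence labels")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - global_identity(seqs[i][1], seqs[j][1])
    return DistanceMatrix(d, names)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining on a distance matrix.

    Q-matrix criterion with the standard branch-length formulas; exact
    on additive matrices. Negative branch lengths are clamped to zero
    with the deficit moved to the sibling edge, and ties in the Q
    criterion break on the lexicographically smallest label pair, so the
    result is deterministic. Returns an unrooted tree (trifurcating root
    for n >= 3; a single split for n == 2).
    """
    d = np.array(dist.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    ids = list(dist.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    # tie-break key: smallest leaf label in each subtree
    keys: list[str] = list(ids)

    if n == 2:
        root = TreeNode()
        a, b = nodes
        a.length = d[0, 1] / 2
        b.length = d[0, 1] / 2
        root.extend([a, b])
        return root

    active = list(range(n))
    dmat = d.copy()
    next_rows = n

    # grow the matrix as new internal nodes are created
    def expand(mat: np.ndarray) -> np.ndarray:
        m = np.zeros((mat.shape[0] + 1, mat.shape[1] + 1))
        m[: mat.shape[0], : mat.shape[1]] = mat
        return m

    while len(active) > 3:
        m = len(active)
        sub = dmat[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a_i in range(m):
            for a_j in range(a_i + 1, m):
                q = (m - 2) * sub[a_i, a_j] - r[a_i] - r[a_j]
                pair_key = tuple(sorted((keys[active[a_i]], keys[active[a_j]])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and pair_key < best[1]):
                    best = (q, pair_key, a_i, a_j)
        _, _, a_i, a_j = best
        i, j = active[a_i], active[a_j]
        dij = dmat[i, j]
        li = dij / 2 + (r[a_i] - r[a_j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        dmat = expand(dmat)
        u = next_rows
        next_rows += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dmat[i, k] + dmat[j, k] - dij)
            dmat[u, k] = dmat[k, u] = max(duk, 0.0)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    # terminal 3-taxon star: closed-form lengths
    a, b, c = active
    la = (dmat[a, b] + dmat[a, c] - dmat[b, c]) / 2
    lb = (dmat[a, b] + dmat[b, c] - dmat[a, c]) / 2
    lc = (dmat[a, c] + dmat[b, c] - dmat[a, b]) / 2
    root = TreeNode()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
        root.append(nodes[idx])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions of an unrooted tree, canonicalised.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf represents the split.
    """
    leaves = sorted(l.name for l in tree.tips())
    full = set(leaves)
    anchor = leaves[0]
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = {l.name for l in node.tips()}
        if len(side) < 2 or len(side) > len(full) - 2:
            continue
        canon = frozenset(side) if anchor not in side else frozenset(full - side)
        out.add(canon)
    return out


# --------------------------------------------------------------------------
# star alignment + bootstrap
# --------------------------------------------------------------------------


def star_alignment(seqs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Fixed-column multiple alignment by projection onto the longest sequence.

    Every sequence is globally aligned to the longest one (ties by
    name); columns are the reference positions, insertions relative to
    the reference are dropped. Crude next to a real progressive MSA, but
    it yields the fixed column set needed for bootstrap resampling.
    """
    if len(seqs) < 2:
        raise ValueError("star_alignment needs at least 2 sequences")
    ref_name, ref_seq = min(seqs, key=lambda kv: (-len(kv[1]), kv[0]))
    rows = []
    for name, seq in seqs:
        if name == ref_name and seq == ref_seq:
            rows.append((name, ref_seq))
            continue
        res = edlib.align(seq, ref_seq, mode="NW", task="path")
        qi = 0
        aligned: list[str] = []
        for num, op in _cigar_ops(res["cigar"]):
            if op in "=X":
                aligned.append(seq[qi : qi + num])
                qi += num
            elif op == "I":  # insertion relative to reference: dropped
                qi += num
            elif op == "D":
                aligned.append("-" * num)
        rows.append((name, "".join(aligned)))
    return rows


def alignment_distance_matrix(msa: list[tuple[str, str]], columns: np.ndarray | None = None) -> DistanceMatrix:
    """Mismatch-fraction distances over (optionally resampled) alignment columns.

    Only columns where both sequences have a base count; pairs with no
    shared columns get distance 1.
    """
    names = [n for n, _ in msa]
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for _, s in msa]
    if columns is not None:
        arrs = [a[columns] for a in arrs]
    gap = ord("-")
    n = len(arrs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arrs[i] != gap) & (arrs[j] != gap)
            total = int(both.sum())
            if total == 0:
                d[i, j] = d[j, i] = 1.0
            else:
                mism = int((arrs[i][both] != arrs[j][both]).sum())
                d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(d, names)


def bootstrap_support(
    msa: list[tuple[str, str]],
    n_boot: int = 100,
    seed: int | None = None,
) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    The reported tree is built from the full alignment's distance
    matrix; for each replicate, alignment columns are resampled with
    replacement, the NJ tree rebuilt, and each internal edge's support
    is the fraction of replicates containing its bipartition. Supports
    are stored on internal nodes as ``node.support``, which scikit-bio
    serialises as the internal node label in newick output.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    length = len(msa[0][1])
    if length < 2 or any(len(s) != length for _, s in msa):
        raise ValueError("msa must have equal-length rows with >= 2 columns")
    tree = nj_tree(alignment_distance_matrix(msa))
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    for _ in range(n_boot):
        cols = rng.integers(0, length, size=length)
        rep = nj_tree(alignment_distance_matrix(msa, cols))
        for bp in bipartitions(rep):
            counts[bp] += 1
    leaves = sorted(l.name for l in tree.tips())
    anchor = leaves[0]
    full = set(leaves)
    for node in tree.non_tips(include_self=False):
        side = {l.name for l in node.tips()}
        if len(side) < 2 or len(side) > len(full) - 2:
            continue
        canon = frozenset(side) if anchor not in side else frozenset(full - side)
        node.support = counts.get(canon, 0) / n_boot
    return tree
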