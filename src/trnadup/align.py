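"""Global alignment identity and greedy identity/coverage clustering.

The aligner is a Gotoh three-state affine-gap global alignment with the
EMBOSS needle parameterisation (match +5, mismatch -4, gap open 10, gap
extend 0.5, end gaps free); a gap run of length L costs
``gap_open + L * gap_extend`` unless it touches a sequence end, in which
case it is free.  Identity is the EMBOSS definition: identical columns
divided by the total number of alignment columns, as a percentage.

Tie-breaking is fixed (diagonal, then up, then left) so that alignments
and all downstream tables are byte-stable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import TRNAGene

__all__ = [
    "ScoringParams",
    "AlignmentResult",
    "SeqCluster",
    "UniqueSequence",
    "global_align",
    "greedy_cluster",
    "unique_sequences",
]

_NEG = float("-inf")


@dataclass(frozen=True)
class ScoringParams:
    """Needle-style scoring over {A, C, G, T, N}.

    N is neutral (scores 0 against anything); ``gap_open + gap_extend`` is
    charged for the first residue of a gap run and ``gap_extend`` for each
    further residue.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_free: bool = True

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("need gap_open >= gap_extend >= 0")

    def score(self, x: str, y: str) -> float:
        if x == "N" or y == "N":
            return 0.0
        return self.match if x == y else self.mismatch


DEFAULT_PARAMS = ScoringParams()


@dataclass
class AlignmentResult:
    """A global alignment with identity and bidirectional coverage."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    coverage_a: float
    coverage_b: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


def _validate(seq: str, name: str) -> str:
    s = seq.upper()
    if not s:
        raise ValueError(f"sequence {name} is empty")
    if not set(s) <= set("ACGTN"):
        raise ValueError(f"sequence {name} has non-ACGTN characters")
    return s


def global_align(a: str, b: str, params: ScoringParams = DEFAULT_PARAMS) -> AlignmentResult:
    """Optimal affine-gap global alignment of two DNA strings.

    Gotoh recurrence with three states: M (match/mismatch), X (gap in b,
    consuming a) and Y (gap in a, consuming b).  With free end gaps the
    terminal gap runs cost nothing; ties in the traceback are resolved
    diagonal > up > left.  Arguments are aligned in a canonical
    orientation (longer, then lexicographically smaller, sequence first)
    so identity and coverage are exactly symmetric under argument swap.
    """
    if (-len(a), a) > (-len(b), b):
        res = global_align(b, a, params)
        return AlignmentResult(
            aligned_a=res.aligned_b,
            aligned_b=res.aligned_a,
            score=res.score,
            identity_pct=res.identity_pct,
            coverage_a=res.coverage_b,
            coverage_b=res.coverage_a,
        )
    a = _validate(a, "a")
    b = _validate(b, "b")
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend
    open_cost = go + ge
    free = params.end_gaps_free
    match, mismatch = params.match, params.mismatch

    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    n_code = ord("N")

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0 if free else -(go + ge * np.arange(1, n + 1))
    Y[0, 1:] = 0.0 if free else -(go + ge * np.arange(1, m + 1))

    # the Y (gap-in-a) state depends on the current row at j-1, which the
    # constant extend cost turns into a running max with linear drift:
    # Y[i, j] = max_k (candidate[k] - (j - k) * ge)
    drift = ge * np.arange(m + 1)
    for i in range(1, n + 1):
        ai = a_arr[i - 1]
        if ai == n_code:
            sv = np.zeros(m)
        else:
            sv = np.where(
                b_arr == n_code, 0.0, np.where(b_arr == ai, match, mismatch)
            )
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = sv + prev_best[:-1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] - open_cost, X[i - 1, 1:] - ge),
            Y[i - 1, 1:] - open_cost,
        )
        # Y[i, j] = max(A[j-1], Y[i, j-1] - ge) with A[k] = max(M,X)[i,k] - open;
        # unrolled, Y[i, j] = max_{k<j} (A[k] + k*ge) - (j-1)*ge, with the
        # initial Y[i, 0] as a pseudo-candidate at k = -1.
        A = np.maximum(M[i], X[i]) - open_cost
        D = np.empty(m + 1)
        D[0] = Y[i, 0] - ge
        D[1:] = A[:-1] + drift[:-1]
        acc = np.maximum.accumulate(D)
        Y[i, 1:] = acc[1:] - drift[:-1]

    # terminal cell: with free end gaps the alignment may stop once one
    # sequence is exhausted; the remainder is a free trailing run.
    end_i, end_j = n, m
    best = max(M[n, m], X[n, m], Y[n, m])
    if free:
        for i in range(n, -1, -1):
            v = max(M[i, m], X[i, m], Y[i, m])
            if v > best:
                best, end_i, end_j = v, i, m
        for j in range(m, -1, -1):
            v = max(M[n, j], X[n, j], Y[n, j])
            if v > best:
                best, end_i, end_j = v, n, j

    # traceback (prefer M, then X=up, then Y=left at equal value)
    out_a: List[str] = []
    out_b: List[str] = []
    i, j = end_i, end_j
    if free:
        out_a.extend(reversed(a[end_i:]))
        out_b.extend("-" * (n - end_i))
        out_a.extend("-" * (m - end_j))
        out_b.extend(reversed(b[end_j:]))
    val = max(M[i][j], X[i][j], Y[i][j])
    state = "M" if M[i][j] == val else ("X" if X[i][j] == val else "Y")
    while i > 0 or j > 0:
        if i == 0:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            continue
        if j == 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        if state == "M":
            s = params.score(a[i - 1], b[j - 1])
            prev = M[i][j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = "M" if M[i][j] == prev else ("X" if X[i][j] == prev else "Y")
        elif state == "X":
            v = X[i][j]
            out_a.append(a[i - 1])
            out_b.append("-")
            if M[i - 1][j] - open_cost == v:
                state = "M"
            elif X[i - 1][j] - ge == v:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            v = Y[i][j]
            out_a.append("-")
            out_b.append(b[j - 1])
            if M[i][j - 1] - open_cost == v:
                state = "M"
            elif Y[i][j - 1] - ge == v:
                state = "Y"
            else:
                state = "X"
            j -= 1

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    ncols = len(aligned_a)
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    identity = 100.0 * matches / ncols if ncols else 0.0

    # coverage: residues inside the core (columns between the first and
    # last position where both sequences have a residue), per sequence
    both = [k for k in range(ncols) if aligned_a[k] != "-" and aligned_b[k] != "-"]
    if both:
        lo, hi = both[0], both[-1]
        core_a = sum(1 for k in range(lo, hi + 1) if aligned_a[k] != "-")
        core_b = sum(1 for k in range(lo, hi + 1) if aligned_b[k] != "-")
        cov_a, cov_b = core_a / n, core_b / m
    else:
        cov_a = cov_b = 0.0

    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=best,
        identity_pct=identity,
        coverage_a=cov_a,
        coverage_b=cov_b,
    )


@dataclass
class SeqCluster:
    """One greedy cluster: a representative id and its member ids."""

    representative: str
    members: List[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def greedy_cluster(
    seqs: Mapping[str, str],
    min_id: float = 0.90,
    min_cov: float = 0.80,
    params: ScoringParams = DEFAULT_PARAMS,
) -> List[SeqCluster]:
    """Deterministic greedy centroid clustering at identity/coverage thresholds.

    Sequences are scanned in (length descending, lexicographic) order; each
    joins the first cluster whose representative aligns at identity >=
    ``min_id`` and min(coverage_a, coverage_b) >= ``min_cov``, otherwise it
    founds a new cluster.  Clusters are returned in creation order (i.e.
    ordered by representative).

    Because identity counts all alignment columns (>= the longer length)
    and matches cannot exceed the shorter length, a pair can only reach
    ``min_id`` if the length ratio does too; shorter candidates are
    skipped without aligning.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), seqs[k], k))
    clusters: List[SeqCluster] = []
    for sid in order:
        seq = seqs[sid].upper()
        placed = False
        for cl in clusters:
            rep = seqs[cl.representative].upper()
            if seq == rep:
                cl.members.append(sid)
                placed = True
                break
            ratio = min(len(seq), len(rep)) / max(len(seq), len(rep))
            if ratio < min_id:
                continue
            res = global_align(rep, seq, params)
            if (
                res.identity_pct >= 100.0 * min_id
                and min(res.coverage_a, res.coverage_b) >= min_cov
            ):
                cl.members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(SeqCluster(representative=sid, members=[sid]))
    return clusters


@dataclass
class UniqueSequence:
    """A deduplicated sequence with its stable name and member genes."""

    name: str
    sequence: str
    isotype: str
    anticodon: str
    member_ids: Tuple[str, ...]


def unique_sequences(genes: Sequence[TRNAGene]) -> List[UniqueSequence]:
    """Exact (case-insensitive) dedup of coding-strand gene sequences.

    Each unique sequence gets a stable name ``<isotype>_<anticodon>_u<k>``
    where k counts unique sequences of that label in lexicographic
    sequence order.  When identical sequences carry conflicting labels the
    majority label wins; ties resolve lexicographically.
    """
    groups: Dict[str, List[TRNAGene]] = {}
    for g in genes:
        groups.setdefault(g.genomic_seq.upper(), []).append(g)
    counters: Counter = Counter()
    out: List[UniqueSequence] = []
    for seq in sorted(groups):
        members = sorted(groups[seq], key=lambda g: g.gene_id)
        labels = Counter((g.isotype, g.anticodon) for g in members)
        top = max(labels.values())
        isotype, anticodon = min(l for l, c in labels.items() if c == top)
        counters[(isotype, anticodon)] += 1
        out.append(
            UniqueSequence(
                name=f"{isotype}_{anticodon}_u{counters[(isotype, anticodon)]}",
                sequence=seq,
                isotype=isotype,
                anticodon=anticodon,
                member_ids=tuple(g.gene_id for g in members),
            )
        )
    return out
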