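"""Consensus-coordinate binding profiles via affine-gap local alignment.

Peak/read sequences are aligned to a LINE-1 consensus with Smith–Waterman
under near-minimal penalties (match +1, mismatch 1, gap open 1, gap extend
1, minimum score 1), which tolerates the high divergence of genomic L1
copies from the consensus.  A gap of length g costs open + g*extend.  Depth
along the consensus is then tallied from the alignment CIGARs and expressed
as ChIP signal over scaled input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cigar import covered_ref_segments, ref_span
from .intervals import IntervalSet, TEAnnotation, annotation_intervals, intersect_any
from .seqio import encode, revcomp

try:  # JIT the DP fill; fall back to the pure-Python fill if numba is absent
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


__all__ = [
    "AlignmentScoring",
    "LocalAlignment",
    "ConsensusProfile",
    "local_align",
    "align_many",
    "profile_from_alignments",
    "extract_region_sequences",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap local alignment scores; defaults permit divergent hits."""

    match: int = 1
    mismatch_penalty: int = 1
    gap_open_penalty: int = 1
    gap_extend_penalty: int = 1
    min_score: int = 1

    def __post_init__(self):
        if self.match < 1:
            raise ValueError("match reward must be >= 1")
        if min(self.mismatch_penalty, self.gap_open_penalty, self.gap_extend_penalty) < 0:
            raise ValueError("penalties must be >= 0")


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a query onto the consensus (0-based half-open)."""

    query_id: str
    ref_start: int
    ref_end: int
    cigar: str
    score: int
    strand: str

    def __post_init__(self):
        if ref_span(self.cigar) != self.ref_end - self.ref_start:
            raise ValueError("CIGAR reference span disagrees with coordinates")


@njit(cache=True)
def _sw_fill(q, r, match, mismatch, gap_first, gap_ext):  # pragma: no cover - jit
    m, n = len(q), len(r)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -10**9, dtype=np.int32)
    F = np.full((m + 1, n + 1), -10**9, dtype=np.int32)
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_first
            if E[i, j - 1] - gap_ext > e:
                e = E[i, j - 1] - gap_ext
            E[i, j] = e
            f = H[i - 1, j] - gap_first
            if F[i - 1, j] - gap_ext > f:
                f = F[i - 1, j] - gap_ext
            F[i, j] = f
            if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                s = H[i - 1, j - 1] + match
            else:
                s = H[i - 1, j - 1] - mismatch
            h = 0
            if s > h:
                h = s
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            if h > best:
                best = h
    return H, E, F, best


def _traceback(H, E, F, q, r, i, j, scoring):
    """Walk back from cell (i, j); diagonal preferred (fewest gaps first)."""
    match, mism = scoring.match, scoring.mismatch_penalty
    gap_first = scoring.gap_open_penalty + scoring.gap_extend_penalty
    gap_ext = scoring.gap_extend_penalty
    ops: list[str] = []
    n_gaps = 0
    end_i, end_j = i, j
    while H[i, j] > 0:
        diag = H[i - 1, j - 1] + (match if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else -mism)
        if H[i, j] == diag:
            ops.append("M")
            i, j = i - 1, j - 1
        elif H[i, j] == E[i, j]:
            n_gaps += 1
            while True:  # gap consuming reference (deletion from query's view)
                ops.append("D")
                if E[i, j] == H[i, j - 1] - gap_first:
                    j -= 1
                    break
                j -= 1
        else:
            n_gaps += 1
            while True:  # gap consuming query (insertion)
                ops.append("I")
                if F[i, j] == H[i - 1, j] - gap_first:
                    i -= 1
                    break
                i -= 1
    ops.reverse()
    return i, j, end_i, end_j, ops, n_gaps


def _compress_ops(ops: Sequence[str]) -> str:
    out = []
    k = 0
    while k < len(ops):
        j = k
        while j < len(ops) and ops[j] == ops[k]:
            j += 1
        out.append(f"{j - k}{ops[k]}")
        k = j
    return "".join(out)


_MAX_TIED_CELLS = 64


def _align_one_strand(q_codes, r_codes, scoring):
    gap_first = scoring.gap_open_penalty + scoring.gap_extend_penalty
    H, E, F, best = _sw_fill(
        q_codes,
        r_codes,
        scoring.match,
        scoring.mismatch_penalty,
        gap_first,
        scoring.gap_extend_penalty,
    )
    if best < scoring.min_score:
        return None
    cells = np.argwhere(H == best)[:_MAX_TIED_CELLS]
    candidates = []
    for i, j in cells:
        qs, rs, qe, je, ops, n_gaps = _traceback(H, E, F, q_codes, r_codes, int(i), int(j), scoring)
        candidates.append((rs, n_gaps, je, qs, qe, ops))
    rs, n_gaps, je, qs, qe, ops = min(candidates)
    cigar_ops = []
    if qs > 0:
        cigar_ops.append(f"{qs}S")
    cigar_ops.append(_compress_ops(ops))
    if qe < len(q_codes):
        cigar_ops.append(f"{len(q_codes) - qe}S")
    return {
        "ref_start": rs,
        "ref_end": je,
        "cigar": "".join(cigar_ops),
        "score": int(best),
        "n_gaps": n_gaps,
    }


def local_align(
    query: str,
    consensus: str,
    scoring: AlignmentScoring = AlignmentScoring(),
    query_id: str = "query",
) -> LocalAlignment | None:
    """Best local alignment of query (either strand) onto the consensus.

    Returns None when the optimum falls below ``scoring.min_score``.
    Tie-breaking: highest score, then smallest ref_start, then fewest gaps,
    then smallest ref_end; an exact strand tie reports "+".  N bases score
    as mismatches.
    """
    if not query or not consensus:
        raise ValueError("empty sequence")
    r_codes = encode(consensus)
    results = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        res = _align_one_strand(encode(q), r_codes, scoring)
        if res is not None:
            results.append((-res["score"], res["ref_start"], res["n_gaps"],
                            res["ref_end"], strand == "-", strand, res))
    if not results:
        return None
    *_, strand, res = min(results)
    return LocalAlignment(
        query_id=query_id,
        ref_start=res["ref_start"],
        ref_end=res["ref_end"],
        cigar=res["cigar"],
        score=res["score"],
        strand=strand,
    )


def align_many(
    queries: Iterable[tuple[str, str]] | Iterable[str],
    consensus: str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> list[LocalAlignment]:
    """Best alignment per query; sub-threshold queries are dropped.

    Only the single best local alignment of each query is kept (the primary
    alignment of a read-mapper).  ``queries`` may be sequences or
    (id, sequence) pairs.
    """
    out = []
    for k, item in enumerate(queries):
        qid, seq = item if isinstance(item, tuple) else (f"q{k}", item)
        aln = local_align(seq, consensus, scoring, query_id=qid)
        if aln is not None:
            out.append(aln)
    return out


@dataclass
class ConsensusProfile:
    """Per-position ChIP and input depth along the consensus, plus ratio."""

    depth_chip: np.ndarray
    depth_input: np.ndarray
    ratio: np.ndarray
    input_scale: float
    pseudocount: float

    @property
    def consensus_length(self) -> int:
        return len(self.depth_chip)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "pos": np.arange(self.consensus_length),
                "chip": self.depth_chip,
                "input": self.depth_input,
                "ratio": self.ratio,
            }
        ).to_csv(path, sep="\t", index=False)


def _depth(alignments: Iterable[LocalAlignment], length: int) -> np.ndarray:
    depth = np.zeros(length)
    for aln in alignments:
        if aln.ref_start < 0 or aln.ref_end > length:
            raise ValueError(
                f"alignment [{aln.ref_start},{aln.ref_end}) outside consensus of length {length}"
            )
        for s, e in covered_ref_segments(aln.ref_start, aln.cigar):
            depth[s:e] += 1
    return depth


def profile_from_alignments(
    chip: Iterable[LocalAlignment],
    input_: Iterable[LocalAlignment],
    consensus_length: int,
    pseudocount: float = 1.0,
) -> ConsensusProfile:
    """Signal-over-input depth profile along the consensus.

    Depth counts alignments covering each position through M/=/X/D CIGAR ops
    (deletions span the reference, insertions do not).  The input track is
    scaled by s = total chip aligned bases / total input aligned bases, and
    ratio[i] = (chip[i] + eps) / (s * input[i] + eps).
    """
    depth_chip = _depth(chip, consensus_length)
    depth_input = _depth(input_, consensus_length)
    total_chip, total_input = depth_chip.sum(), depth_input.sum()
    scale = float(total_chip / total_input) if total_input > 0 else 1.0
    eps = pseudocount
    ratio = (depth_chip + eps) / (scale * depth_input + eps)
    return ConsensusProfile(depth_chip, depth_input, ratio, scale, eps)


def extract_region_sequences(
    reads_or_peaks: IntervalSet,
    genome: Mapping[str, str],
    l1_annotations: Iterable[TEAnnotation],
) -> list[str]:
    """Forward-strand genomic sequences of intervals overlapping >=1 L1 copy."""
    subject = annotation_intervals(list(l1_annotations), reads_or_peaks.layout)
    hits = intersect_any(reads_or_peaks, subject)
    out = []
    for iv in hits:
        seq = genome[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"interval {iv} beyond chromosome end")
        out.append(seq[iv.start : iv.end].upper())
    return out
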