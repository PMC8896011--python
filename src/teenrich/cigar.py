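"""CIGAR string parsing shared by coverage, profiling and indel detection."""

from __future__ import annotations

import re

__all__ = ["parse_cigar", "ref_span", "query_span", "covered_ref_segments", "has_indel"]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: ops that consume the reference
REF_OPS = frozenset("MDN=X")
#: ops that consume the query
QUERY_OPS = frozenset("MIS=X")
#: ops counted as covering the reference (deletions span it, skips do not)
COVER_OPS = frozenset("MD=X")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops or "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return ops


def ref_span(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in REF_OPS)


def query_span(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in QUERY_OPS)


def covered_ref_segments(start: int, cigar: str) -> list[tuple[int, int]]:
    """Half-open reference segments covered by M/=/X/D ops (N splits segments)."""
    segments: list[tuple[int, int]] = []
    pos = start
    for op, n in parse_cigar(cigar):
        if op in COVER_OPS:
            if segments and segments[-1][1] == pos:
                segments[-1] = (segments[-1][0], pos + n)
            else:
                segments.append((pos, pos + n))
            pos += n
        elif op == "N":
            pos += n
    return segments


def has_indel(cigar: str) -> bool:
    return any(op in "ID" for op, _ in parse_cigar(cigar))
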