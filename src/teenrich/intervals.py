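"""Genomic-interval data model and BEDtools-compatible set operations.

Coordinates are 0-based half-open everywhere (BED convention).  Overlap means
at least one shared base pair; half-open abutment ([0,10) vs [10,20)) is not
overlap.  Iteration over an :class:`IntervalSet` is deterministic: sorted by
the layout's chromosome order, then start, then end, then strand, then name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "TEAnnotation",
    "IntervalSet",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_repeatmasker",
    "write_repeatmasker",
    "intersect_any",
    "nearest_distance",
]

STRANDS = ("+", "-", ".")


class BedFormatError(ValueError):
    """Malformed record in a BED-like file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths: the coordinate universe.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers in canonical order.
    chrom_lengths
        Length in bp per chromosome, keyed by name.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names in layout")
        if set(self.chrom_names) != set(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths disagree")
        for name, length in self.chrom_lengths.items():
            if int(length) < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        object.__setattr__(
            self, "chrom_lengths", {n: int(self.chrom_lengths[n]) for n in self.chrom_names}
        )

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), dict(lengths))

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def __len__(self) -> int:
        return len(self.chrom_names)

    def chrom_index(self, chrom: str) -> int:
        return self.chrom_names.index(chrom)


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between closest edges; 0 when overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def validate(self, layout: GenomeLayout) -> None:
        if self.chrom not in layout:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > layout.chrom_lengths[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:[{self.start},{self.end}) exceeds "
                f"chromosome length {layout.chrom_lengths[self.chrom]}"
            )


@dataclass(frozen=True)
class TEAnnotation:
    """One RepeatMasker-style repeat copy: interval plus repeat identity."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    repeat_family: str
    divergence_pct: float | None = None


def _sort_key(layout: GenomeLayout):
    order = {name: i for i, name in enumerate(layout.chrom_names)}

    def key(iv: GenomicInterval):
        return (order[iv.chrom], iv.start, iv.end, iv.strand, iv.name)

    return key


class IntervalSet:
    """A deterministic, layout-validated collection of :class:`GenomicInterval`."""

    def __init__(self, intervals: Iterable[GenomicInterval], layout: GenomeLayout):
        self.layout = layout
        ivs = list(intervals)
        for iv in ivs:
            iv.validate(layout)
        self._intervals = sorted(ivs, key=_sort_key(layout))

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IntervalSet)
            and self.layout == other.layout
            and self._intervals == other._intervals
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals over {len(self.layout)} chromosomes)"

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees (half-open, matching our convention)."""
        out: dict[str, IntervalTree] = {}
        for chrom, ivs in self.by_chrom().items():
            out[chrom] = IntervalTree.from_tuples((iv.start, iv.end, iv) for iv in ivs)
        return out


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a UCSC chrom.sizes two-column (name, length) table."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedFormatError("expected 2 tab-separated columns", lineno)
            names.append(fields[0])
            lengths[fields[0]] = int(fields[1])
    return GenomeLayout(tuple(names), lengths)


def _parse_bed_line(fields: Sequence[str], lineno: int) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedFormatError(f"non-integer coordinate: {exc}", lineno) from None
    if start < 0 or start >= end:
        raise BedFormatError(f"invalid coordinates start={start} end={end}", lineno)
    name = fields[3] if len(fields) > 3 else "."
    score: float | None = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        score = float(fields[4])
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in STRANDS:
        raise BedFormatError(f"invalid strand {strand!r}", lineno)
    return GenomicInterval(fields[0], start, end, strand, name, score)


def read_bed(path: str | Path, layout: GenomeLayout, *, strict: bool = False) -> IntervalSet:
    """Read a BED3/BED6 file into an :class:`IntervalSet`.

    Records on chromosomes absent from *layout* (alt contigs in public files)
    are skipped with a warning by default; ``strict=True`` raises instead.
    Malformed coordinates always raise, with the offending line number.
    """
    intervals: list[GenomicInterval] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError("expected >=3 tab-separated columns", lineno)
            iv = _parse_bed_line(fields, lineno)
            if iv.chrom not in layout:
                if strict:
                    raise BedFormatError(f"unknown chromosome {iv.chrom!r}", lineno)
                skipped += 1
                continue
            try:
                iv.validate(layout)
            except ValueError as exc:
                raise BedFormatError(str(exc), lineno) from None
            intervals.append(iv)
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} record(s) on chromosomes absent from layout",
            stacklevel=2,
        )
    return IntervalSet(intervals, layout)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (score '.' when absent); coordinates verbatim."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


_RMSK_COLUMNS = ("chrom", "start", "end", "strand", "repeat_name", "repeat_class", "repeat_family")


def read_repeatmasker(
    path: str | Path,
    layout: GenomeLayout,
    *,
    one_based: bool = False,
    strict: bool = False,
) -> list[TEAnnotation]:
    """Read a UCSC-rmsk-dialect annotation table.

    Tab-separated columns: chrom, start, end, strand, repeat_name,
    repeat_class, repeat_family, and optionally divergence_pct.  A leading
    header naming the first column ``chrom`` (or a ``#`` line) is skipped.
    ``one_based=True`` converts RepeatMasker .out-style 1-based inclusive
    starts to the internal 0-based half-open convention.

    A repeat name carrying two different (class, family) pairs within one
    file triggers a consistency warning listing the offenders.
    """
    annotations: list[TEAnnotation] = []
    name_to_cf: dict[str, tuple[str, str]] = {}
    offenders: set[str] = set()
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":
                continue
            if len(fields) < 7:
                raise BedFormatError("expected >=7 tab-separated columns", lineno)
            chrom, start_s, end_s, strand, rname, rclass, rfamily = fields[:7]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedFormatError(f"non-integer coordinate: {exc}", lineno) from None
            if one_based:
                start -= 1
            if chrom not in layout:
                if strict:
                    raise BedFormatError(f"unknown chromosome {chrom!r}", lineno)
                skipped += 1
                continue
            if start < 0 or start >= end:
                raise BedFormatError(f"invalid coordinates start={start} end={end}", lineno)
            divergence = float(fields[7]) if len(fields) > 7 and fields[7] not in (".", "") else None
            iv = GenomicInterval(chrom, start, end, strand, rname)
            try:
                iv.validate(layout)
            except ValueError as exc:
                raise BedFormatError(str(exc), lineno) from None
            cf = (rclass, rfamily)
            prev = name_to_cf.setdefault(rname, cf)
            if prev != cf:
                offenders.add(rname)
            annotations.append(TEAnnotation(iv, rname, rclass, rfamily, divergence))
    if offenders:
        warnings.warn(
            "inconsistent class/family for repeat name(s): " + ", ".join(sorted(offenders)),
            stacklevel=2,
        )
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} annotation(s) on chromosomes absent from layout",
            stacklevel=2,
        )
    return annotations


def write_repeatmasker(annotations: Iterable[TEAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_RMSK_COLUMNS + ("divergence_pct",)) + "\n")
        for ann in annotations:
            iv = ann.interval
            div = "." if ann.divergence_pct is None else format(ann.divergence_pct, "g")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{ann.repeat_name}\t{ann.repeat_class}\t{ann.repeat_family}\t{div}\n"
            )


def annotation_intervals(
    annotations: Iterable[TEAnnotation], layout: GenomeLayout
) -> IntervalSet:
    """IntervalSet view of annotations (interval names = repeat names)."""
    return IntervalSet((a.interval for a in annotations), layout)


def merge_intervals(ivs: Iterable[GenomicInterval]) -> tuple[np.ndarray, np.ndarray]:
    """Merged, sorted (starts, ends) arrays of possibly overlapping intervals."""
    pairs = sorted((iv.start, iv.end) for iv in ivs)
    starts: list[int] = []
    ends: list[int] = []
    for s, e in pairs:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


class OverlapIndex:
    """Merged per-chromosome subject intervals with vectorised any-overlap tests."""

    def __init__(self, subjects: IntervalSet):
        self.layout = subjects.layout
        self._merged = {
            chrom: merge_intervals(ivs) for chrom, ivs in subjects.by_chrom().items()
        }

    def overlaps_any(self, queries: IntervalSet) -> np.ndarray:
        """Boolean per query interval (in the set's deterministic order)."""
        if queries.layout != self.layout:
            raise ValueError("interval sets are bound to different genome layouts")
        out = np.zeros(len(queries), dtype=bool)
        offset = 0
        for chrom, ivs in queries.by_chrom().items():
            n = len(ivs)
            merged = self._merged.get(chrom)
            if merged is not None and len(merged[0]):
                m_starts, m_ends = merged
                q_starts = np.fromiter((iv.start for iv in ivs), np.int64, n)
                q_ends = np.fromiter((iv.end for iv in ivs), np.int64, n)
                idx = np.searchsorted(m_starts, q_ends, side="left")
                hit = (idx > 0) & (m_ends[np.maximum(idx - 1, 0)] > q_starts)
                out[offset : offset + n] = hit
            offset += n
        return out


def intersect_any(a: IntervalSet, b: IntervalSet | OverlapIndex) -> IntervalSet:
    """Subset of *a* overlapping (>=1 bp) at least one interval of *b*.

    Each a-interval is reported at most once (``bedtools intersect -u``
    semantics); output order follows IntervalSet's deterministic sort.
    *b* may be a pre-built :class:`OverlapIndex` to amortise repeated tests.
    """
    index = b if isinstance(b, OverlapIndex) else OverlapIndex(b)
    hit = index.overlaps_any(a)
    return IntervalSet((iv for iv, h in zip(a, hit) if h), a.layout)


def count_overlapping(a: IntervalSet, b: IntervalSet | OverlapIndex) -> int:
    """Number of a-intervals overlapping >=1 b-interval (``-u`` count)."""
    index = b if isinstance(b, OverlapIndex) else OverlapIndex(b)
    return int(index.overlaps_any(a).sum())


def nearest_distance(
    query: IntervalSet, subjects: IntervalSet
) -> list[tuple[GenomicInterval, int | None]]:
    """Distance in bp from each query interval to its nearest subject.

    Distance is 0 for any overlap, else the gap between closest edges;
    strand is ignored.  Ties go to the leftmost subject (same distance
    either way).  Queries with no same-chromosome subject get ``None``.
    """
    if query.layout != subjects.layout:
        raise ValueError("interval sets are bound to different genome layouts")
    import bisect

    by_chrom = subjects.by_chrom()
    # per chromosome: subject starts (sorted already) and running max of ends
    index: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in by_chrom.items():
        starts = [iv.start for iv in ivs]
        ends = [iv.end for iv in ivs]
        run_max_end = []
        m = 0
        for e in ends:
            m = max(m, e)
            run_max_end.append(m)
        index[chrom] = (starts, run_max_end)

    out: list[tuple[GenomicInterval, int | None]] = []
    for q in query:
        if q.chrom not in index:
            out.append((q, None))
            continue
        starts, run_max_end = index[q.chrom]
        # nearest on the right: first subject with start >= q.end
        i = bisect.bisect_left(starts, q.end)
        right = starts[i] - q.end if i < len(starts) else None
        # nearest on the left / overlap: largest end among subjects with start < q.end
        left = None
        if i > 0:
            left = max(0, q.start - run_max_end[i - 1])
            # any subject with end > q.start among the first i overlaps q
        candidates = [d for d in (left, right) if d is not None]
        out.append((q, min(candidates) if candidates else None))
    return out
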