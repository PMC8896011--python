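"""RNA-seq quantification over L1 elements and CRISPR indel detection.

Fragment counting uses union semantics: a paired-end fragment counts once
toward a region when at least one of its records overlaps it by >=1
reference bp.  Expression is reported as fragments per million (fpm) and,
where region lengths are known, FPKM.  The indel detector classifies each
aligned record by whether its CIGAR carries an insertion or deletion and
reports the per-position ratio of indel-bearing depth over total depth —
high ratios at an sgRNA target site indicate successful disruption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cigar import covered_ref_segments, has_indel, ref_span
from .intervals import GenomeLayout, GenomicInterval, IntervalSet

__all__ = [
    "AlignmentRecord",
    "ExpressionTable",
    "GuideVerdict",
    "read_sam",
    "write_sam",
    "count_fragments",
    "downstream_windows",
    "indel_coverage_ratio",
    "disruption_call",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal aligned-read record; paired mates share ``fragment_id``."""

    chrom: str
    start: int
    cigar: str
    strand: str = "+"
    is_primary: bool = True
    is_unique: bool = True
    fragment_id: str = ""

    def __post_init__(self):
        if ref_span(self.cigar) < 1:
            raise ValueError(f"CIGAR {self.cigar!r} consumes no reference")

    @property
    def end(self) -> int:
        return self.start + ref_span(self.cigar)


#: mapping quality at or above which a record counts as uniquely mapped
UNIQUE_MAPQ = 30


def read_sam(path: str | Path, unique_mapq: int = UNIQUE_MAPQ) -> list[AlignmentRecord]:
    """Read mapped records from a SAM file (text; subset of fields).

    ``fragment_id`` is the query name; ``is_unique`` proxies mapping quality
    >= ``unique_mapq``; secondary/supplementary records are kept but flagged
    non-primary.
    """
    import pysam

    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.cigarstring is None:
                continue
            records.append(
                AlignmentRecord(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    cigar=rec.cigarstring,
                    strand="-" if rec.is_reverse else "+",
                    is_primary=not (rec.is_secondary or rec.is_supplementary),
                    is_unique=rec.mapping_quality >= unique_mapq,
                    fragment_id=rec.query_name,
                )
            )
    return records


def write_sam(
    records: Iterable[AlignmentRecord], layout: GenomeLayout, path: str | Path
) -> None:
    """Write records as minimal SAM (flags encode strand/primary; MAPQ encodes uniqueness)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in layout.chrom_names:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{layout.chrom_lengths[chrom]}\n")
        for rec in records:
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if not rec.is_primary:
                flag |= 256
            mapq = 60 if rec.is_unique else 0
            fh.write(
                f"{rec.fragment_id or '*'}\t{flag}\t{rec.chrom}\t{rec.start + 1}\t"
                f"{mapq}\t{rec.cigar}\t*\t0\t0\t*\t*\n"
            )


@dataclass
class ExpressionTable:
    """Per-region fragment counts with fpm/fpkm, plus the library size."""

    table: pd.DataFrame  # columns: region, length, count, fpm, fpkm
    library_size: int

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __getitem__(self, region: str) -> pd.Series:
        return self.table.set_index("region").loc[region]


def count_fragments(
    alignments: Iterable[AlignmentRecord],
    regions: IntervalSet,
    unique_only: bool = True,
) -> ExpressionTable:
    """Union-semantics fragment counts over regions.

    A fragment is counted once per region when any of its records overlaps
    the region by >=1 bp of reference-consuming CIGAR.  ``unique_only``
    drops fragments with any non-unique record.  The library size is the
    number of counted-eligible fragments; fpm = count * 1e6 / library_size
    and fpkm = fpm * 1e3 / region_length.
    """
    by_fragment: dict[str, list[AlignmentRecord]] = {}
    for k, rec in enumerate(alignments):
        if not rec.is_primary:
            continue
        by_fragment.setdefault(rec.fragment_id or f"frag{k}", []).append(rec)

    region_list = list(regions)
    region_ids = [
        iv.name if iv.name not in (".", "") else f"{iv.chrom}:{iv.start}-{iv.end}"
        for iv in region_list
    ]
    trees = regions.trees()
    # map tree payload (interval object) back to positional index
    idx_of = {id(iv): i for i, iv in enumerate(region_list)}

    counts = np.zeros(len(region_list), dtype=np.int64)
    library_size = 0
    for frag_id, recs in by_fragment.items():
        if unique_only and not all(r.is_unique for r in recs):
            continue
        if len({r.chrom for r in recs}) > 1:
            warnings.warn(f"fragment {frag_id!r} has mates on different chromosomes",
                          stacklevel=2)
        library_size += 1
        hit: set[int] = set()
        for r in recs:
            tree = trees.get(r.chrom)
            if tree is None:
                continue
            for s, e in covered_ref_segments(r.start, r.cigar):
                for node in tree.overlap(s, e):
                    hit.add(idx_of[id(node.data)])
        for i in hit:
            counts[i] += 1

    lengths = np.array([len(iv) for iv in region_list], dtype=float)
    fpm = counts * 1e6 / library_size if library_size else np.zeros_like(counts, dtype=float)
    fpkm = fpm * 1e3 / lengths
    table = pd.DataFrame(
        {
            "region": region_ids,
            "length": lengths.astype(int),
            "count": counts,
            "fpm": fpm,
            "fpkm": fpkm,
        }
    )
    return ExpressionTable(table=table, library_size=library_size)


def downstream_windows(
    elements: IntervalSet, width: int = 1000
) -> IntervalSet:
    """Fixed-width windows immediately 3' of each stranded element.

    For + elements [end, end+width); for − elements [start−width, start).
    Windows are clipped at chromosome bounds; a clipped window, or one
    overlapping any source element, carries a ``clipped``/``overlaps_element``
    marker in its name suffix.
    """
    layout = elements.layout
    sources = list(elements)
    trees = elements.trees()
    windows = []
    for iv in sources:
        if iv.strand not in "+-":
            raise ValueError(f"unstranded element {iv}")
        if iv.strand == "+":
            lo, hi = iv.end, iv.end + width
        else:
            lo, hi = iv.start - width, iv.start
        clipped_lo, clipped_hi = max(lo, 0), min(hi, layout.chrom_lengths[iv.chrom])
        if clipped_hi <= clipped_lo:
            continue
        flags = []
        if (clipped_lo, clipped_hi) != (lo, hi):
            flags.append("clipped")
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(clipped_lo, clipped_hi):
            flags.append("overlaps_element")
        name = iv.name if iv.name not in (".", "") else f"{iv.chrom}:{iv.start}-{iv.end}"
        name += "_down" + ("|" + ",".join(flags) if flags else "")
        windows.append(
            GenomicInterval(iv.chrom, clipped_lo, clipped_hi, iv.strand, name)
        )
    return IntervalSet(windows, layout)


def indel_coverage_ratio(
    alignments: Iterable[AlignmentRecord], target_length: int
) -> np.ndarray:
    """Per-position indel-bearing depth over total depth on a cDNA reference.

    A record is indel-bearing iff its CIGAR contains >=1 I or D op.  Depth
    counts reference-covering ops (M/=/X/D).  Positions with zero total
    depth are NaN and excluded from summaries.
    """
    depth_total = np.zeros(target_length)
    depth_indel = np.zeros(target_length)
    for rec in alignments:
        indel = has_indel(rec.cigar)
        for s, e in covered_ref_segments(rec.start, rec.cigar):
            s, e = max(s, 0), min(e, target_length)
            if s >= e:
                continue
            depth_total[s:e] += 1
            if indel:
                depth_indel[s:e] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(depth_total > 0, depth_indel / np.maximum(depth_total, 1), np.nan)
    return ratio


@dataclass(frozen=True)
class GuideVerdict:
    """Disruption verdict at one sgRNA site."""

    position: int
    treated_mean: float
    control_mean: float
    disrupted: bool


def disruption_call(
    ratio_profile: np.ndarray,
    guide_sites: Sequence[int],
    window: int = 20,
    background_profile: np.ndarray | None = None,
    min_ratio: float = 0.10,
    max_control: float = 0.02,
) -> list[GuideVerdict]:
    """Call CRISPR disruption per guide from indel-coverage ratios.

    A guide is "disrupted" when the mean treated ratio within ±window of
    its site is >= ``min_ratio`` while the control mean at the same window
    is < ``max_control``.  Windows are clipped at the profile ends; NaN
    (uncovered) positions are excluded from the means.
    """
    n = len(ratio_profile)
    if background_profile is None:
        background_profile = np.zeros(n)
    verdicts = []
    for pos in guide_sites:
        if not (0 <= pos < n):
            raise ValueError(f"guide position {pos} outside profile of length {n}")
        lo, hi = max(0, pos - window), min(n, pos + window + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            treated = float(np.nanmean(ratio_profile[lo:hi]))
            control = float(np.nanmean(background_profile[lo:hi]))
        treated = 0.0 if np.isnan(treated) else treated
        control = 0.0 if np.isnan(control) else control
        verdicts.append(
            GuideVerdict(
                position=int(pos),
                treated_mean=treated,
                control_mean=control,
                disrupted=bool(treated >= min_ratio and control < max_control),
            )
        )
    return verdicts
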