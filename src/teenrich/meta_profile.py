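"""Coverage tracks, meta-profile matrices, and theoretical mappability.

Meta-profiles come in two flavours: anchor mode (binned signal in a fixed
window around each anchor midpoint, e.g. motif occurrences ± 1 kb) and
scaled mode (each region's signal linearly rescaled to a common length,
e.g. full-length L1 elements normalised to 5 kb).  Rows of minus-strand
features are flipped so every row reads 5'→3'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cigar import covered_ref_segments
from .intervals import GenomeLayout, GenomicInterval, IntervalSet

__all__ = [
    "CoverageTrack",
    "ProfileMatrix",
    "anchor_matrix",
    "scaled_region_matrix",
    "mappability_track",
    "coverage_from_alignments",
]


@dataclass
class CoverageTrack:
    """Dense per-base signal per chromosome, bound to a genome layout."""

    data: dict[str, np.ndarray]
    layout: GenomeLayout

    def __post_init__(self):
        for chrom in self.layout.chrom_names:
            if chrom not in self.data:
                self.data[chrom] = np.zeros(self.layout.chrom_lengths[chrom])
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) != self.layout.chrom_lengths[chrom]:
                raise ValueError(
                    f"track length {len(arr)} != chromosome length "
                    f"{self.layout.chrom_lengths[chrom]} for {chrom!r}"
                )
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in track for {chrom!r}")
            self.data[chrom] = arr

    @classmethod
    def zeros(cls, layout: GenomeLayout) -> "CoverageTrack":
        return cls({c: np.zeros(layout.chrom_lengths[c]) for c in layout.chrom_names}, layout)

    @classmethod
    def constant(cls, layout: GenomeLayout, value: float) -> "CoverageTrack":
        return cls(
            {c: np.full(layout.chrom_lengths[c], float(value)) for c in layout.chrom_names},
            layout,
        )

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    @property
    def mean(self) -> float:
        total = sum(a.sum() for a in self.data.values())
        return total / self.layout.total_length

    def to_bedgraph(self, path: str | Path) -> None:
        """Run-length encoded bedGraph (zero runs included for losslessness)."""
        with open(path, "w") as fh:
            for chrom in self.layout.chrom_names:
                arr = self.data[chrom]
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, layout: GenomeLayout) -> "CoverageTrack":
        track = cls.zeros(layout)
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split("\t")[:4]
                if chrom in layout:
                    track.data[chrom][int(s) : int(e)] = float(v)
        return track


@dataclass
class ProfileMatrix:
    """Rows = anchors/regions (stable ids), columns = bins of mean signal."""

    values: np.ndarray
    row_ids: list[str]
    bin_size: int
    mode: str  # "anchor" or "scaled"
    flank: int | None = None
    target_len: int | None = None
    group_labels: list[str] | None = None

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row_means(self) -> np.ndarray:
        return np.nanmean(self.values, axis=1)

    def column_means(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    def central_bin_means(self, n_central: int = 1) -> np.ndarray:
        """Per-row mean over the n_central bins around the matrix centre."""
        mid = self.n_bins // 2
        lo = max(0, mid - n_central // 2)
        hi = min(self.n_bins, lo + n_central)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values[:, lo:hi], axis=1)

    def sorted_by_mean(self) -> "ProfileMatrix":
        """Rows in descending mean signal (heatmap presentation order)."""
        order = np.argsort(-np.nan_to_num(self.row_means()))
        return ProfileMatrix(
            self.values[order],
            [self.row_ids[i] for i in order],
            self.bin_size,
            self.mode,
            self.flank,
            self.target_len,
            [self.group_labels[i] for i in order] if self.group_labels else None,
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mode={self.mode} bin_size={self.bin_size} "
                     f"flank={self.flank} target_len={self.target_len}\n")
            df = pd.DataFrame(self.values, index=self.row_ids)
            df.index.name = "region"
            df.to_csv(fh, sep="\t")


def _bin_means(values: np.ndarray, bin_size: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(values.reshape(-1, bin_size), axis=1)


def _row_id(iv: GenomicInterval, k: int) -> str:
    base = f"{iv.chrom}:{iv.start}-{iv.end}#{k}"
    return base if iv.name in (".", "") else f"{iv.name}|{base}"


def anchor_matrix(
    track: CoverageTrack,
    anchors: IntervalSet,
    flank: int = 1000,
    bin_size: int = 50,
) -> ProfileMatrix:
    """Binned mean signal in [midpoint − flank, midpoint + flank) per anchor.

    Minus-strand rows are reversed.  Parts of the window truncated by a
    chromosome end are NaN (excluded from bin means and summaries).
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    rows, ids, labels = [], [], []
    for k, iv in enumerate(anchors):
        if iv.chrom not in track.layout:
            raise ValueError(f"anchor on unknown chromosome {iv.chrom!r}")
        arr = track[iv.chrom]
        mid = iv.midpoint
        lo, hi = mid - flank, mid + flank
        window = np.full(2 * flank, np.nan)
        s, e = max(lo, 0), min(hi, len(arr))
        if s < e:
            window[s - lo : e - lo] = arr[s:e]
        if iv.strand == "-":
            window = window[::-1]
        rows.append(_bin_means(window, bin_size))
        ids.append(_row_id(iv, k))
        labels.append(iv.name)
    values = np.vstack(rows) if rows else np.zeros((0, 2 * flank // bin_size))
    return ProfileMatrix(values, ids, bin_size, "anchor", flank=flank, group_labels=labels)


def scaled_region_matrix(
    track: CoverageTrack,
    regions: IntervalSet,
    target_len: int = 5000,
    bin_size: int = 50,
) -> ProfileMatrix:
    """Each region's signal linearly rescaled to target_len bp, then binned.

    Values (not mass) are interpolated, so a constant region stays constant
    regardless of its true length.  Minus-strand rows are flipped after
    scaling so all rows read 5'→3'.  Region order is preserved (group
    panels keep their input ordering).
    """
    if target_len % bin_size:
        raise ValueError("target_len must be a multiple of bin_size")
    rows, ids, labels = [], [], []
    for k, iv in enumerate(regions):
        arr = track[iv.chrom][iv.start : iv.end]
        if len(arr) == 1:
            scaled = np.full(target_len, arr[0])
        else:
            xp = np.arange(len(arr))
            x = np.linspace(0, len(arr) - 1, target_len)
            scaled = np.interp(x, xp, arr)
        if iv.strand == "-":
            scaled = scaled[::-1]
        rows.append(_bin_means(scaled, bin_size))
        ids.append(_row_id(iv, k))
        labels.append(iv.name)
    values = np.vstack(rows) if rows else np.zeros((0, target_len // bin_size))
    return ProfileMatrix(
        values, ids, bin_size, "scaled", target_len=target_len, group_labels=labels
    )


def mappability_track(genome: Mapping[str, str], k: int = 100) -> CoverageTrack:
    """Theoretical k-mer mappability: 1 / occurrence count, both strands.

    The value at position i is 1/(number of occurrences of the k-mer
    starting at i anywhere in the genome, counting both strands), so 1 marks
    globally unique sequence and 1/2 a two-copy repeat.  The last k−1
    positions of a chromosome, where no k-mer starts, repeat the last
    defined value.
    """
    from .seqio import layout_from_genome, revcomp

    layout = layout_from_genome(dict(genome))
    if k > min(layout.chrom_lengths.values()):
        raise ValueError("k exceeds the shortest chromosome")
    for seq in genome.values():
        if set(seq) - set("ACGTN"):
            raise ValueError("genome contains non-ACGTN letters")

    counts: dict[str, int] = {}
    for seq in genome.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1

    track = CoverageTrack.zeros(layout)
    for chrom, seq in genome.items():
        arr = track.data[chrom]
        last = 1.0
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            rc = revcomp(kmer)
            occ = counts.get(kmer, 0) + (counts.get(rc, 0) if rc != kmer else 0)
            last = 1.0 / occ
            arr[i] = last
        arr[len(seq) - k + 1 :] = last
    return track


def coverage_from_alignments(
    alignments: Iterable,
    layout: GenomeLayout,
    mode: str = "all_primary",
    normalize_1x: bool = False,
) -> CoverageTrack:
    """Per-bp depth from alignment records (M/=/X/D cover; N/I/S do not).

    ``mode="unique_only"`` keeps records flagged unique; ``"all_primary"``
    keeps primary records regardless of uniqueness.  ``normalize_1x``
    rescales so the genome-wide mean depth is 1 (deepTools --normalizeTo1x
    analogue).
    """
    if mode not in ("unique_only", "all_primary"):
        raise ValueError(f"unknown mode {mode!r}")
    track = CoverageTrack.zeros(layout)
    for rec in alignments:
        if not rec.is_primary:
            continue
        if mode == "unique_only" and not rec.is_unique:
            continue
        arr = track.data[rec.chrom]
        for s, e in covered_ref_segments(rec.start, rec.cigar):
            arr[s : min(e, len(arr))] += 1
    if normalize_1x:
        mean = track.mean
        if mean > 0:
            for arr in track.data.values():
                arr /= mean
    return track
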