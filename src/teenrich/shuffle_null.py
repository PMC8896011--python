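"""Shuffled-interval null model and TE-class enrichment screening.

The screen relocates each peak to a random genomic position (chromosome
chosen with probability proportional to its length, then a uniform legal
start), keeping its length, avoiding a blacklist and — by default —
previously placed intervals, with a bounded number of attempts per interval.
Observed peak/TE-class intersection counts are compared with the mean over
``n_shuffles`` independent shuffles as ``log2((obs + eps) / (exp + eps))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    OverlapIndex,
    TEAnnotation,
    annotation_intervals,
    count_overlapping,
)

__all__ = [
    "ShuffleConfig",
    "EnrichmentMatrix",
    "EnrichmentCalls",
    "DEFAULT_CLASSES",
    "shuffle_intervals",
    "class_intersection_counts",
    "enrichment_matrix",
    "classify_enriched",
]

#: Abundant TE classes screened by default (LTR retrovirus subclasses kept
#: separate, mirroring common RepeatMasker class/family usage).
DEFAULT_CLASSES = ("LINE", "SINE", "LTR", "DNA")


@dataclass(frozen=True)
class ShuffleConfig:
    """Parameters of the shuffled background model.

    ``n_shuffles`` independent relocations of the whole peak set are
    averaged into the expected count.  ``exclude`` is a blacklist of regions
    no shuffled interval may touch.  ``no_overlap`` forbids shuffled
    intervals from overlapping each other; placement of one interval is
    retried up to ``max_tries`` times before it is dropped (with a warning
    and a recorded drop count).
    """

    n_shuffles: int = 10
    exclude: IntervalSet | None = None
    no_overlap: bool = True
    max_tries: int = 1000
    seed: int = 0
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.max_tries < 1:
            raise ValueError("max_tries must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class EnrichmentMatrix:
    """Experiments x TE-classes enrichment table.

    ``observed`` holds integer peak/class intersection counts, ``expected``
    the mean over shuffles (rescaled for dropped intervals), ``log2_ratio``
    the pseudocount-stabilised log2(obs/exp).  ``shuffle_counts`` retains the
    per-shuffle counts; ``n_peaks`` and ``dropped`` record per-experiment
    peak totals and mean dropped-per-shuffle counts.
    """

    observed: pd.DataFrame
    expected: pd.DataFrame
    log2_ratio: pd.DataFrame
    shuffle_counts: dict[str, pd.DataFrame]
    n_peaks: pd.Series
    dropped: pd.Series
    pseudocount: float = 1.0

    @property
    def experiments(self) -> list[str]:
        return list(self.observed.index)

    @property
    def classes(self) -> list[str]:
        return list(self.observed.columns)

    def ratio(self) -> pd.DataFrame:
        """Pseudocount-adjusted observed/expected fold ratio."""
        eps = self.pseudocount
        return (self.observed + eps) / (self.expected + eps)

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format (experiment, te_class, observed, expected, log2_ratio)."""
        long = (
            self.log2_ratio.stack()
            .rename("log2_ratio")
            .reset_index()
            .rename(columns={"level_0": "experiment", "level_1": "te_class"})
        )
        long["observed"] = [
            self.observed.at[r, c] for r, c in zip(long["experiment"], long["te_class"])
        ]
        long["expected"] = [
            self.expected.at[r, c] for r, c in zip(long["experiment"], long["te_class"])
        ]
        return long[["experiment", "te_class", "observed", "expected", "log2_ratio"]]

    def to_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def _merged_starts_ends(regions: Iterable[GenomicInterval]) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted((iv.start, iv.end) for iv in regions)
    starts: list[int] = []
    ends: list[int] = []
    for s, e in ivs:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


class _OcclusionIndex:
    """Per-chromosome occupied regions with O(log n) overlap checks and inserts."""

    def __init__(self, layout: GenomeLayout, exclude: IntervalSet | None):
        self._regions: dict[str, tuple[list[int], list[int]]] = {
            c: ([], []) for c in layout.chrom_names
        }
        if exclude is not None:
            for chrom, ivs in exclude.by_chrom().items():
                s, e = _merged_starts_ends(ivs)
                self._regions[chrom] = (list(s), list(e))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        import bisect

        starts, ends = self._regions[chrom]
        i = bisect.bisect_left(starts, end)
        return i > 0 and ends[i - 1] > start

    def insert(self, chrom: str, start: int, end: int) -> None:
        import bisect

        starts, ends = self._regions[chrom]
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def shuffle_intervals(
    peaks: IntervalSet,
    layout: GenomeLayout,
    cfg: ShuffleConfig,
    rng: np.random.Generator | None = None,
) -> IntervalSet:
    """Relocate every peak uniformly at random, preserving lengths.

    Placement law matches ``bedtools shuffle`` without ``-chrom``: the
    chromosome is drawn with probability proportional to its length, then a
    start uniform over positions where the interval fits inside the
    chromosome.  Draws hitting ``cfg.exclude`` (or, when ``cfg.no_overlap``,
    an already placed interval) are rejected and retried; after
    ``cfg.max_tries`` failures the interval is dropped with a warning.

    Identical (peaks, layout, cfg) — including ``cfg.seed`` — give
    bit-identical output.  Pass ``rng`` to draw from an external stream
    instead of ``cfg.seed``.
    """
    if cfg.exclude is not None and cfg.exclude.layout != layout:
        raise ValueError("exclude set is bound to a different layout")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chroms = list(layout.chrom_names)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=np.float64)
    probs = lengths / lengths.sum()
    occupied = _OcclusionIndex(layout, cfg.exclude)
    placed: list[GenomicInterval] = []
    dropped = 0
    for iv in peaks:
        L = len(iv)
        ok = False
        for _ in range(cfg.max_tries):
            ci = int(rng.choice(len(chroms), p=probs))
            max_start = layout.chrom_lengths[chroms[ci]] - L
            if max_start < 0:
                continue
            start = int(rng.integers(0, max_start + 1))
            if occupied.overlaps(chroms[ci], start, start + L):
                continue
            placed.append(
                GenomicInterval(chroms[ci], start, start + L, iv.strand, iv.name, iv.score)
            )
            if cfg.no_overlap:
                occupied.insert(chroms[ci], start, start + L)
            ok = True
            break
        if not ok:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} unplaceable interval(s) after max_tries", stacklevel=2)
    out = IntervalSet(placed, layout)
    out.dropped = dropped  # type: ignore[attr-defined]
    return out


def class_overlap_indexes(
    annotations: Iterable[TEAnnotation],
    classes: Sequence[str],
    layout: GenomeLayout,
) -> dict[str, OverlapIndex | None]:
    """Pre-built per-class overlap indexes (None for classes without annotations)."""
    by_class: dict[str, list[TEAnnotation]] = {}
    for ann in annotations:
        by_class.setdefault(ann.repeat_class, []).append(ann)
    return {
        cls: OverlapIndex(annotation_intervals(by_class[cls], layout))
        if by_class.get(cls)
        else None
        for cls in classes
    }


def class_intersection_counts(
    peaks: IntervalSet,
    annotations: Iterable[TEAnnotation] | dict[str, OverlapIndex | None],
    classes: Sequence[str] = DEFAULT_CLASSES,
) -> dict[str, int]:
    """Per-class count of peaks overlapping >=1 annotation of that class.

    ``-u`` semantics within each class: a peak counts once per class but may
    count toward several classes.  ``annotations`` may be a prebuilt index
    dict from :func:`class_overlap_indexes` to amortise repeated screens.
    """
    if isinstance(annotations, dict):
        indexes = annotations
    else:
        indexes = class_overlap_indexes(annotations, classes, peaks.layout)
    counts: dict[str, int] = {}
    for cls in classes:
        index = indexes.get(cls)
        if index is None:
            warnings.warn(f"no annotations for requested class {cls!r}", stacklevel=2)
            counts[cls] = 0
            continue
        counts[cls] = count_overlapping(peaks, index)
    return counts


def enrichment_matrix(
    experiments: Mapping[str, IntervalSet],
    annotations: Iterable[TEAnnotation],
    layout: GenomeLayout,
    cfg: ShuffleConfig,
    classes: Sequence[str] = DEFAULT_CLASSES,
) -> EnrichmentMatrix:
    """Observed-vs-shuffled TE-class enrichment for a cohort of peak sets.

    Expected counts are the mean over ``cfg.n_shuffles`` independent
    shuffles, each count rescaled by n_peaks/n_placed when intervals were
    dropped.  Per-shuffle RNG streams are spawned as
    ``default_rng([seed, experiment_index, shuffle_index])`` so results with
    ``n_shuffles=10`` are a prefix of results with ``n_shuffles=100``.
    """
    classes = list(classes)
    indexes = class_overlap_indexes(list(annotations), classes, layout)
    exp_names = list(experiments)
    observed = pd.DataFrame(0, index=exp_names, columns=classes, dtype=np.int64)
    expected = pd.DataFrame(0.0, index=exp_names, columns=classes)
    shuffle_counts: dict[str, pd.DataFrame] = {}
    n_peaks = pd.Series(0, index=exp_names, dtype=np.int64)
    dropped = pd.Series(0.0, index=exp_names)
    for ei, name in enumerate(exp_names):
        peaks = experiments[name]
        if len(peaks) == 0:
            raise ValueError(f"experiment {name!r} has no peaks")
        n_peaks[name] = len(peaks)
        obs = class_intersection_counts(peaks, indexes, classes)
        for cls in classes:
            observed.at[name, cls] = obs[cls]
        per_shuffle = pd.DataFrame(
            np.nan, index=range(cfg.n_shuffles), columns=classes
        )
        drop_total = 0
        for si in range(cfg.n_shuffles):
            rng = np.random.default_rng([cfg.seed, ei, si])
            shuffled = shuffle_intervals(peaks, layout, cfg, rng=rng)
            n_dropped = getattr(shuffled, "dropped", 0)
            drop_total += n_dropped
            cnt = class_intersection_counts(shuffled, indexes, classes)
            scale = len(peaks) / max(len(shuffled), 1) if len(shuffled) else np.nan
            for cls in classes:
                per_shuffle.at[si, cls] = cnt[cls] * scale
        shuffle_counts[name] = per_shuffle
        expected.loc[name] = per_shuffle.mean(axis=0)
        dropped[name] = drop_total / cfg.n_shuffles
    eps = cfg.pseudocount
    log2_ratio = np.log2((observed + eps) / (expected + eps))
    return EnrichmentMatrix(
        observed=observed,
        expected=expected,
        log2_ratio=log2_ratio,
        shuffle_counts=shuffle_counts,
        n_peaks=n_peaks,
        dropped=dropped,
        pseudocount=eps,
    )


@dataclass
class EnrichmentCalls:
    """Per-experiment enrichment labels at a fold threshold.

    ``enriched_classes`` maps experiment -> classes whose pseudocount-
    adjusted obs/exp ratio exceeds the fold threshold.  ``single_class``
    lists experiments enriched for exactly one class; ``class_tally`` counts
    enriched experiments per class (an experiment enriched for k classes
    contributes to k tallies).
    """

    fold: float
    enriched_classes: dict[str, list[str]]

    @property
    def enriched(self) -> list[str]:
        return [e for e, cs in self.enriched_classes.items() if cs]

    @property
    def single_class(self) -> dict[str, str]:
        return {e: cs[0] for e, cs in self.enriched_classes.items() if len(cs) == 1}

    @property
    def class_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for cs in self.enriched_classes.values():
            for c in cs:
                tally[c] = tally.get(c, 0) + 1
        return tally

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "experiment": e,
                "n_enriched_classes": len(cs),
                "enriched_classes": ",".join(cs) if cs else ".",
                "single_class": cs[0] if len(cs) == 1 else ".",
            }
            for e, cs in self.enriched_classes.items()
        ]
        return pd.DataFrame(rows)


def classify_enriched(matrix: EnrichmentMatrix, fold: float = 2.0) -> EnrichmentCalls:
    """Label experiments whose obs/exp ratio exceeds *fold* for some class."""
    ratio = matrix.ratio()
    enriched: dict[str, list[str]] = {}
    for exp in matrix.experiments:
        enriched[exp] = [c for c in matrix.classes if ratio.at[exp, c] > fold]
    return EnrichmentCalls(fold=fold, enriched_classes=enriched)
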