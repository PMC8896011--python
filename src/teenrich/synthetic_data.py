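"""Synthetic genomes with an age-graded LINE-1 subfamily ladder.

Everything the pipeline consumes can be generated here from a seed and a
declarative spec: a background genome with planted L1 copies whose
divergence from a shared consensus increases with subfamily "age", a
binding motif kept intact in young subfamilies and ablated (two fixed
substitutions in the 13-mer core) in old ones, ChIP peak sets and coverage
tracks concentrated at intact motif sites, and paired-end RNA-seq-like
alignment records with indels planted at sgRNA target sites.

All outputs are deterministic functions of (spec, seed): identical inputs
give byte-identical genomes, annotations, peaks, tracks and records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    TEAnnotation,
)
from .l1_expression import AlignmentRecord
from .meta_profile import CoverageTrack
from .seqio import ALPHABET, revcomp

__all__ = [
    "SubfamilySpec",
    "SyntheticGenomeSpec",
    "PlantedSite",
    "PlantedElement",
    "TruthTable",
    "default_subfamily_ladder",
    "make_genome",
    "make_chip_experiment",
    "make_rnaseq_library",
]

#: default 13-mer motif cores planted in the consensus (near the 5' and 3'
#: ends of ORF2, mirroring where the two binding sites sit in full-length L1)
DEFAULT_MOTIFS: dict[str, str] = {
    "orf2_5p": "GATCGGAATGACT",
    "orf2_3p": "TCAGTCCATAGGC",
}

#: fixed 2-bp substitution used to ablate a motif core (positions 5 and 8)
ABLATION_POSITIONS = (5, 8)
_ABLATE = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass(frozen=True)
class SubfamilySpec:
    """One rung of the L1 age ladder.

    ``divergence_pct`` is the per-site substitution rate from the ancestral
    consensus (transitions:transversions 2:1); it increases with subfamily
    age.  Truncated copies keep the 3' end (L1 truncation is 5'-biased).
    ``motif_intact`` says, per motif id, whether planted copies carry the
    intact core or the 2-bp-ablated one.
    """

    name: str
    n_full_length: int
    n_truncated: int
    divergence_pct: float
    motif_intact: Mapping[str, bool] = field(default_factory=dict)
    intact_orfs: bool = True

    def __post_init__(self):
        if not (0 <= self.divergence_pct <= 30):
            raise ValueError("divergence_pct must be in [0, 30]")


def default_subfamily_ladder() -> list[SubfamilySpec]:
    """Young-to-old ladder: motif intact in young rungs, ablated in old."""
    intact = {m: True for m in DEFAULT_MOTIFS}
    ablated = {m: False for m in DEFAULT_MOTIFS}
    return [
        SubfamilySpec("L1PA1", 2, 4, 1.0, intact, intact_orfs=True),
        SubfamilySpec("L1PA4", 2, 6, 5.0, intact, intact_orfs=False),
        SubfamilySpec("L1PA7", 2, 6, 10.0, intact, intact_orfs=False),
        SubfamilySpec("L1PA13", 2, 6, 17.0, ablated, intact_orfs=False),
        SubfamilySpec("L1PA17", 2, 5, 24.0, ablated, intact_orfs=False),
    ]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Declarative description of the toy genome.

    The consensus is ~6 kb with ORF1 at [900, 1900) and ORF2 at
    [1990, 5810); two 13-mer motif cores sit inside ORF2 near its 5' and 3'
    ends.  ``other_classes`` maps decoy TE class name to the approximate
    fraction of the genome its (annotation-only) copies should cover, so
    enrichment screens see several abundant classes.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 400_000}
    )
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    subfamilies: Sequence[SubfamilySpec] = field(default_factory=default_subfamily_ladder)
    consensus_length: int = 6000
    orf1: tuple[int, int] = (900, 1900)
    orf2: tuple[int, int] = (1990, 5810)
    motif_offsets: Mapping[str, int] = field(
        default_factory=lambda: {"orf2_5p": 2100, "orf2_3p": 5600}
    )
    motif_sequences: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    other_classes: Mapping[str, float] = field(
        default_factory=lambda: {"SINE": 0.08, "LTR": 0.06, "DNA": 0.06}
    )
    other_element_length: int = 300
    min_truncated_length: int = 800
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.background_composition) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")
        for mid, off in self.motif_offsets.items():
            w = len(self.motif_sequences[mid])
            if not (self.orf2[0] <= off and off + w <= self.orf2[1]):
                raise ValueError(f"motif {mid!r} not inside ORF2")


@dataclass(frozen=True)
class PlantedSite:
    """Genomic location and status of one planted motif core."""

    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str
    intact: bool
    element_index: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PlantedElement:
    """One planted L1 copy; ``consensus_offset`` is where its 5' end sits
    on the consensus (0 for full-length, >0 for 5'-truncated copies)."""

    index: int
    subfamily: str
    chrom: str
    start: int
    end: int
    strand: str
    full_length: bool
    consensus_offset: int
    divergence_pct: float
    intact_orfs: bool
    motif_sites: tuple[PlantedSite, ...]


@dataclass
class TruthTable:
    """Complete ground truth for a synthetic genome and its experiments."""

    consensus: str
    motif_sequences: dict[str, str]
    motif_offsets: dict[str, int]
    orf1: tuple[int, int]
    orf2: tuple[int, int]
    elements: list[PlantedElement]
    peak_sources: dict[str, PlantedSite | None] = field(default_factory=dict)
    read_sources: dict[str, str] = field(default_factory=dict)

    def sites(self, motif_id: str | None = None, intact: bool | None = None) -> list[PlantedSite]:
        out = []
        for el in self.elements:
            for s in el.motif_sites:
                if motif_id is not None and s.motif_id != motif_id:
                    continue
                if intact is not None and s.intact != intact:
                    continue
                out.append(s)
        return out

    def elements_of(self, subfamily: str) -> list[PlantedElement]:
        return [el for el in self.elements if el.subfamily == subfamily]


def _random_seq(rng: np.random.Generator, length: int, composition) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(composition, dtype=float))


_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])  # two options per base


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Site-independent substitutions at the given rate, ti:tv = 2:1."""
    out = codes.copy()
    hit = np.flatnonzero(rng.random(len(codes)) < rate)
    if len(hit) == 0:
        return out
    is_transition = rng.random(len(hit)) < 2 / 3
    tv_choice = rng.integers(0, 2, size=len(hit))
    for idx, pos in enumerate(hit):
        base = out[pos]
        out[pos] = _TRANSITION[base] if is_transition[idx] else _TRANSVERSIONS[base][tv_choice[idx]]
    return out


def _ablated(core: str) -> str:
    chars = list(core)
    for p in ABLATION_POSITIONS:
        chars[p] = _ABLATE[chars[p]]
    return "".join(chars)


class _Occupancy:
    """Per-chromosome occupied spans with binary-search overlap checks."""

    def __init__(self, chroms: Iterable[str]):
        self._spans: dict[str, tuple[list[int], list[int]]] = {c: ([], []) for c in chroms}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        import bisect

        starts, ends = self._spans[chrom]
        i = bisect.bisect_left(starts, end)
        return i > 0 and ends[i - 1] > start

    def insert(self, chrom: str, start: int, end: int) -> None:
        import bisect

        starts, ends = self._spans[chrom]
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def _place(rng, layout: GenomeLayout, length: int, occupancy: _Occupancy,
           max_tries: int = 1000) -> tuple[str, int]:
    chroms = list(layout.chrom_names)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(max_tries):
        ci = int(rng.choice(len(chroms), p=probs))
        max_start = layout.chrom_lengths[chroms[ci]] - length
        if max_start < 0:
            continue
        start = int(rng.integers(0, max_start + 1))
        if not occupancy.overlaps(chroms[ci], start, start + length):
            return chroms[ci], start
    raise RuntimeError(f"could not place an element of length {length} after {max_tries} tries")


def make_genome(
    spec: SyntheticGenomeSpec = SyntheticGenomeSpec(),
) -> tuple[dict[str, str], list[TEAnnotation], TruthTable]:
    """Build the genome, its repeat annotation, and the ground truth.

    The consensus is drawn from the background composition with the motif
    cores written in at their offsets.  Each planted copy is the consensus
    mutated at the subfamily's divergence (ti:tv 2:1), 5'-truncated for
    fragment copies, reverse-complemented on the minus strand; motif cores
    are then forced exactly intact or exactly 2-bp-ablated per the spec, so
    site-level truth stays exact.  Decoy TE classes contribute
    annotation-only intervals over the background.
    """
    rng = np.random.default_rng(spec.seed)
    layout = GenomeLayout.from_dict(dict(spec.chrom_lengths))
    comp = np.asarray(spec.background_composition, dtype=float)

    consensus_codes = _random_seq(rng, spec.consensus_length, comp)
    consensus = "".join(ALPHABET[c] for c in consensus_codes)
    for mid, off in spec.motif_offsets.items():
        core = spec.motif_sequences[mid]
        consensus = consensus[:off] + core + consensus[off + len(core) :]

    total_planted = sum(
        sf.n_full_length * spec.consensus_length
        + sf.n_truncated * (spec.min_truncated_length + spec.consensus_length) // 2
        for sf in spec.subfamilies
    )
    if total_planted >= 0.8 * layout.total_length:
        raise ValueError("planted elements exceed 80% of the genome")

    chrom_codes = {
        c: _random_seq(rng, layout.chrom_lengths[c], comp) for c in layout.chrom_names
    }
    chrom_seqs = {c: list("".join(ALPHABET[x] for x in codes)) for c, codes in chrom_codes.items()}

    occupancy = _Occupancy(layout.chrom_names)
    elements: list[PlantedElement] = []
    annotations: list[TEAnnotation] = []
    el_index = 0
    for sf in spec.subfamilies:
        copies = [spec.consensus_length] * sf.n_full_length
        for _ in range(sf.n_truncated):
            copies.append(int(rng.integers(spec.min_truncated_length, spec.consensus_length)))
        for length in copies:
            offset = spec.consensus_length - length  # 5'-truncation keeps the 3' end
            piece = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in consensus[offset:]],
                             dtype=np.int64)
            mutated = _mutate(rng, piece, sf.divergence_pct / 100)
            seq = "".join(ALPHABET[c] for c in mutated)
            # force motif cores to their exact intact/ablated form
            site_specs = []
            for mid, moff in spec.motif_offsets.items():
                core = spec.motif_sequences[mid]
                local = moff - offset
                if local < 0 or local + len(core) > length:
                    continue
                intact = bool(sf.motif_intact.get(mid, True))
                written = core if intact else _ablated(core)
                seq = seq[:local] + written + seq[local + len(core) :]
                site_specs.append((mid, local, len(core), intact))

            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = _place(rng, layout, length, occupancy)
            occupancy.insert(chrom, start, start + length)
            placed = seq if strand == "+" else revcomp(seq)
            chrom_seqs[chrom][start : start + length] = list(placed)

            sites = []
            for mid, local, w, intact in site_specs:
                if strand == "+":
                    gs = start + local
                else:
                    gs = start + length - local - w
                sites.append(
                    PlantedSite(mid, chrom, gs, gs + w, strand, intact, el_index)
                )
            element = PlantedElement(
                index=el_index,
                subfamily=sf.name,
                chrom=chrom,
                start=start,
                end=start + length,
                strand=strand,
                full_length=length == spec.consensus_length,
                consensus_offset=offset,
                divergence_pct=sf.divergence_pct,
                intact_orfs=sf.intact_orfs and length == spec.consensus_length,
                motif_sites=tuple(sites),
            )
            elements.append(element)
            annotations.append(
                TEAnnotation(
                    GenomicInterval(chrom, start, start + length, strand, sf.name),
                    sf.name,
                    "LINE",
                    "L1",
                    sf.divergence_pct,
                )
            )
            el_index += 1

    # decoy classes: annotation-only intervals over background sequence
    for cls in sorted(spec.other_classes):
        fraction = spec.other_classes[cls]
        L = spec.other_element_length
        n = int(round(fraction * layout.total_length / L))
        for i in range(n):
            chrom, start = _place(rng, layout, L, occupancy)
            occupancy.insert(chrom, start, start + L)
            name = f"{cls}_rep"
            annotations.append(
                TEAnnotation(
                    GenomicInterval(chrom, start, start + L, "+", name), name, cls, cls, None
                )
            )

    genome = {c: "".join(chrom_seqs[c]) for c in layout.chrom_names}
    truth = TruthTable(
        consensus=consensus,
        motif_sequences=dict(spec.motif_sequences),
        motif_offsets=dict(spec.motif_offsets),
        orf1=spec.orf1,
        orf2=spec.orf2,
        elements=elements,
    )
    return genome, annotations, truth


def make_chip_experiment(
    genome: Mapping[str, str],
    truth: TruthTable,
    factor: str,
    signal_fraction: float = 0.9,
    n_peaks: int = 200,
    peak_width: int = 200,
    seed: int = 0,
    name: str | None = None,
) -> tuple[IntervalSet, CoverageTrack, CoverageTrack]:
    """Simulate one ChIP experiment against a planted motif.

    ``signal_fraction`` of the peaks are centred (with small jitter) on
    distinct intact planted sites of ``factor``; the rest fall uniformly.
    The ChIP track is a smoothed peak pileup over a unit baseline; the
    input track is flat.  Peak provenance is recorded in
    ``truth.peak_sources`` keyed by peak name.
    """
    if not (0 <= signal_fraction <= 1):
        raise ValueError("signal_fraction must be in [0, 1]")
    from .seqio import layout_from_genome

    import zlib

    layout = layout_from_genome(dict(genome))
    rng = np.random.default_rng([seed, zlib.crc32(factor.encode()) % (2**31)])
    sites = truth.sites(motif_id=factor, intact=True)
    n_signal = int(round(signal_fraction * n_peaks))
    if n_signal > len(sites):
        raise ValueError(
            f"{n_signal} signal peaks requested but only {len(sites)} intact sites of "
            f"{factor!r} exist"
        )
    prefix = name or f"{factor}_s{seed}"
    chosen = [sites[i] for i in rng.choice(len(sites), size=n_signal, replace=False)]

    chroms = list(layout.chrom_names)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    peaks: list[GenomicInterval] = []
    centers: list[tuple[str, int]] = []
    for i in range(n_peaks):
        pk_name = f"{prefix}_pk{i}"
        if i < n_signal:
            site = chosen[i]
            jitter = int(rng.integers(-(peak_width // 4), peak_width // 4 + 1))
            mid = site.midpoint + jitter
            chrom = site.chrom
            truth.peak_sources[pk_name] = site
        else:
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            mid = int(rng.integers(peak_width // 2, layout.chrom_lengths[chrom] - peak_width // 2))
            truth.peak_sources[pk_name] = None
        lo = max(0, mid - peak_width // 2)
        hi = min(layout.chrom_lengths[chrom], mid + peak_width // 2)
        peaks.append(GenomicInterval(chrom, lo, hi, ".", pk_name))
        centers.append((chrom, mid))

    chip = CoverageTrack.constant(layout, 1.0)
    sigma = peak_width / 4
    half = int(3 * sigma)
    kernel = 9.0 * np.exp(-0.5 * ((np.arange(-half, half + 1)) / sigma) ** 2)
    for chrom, mid in centers:
        arr = chip.data[chrom]
        lo, hi = max(0, mid - half), min(len(arr), mid + half + 1)
        arr[lo:hi] += kernel[lo - (mid - half) : hi - (mid - half)]
    input_track = CoverageTrack.constant(layout, 1.0)
    return IntervalSet(peaks, layout), chip, input_track


def make_rnaseq_library(
    genome: Mapping[str, str],
    truth: TruthTable,
    gene_models: IntervalSet,
    guide_sites: Sequence[tuple[str, int]] = (),
    indel_fraction: float = 0.0,
    n_fragments: int = 10_000,
    seed: int = 0,
    read_len: int = 100,
    fragment_len_range: tuple[int, int] = (200, 400),
    readthrough_weight: float = 0.0,
) -> list[AlignmentRecord]:
    """Simulate a paired-end RNA-seq library as alignment records.

    Fragments are sampled from ``gene_models`` with expression weights (the
    interval ``score``; default 1).  Records whose span covers a guide site
    carry a 1–5 bp insertion or deletion in their CIGAR with probability
    ``indel_fraction``.  Planted L1 elements are transcriptionally silent;
    ``readthrough_weight > 0`` adds the 1 kb windows downstream of
    full-length planted elements as weak transcription sources, emulating
    read-through.  Mates share a ``fragment_id``.
    """
    if not (0 <= indel_fraction <= 1):
        raise ValueError("indel_fraction must be in [0, 1]")
    from .seqio import layout_from_genome

    layout = layout_from_genome(dict(genome))
    rng = np.random.default_rng([seed, 7_919])

    fmin = max(fragment_len_range[0], read_len)
    sources = [iv for iv in gene_models if len(iv) >= fmin]
    if not sources:
        raise ValueError(f"no gene model is at least {fmin} bp long")
    weights = [iv.score if iv.score is not None else 1.0 for iv in sources]
    if readthrough_weight > 0:
        for el in truth.elements:
            if not el.full_length:
                continue
            if el.strand == "+":
                lo, hi = el.end, min(el.end + 1000, layout.chrom_lengths[el.chrom])
            else:
                lo, hi = max(0, el.start - 1000), el.start
            if hi - lo >= fmin:
                sources.append(GenomicInterval(el.chrom, lo, hi, el.strand, f"rt_{el.index}"))
                weights.append(readthrough_weight)
    w = np.asarray(weights, dtype=float)
    w /= w.sum()

    fmax = fragment_len_range[1]
    guides_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in guide_sites:
        guides_by_chrom.setdefault(chrom, []).append(int(pos))

    records: list[AlignmentRecord] = []
    for i in range(n_fragments):
        gi = int(rng.choice(len(sources), p=w))
        gene = sources[gi]
        glen = len(gene)
        flen = int(rng.integers(fmin, min(fmax, glen) + 1)) if glen > fmin else glen
        fs = int(rng.integers(gene.start, gene.end - flen + 1))
        fid = f"frag{i}"
        truth.read_sources[fid] = gene.name
        mates = [
            (fs, "+"),
            (fs + flen - read_len, "-"),
        ]
        for start, strand in mates:
            cigar = f"{read_len}M"
            for gpos in guides_by_chrom.get(gene.chrom, ()):
                off = gpos - start
                if 1 <= off <= read_len - 2 and rng.random() < indel_fraction:
                    ilen = int(rng.integers(1, 6))
                    if rng.random() < 0.5 and off <= read_len - ilen - 1:
                        cigar = f"{off}M{ilen}I{read_len - off - ilen}M"
                    else:
                        cigar = f"{off}M{ilen}D{read_len - off}M"
                    break
            records.append(
                AlignmentRecord(
                    chrom=gene.chrom,
                    start=start,
                    cigar=cigar,
                    strand=strand,
                    is_primary=True,
                    is_unique=True,
                    fragment_id=fid,
                )
            )
    return records
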