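import numpy as np
import pytest

from teenrich import (
    GenomicInterval,
    IntervalSet,
    SubfamilySpec,
    SyntheticGenomeSpec,
    indel_coverage_ratio,
    count_fragments,
    downstream_windows,
    layout_from_genome,
    make_chip_experiment,
    make_genome,
    make_rnaseq_library,
    scan_genome,
)
from teenrich.seqio import revcomp
from teenrich.synthetic_data import DEFAULT_MOTIFS, _ablated


def _tiny_spec(**kwargs):
    defaults = dict(
        seed=0,
        chrom_lengths={"chr1": 120_000},
        subfamilies=[
            SubfamilySpec("L1PA1", 2, 2, 0.0, {m: True for m in DEFAULT_MOTIFS}, True),
        ],
        other_classes={},
    )
    defaults.update(kwargs)
    return SyntheticGenomeSpec(**defaults)


class TestMakeGenome:
    def test_zero_divergence_plants_exact_consensus(self):
        genome, anns, truth = make_genome(_tiny_spec())
        for el in truth.elements:
            if not el.full_length:
                continue
            planted = genome[el.chrom][el.start : el.end]
            expect = truth.consensus if el.strand == "+" else revcomp(truth.consensus)
            assert planted == expect

    def test_truncation_keeps_three_prime_end(self):
        genome, anns, truth = make_genome(_tiny_spec())
        for el in truth.elements:
            if el.full_length:
                continue
            planted = genome[el.chrom][el.start : el.end]
            if el.strand == "-":
                planted = revcomp(planted)
            assert planted == truth.consensus[el.consensus_offset :]

    def test_divergence_within_binomial_bounds(self):
        spec = _tiny_spec(
            subfamilies=[SubfamilySpec("L1PA7", 3, 0, 10.0, {}, False)],
            chrom_lengths={"chr1": 200_000},
        )
        genome, _, truth = make_genome(spec)
        n = len(truth.consensus)
        for el in truth.elements:
            planted = genome[el.chrom][el.start : el.end]
            if el.strand == "-":
                planted = revcomp(planted)
            protected = sum(len(m) for m in truth.motif_sequences.values())
            mismatches = sum(a != b for a, b in zip(planted, truth.consensus))
            # 10% of ~6 kb, minus up to 26 motif-protected bases; 3 binomial SDs
            sd = np.sqrt(n * 0.1 * 0.9)
            assert abs(mismatches - 0.1 * n) <= 3 * sd + protected

    def test_annotations_match_elements_one_to_one(self):
        genome, anns, truth = make_genome(_tiny_spec())
        line_anns = [a for a in anns if a.repeat_class == "LINE"]
        assert len(line_anns) == len(truth.elements)
        coords = {(a.interval.chrom, a.interval.start, a.interval.end) for a in line_anns}
        assert coords == {(e.chrom, e.start, e.end) for e in truth.elements}

    def test_byte_identical_under_same_seed(self):
        g1, a1, t1 = make_genome(_tiny_spec(seed=5))
        g2, a2, t2 = make_genome(_tiny_spec(seed=5))
        assert g1 == g2
        assert a1 == a2
        assert t1.elements == t2.elements

    def test_divergence_ladder_monotone_identity(self):
        spec = _tiny_spec(
            chrom_lengths={"chr1": 400_000},
            subfamilies=[
                SubfamilySpec("PA_young", 2, 0, 2.0, {}, True),
                SubfamilySpec("PA_mid", 2, 0, 10.0, {}, False),
                SubfamilySpec("PA_old", 2, 0, 22.0, {}, False),
            ],
        )
        genome, _, truth = make_genome(spec)
        identity = {}
        for name in ("PA_young", "PA_mid", "PA_old"):
            vals = []
            for el in truth.elements_of(name):
                planted = genome[el.chrom][el.start : el.end]
                if el.strand == "-":
                    planted = revcomp(planted)
                vals.append(np.mean([a == b for a, b in zip(planted, truth.consensus)]))
            identity[name] = np.mean(vals)
        assert identity["PA_young"] > identity["PA_mid"] > identity["PA_old"]

    def test_motif_scan_finds_only_intact_subfamily(self, small_genome):
        genome, anns, truth = small_genome
        core = truth.motif_sequences["orf2_3p"]
        from test_motif import sharp_motif

        occ = scan_genome(sharp_motif(core), genome, p_threshold=5e-6)
        found = {(o.interval.chrom, o.interval.start) for o in occ}
        for site in truth.sites("orf2_3p", intact=True):
            assert (site.chrom, site.start) in found
        for site in truth.sites("orf2_3p", intact=False):
            assert (site.chrom, site.start) not in found

    def test_overfull_spec_rejected(self):
        spec = _tiny_spec(
            chrom_lengths={"chr1": 20_000},
            subfamilies=[SubfamilySpec("L1PA1", 4, 0, 0.0, {}, True)],
        )
        with pytest.raises(ValueError):
            make_genome(spec)

    def test_ablation_is_two_substitutions(self):
        core = DEFAULT_MOTIFS["orf2_5p"]
        broken = _ablated(core)
        assert len(broken) == len(core)
        assert sum(a != b for a, b in zip(core, broken)) == 2


class TestMakeChipExperiment:
    def test_full_signal_peaks_center_on_intact_sites(self, small_genome):
        genome, _, truth = small_genome
        n_sites = len(truth.sites("orf2_5p", intact=True))
        peaks, chip, inp = make_chip_experiment(
            genome, truth, "orf2_5p", signal_fraction=1.0, n_peaks=n_sites,
            peak_width=200, seed=3,
        )
        site_mids = [s.midpoint for s in truth.sites("orf2_5p", intact=True)]
        for iv in peaks:
            assert any(
                abs(iv.midpoint - m) <= 100 for m in site_mids
            ), f"peak {iv} not near any intact site"

    def test_provenance_recorded(self, small_genome):
        genome, _, truth = small_genome
        peaks, *_ = make_chip_experiment(
            genome, truth, "orf2_5p", signal_fraction=0.5, n_peaks=8, seed=4, name="expP"
        )
        sources = [truth.peak_sources[iv.name] for iv in peaks]
        assert sum(s is not None for s in sources) == 4

    def test_oversubscribed_sites_rejected(self, small_genome):
        genome, _, truth = small_genome
        with pytest.raises(ValueError, match="intact sites"):
            make_chip_experiment(genome, truth, "orf2_5p", 1.0, 10_000, seed=0)

    def test_deterministic(self, small_genome):
        genome, _, truth = small_genome
        p1, c1, i1 = make_chip_experiment(genome, truth, "orf2_3p", 0.5, 20, seed=8)
        p2, c2, i2 = make_chip_experiment(genome, truth, "orf2_3p", 0.5, 20, seed=8)
        assert list(p1) == list(p2)
        assert all(np.array_equal(c1.data[c], c2.data[c]) for c in c1.data)


class TestMakeRnaseqLibrary:
    def _gene(self, layout, start=10_000, end=14_000, chrom="chr1"):
        return IntervalSet([GenomicInterval(chrom, start, end, "+", "geneA")], layout)

    def test_no_indels_without_planting(self, small_genome):
        genome, _, truth = small_genome
        layout = layout_from_genome(genome)
        recs = make_rnaseq_library(
            genome, truth, self._gene(layout), [("chr1", 12_000)],
            indel_fraction=0.0, n_fragments=300, seed=0,
        )
        ratio = indel_coverage_ratio([r for r in recs], layout.chrom_lengths["chr1"])
        defined = ratio[~np.isnan(ratio)]
        assert np.all(defined == 0)

    def test_indel_fraction_recovered_at_guide(self, small_genome):
        genome, _, truth = small_genome
        layout = layout_from_genome(genome)
        recs = make_rnaseq_library(
            genome, truth, self._gene(layout), [("chr1", 12_000)],
            indel_fraction=0.3, n_fragments=2_000, seed=1,
        )
        ratio = indel_coverage_ratio(recs, layout.chrom_lengths["chr1"])
        depth = sum(1 for r in recs if r.start <= 12_000 < r.end)
        sd = np.sqrt(0.3 * 0.7 / depth)
        assert abs(ratio[12_000] - 0.3) <= 3 * sd + 0.02

    def test_mates_share_fragment_id(self, small_genome):
        genome, _, truth = small_genome
        layout = layout_from_genome(genome)
        recs = make_rnaseq_library(genome, truth, self._gene(layout), n_fragments=50, seed=2)
        assert len(recs) == 100
        ids = {}
        for r in recs:
            ids.setdefault(r.fragment_id, []).append(r)
        assert all(len(v) == 2 for v in ids.values())

    def test_silent_l1_without_readthrough(self, small_genome):
        genome, _, truth = small_genome
        layout = layout_from_genome(genome)
        recs = make_rnaseq_library(genome, truth, self._gene(layout), n_fragments=400, seed=3)
        elements = IntervalSet(
            [
                GenomicInterval(e.chrom, e.start, e.end, e.strand, f"el{e.index}")
                for e in truth.elements
                if e.full_length
            ],
            layout,
        )
        windows = downstream_windows(elements)
        table = count_fragments(recs, windows)
        assert table.table["count"].sum() == 0

    def test_readthrough_populates_downstream_windows(self, small_genome):
        genome, _, truth = small_genome
        layout = layout_from_genome(genome)
        recs = make_rnaseq_library(
            genome, truth, self._gene(layout), n_fragments=600, seed=4,
            readthrough_weight=0.3,
        )
        rt = [r for r in recs if truth.read_sources[r.fragment_id].startswith("rt_")]
        assert len(rt) > 0
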