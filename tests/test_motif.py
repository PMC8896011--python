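import itertools

import numpy as np
import pytest

from teenrich import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    MotifModel,
    TEAnnotation,
    bin_occurrences_by_subfamily,
    discover_motif_zoops,
    read_meme,
    scan_genome,
    score_pvalue_table,
    write_meme,
)
from teenrich.seqio import revcomp


def sharp_motif(word, p=0.97, background=None):
    pfm = np.full((len(word), 4), (1 - p) / 3)
    for i, b in enumerate(word):
        pfm[i, "ACGT".index(b)] = p
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return MotifModel(pfm=pfm, background=bg, name="test")


def plant_sequences(rng, core, n=200, length=60):
    seqs, offsets = [], []
    for _ in range(n):
        s = "".join(rng.choice(list("ACGT"), length))
        off = int(rng.integers(0, length - len(core) + 1))
        seqs.append(s[:off] + core + s[off + len(core):])
        offsets.append(off)
    return seqs, offsets


class TestScorePValueTable:
    def enumerate_pvalues(self, table, motif):
        """Exhaustive oracle: exact p per word by enumerating all 4^W words."""
        width = motif.width
        bg = motif.background
        words = list(itertools.product(range(4), repeat=width))
        scores = np.array(
            [sum(int(table.int_matrix[k, a]) for k, a in enumerate(w)) for w in words]
        )
        probs = np.array([np.prod([bg[a] for a in w]) for w in words])
        pvals = {}
        for s in np.unique(scores):
            pvals[int(s)] = probs[scores >= s].sum()
        return scores, pvals, words

    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_matches_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        pfm = rng.dirichlet(np.ones(4) * 2, size=width)
        bg = rng.dirichlet(np.ones(4) * 10)
        motif = MotifModel(pfm=pfm, background=bg)
        table = score_pvalue_table(motif, granularity=1000)
        scores, oracle, words = self.enumerate_pvalues(table, motif)
        for s in oracle:
            assert abs(table.pvalue(s) - oracle[s]) <= 1e-12

    def test_uniform_motif_scores_zero_everywhere(self):
        motif = MotifModel(pfm=np.full((5, 4), 0.25), background=np.full(4, 0.25))
        table = score_pvalue_table(motif)
        assert table.min_score == table.max_score == 0
        assert table.pvalue(0) == 1.0

    def test_top_word_pvalue_is_product_of_background_probs(self):
        rng = np.random.default_rng(7)
        bg = rng.dirichlet(np.ones(4) * 5)
        motif = sharp_motif("ACGTG", background=bg)
        table = score_pvalue_table(motif, granularity=2000)
        top = table.score_word("ACGTG")
        expect = np.prod([bg["ACGT".index(b)] for b in "ACGTG"])
        assert np.isclose(table.pvalue(top), expect, rtol=0, atol=1e-12)

    def test_pvalues_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(8)
        motif = MotifModel(pfm=rng.dirichlet(np.ones(4), size=8), background=np.full(4, 0.25))
        table = score_pvalue_table(motif)
        assert np.all(np.diff(table.pvalues) <= 1e-15)

    def test_granularity_floor(self):
        with pytest.raises(ValueError):
            score_pvalue_table(sharp_motif("ACGT"), granularity=10)


class TestZoopsDiscovery:
    CORE = "TTAGGGTTAGGGT"

    def test_planted_motif_recovered(self):
        rng = np.random.default_rng(0)
        seqs, offsets = plant_sequences(rng, self.CORE)
        result = discover_motif_zoops(seqs, width=13, n_starts=5, seed=0)
        assert result.consensus == self.CORE
        recall = sum(
            1 for call, off in zip(result.site_calls, offsets)
            if call is not None and call[0] == off and call[1] == "+"
        ) / len(seqs)
        assert recall >= 0.9

    def test_homopolymer_degenerates_to_background(self):
        seqs = ["A" * 30] * 20
        result = discover_motif_zoops(seqs, width=4, n_starts=2, seed=1)
        assert np.allclose(result.motif.pfm[:, 0], 1.0, atol=0.02)
        # with motif == background the site model adds nothing
        assert np.allclose(result.motif.pfm, result.motif.background, atol=0.02)

    def test_bit_identical_under_same_seed(self):
        rng = np.random.default_rng(2)
        seqs, _ = plant_sequences(rng, self.CORE, n=50)
        r1 = discover_motif_zoops(seqs, width=13, n_starts=3, seed=9)
        r2 = discover_motif_zoops(seqs, width=13, n_starts=3, seed=9)
        assert np.array_equal(r1.motif.pfm, r2.motif.pfm)
        assert r1.site_calls == r2.site_calls

    def test_objective_non_decreasing(self):
        rng = np.random.default_rng(3)
        seqs, _ = plant_sequences(rng, self.CORE, n=80)
        result = discover_motif_zoops(seqs, width=13, n_starts=3, seed=3)
        assert np.all(np.diff(result.objective_trace) >= -1e-6)

    def test_too_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            discover_motif_zoops(["ACG", "TTT"], width=13)


class TestScanGenome:
    def _planted_genome(self, core, rng, length=4000):
        seq = "".join(rng.choice(list("ACGT"), length))
        pos = 1717
        return {"chrT": seq[:pos] + core + seq[pos + len(core):]}, pos

    def test_single_planted_occurrence(self):
        rng = np.random.default_rng(4)
        core = "GATCGGAATGACT"
        genome, pos = self._planted_genome(core, rng)
        occ = scan_genome(sharp_motif(core), genome, p_threshold=5e-6)
        assert len(occ) == 1
        assert (occ[0].interval.start, occ[0].interval.end, occ[0].strand) == (pos, pos + 13, "+")

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(5)
        core = "GATCGGAATGACT"
        genome, pos = self._planted_genome(core, rng)
        motif = sharp_motif(core)
        fwd = scan_genome(motif, genome, p_threshold=5e-6)
        rc_genome = {"chrT": revcomp(genome["chrT"])}
        rev = scan_genome(motif, rc_genome, p_threshold=5e-6)
        L = len(genome["chrT"])
        assert len(rev) == len(fwd) == 1
        assert rev[0].strand == "-"
        assert rev[0].interval.start == L - fwd[0].interval.end

    def test_threshold_one_reports_every_window_both_strands(self):
        rng = np.random.default_rng(6)
        genome = {"chrT": "".join(rng.choice(list("ACGT"), 200))}
        occ = scan_genome(sharp_motif("GATCG"), genome, p_threshold=1.0)
        assert len(occ) == (200 - 5 + 1) * 2

    def test_windows_with_n_are_skipped(self):
        genome = {"chrT": "GATCG" + "N" + "GATCG" + "ACGTACGTAC"}
        occ = scan_genome(sharp_motif("GATCG"), genome, p_threshold=1e-3, background="motif")
        starts = {o.interval.start for o in occ}
        assert 0 in starts and 6 in starts
        assert all(
            "N" not in genome["chrT"][o.interval.start : o.interval.end] for o in occ
        )


class TestBinOccurrences:
    def _occurrence(self, chrom, start, width=13):
        from teenrich.motif import MotifOccurrence

        return MotifOccurrence(
            GenomicInterval(chrom, start, start + width), "+", 10.0, 1e-8
        )

    def test_assignment_and_unassigned(self, toy_layout):
        anns = [
            TEAnnotation(GenomicInterval("chr1", 100, 500), "L1PA7", "LINE", "L1"),
        ]
        occs = [self._occurrence("chr1", 200), self._occurrence("chr1", 2_000)]
        bins = bin_occurrences_by_subfamily(occs, anns, toy_layout)
        assert len(bins["L1PA7"]) == 1
        assert len(bins["unassigned"]) == 1

    def test_larger_overlap_wins(self, toy_layout):
        # occurrence [495,508) straddles L1PA7 (8 bp in [100,503)) and L1PA4 (5 bp)
        anns = [
            TEAnnotation(GenomicInterval("chr1", 100, 503), "L1PA7", "LINE", "L1"),
            TEAnnotation(GenomicInterval("chr1", 503, 900), "L1PA4", "LINE", "L1"),
        ]
        bins = bin_occurrences_by_subfamily([self._occurrence("chr1", 495)], anns, toy_layout)
        assert list(bins) == ["L1PA7"]


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        motif = MotifModel(
            pfm=rng.dirichlet(np.ones(4), size=13),
            background=np.array([0.3, 0.2, 0.2, 0.3]),
            site_count=42,
            name="znf_like",
        )
        path = tmp_path / "motif.meme"
        write_meme([motif], path)
        (loaded,) = read_meme(path)
        assert loaded.name == "znf_like"
        assert loaded.site_count == 42
        assert np.allclose(loaded.pfm, motif.pfm, atol=1e-6)
        assert np.allclose(loaded.background, motif.background, atol=1e-6)
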