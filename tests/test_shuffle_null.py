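import numpy as np
import pytest
from scipy.stats import chisquare

from teenrich import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    ShuffleConfig,
    TEAnnotation,
    class_intersection_counts,
    classify_enriched,
    enrichment_matrix,
    shuffle_intervals,
)

from conftest import brute_force_overlap, random_interval_set


def _set(layout, tuples):
    return IntervalSet([GenomicInterval(*t) for t in tuples], layout)


class TestShuffleIntervals:
    def test_single_legal_placement(self):
        layout = GenomeLayout.from_dict({"chr1": 1_000})
        peaks = _set(layout, [("chr1", 0, 10)])
        exclude = _set(layout, [("chr1", 0, 990)])
        cfg = ShuffleConfig(exclude=exclude, max_tries=50_000, seed=5)
        (iv,) = shuffle_intervals(peaks, layout, cfg)
        assert (iv.start, iv.end) == (990, 1000)

    def test_lengths_preserved_and_exclude_avoided(self, mb_layout):
        rng = np.random.default_rng(7)
        peaks = random_interval_set(rng, mb_layout, 100, max_len=300)
        exclude = _set(mb_layout, [("chr1", 400_000, 600_000)])
        cfg = ShuffleConfig(exclude=exclude, seed=7)
        shuffled = shuffle_intervals(peaks, mb_layout, cfg)
        assert sorted(len(iv) for iv in shuffled) == sorted(len(iv) for iv in peaks)
        for iv in shuffled:
            assert not (iv.start < 600_000 and 400_000 < iv.end)

    def test_no_overlap_placement(self, mb_layout):
        rng = np.random.default_rng(8)
        peaks = random_interval_set(rng, mb_layout, 200, max_len=2_000)
        shuffled = sorted(
            shuffle_intervals(peaks, mb_layout, ShuffleConfig(seed=8)),
            key=lambda iv: iv.start,
        )
        for prev, cur in zip(shuffled, shuffled[1:]):
            assert prev.end <= cur.start

    def test_unplaceable_interval_dropped_with_warning(self):
        layout = GenomeLayout.from_dict({"chr1": 1_000})
        peaks = _set(layout, [("chr1", 0, 600), ("chr1", 0, 600)])
        with pytest.warns(UserWarning, match="dropped 1"):
            shuffled = shuffle_intervals(peaks, layout, ShuffleConfig(seed=1, max_tries=200))
        assert len(shuffled) == 1  # pigeonhole: two 600-mers cannot both fit

    def test_deterministic_under_seed(self, mb_layout):
        rng = np.random.default_rng(9)
        peaks = random_interval_set(rng, mb_layout, 50)
        cfg = ShuffleConfig(seed=123)
        a = shuffle_intervals(peaks, mb_layout, cfg)
        b = shuffle_intervals(peaks, mb_layout, cfg)
        assert list(a) == list(b)

    def test_midpoints_uniform_by_chi_square(self, mb_layout):
        """Placement law: uniform over legal starts (chi-square, 20 bins)."""
        peaks = _set(mb_layout, [("chr1", i * 60, i * 60 + 50) for i in range(100)])
        mids = []
        for seed in range(40):
            cfg = ShuffleConfig(seed=seed, no_overlap=False)
            mids.extend(iv.midpoint for iv in shuffle_intervals(peaks, mb_layout, cfg))
        counts, _ = np.histogram(mids, bins=20, range=(0, 1_000_000))
        assert chisquare(counts).pvalue > 0.001


def _class_annotations(layout):
    return [
        TEAnnotation(GenomicInterval("chr1", 100, 300), "L1X", "LINE", "L1"),
        TEAnnotation(GenomicInterval("chr1", 250, 500), "ERVK1", "LTR", "ERVK"),
        TEAnnotation(GenomicInterval("chr2", 0, 200), "AluY", "SINE", "Alu"),
    ]


class TestClassCounts:
    def test_per_class_membership(self, toy_layout):
        peaks = _set(toy_layout, [("chr1", 150, 160), ("chr1", 120, 130), ("chr1", 190, 210)])
        counts = class_intersection_counts(
            peaks, _class_annotations(toy_layout), ("LINE", "SINE")
        )
        assert counts == {"LINE": 3, "SINE": 0}

    def test_peak_spanning_two_classes_counts_in_each(self, toy_layout):
        peaks = _set(toy_layout, [("chr1", 280, 320)])
        counts = class_intersection_counts(
            peaks, _class_annotations(toy_layout), ("LINE", "LTR")
        )
        assert counts == {"LINE": 1, "LTR": 1}

    def test_missing_class_warns_and_counts_zero(self, toy_layout):
        peaks = _set(toy_layout, [("chr1", 0, 10)])
        with pytest.warns(UserWarning, match="DNA"):
            counts = class_intersection_counts(peaks, _class_annotations(toy_layout), ("DNA",))
        assert counts == {"DNA": 0}

    def test_counts_match_brute_force_tally(self, toy_layout):
        rng = np.random.default_rng(11)
        classes = ("LINE", "SINE")
        anns = []
        for i in range(50):
            cls = classes[int(rng.integers(2))]
            s = int(rng.integers(0, 9_000))
            anns.append(
                TEAnnotation(GenomicInterval("chr1", s, s + 100), f"r{i}", cls, cls)
            )
        peaks = random_interval_set(rng, toy_layout, 200, max_len=150)
        counts = class_intersection_counts(peaks, anns, classes)
        for cls in classes:
            subjects = [a.interval for a in anns if a.repeat_class == cls]
            expect = len(brute_force_overlap(peaks, subjects))
            assert counts[cls] == expect


class TestEnrichmentMatrix:
    def _screen(self, layout, peaks, anns, seed=0, n_shuffles=10, classes=("LINE", "SINE")):
        cfg = ShuffleConfig(n_shuffles=n_shuffles, seed=seed)
        return enrichment_matrix({"exp": peaks}, anns, layout, cfg, classes)

    def test_planted_class_enriched(self, mb_layout):
        # all 50 peaks inside a class covering 1% of the genome
        anns = [
            TEAnnotation(GenomicInterval("chr1", i * 10_000, i * 10_000 + 200), f"L{i}", "LINE", "L1")
            for i in range(50)
        ]
        peaks = _set(mb_layout, [(a.interval.chrom, a.interval.start, a.interval.end) for a in anns])
        with pytest.warns(UserWarning):
            matrix = self._screen(mb_layout, peaks, anns, classes=("LINE", "SINE"))
        assert matrix.observed.at["exp", "LINE"] == 50
        assert matrix.log2_ratio.at["exp", "LINE"] >= np.log2(10)

    def test_zero_observed_zero_expected_gives_zero_log_ratio(self, toy_layout):
        anns = _class_annotations(toy_layout)
        peaks = _set(toy_layout, [("chr2", 4_000, 4_010)])
        cfg = ShuffleConfig(n_shuffles=3, seed=2, exclude=_set(toy_layout, [("chr1", 0, 600), ("chr2", 0, 300)]))
        matrix = enrichment_matrix({"exp": peaks}, anns, toy_layout, cfg, ("LINE", "SINE"))
        assert matrix.observed.at["exp", "LINE"] == 0
        assert matrix.expected.at["exp", "LINE"] == 0
        assert matrix.log2_ratio.at["exp", "LINE"] == 0.0

    def test_matrix_deterministic(self, toy_layout):
        rng = np.random.default_rng(13)
        peaks = random_interval_set(rng, toy_layout, 30, max_len=100)
        anns = _class_annotations(toy_layout)
        m1 = self._screen(toy_layout, peaks, anns, seed=3)
        m2 = self._screen(toy_layout, peaks, anns, seed=3)
        assert m1.log2_ratio.equals(m2.log2_ratio)
        assert m1.expected.equals(m2.expected)

    def test_prefix_stability_of_shuffle_streams(self, toy_layout):
        """The first 10 shuffles of an n_shuffles=20 run equal the n_shuffles=10 run."""
        rng = np.random.default_rng(14)
        peaks = random_interval_set(rng, toy_layout, 20, max_len=100)
        anns = _class_annotations(toy_layout)
        m10 = self._screen(toy_layout, peaks, anns, seed=4, n_shuffles=10)
        m20 = self._screen(toy_layout, peaks, anns, seed=4, n_shuffles=20)
        assert m20.shuffle_counts["exp"].iloc[:10].equals(m10.shuffle_counts["exp"])


class TestClassifyEnriched:
    def _matrix_from_ratios(self, ratios):
        import pandas as pd

        from teenrich.shuffle_null import EnrichmentMatrix

        obs = pd.DataFrame({c: [int(100 * r)] for c, r in ratios.items()}, index=["exp"])
        exp = pd.DataFrame({c: [100.0] for c in ratios}, index=["exp"])
        eps = 1e-9  # negligible pseudocount so ratios are exact
        return EnrichmentMatrix(
            observed=obs,
            expected=exp,
            log2_ratio=np.log2((obs + eps) / (exp + eps)),
            shuffle_counts={},
            n_peaks=pd.Series([1000], index=["exp"]),
            dropped=pd.Series([0.0], index=["exp"]),
            pseudocount=eps,
        )

    def test_single_class_label(self):
        calls = classify_enriched(self._matrix_from_ratios({"LINE": 4.0, "SINE": 1.1}))
        assert calls.single_class == {"exp": "LINE"}

    def test_multi_class_label(self):
        calls = classify_enriched(self._matrix_from_ratios({"LINE": 2.5, "ERVK": 3.0}))
        assert calls.enriched == ["exp"]
        assert calls.single_class == {}
        assert calls.class_tally == {"LINE": 1, "ERVK": 1}

    def test_monotone_in_fold_threshold(self):
        matrix = self._matrix_from_ratios({"LINE": 4.0, "SINE": 2.6, "DNA": 1.2})
        labels = [
            set(classify_enriched(matrix, fold=f).enriched_classes["exp"])
            for f in (1.5, 2.0, 2.5, 3.0, 5.0)
        ]
        for wider, narrower in zip(labels, labels[1:]):
            assert narrower <= wider
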