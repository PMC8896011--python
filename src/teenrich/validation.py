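"""Planted-truth validation scenarios for the whole pipeline.

Each function builds its inputs from a seed (synthetic genomes, peak sets,
libraries, or random fixtures), runs the relevant pipeline stage, and
returns plain summary numbers.  The scenarios double as calibration
evidence: a null screen that should show no enrichment, planted binders
that must be recovered, exact-oracle comparisons for the interval,
alignment and p-value engines, and planted-indel libraries whose indel
fraction must be re-estimated.  The test-suite asserts on these numbers and
``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import itertools

import numpy as np

from .consensus_profile import AlignmentScoring, local_align
from .intervals import GenomicInterval, IntervalSet, intersect_any
from .l1_expression import disruption_call, indel_coverage_ratio
from .meta_profile import anchor_matrix, mappability_track
from .motif import MotifModel, discover_motif_zoops, scan_genome, score_pvalue_table
from .seqio import layout_from_genome, revcomp
from .shuffle_null import ShuffleConfig, classify_enriched, enrichment_matrix
from .synthetic_data import (
    DEFAULT_MOTIFS,
    SubfamilySpec,
    SyntheticGenomeSpec,
    TruthTable,
    make_chip_experiment,
    make_genome,
    make_rnaseq_library,
)

SCREEN_CLASSES = ("LINE", "SINE", "LTR", "DNA")

#: planted discovery target; deliberately period-6-repetitive, the hardest
#: register/orientation case for ZOOPS EM
DISCOVERY_CORE = "TTAGGGTTAGGGT"


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), *stream])


def _random_peaks(rng, layout, n, width=200) -> IntervalSet:
    chroms = list(layout.chrom_names)
    lengths = np.array([layout.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    ivs = []
    for i in range(n):
        ci = int(rng.choice(len(chroms), p=probs))
        s = int(rng.integers(0, layout.chrom_lengths[chroms[ci]] - width + 1))
        ivs.append(GenomicInterval(chroms[ci], s, s + width, ".", f"pk{i}"))
    return IntervalSet(ivs, layout)


# ---------------------------------------------------------------------------
# enrichment screen: null calibration and planted-binder recovery
# ---------------------------------------------------------------------------


def _screen_null_spec(seed: int) -> SyntheticGenomeSpec:
    """1 Mb screening genome; every class abundant enough that a 200-peak
    screen has the statistical power the 0.5-log2 calibration band implies
    (effective per-peak hit probabilities >~0.2 for each class)."""
    intact = {m: True for m in DEFAULT_MOTIFS}
    ablated = {m: False for m in DEFAULT_MOTIFS}
    return SyntheticGenomeSpec(
        seed=seed,
        chrom_lengths={"chr1": 1_000_000},
        subfamilies=[
            SubfamilySpec("L1PA1", 3, 6, 1.0, intact, True),
            SubfamilySpec("L1PA4", 5, 12, 5.0, intact, False),
            SubfamilySpec("L1PA7", 5, 12, 10.0, intact, False),
            SubfamilySpec("L1PA13", 3, 8, 17.0, ablated, False),
            SubfamilySpec("L1PA17", 2, 6, 24.0, ablated, False),
        ],
        other_classes={"SINE": 0.10, "LTR": 0.10, "DNA": 0.10},
        other_element_length=200,
    )


def screen_null_calibration(seed: int = 0, n_replicates: int = 100,
                            n_peaks: int = 200, peak_width: int = 600) -> dict:
    """Uniform-random peaks should show no TE-class enrichment.

    One synthetic 1 Mb genome with the four screened classes each covering
    >=5 %; per replicate, ``n_peaks`` peaks are placed uniformly and
    screened with 10 shuffles.  A replicate passes a class when the class's
    |log2(obs/exp)| < 0.5; reported are the per-replicate all-class pass
    fraction and the worst per-class pass fraction.
    """
    spec = _screen_null_spec(int(_rng(seed, 0).integers(2**31)))
    genome, annotations, _ = make_genome(spec)
    layout = layout_from_genome(genome)
    n_pass_all = 0
    class_pass = np.zeros(len(SCREEN_CLASSES))
    worst = 0.0
    for rep in range(n_replicates):
        rng = _rng(seed, 1, rep)
        peaks = _random_peaks(rng, layout, n_peaks, width=peak_width)
        cfg = ShuffleConfig(n_shuffles=10, seed=int(rng.integers(2**31)))
        matrix = enrichment_matrix({"null": peaks}, annotations, layout, cfg, SCREEN_CLASSES)
        abs_log2 = matrix.log2_ratio.abs().loc["null", list(SCREEN_CLASSES)].values
        worst = max(worst, float(abs_log2.max()))
        class_pass += abs_log2 < 0.5
        n_pass_all += bool((abs_log2 < 0.5).all())
    return {
        "n_replicates": n_replicates,
        "pass_fraction": n_pass_all / n_replicates,
        "min_class_pass_fraction": float(class_pass.min() / n_replicates),
        "worst_abs_log2": worst,
    }


def _cohort_spec(seed: int) -> SyntheticGenomeSpec:
    """Larger genome whose young subfamilies carry ~200 intact 3'-ORF2 sites."""
    intact = {m: True for m in DEFAULT_MOTIFS}
    ablated = {m: False for m in DEFAULT_MOTIFS}
    return SyntheticGenomeSpec(
        seed=seed,
        chrom_lengths={"chr1": 2_500_000, "chr2": 1_500_000},
        subfamilies=[
            SubfamilySpec("L1PA1", 8, 22, 1.0, intact, True),
            SubfamilySpec("L1PA4", 15, 60, 5.0, intact, False),
            SubfamilySpec("L1PA7", 15, 60, 10.0, intact, False),
            SubfamilySpec("L1PA13", 4, 16, 17.0, ablated, False),
            SubfamilySpec("L1PA17", 3, 12, 24.0, ablated, False),
        ],
    )


def planted_binder_recovery(seed: int = 0, n_seeds: int = 10, n_experiments: int = 20,
                            n_binders: int = 5, n_peaks: int = 200) -> dict:
    """A cohort with 5 planted L1 binders must be classified exactly.

    Per cohort seed, 20 simulated ChIP experiments are screened: 5 binders
    (signal_fraction 0.9 against the 3'-ORF2 motif) and 15 pure-background
    experiments, all with ``n_peaks`` peaks.  Recovery requires the binders
    — and only the binders — to be labelled single-class LINE-enriched at
    the 2-fold threshold.
    """
    spec = _cohort_spec(int(_rng(seed, 10).integers(2**31)))
    genome, annotations, truth = make_genome(spec)
    layout = layout_from_genome(genome)
    recovered_per_seed = []
    false_total = 0
    for rep in range(n_seeds):
        rng = _rng(seed, 11, rep)
        experiments = {}
        binder_names = set()
        for e in range(n_experiments):
            name = f"exp{rep}_{e}"
            sf = 0.9 if e < n_binders else 0.0
            if sf > 0:
                binder_names.add(name)
            peaks, _, _ = make_chip_experiment(
                genome, truth, "orf2_3p", signal_fraction=sf, n_peaks=n_peaks,
                peak_width=200, seed=int(rng.integers(2**31)), name=name,
            )
            experiments[name] = peaks
        cfg = ShuffleConfig(n_shuffles=10, seed=int(rng.integers(2**31)))
        matrix = enrichment_matrix(experiments, annotations, layout, cfg, SCREEN_CLASSES)
        calls = classify_enriched(matrix, fold=2.0)
        single = calls.single_class
        hits = {e for e, cls in single.items() if cls == "LINE"}
        recovered_per_seed.append(len(hits & binder_names))
        false_total += len(calls.enriched) - len(hits & binder_names)
    return {
        "n_seeds": n_seeds,
        "n_binders": n_binders,
        "recovered_min": min(recovered_per_seed),
        "recovered_mean": float(np.mean(recovered_per_seed)),
        "false_positive_total": false_total,
    }


# ---------------------------------------------------------------------------
# exact-oracle comparisons
# ---------------------------------------------------------------------------


def brute_force_intersect(a: IntervalSet, b: IntervalSet) -> list:
    """All-pairs any-overlap oracle (O(n*m))."""
    return [
        iva
        for iva in a
        if any(
            iva.chrom == ivb.chrom and iva.start < ivb.end and ivb.start < iva.end
            for ivb in b
        )
    ]


def intersect_oracle_agreement(seed: int = 0, n_fixtures: int = 1000) -> dict:
    """intersect_any vs the all-pairs oracle on random 10 kb fixtures."""
    from .intervals import GenomeLayout

    layout = GenomeLayout.from_dict({"chr1": 10_000, "chr2": 10_000})
    agree = 0
    for k in range(n_fixtures):
        rng = _rng(seed, 20, k)
        sets = []
        for n in (int(rng.integers(1, 100)), int(rng.integers(1, 50))):
            ivs = []
            for i in range(n):
                chrom = "chr1" if rng.random() < 0.5 else "chr2"
                L = int(rng.integers(1, 400))
                s = int(rng.integers(0, 10_000 - L))
                ivs.append(GenomicInterval(chrom, s, s + L, ".", f"i{i}"))
            sets.append(IntervalSet(ivs, layout))
        a, b = sets
        agree += list(intersect_any(a, b)) == brute_force_intersect(a, b)
    return {"n_fixtures": n_fixtures, "agreement_fraction": agree / n_fixtures}


def sw_score_oracle(query: str, ref: str, scoring: AlignmentScoring) -> int:
    """Unoptimised full-DP affine Smith-Waterman score (gap costs open+g*ext)."""
    m, n = len(query), len(ref)
    NEG = -(10**9)
    first = scoring.gap_open_penalty + scoring.gap_extend_penalty
    ext = scoring.gap_extend_penalty
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        qc = query[i - 1]
        for j in range(1, n + 1):
            Ei[j] = max(Hi[j - 1] - first, Ei[j - 1] - ext)
            Fi[j] = max(Hi1[j] - first, Fi1[j] - ext)
            s = scoring.match if (qc == ref[j - 1] and qc != "N") else -scoring.mismatch_penalty
            h = max(0, Hi1[j - 1] + s, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best = h
    return best


def alignment_oracle_agreement(seed: int = 0, n_instances: int = 100,
                               query_len: int = 60, ref_len: int = 500) -> dict:
    """local_align scores vs the full-DP oracle on random instances.

    Half the queries are 10%-mutated fragments of the reference (realistic
    divergent hits), half unrelated random sequence.
    """
    scoring = AlignmentScoring()
    agree = 0
    for k in range(n_instances):
        rng = _rng(seed, 30, k)
        ref = "".join(rng.choice(list("ACGT"), ref_len))
        if k % 2 == 0:
            s = int(rng.integers(0, ref_len - query_len))
            q = list(ref[s : s + query_len])
            for i in range(query_len):
                if rng.random() < 0.1:
                    q[i] = "ACGT"[int(rng.integers(4))]
            query = "".join(q)
        else:
            query = "".join(rng.choice(list("ACGT"), query_len))
        aln = local_align(query, ref, scoring)
        got = 0 if aln is None else aln.score
        expect = max(
            sw_score_oracle(query, ref, scoring),
            sw_score_oracle(revcomp(query), ref, scoring),
        )
        agree += got == expect
    return {"n_instances": n_instances, "agreement_fraction": agree / n_instances}


def pvalue_oracle_max_error(seed: int = 0, widths: tuple = (4, 5, 6, 7, 8),
                            granularity: int = 1000) -> dict:
    """Exact p-value DP vs exhaustive enumeration of all 4^W words."""
    max_err = 0.0
    for w in widths:
        rng = _rng(seed, 40, w)
        pfm = rng.dirichlet(np.ones(4) * 2, size=w)
        bg = rng.dirichlet(np.ones(4) * 10)
        motif = MotifModel(pfm=pfm, background=bg)
        table = score_pvalue_table(motif, granularity=granularity)
        words = np.array(list(itertools.product(range(4), repeat=w)), dtype=np.int64)
        scores = table.int_matrix[np.arange(w), words].sum(axis=1)
        probs = np.prod(bg[words], axis=1)
        # oracle p per distinct score = total probability of words scoring >= it
        for s in np.unique(scores):
            oracle_p = probs[scores >= s].sum()
            err = abs(table.pvalue(int(s)) - oracle_p)
            max_err = max(max_err, float(err))
    return {"widths": list(widths), "max_abs_error": max_err}


# ---------------------------------------------------------------------------
# motif discovery, subfamily specificity, mappability, indels
# ---------------------------------------------------------------------------


def motif_discovery_recovery(seed: int = 0, n_seeds: int = 20, n_sequences: int = 200,
                             seq_len: int = 60, n_starts: int = 5) -> dict:
    """ZOOPS EM must recover a planted 13-mer and its site positions."""
    core = DISCOVERY_CORE
    exact = 0
    recalls = []
    for rep in range(n_seeds):
        rng = _rng(seed, 50, rep)
        seqs, offsets = [], []
        for _ in range(n_sequences):
            s = "".join(rng.choice(list("ACGT"), seq_len))
            off = int(rng.integers(0, seq_len - len(core) + 1))
            seqs.append(s[:off] + core + s[off + len(core):])
            offsets.append(off)
        result = discover_motif_zoops(
            seqs, width=13, n_starts=n_starts, seed=int(rng.integers(2**31))
        )
        exact += result.consensus == core
        recall = sum(
            1 for call, off in zip(result.site_calls, offsets)
            if call is not None and call[0] == off and call[1] == "+"
        ) / n_sequences
        recalls.append(recall)
    return {
        "n_seeds": n_seeds,
        "exact_consensus_count": exact,
        "mean_site_recall": float(np.mean(recalls)),
        "min_site_recall": float(np.min(recalls)),
    }


def binder_pwm(core: str, p: float = 0.91) -> MotifModel:
    """PWM of a binder with known core: consensus probability ``p`` per
    position (the sharpness a few hundred aligned sites would support)."""
    pfm = np.full((len(core), 4), (1 - p) / 3)
    for i, b in enumerate(core):
        pfm[i, "ACGT".index(b)] = p
    return MotifModel(pfm=pfm, background=np.full(4, 0.25), name="binder")


def subfamily_specificity(seed: int = 0, peak_width: int = 200) -> dict:
    """Young (motif-intact) vs old (motif-ablated) subfamily profile contrast.

    ChIP peaks/coverage are simulated only at intact sites; the genome is
    scanned with the binder PWM at p < 5e-6, and anchor profiles are taken
    at every planted site.  Reports the young/old central-signal fold
    change and the number of scan hits inside intact and ablated sites.
    """
    spec = SyntheticGenomeSpec(seed=int(_rng(seed, 60).integers(2**31)))
    genome, annotations, truth = make_genome(spec)
    layout = layout_from_genome(genome)
    factor = "orf2_3p"
    intact_sites = truth.sites(factor, intact=True)
    peaks, chip, _ = make_chip_experiment(
        genome, truth, factor, signal_fraction=1.0, n_peaks=len(intact_sites),
        peak_width=peak_width, seed=int(_rng(seed, 61).integers(2**31)),
    )

    occurrences = scan_genome(
        binder_pwm(truth.motif_sequences[factor]), genome, p_threshold=5e-6,
        background="motif",
    )
    spans = [(o.interval.chrom, o.interval.start, o.interval.end) for o in occurrences]

    def hits_in(sites):
        return sum(
            any(c == s.chrom and a < s.end and s.start < b for (c, a, b) in spans)
            for s in sites
        )

    ablated_hits = hits_in(truth.sites(factor, intact=False))
    intact_hits = hits_in(intact_sites)

    # anchor profiles at every planted site of the factor, grouped by status
    sites = truth.sites(factor)
    anchors = IntervalSet(
        [
            GenomicInterval(s.chrom, s.start, s.end, s.strand,
                            "young" if s.intact else "old")
            for s in sites
        ],
        layout,
    )
    matrix = anchor_matrix(chip, anchors, flank=1000, bin_size=50)
    central = matrix.central_bin_means(n_central=2)
    labels = np.array(matrix.group_labels)
    young_mean = float(np.nanmean(central[labels == "young"]))
    old_mean = float(np.nanmean(central[labels == "old"]))
    return {
        "young_central_mean": young_mean,
        "old_central_mean": old_mean,
        "young_old_fold": young_mean / old_mean,
        "intact_site_hits": int(intact_hits),
        "ablated_site_hits": int(ablated_hits),
        "n_intact_sites": len(intact_sites),
        "n_ablated_sites": len(truth.sites(factor, intact=False)),
    }


def mappability_exactness(seed: int = 0, k: int = 100, block_len: int = 200,
                          flank_len: int = 1500) -> dict:
    """Mappability on a unique genome with one duplicated block, vs hand derivation.

    The genome is unique random sequence except for one ``block_len``-mer
    planted twice; every k-mer lying fully inside either copy occurs twice
    (value 1/2), everything else once (value 1).
    """
    from collections import Counter

    rng = _rng(seed, 70)
    for _ in range(20):
        flanks = ["".join(rng.choice(list("ACGT"), flank_len)) for _ in range(3)]
        block = "".join(rng.choice(list("ACGT"), block_len))
        chrom = flanks[0] + block + flanks[1] + block + flanks[2]
        kmers = [chrom[i : i + k] for i in range(len(chrom) - k + 1)]
        fwd = Counter(kmers)
        occ = [fwd[w] + fwd.get(revcomp(w), 0) for w in kmers]
        # construction check: exactly the block-interior k-mers occur twice
        n_dup = sum(1 for o in occ if o == 2)
        if max(occ) == 2 and n_dup == 2 * (block_len - k + 1):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not build a clean duplicated-block genome")

    expected = np.ones(len(chrom))
    a = flank_len
    b2 = flank_len + block_len + flank_len  # start of the second block copy
    for i in range(a, a + block_len - k + 1):
        expected[i] = 0.5
    for i in range(b2, b2 + block_len - k + 1):
        expected[i] = 0.5
    expected[len(chrom) - k + 1 :] = expected[len(chrom) - k]

    track = mappability_track({"chr1": chrom}, k=k)
    max_err = float(np.abs(track.data["chr1"] - expected).max())
    return {"k": k, "max_abs_error": max_err, "genome_length": len(chrom)}


def indel_recovery(seed: int = 0, n_seeds: int = 10, indel_fraction: float = 0.3,
                   n_fragments: int = 4000) -> dict:
    """Planted indels at 2 of 4 guide sites must be detected, the others not.

    A 3 kb cDNA "chromosome" is transcribed uniformly; the treated library
    plants ``indel_fraction`` indels at guides 1 and 3, the control none.
    Recovery requires the per-guide ratio at planted sites within 3
    binomial SDs of the planted fraction and disruption calls exactly at
    the planted guides, control-aware.
    """
    guide_positions = [500, 1200, 1900, 2600]
    planted = {500, 1900}
    correct_per_seed = []
    false_total = 0
    max_ratio_err_sd = 0.0
    recovered = []
    for rep in range(n_seeds):
        rng = _rng(seed, 80, rep)
        cdna = "".join(rng.choice(list("ACGT"), 3000))
        genome = {"cdna": cdna}
        layout = layout_from_genome(genome)
        truth = TruthTable("", {}, {}, (0, 0), (0, 0), [])
        gene = IntervalSet([GenomicInterval("cdna", 0, 3000, "+", "gene")], layout)
        treated = make_rnaseq_library(
            genome, truth, gene, [("cdna", p) for p in planted],
            indel_fraction=indel_fraction, n_fragments=n_fragments,
            seed=int(rng.integers(2**31)),
        )
        control = make_rnaseq_library(
            genome, truth, gene, [], indel_fraction=0.0,
            n_fragments=n_fragments, seed=int(rng.integers(2**31)),
        )
        r_treated = indel_coverage_ratio(treated, 3000)
        r_control = indel_coverage_ratio(control, 3000)
        verdicts = disruption_call(r_treated, guide_positions, window=20,
                                   background_profile=r_control)
        called = {v.position for v in verdicts if v.disrupted}
        correct_per_seed.append(len(called & planted))
        false_total += len(called - planted)
        for p in planted:
            depth = sum(1 for r in treated if r.start <= p < r.end)
            sd = np.sqrt(indel_fraction * (1 - indel_fraction) / max(depth, 1))
            err_sd = abs(r_treated[p] - indel_fraction) / sd
            max_ratio_err_sd = max(max_ratio_err_sd, float(err_sd))
            recovered.append(float(r_treated[p]))
    return {
        "n_seeds": n_seeds,
        "planted_fraction": indel_fraction,
        "mean_recovered_fraction": float(np.mean(recovered)),
        "correct_calls_min": min(correct_per_seed),
        "false_calls_total": false_total,
        "max_ratio_error_binomial_sds": max_ratio_err_sd,
    }


def determinism_check(seed: int = 0) -> dict:
    """Every stochastic entry point must be byte-reproducible under a seed."""
    spec = SyntheticGenomeSpec(seed=seed, chrom_lengths={"chr1": 200_000},
                               subfamilies=[
                                   SubfamilySpec("L1PA1", 2, 2, 2.0,
                                                 {m: True for m in DEFAULT_MOTIFS}, True)
                               ])
    g1, a1, t1 = make_genome(spec)
    g2, a2, t2 = make_genome(spec)
    genome_ok = g1 == g2 and a1 == a2 and t1.elements == t2.elements

    layout = layout_from_genome(g1)
    p1, c1, _ = make_chip_experiment(g1, t1, "orf2_3p", 0.5, 8, seed=seed)
    p2, c2, _ = make_chip_experiment(g1, t1, "orf2_3p", 0.5, 8, seed=seed)
    chip_ok = list(p1) == list(p2) and all(
        np.array_equal(c1.data[c], c2.data[c]) for c in c1.data
    )

    from .shuffle_null import shuffle_intervals

    cfg = ShuffleConfig(seed=seed)
    s1 = shuffle_intervals(p1, layout, cfg)
    s2 = shuffle_intervals(p1, layout, cfg)
    shuffle_ok = list(s1) == list(s2)

    rng = _rng(seed, 90)
    seqs = []
    for _ in range(40):
        s = "".join(rng.choice(list("ACGT"), 40))
        off = int(rng.integers(0, 28))
        seqs.append(s[:off] + DISCOVERY_CORE + s[off + 13:])
    e1 = discover_motif_zoops(seqs, width=13, n_starts=3, seed=seed)
    e2 = discover_motif_zoops(seqs, width=13, n_starts=3, seed=seed)
    em_ok = np.array_equal(e1.motif.pfm, e2.motif.pfm) and e1.site_calls == e2.site_calls

    gene = IntervalSet([GenomicInterval("chr1", 10_000, 14_000, "+", "g")], layout)
    r1 = make_rnaseq_library(g1, t1, gene, [("chr1", 12_000)], 0.3, 200, seed=seed)
    r2 = make_rnaseq_library(g1, t1, gene, [("chr1", 12_000)], 0.3, 200, seed=seed)
    rnaseq_ok = r1 == r2

    return {
        "genome": genome_ok,
        "chip": chip_ok,
        "shuffle": shuffle_ok,
        "em": em_ok,
        "rnaseq": rnaseq_ok,
        "all_deterministic": all([genome_ok, chip_ok, shuffle_ok, em_ok, rnaseq_ok]),
    }
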