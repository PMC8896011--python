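# teenrich

Repeat-centric ChIP-seq/RNA-seq analysis for discovering and characterising
DNA-binding proteins that target transposable elements (TEs) — LINE-1 (L1)
in particular.

Transposable elements make up roughly half the human genome, and most
standard ChIP-seq pipelines discard or under-weight the multi-mapping reads
that land on them.  `teenrich` implements the repeat-aware analyses needed
to screen binding data for TE-targeting factors and to dissect where inside
an element, and in which evolutionary subfamilies, a factor binds:

- **Enrichment screening** (`teenrich.shuffle_null`): for each experiment
  and TE class, the number of peaks overlapping the class is compared with
  its expectation under random relocation of the peaks
  (length-preserving, blacklist-aware, non-overlapping; 10 shuffles by
  default).  The statistic is `log2((obs+ε)/(exp+ε))` with ε = 1;
  experiments with a single >2-fold class are the screen's hits.
- **Motif discovery and scanning** (`teenrich.motif`): single-motif ZOOPS
  EM (zero-or-one occurrence per sequence, both strands, order-0
  background, default width 13) and PWM scanning with *exact* p-values via
  the discretised-score convolution (default cutoff p < 5e-6), plus
  binning of occurrences by L1 subfamily.
- **Consensus profiles** (`teenrich.consensus_profile`): affine-gap
  Smith–Waterman alignment of peak/read sequences onto an L1 consensus at
  near-minimal penalties (match +1, mismatch/gap-open/gap-extend 1), and
  per-position ChIP-over-scaled-input depth along consensus coordinates.
- **Meta-profiles and mappability** (`teenrich.meta_profile`):
  anchor-centred (±1 kb) and length-normalised (→5 kb) coverage matrices
  with strand-aware orientation, and theoretical k-mer mappability
  (1/occurrence count, both strands, k = 100).
- **Expression and CRISPR indels** (`teenrich.l1_expression`): union-rule
  paired-end fragment counting (fpm/FPKM) over elements and their 1-kb
  downstream read-through windows, and the per-position
  indel-depth/total-depth ratio that confirms Cas9 disruption at sgRNA
  sites.
- **Synthetic data with ground truth** (`teenrich.synthetic_data`): a
  seeded generator for genomes carrying an age-graded L1 subfamily ladder
  (older copies more diverged, 5′-truncated fragments, a binding motif
  intact in young subfamilies and ablated in old ones), ChIP peak
  sets/coverage tracks, and paired-end RNA-seq-like records with planted
  indels — so the full pipeline runs and is tested without any downloads.

Interval semantics follow BED/bedtools throughout: 0-based half-open
coordinates, overlap = at least one shared base pair.

## Worked example

Simulate a 1 Mb genome with planted L1 subfamilies, screen a simulated
binder against a background control, then recover and locate its motif:

```python
import numpy as np
import teenrich as te

genome, annotations, truth = te.make_genome(te.SyntheticGenomeSpec(seed=7))
layout = te.layout_from_genome(genome)

binder, chip, inp = te.make_chip_experiment(
    genome, truth, "orf2_3p", signal_fraction=0.9, n_peaks=20, seed=7, name="binder")
control, *_ = te.make_chip_experiment(
    genome, truth, "orf2_3p", signal_fraction=0.0, n_peaks=20, seed=8, name="control")

cfg = te.ShuffleConfig(n_shuffles=10, seed=7)
matrix = te.enrichment_matrix({"binder": binder, "control": control},
                              annotations, layout, cfg,
                              classes=("LINE", "SINE", "LTR", "DNA"))
print(matrix.log2_ratio.round(2))
print("single-class calls:", te.classify_enriched(matrix, fold=2.0).single_class)
```

```
         LINE  SINE   LTR   DNA
binder   2.25 -1.49 -1.32 -1.54
control -0.62  0.32  0.26  0.00
single-class calls: {'binder': 'LINE'}
```

The binder's peaks are ~4.8-fold enriched on LINEs (log2 = 2.25) and at or
below expectation everywhere else, so it is called a single-class LINE
binder; the control stays inside the null band.  Discovery on sequences
carrying the binding site then recovers the planted 13-mer exactly, and an
exact-p-value scan of the genome places occurrences almost entirely in the
motif-intact young subfamilies:

```python
rng = np.random.default_rng(7)
core = truth.motif_sequences["orf2_3p"]
seqs = []
for _ in range(100):
    s = "".join(rng.choice(list("ACGT"), 60)); off = int(rng.integers(0, 48))
    seqs.append(s[:off] + core + s[off + 13:])
result = te.discover_motif_zoops(seqs, width=13, seed=7)
print(result.summary())

occ = te.scan_genome(result.motif, genome, p_threshold=5e-6)
bins = te.bin_occurrences_by_subfamily(occ, annotations, layout)
print("occurrences per subfamily:", {k: len(v) for k, v in bins.items()})
```

```
ZOOPS motif (width 13, 10 restarts, seed 7)
  consensus        : TCAGTCCATAGGC
  site prior gamma : 1.0000
  log-likelihood   : -6972.891
  iterations       : 3 (converged)
  sequences w/ site: 100/100
occurrences per subfamily: {'L1PA1': 6, 'L1PA13': 2, 'L1PA4': 8, 'L1PA7': 8, 'LTR_rep': 2, 'unassigned': 9}
```

The 22 hits in L1PA1/PA4/PA7 are exactly the planted intact sites of the
young subfamilies; the ablated old-subfamily sites are not recovered (the
scattered remaining hits are the near-threshold background matches one
expects at p < 5e-6 over 2 × 1 Mb strands).

See `docs/methods.md` for the models, parameter defaults and the
synthetic-data generator's scope.

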