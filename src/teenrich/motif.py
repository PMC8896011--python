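"""Motif discovery (ZOOPS EM) and PWM scanning with exact p-values.

The discovery model is "zero or one occurrence per sequence": each input
sequence contains at most one motif site, on either strand, against an
order-0 background estimated from the input composition.  EM alternates a
posterior over site positions/strands (plus a no-site state) with
re-estimation of the position frequency matrix and the per-sequence site
prior; the best of several seeded restarts is kept.

Scanning discretises the log-odds score (base 2) to a fixed quantum of
``1/granularity`` bits and computes the exact null score distribution under
the background by position-wise convolution, so every reported p-value is
exact for the discretised score — the dynamic programme FIMO uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .intervals import GenomeLayout, GenomicInterval, IntervalSet, TEAnnotation
from .seqio import ALPHABET, N_CODE, encode, layout_from_genome

__all__ = [
    "MotifModel",
    "MotifOccurrence",
    "ZoopsMotifResult",
    "ScorePValueTable",
    "discover_motif_zoops",
    "score_pvalue_table",
    "scan_genome",
    "bin_occurrences_by_subfamily",
    "read_meme",
    "write_meme",
]


@dataclass
class MotifModel:
    """Fixed-width position frequency matrix with an order-0 background.

    ``pfm`` is a width x 4 matrix of probabilities over (A,C,G,T); rows sum
    to 1.  ``background`` is the order-0 composition the motif was learned
    against; ``site_count`` the (effective) number of sites supporting it.
    """

    pfm: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.1
    site_count: int = 0
    name: str = "motif"

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[1] != 4:
            raise ValueError("pfm must be width x 4")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.pfm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pfm rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.pfm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[a] for a in self.pfm.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Base-2 log-odds matrix; background zeros with motif mass raise."""
        if np.any((self.background == 0) & (self.pfm.sum(axis=0) > 0)):
            raise ValueError("zero background probability for a letter with motif mass")
        with np.errstate(divide="ignore"):
            lo = np.log2(self.pfm) - np.log2(self.background)
        if not np.isfinite(lo).all():
            raise ValueError("pfm contains zero probabilities; increase pseudocount")
        return lo

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(
            pfm=self.pfm[::-1, ::-1].copy(),
            background=self.background.copy(),
            pseudocount=self.pseudocount,
            site_count=self.site_count,
            name=self.name + "_rc",
        )

    def with_background(self, background: np.ndarray) -> "MotifModel":
        return MotifModel(
            pfm=self.pfm.copy(),
            background=np.asarray(background, dtype=float),
            pseudocount=self.pseudocount,
            site_count=self.site_count,
            name=self.name,
        )


@dataclass(frozen=True)
class MotifOccurrence:
    """One PWM match: a width-bp interval, strand, score (bits), exact p."""

    interval: GenomicInterval
    strand: str
    score: float
    p_value: float


# ---------------------------------------------------------------------------
# ZOOPS EM discovery
# ---------------------------------------------------------------------------


@dataclass
class ZoopsMotifResult:
    """Fitted ZOOPS motif model plus diagnostics.

    ``objective_trace`` is the EM objective (data log-likelihood plus the
    Dirichlet pseudocount prior on the matrix), guaranteed non-decreasing
    per iteration; ``log_likelihood`` is the final data log-likelihood.
    ``site_calls`` holds, per input sequence, the posterior-mode site as
    (start, strand, posterior) or None when the no-site state wins.
    """

    motif: MotifModel
    gamma: float
    log_likelihood: float
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    n_starts: int
    seed: int
    site_calls: list[tuple[int, str, float] | None] = field(default_factory=list)

    @property
    def consensus(self) -> str:
        return self.motif.consensus

    def summary(self) -> str:
        lines = [
            f"ZOOPS motif (width {self.motif.width}, {self.n_starts} restarts, seed {self.seed})",
            f"  consensus        : {self.consensus}",
            f"  site prior gamma : {self.gamma:.4f}",
            f"  log-likelihood   : {self.log_likelihood:.3f}",
            f"  iterations       : {self.n_iter} ({'converged' if self.converged else 'NOT converged'})",
            f"  sequences w/ site: {sum(c is not None for c in self.site_calls)}/{len(self.site_calls)}",
        ]
        return "\n".join(lines)


def _background_from_sequences(encoded: Sequence[np.ndarray]) -> np.ndarray:
    counts = np.zeros(4)
    for x in encoded:
        counts += np.bincount(x[x < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("sequences contain no ACGT letters")
    bg = counts / counts.sum()
    # floor so absent letters keep finite log-odds downstream
    bg = np.maximum(bg, 1e-4)
    return bg / bg.sum()


def _window_views(x: np.ndarray, width: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, width)


class _ZoopsData:
    """Pre-encoded sequences with per-window background log-likelihoods."""

    def __init__(self, sequences: Sequence[str], width: int):
        if not sequences:
            raise ValueError("no sequences given")
        self.width = width
        self.encoded = [encode(s) for s in sequences]
        if all(len(x) < width for x in self.encoded):
            raise ValueError("all sequences shorter than motif width")
        self.background = _background_from_sequences(self.encoded)
        log_bg = np.log(self.background)
        self.windows: list[np.ndarray] = []
        self.valid: list[np.ndarray] = []
        self.bg_win_ll: list[np.ndarray] = []
        self.total_bg_ll: list[float] = []
        for x in self.encoded:
            acgt = x[x < 4]
            self.total_bg_ll.append(float(log_bg[acgt].sum()) if len(acgt) else 0.0)
            if len(x) < width:
                self.windows.append(np.empty((0, width), dtype=np.int8))
                self.valid.append(np.zeros(0, dtype=bool))
                self.bg_win_ll.append(np.zeros(0))
                continue
            win = _window_views(x, width)
            valid = ~(win == N_CODE).any(axis=1)
            safe = np.where(win == N_CODE, 0, win)
            self.windows.append(safe)
            self.valid.append(valid)
            self.bg_win_ll.append(log_bg[safe].sum(axis=1))


def _motif_window_ll(data: _ZoopsData, log_pfm: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-sequence (forward, reverse) motif log-likelihood for each window."""
    w = data.width
    pos = np.arange(w)
    log_pfm_rc = log_pfm[::-1, ::-1]
    out = []
    for win in data.windows:
        if len(win) == 0:
            out.append((np.zeros(0), np.zeros(0)))
            continue
        fwd = log_pfm[pos, win].sum(axis=1)
        rev = log_pfm_rc[pos, win].sum(axis=1)
        out.append((fwd, rev))
    return out


def discover_motif_zoops(
    sequences: Sequence[str],
    width: int = 13,
    n_starts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    pseudocount: float = 0.1,
) -> ZoopsMotifResult:
    """Fit a single fixed-width motif to sequences under the ZOOPS model.

    Both strands are searched; windows containing N are excluded from site
    candidacy.  Each restart initialises the matrix from a randomly chosen
    input subsequence (letter probability 0.5 at the observed base).  The
    restart with the highest final objective wins; identical inputs and seed
    give bit-identical results.

    Returns a :class:`ZoopsMotifResult`; the fitted matrix is ``.motif``.
    """
    data = _ZoopsData(sequences, width)
    bg = data.background
    rng = np.random.default_rng(seed)

    # candidate (sequence, offset) pairs for seeding restarts
    candidates = [
        (i, j) for i, v in enumerate(data.valid) for j in np.flatnonzero(v)
    ]
    if not candidates:
        raise ValueError("no N-free windows of the requested width")

    best = None
    best_obj = -np.inf
    for start_idx in range(n_starts):
        i, j = candidates[int(rng.integers(len(candidates)))]
        word = data.windows[i][j]
        pfm = np.full((width, 4), 0.5 / 3)
        pfm[np.arange(width), word] = 0.5
        result = _run_em(data, pfm, gamma0=0.5, max_iter=max_iter, tol=tol,
                         pseudocount=pseudocount)
        if best is None or result[2][-1] > best_obj:
            best = result
            best_obj = result[2][-1]

    # phase-shift refinement: periodic motifs trap EM in a register shifted
    # by a few columns; sliding the matrix and re-running EM escapes that
    # local optimum when the shifted register explains the data better
    improved = True
    rounds = 0
    while improved and rounds < 4:
        improved = False
        rounds += 1
        for shift in (-2, -1, 1, 2):
            shifted = np.tile(data.background, (width, 1))
            if shift > 0:
                shifted[shift:] = best[0][:-shift]
            else:
                shifted[:shift] = best[0][-shift:]
            result = _run_em(data, shifted, gamma0=best[1], max_iter=max_iter,
                             tol=tol, pseudocount=pseudocount)
            if result[2][-1] > best_obj + 1e-9:
                best, best_obj = result, result[2][-1]
                improved = True

    pfm, gamma, obj_trace, ll, converged, n_iter, site_calls = best
    # a motif and its reverse complement are likelihood-equivalent under the
    # two-strand model; orient so most supporting sites are forward-strand
    n_minus = sum(1 for c in site_calls if c is not None and c[1] == "-")
    n_plus = sum(1 for c in site_calls if c is not None and c[1] == "+")
    if n_minus > n_plus:
        pfm = pfm[::-1, ::-1].copy()
        site_calls = [
            None if c is None else (c[0], "+" if c[1] == "-" else "-", c[2])
            for c in site_calls
        ]
    model = MotifModel(
        pfm=pfm,
        background=bg,
        pseudocount=pseudocount,
        site_count=sum(c is not None for c in site_calls),
    )
    return ZoopsMotifResult(
        motif=model,
        gamma=gamma,
        log_likelihood=ll,
        objective_trace=np.asarray(obj_trace),
        converged=converged,
        n_iter=n_iter,
        n_starts=n_starts,
        seed=seed,
        site_calls=site_calls,
    )


def _run_em(data: _ZoopsData, pfm: np.ndarray, gamma0: float, max_iter: int,
            tol: float, pseudocount: float):
    width = data.width
    bg = data.background
    alpha = pseudocount * bg  # Dirichlet pseudo-counts, background-proportional
    gamma = gamma0
    obj_trace: list[float] = []
    converged = False
    n_iter = 0
    ll = -np.inf
    pos = np.arange(width)

    for it in range(max_iter):
        n_iter = it + 1
        log_pfm = np.log(pfm)
        win_ll = _motif_window_ll(data, log_pfm)

        counts = np.zeros((width, 4))
        gamma_num = 0.0
        ll = 0.0
        site_calls: list[tuple[int, str, float] | None] = []
        for i, (fwd, rev) in enumerate(win_ll):
            valid = data.valid[i]
            m = int(valid.sum())
            if m == 0:
                ll += data.total_bg_ll[i]
                site_calls.append(None)
                continue
            bgw = data.bg_win_ll[i]
            # log weights relative to the all-background likelihood
            lw_no = np.log1p(-gamma)
            lw_f = np.where(valid, np.log(gamma / (2 * m)) + fwd - bgw, -np.inf)
            lw_r = np.where(valid, np.log(gamma / (2 * m)) + rev - bgw, -np.inf)
            norm = logsumexp(np.concatenate(([lw_no], lw_f, lw_r)))
            ll += data.total_bg_ll[i] + norm
            zf = np.exp(lw_f - norm)
            zr = np.exp(lw_r - norm)
            gamma_num += zf.sum() + zr.sum()
            win = data.windows[i]
            np.add.at(counts, (pos[None, :], win), zf[:, None])
            np.add.at(counts, (pos[None, :], 3 - win[:, ::-1]), zr[:, None])
            # posterior-mode site call
            jf, jr = int(np.argmax(lw_f)), int(np.argmax(lw_r))
            best_lw, best_j, best_s = max(
                (lw_f[jf], jf, "+"), (lw_r[jr], jr, "-"), key=lambda t: t[0]
            )
            if best_lw > lw_no:
                site_calls.append((best_j, best_s, float(np.exp(best_lw - norm))))
            else:
                site_calls.append(None)

        # objective: data log-likelihood + Dirichlet(alpha+1) log-prior on pfm
        obj = ll + float((alpha * np.log(pfm)).sum())
        obj_trace.append(obj)
        if it > 0 and abs(obj_trace[-1] - obj_trace[-2]) < tol * (1 + abs(obj_trace[-2])):
            converged = True
            break

        # M-step
        pfm = counts + alpha
        pfm /= pfm.sum(axis=1, keepdims=True)
        n_candidates = sum(1 for v in data.valid if v.any())
        gamma = float(np.clip(gamma_num / max(n_candidates, 1), 1e-6, 1 - 1e-6))

    return pfm, gamma, obj_trace, float(ll), converged, n_iter, site_calls


# ---------------------------------------------------------------------------
# Exact p-values and scanning
# ---------------------------------------------------------------------------


@dataclass
class ScorePValueTable:
    """Exact null distribution of the integer-discretised log-odds score.

    Scores are in units of ``1/granularity`` bits.  ``pvalues[t]`` is
    P(score >= t + min_score) under the order-0 background, computed by
    position-wise convolution over the motif columns.
    """

    int_matrix: np.ndarray  # width x 4 integer scores
    granularity: int
    min_score: int
    pvalues: np.ndarray

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.pvalues) - 1

    def score_word(self, word: str | np.ndarray) -> int:
        codes = encode(word) if isinstance(word, str) else word
        if len(codes) != self.int_matrix.shape[0]:
            raise ValueError("word length does not match motif width")
        if (codes >= 4).any():
            raise ValueError("word contains N")
        return int(self.int_matrix[np.arange(len(codes)), codes].sum())

    def pvalue(self, int_score: int | np.ndarray) -> float | np.ndarray:
        idx = np.clip(np.asarray(int_score) - self.min_score, 0, len(self.pvalues) - 1)
        out = self.pvalues[idx]
        return float(out) if np.isscalar(int_score) or np.ndim(int_score) == 0 else out

    def bits(self, int_score: int) -> float:
        return int_score / self.granularity


def score_pvalue_table(motif: MotifModel, granularity: int = 1000) -> ScorePValueTable:
    """Exact score -> p-value table under the motif's background.

    The base-2 log-odds matrix is rounded to integer multiples of
    ``1/granularity`` bits; the exact distribution of the integer total over
    random background words is obtained by convolving the four-point column
    distributions, and p-values are the upper tail P(score >= s).
    """
    if granularity < 100:
        raise ValueError("granularity must be >= 100")
    lo = motif.log_odds()
    int_matrix = np.rint(lo * granularity).astype(np.int64)
    offsets = int_matrix.min(axis=1)
    shifted = int_matrix - offsets[:, None]
    span = int(shifted.max(axis=1).sum())
    prob = np.zeros(span + 1)
    prob[0] = 1.0
    width = motif.width
    bg = motif.background
    top = 0
    for k in range(width):
        new = np.zeros_like(prob)
        for a in range(4):
            s = int(shifted[k, a])
            if bg[a] > 0:
                new[s : s + top + 1] += prob[: top + 1] * bg[a]
        top += int(shifted[k].max())
        prob = new
    pvalues = np.cumsum(prob[::-1])[::-1]
    pvalues = np.minimum(pvalues, 1.0)
    return ScorePValueTable(
        int_matrix=int_matrix,
        granularity=granularity,
        min_score=int(offsets.sum()),
        pvalues=pvalues,
    )


def _window_int_scores(codes: np.ndarray, int_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(scores, valid) per window start; N windows flagged invalid."""
    width = int_matrix.shape[0]
    if len(codes) < width:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    win = _window_views(codes, width)
    valid = ~(win == N_CODE).any(axis=1)
    safe = np.where(win == N_CODE, 0, win)
    scores = int_matrix[np.arange(width), safe].sum(axis=1)
    return scores, valid


def scan_genome(
    motif: MotifModel,
    genome: Mapping[str, str],
    regions: IntervalSet | None = None,
    p_threshold: float = 5e-6,
    granularity: int = 1000,
    background: str | np.ndarray | None = None,
) -> list[MotifOccurrence]:
    """Report every window (both strands) with exact p-value < threshold.

    Coordinates are 0-based half-open on the forward strand regardless of
    match strand.  Windows containing N are skipped.  By default the null
    background is re-estimated from the scanned sequence (order-0,
    strand-symmetric); pass ``background="motif"`` to keep the motif's own
    background, or an explicit length-4 vector.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    layout = layout_from_genome(dict(genome))
    if regions is None:
        targets = [
            GenomicInterval(c, 0, layout.chrom_lengths[c]) for c in layout.chrom_names
        ]
    else:
        targets = list(regions)
        for iv in targets:
            iv.validate(layout)

    target_codes = [(iv, encode(genome[iv.chrom][iv.start : iv.end])) for iv in targets]

    if background is None:
        bg = _background_from_sequences([c for _, c in target_codes])
    elif isinstance(background, str) and background == "motif":
        bg = motif.background
    else:
        bg = np.asarray(background, dtype=float)
    table = score_pvalue_table(motif.with_background(bg), granularity)
    int_fwd = table.int_matrix
    int_rev = int_fwd[::-1, ::-1]  # score of the reverse-complement match
    width = motif.width

    occurrences: list[MotifOccurrence] = []
    for iv, codes in target_codes:
        sf, valid = _window_int_scores(codes, int_fwd)
        sr, _ = _window_int_scores(codes, int_rev)
        pf = table.pvalue(sf)
        pr = table.pvalue(sr)
        if p_threshold >= 1.0:  # threshold 1 means "report every window"
            hit_f = valid.copy()
            hit_r = valid.copy()
        else:
            hit_f = valid & (pf < p_threshold)
            hit_r = valid & (pr < p_threshold)
        for j in np.flatnonzero(hit_f | hit_r):
            j = int(j)
            g = GenomicInterval(iv.chrom, iv.start + j, iv.start + j + width)
            both = hit_f[j] and hit_r[j]
            if hit_f[j]:
                occurrences.append(
                    MotifOccurrence(g, "+", table.bits(int(sf[j])), float(pf[j]))
                )
            if hit_r[j] and not (both and sr[j] == sf[j]):  # palindromic tie: + only
                occurrences.append(
                    MotifOccurrence(g, "-", table.bits(int(sr[j])), float(pr[j]))
                )
    order = {c: i for i, c in enumerate(layout.chrom_names)}
    occurrences.sort(key=lambda o: (order[o.interval.chrom], o.interval.start, o.strand))
    return occurrences


def bin_occurrences_by_subfamily(
    occurrences: Iterable[MotifOccurrence],
    te_annotations: Iterable[TEAnnotation],
    layout: GenomeLayout,
) -> dict[str, IntervalSet]:
    """Assign each occurrence to the subfamily of its containing annotation.

    An occurrence overlapping several annotations goes to the one with the
    larger overlap (leftmost annotation on ties); occurrences outside every
    annotation land in the ``"unassigned"`` bin.
    """
    anns = sorted(
        te_annotations, key=lambda a: (a.interval.chrom, a.interval.start, a.interval.end)
    )
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for idx, ann in enumerate(anns):
        iv = ann.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)

    bins: dict[str, list[GenomicInterval]] = {}
    for occ in occurrences:
        iv = occ.interval
        tree = trees.get(iv.chrom)
        hits = sorted(tree.overlap(iv.start, iv.end), key=lambda h: h.data) if tree else []
        if not hits:
            key = "unassigned"
        else:
            best = max(
                hits,
                key=lambda h: (
                    anns[h.data].interval.overlap_length(iv),
                    -anns[h.data].interval.start,
                    -h.data,
                ),
            )
            key = anns[best.data].repeat_name
        marked = GenomicInterval(
            iv.chrom, iv.start, iv.end, occ.strand,
            name=key, score=-np.log10(max(occ.p_value, 1e-300)),
        )
        bins.setdefault(key, []).append(marked)
    return {k: IntervalSet(v, layout) for k, v in sorted(bins.items())}


# ---------------------------------------------------------------------------
# MEME minimal text format
# ---------------------------------------------------------------------------


def write_meme(motifs: Iterable[MotifModel], path: str | Path) -> None:
    motifs = list(motifs)
    bg = motifs[0].background if motifs else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip(ALPHABET, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {max(m.site_count, 1)} E= 0\n"
            )
            for row in m.pfm:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[MotifModel]:
    motifs: list[MotifModel] = []
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else "motif"
            i += 1
            header = lines[i].strip()
            tokens = header.replace("=", " = ").split()
            width = int(tokens[tokens.index("w") + 2])
            nsites = int(tokens[tokens.index("nsites") + 2]) if "nsites" in tokens else 0
            rows = []
            for k in range(width):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            pfm = np.asarray(rows)
            pfm /= pfm.sum(axis=1, keepdims=True)
            motifs.append(
                MotifModel(pfm=pfm, background=background, site_count=nsites, name=name)
            )
        i += 1
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs
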