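"""Promoter windows, PWM scanning, and central motif enrichment.

The question asked here: are binding motifs (e.g., the RFX consensus)
concentrated near the transcription start sites of an up-regulated gene set,
relative to a negative set of randomly drawn genes? Promoter windows span
500 bp on each side of the TSS in gene orientation; both strands are scanned
with a log-odds position weight matrix; per gene the best hit is kept, and
enrichment of best hits inside a central region is tested with a binomial
upper tail whose success probability is the empirical concentration observed
in the negative set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy.stats import binom

from .synthetic import reverse_complement

log = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "PromoterWindow",
    "MotifHit",
    "CentralEnrichmentResult",
    "load_jaspar",
    "load_meme_minimal",
    "extract_promoter_windows",
    "windows_from_sequences",
    "scan_pwm",
    "best_hits",
    "central_enrichment",
    "motif_probability_curve",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position probability matrix with background model and log-odds scores.

    ``probs`` is (width, 4) over A,C,G,T; a pseudocount is added per cell and
    columns renormalized, so every column sums to 1. Scores are in bits:
    sum over positions of log2(p_base / bg_base); an N contributes 0
    (scored as background).
    """

    motif_id: str
    probs: np.ndarray
    pseudocount: float = 0.01
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be (width, 4) with width >= 1")
        probs = probs + self.pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        object.__setattr__(self, "probs", probs)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6:
            raise ValueError("background must be 4 frequencies summing to 1")
        object.__setattr__(self, "background", bg)

    @property
    def width(self):
        return self.probs.shape[0]

    @property
    def log_odds(self):
        """(width, 5) log2-odds matrix; column 4 (N) is all zeros."""
        lo = np.log2(self.probs / self.background)
        return np.hstack([lo, np.zeros((self.width, 1))])

    @property
    def max_score(self):
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self):
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self):
        return PWM(self.motif_id + "_rc", self.probs[::-1, ::-1],
                   pseudocount=0.0, background=self.background[::-1])

    @classmethod
    def from_counts(cls, motif_id, counts, pseudocount=0.01, background=None):
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=1, keepdims=True)
        kwargs = {} if background is None else {"background": background}
        return cls(motif_id, probs, pseudocount=pseudocount, **kwargs)


def _from_biopython(m, pseudocount, background):
    counts = np.column_stack([m.counts[b] for b in _BASES])
    name = m.matrix_id if getattr(m, "matrix_id", None) else (m.name or "motif")
    return PWM.from_counts(name, counts, pseudocount=pseudocount,
                           background=background)


def load_jaspar(path, pseudocount=0.01, background=None):
    """Parse a JASPAR PFM file into a list of PWMs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    return [_from_biopython(m, pseudocount, background) for m in parsed]


def load_meme_minimal(path, pseudocount=0.01, background=None):
    """Parse a MEME minimal-format motif file into a list of PWMs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    return [_from_biopython(m, pseudocount, background) for m in parsed]


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterWindow:
    """TSS-centered promoter sequence, oriented with the gene.

    Offset 0 is the TSS and negative offsets are upstream in gene
    orientation. Both strands use the genomic interval [tss-hw, tss+hw);
    minus-strand sequences are reverse-complemented, so minus-strand offsets
    span -hw+1 .. +hw while plus-strand offsets span -hw .. +hw-1.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    tss: int
    strand: str
    sequence: str
    half_width: int = 500
    clipped: bool = False

    def offset_of_index(self, i):
        """TSS-relative offset (gene orientation) of sequence index ``i``."""
        if self.strand == "+":
            return self.start + i - self.tss
        return self.tss - (self.end - 1 - i)


def extract_promoter_windows(genes, fasta, half_width=500):
    """Extract TSS +/- half_width windows from an indexed genome FASTA.

    ``genes`` is a DataFrame with gene_id, chrom, tss, strand (0-based TSS);
    ``fasta`` is a ``pyfaidx.Fasta``. Minus-strand windows are
    reverse-complemented. Windows at chromosome edges are clipped and
    flagged; genes on missing chromosomes raise. Genes with a null TSS are
    skipped with a warning.
    """
    windows = []
    for _, g in genes.iterrows():
        if pd.isna(g["tss"]):
            log.warning("gene %s has no TSS; skipped", g["gene_id"])
            continue
        chrom = g["chrom"]
        if chrom not in fasta:
            raise ValueError(f"chromosome {chrom} missing from FASTA")
        length = len(fasta[chrom])
        tss = int(g["tss"])
        start, end = tss - half_width, tss + half_width
        clipped = start < 0 or end > length
        start_c, end_c = max(start, 0), min(end, length)
        seq = str(fasta[chrom][start_c:end_c]).upper()
        if g["strand"] == "-":
            seq = reverse_complement(seq)
        windows.append(PromoterWindow(
            gene_id=g["gene_id"], chrom=chrom, start=start_c, end=end_c,
            tss=tss, strand=g["strand"], sequence=seq,
            half_width=half_width, clipped=clipped))
    return windows


def windows_from_sequences(seqs, half_width=500, strand="+"):
    """Wrap pre-extracted promoter sequences (e.g., from the generator).

    The TSS is taken to sit at index ``half_width`` of each sequence.
    """
    return [PromoterWindow(gene_id=g, chrom=".", start=0, end=len(s),
                           tss=half_width, strand=strand, sequence=s,
                           half_width=half_width)
            for g, s in seqs.items()]


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    offset: int      # hit-center offset relative to TSS; upstream negative
    strand: str      # strand of the match relative to the gene
    score: float     # log-odds, bits


def _encode(seq):
    return np.fromiter((_BASE_INDEX.get(b, 4) for b in seq), dtype=np.int8,
                       count=len(seq))


def _window_scores(codes, log_odds):
    """Scores of every ungapped placement of the matrix along ``codes``."""
    width = log_odds.shape[0]
    if codes.size - width + 1 <= 0:
        return np.empty(0)
    view = np.lib.stride_tricks.sliding_window_view(codes, width)
    return log_odds[np.arange(width)[None, :], view].sum(axis=1)


def scan_pwm(window, pwm, score_threshold=None):
    """Scan one promoter window on both strands.

    Reports every placement scoring at or above ``score_threshold``
    (default: 80% of the PWM's maximal log-odds). The hit center is
    floor(width/2) bases from the hit start; offsets are TSS-relative in
    gene orientation. Ambiguous bases (N) score as background (0 bits);
    an all-N window yields no hits above any positive threshold.
    """
    if len(window.sequence) < pwm.width:
        raise ValueError("window shorter than PWM width")
    if score_threshold is None:
        score_threshold = 0.8 * pwm.max_score
    codes = _encode(window.sequence)
    width = pwm.width
    center_shift = width // 2
    off = window.offset_of_index
    hits = []
    fwd = _window_scores(codes, pwm.log_odds)
    for i in np.flatnonzero(fwd >= score_threshold):
        hits.append(MotifHit(window.gene_id, off(int(i) + center_shift),
                             "+", float(fwd[i])))
    rc = pwm.reverse_complement()
    rev = _window_scores(codes, rc.log_odds)
    for i in np.flatnonzero(rev >= score_threshold):
        hits.append(MotifHit(window.gene_id, off(int(i) + center_shift),
                             "-", float(rev[i])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def best_hits(hits_by_gene):
    """Best hit per gene: max score, ties to the most TSS-central, then 5'.

    ``hits_by_gene`` maps gene_id -> list of MotifHit (possibly empty).
    Returns gene_id -> MotifHit-or-None for every gene.
    """
    out = {}
    for gene, hits in hits_by_gene.items():
        if not hits:
            out[gene] = None
            continue
        out[gene] = max(hits, key=lambda h: (h.score, -abs(h.offset),
                                             -h.offset))
    return out


def scan_windows(windows, pwm, score_threshold=None):
    """Scan many windows; returns gene_id -> hit list (all genes present)."""
    return {w.gene_id: scan_pwm(w, pwm, score_threshold) for w in windows}


# ---------------------------------------------------------------------------
# central enrichment
# ---------------------------------------------------------------------------

@dataclass
class CentralEnrichmentResult:
    motif_id: str
    central_half_width: int      # selected w*
    n_target: int                # target genes scanned
    k_target: int                # target best hits within +/- w*
    n_negative: int
    k_negative: int
    negative_concentration: float  # pi(w*): empirical fraction in negatives
    fold_concentration: float
    pvalue: float
    n_widths_tested: int


def central_enrichment(target_best, negative_best, w_grid=(250,),
                       motif_id="motif"):
    """Binomial test of best-hit concentration near the TSS.

    For each candidate central half-width w, pi(w) is the fraction of
    negative-set genes whose best hit falls within +/- w of the TSS (genes
    without hits count in the denominator); the target count is tested
    against Binomial(n_target, pi(w)) upper tail. With more than one w the
    minimal p is Bonferroni-corrected by the grid size and the winning w is
    reported. The default is a single pre-chosen central region of 250 bp
    (half the promoter window) so the test's size is calibrated.
    """
    if not w_grid:
        raise ValueError("w_grid must be non-empty")
    n_t = len(target_best)
    n_n = len(negative_best)
    if n_n == 0:
        raise ValueError("empty negative set")
    t_offsets = np.array([h.offset for h in target_best.values()
                          if h is not None])
    n_offsets = np.array([h.offset for h in negative_best.values()
                          if h is not None])
    if t_offsets.size == 0 or n_t == 0:
        return CentralEnrichmentResult(motif_id, int(w_grid[0]), n_t, 0,
                                       n_n, 0, 0.0, 0.0, 1.0, len(w_grid))
    best = None
    for w in w_grid:
        k_t = int((np.abs(t_offsets) <= w).sum())
        k_n = int((np.abs(n_offsets) <= w).sum())
        # clamp pi away from 0 so the tail is defined when negatives are bare
        pi = max(k_n / n_n, 1.0 / (2 * n_n))
        p = float(binom.sf(k_t - 1, n_t, min(pi, 1.0))) if k_t else 1.0
        if best is None or p < best[0]:
            best = (p, int(w), k_t, k_n, pi)
    p, w_star, k_t, k_n, pi = best
    p = min(1.0, p * len(w_grid))
    fold = (k_t / n_t) / pi if pi > 0 else np.inf
    return CentralEnrichmentResult(motif_id, w_star, n_t, k_t, n_n, k_n,
                                   pi, fold, max(p, np.nextafter(0, 1)),
                                   len(w_grid))


def motif_probability_curve(best, half_width=500, bin_width=50):
    """Per-bin fraction of genes whose best hit centers in the bin.

    Mirrors a motif-probability graph: x is TSS-relative offset, y the
    fraction of scanned genes with their best hit in that bin. The curve
    sums to <= 1 because genes may lack hits.
    """
    if (2 * half_width) % bin_width:
        raise ValueError("bin_width must divide the window evenly")
    edges = np.arange(-half_width, half_width + 1, bin_width)
    offsets = np.array([h.offset for h in best.values() if h is not None])
    n_genes = len(best)
    counts, _ = np.histogram(offsets, bins=edges) if offsets.size else (
        np.zeros(len(edges) - 1, dtype=int), edges)
    prob = counts / n_genes if n_genes else counts.astype(float)
    return pd.DataFrame({"offset_left": edges[:-1], "offset_right": edges[1:],
                         "probability": prob})
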