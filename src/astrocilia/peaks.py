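"""TSS-proximal ChIP-peak enrichment against constructed negative gene sets.

Tests whether transcription-factor binding sites (ChIP-seq peaks, e.g.
RFX1-3) are over-represented within 10 kb of the transcription start sites
of an up-regulated gene set. Signed distance distributions (upstream
negative, in gene orientation) are compared with two kinds of negative gene
sets — random genome draws or expressed-but-unchanged genes — and
significance is assessed with an empirical resampling test: the statistic
is the mean number of peaks per gene within the window, the null is built
from matched-size negative-set redraws.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "DistanceProfile",
    "PositionalEnrichmentResult",
    "read_bed",
    "read_tss_tsv",
    "read_gff3_genes",
    "select_tss",
    "signed_distances",
    "peak_counts_per_gene",
    "distance_profile",
    "sample_negative_genes",
    "positional_enrichment_test",
]

NEGATIVE_MODES = ("genome_random", "expressed_unchanged")


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_bed(path, tf_label=None):
    """Read a BED file (0-based half-open) of peak intervals."""
    peaks = pd.read_csv(path, sep="\t", comment="#", header=None)
    peaks = peaks.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if 3 in peaks.columns:
        peaks = peaks.rename(columns={3: "name"})
    else:
        peaks["name"] = tf_label or "."
    peaks = peaks[["chrom", "start", "end", "name"]]
    if (peaks["start"] >= peaks["end"]).any():
        bad = peaks.index[peaks["start"] >= peaks["end"]].tolist()[:5]
        raise ValueError(f"BED intervals with start >= end at rows {bad}")
    return peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def read_tss_tsv(path):
    """Read a TSS table: gene_id, chrom, pos (0-based bp), strand."""
    tss = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "pos", "strand"}
    missing = required - set(tss.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    if (tss["pos"] < 0).any():
        raise ValueError("negative TSS position")
    return tss


def _gff3_attr(attrs, key):
    for part in attrs.split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


def read_gff3_genes(path):
    """Parse gene and transcript records from a GFF3 file.

    Returns a DataFrame of transcripts: gene_id, chrom, start, end, strand
    with 1-based inclusive coordinates converted to 0-based half-open.
    Transcripts are attached to genes via their Parent attribute; a gene
    without transcripts falls back to its own record.
    """
    cols = ["chrom", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    genes = df[df["type"] == "gene"].copy()
    tx = df[df["type"].isin(["mRNA", "transcript"])].copy()
    genes["gene_id"] = genes["attributes"].map(lambda a: _gff3_attr(a, "ID"))
    tx["gene_id"] = tx["attributes"].map(lambda a: _gff3_attr(a, "Parent"))
    have_tx = set(tx["gene_id"])
    orphan = genes[~genes["gene_id"].isin(have_tx)]
    if len(orphan):
        log.warning("%d genes without transcripts; using the gene record",
                    len(orphan))
    out = pd.concat([tx, orphan], ignore_index=True)
    out = out[["gene_id", "chrom", "start", "end", "strand"]].copy()
    out["start"] = out["start"].astype(int) - 1  # to 0-based half-open
    out["end"] = out["end"].astype(int)
    return out


def select_tss(transcripts, policy="five_prime"):
    """One TSS per gene: the 5'-most transcript start in gene orientation.

    ``transcripts``: DataFrame from :func:`read_gff3_genes` (0-based
    half-open). On + the TSS is the minimal start; on - it is the maximal
    end - 1. Returns gene_id, chrom, pos, strand.
    """
    if policy != "five_prime":
        raise ValueError(f"unknown TSS policy: {policy}")
    rows = []
    for gene_id, sub in transcripts.groupby("gene_id", sort=True):
        strand = sub["strand"].iloc[0]
        chrom = sub["chrom"].iloc[0]
        if strand == "+":
            pos = int(sub["start"].min())
        else:
            pos = int(sub["end"].max()) - 1
        rows.append((gene_id, chrom, pos, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand"])


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def signed_distances(tss, peaks, half_width=10_000):
    """Signed peak-center-to-TSS distances within +/- half_width.

    Peak center = floor((start+end)/2). Distance = center - tss on +,
    negated on -, so negative always means upstream in gene orientation.
    Raises if the two inputs share no chromosome naming.

    Returns a DataFrame: gene_id, distance (one row per gene-peak pair
    inside the window).
    """
    tss_chroms = set(tss["chrom"])
    peak_chroms = set(peaks["chrom"])
    if len(peaks) and len(tss) and not (tss_chroms & peak_chroms):
        raise ValueError(
            f"no shared chromosomes between TSS ({sorted(tss_chroms)[:3]}) "
            f"and peaks ({sorted(peak_chroms)[:3]})")
    out_genes, out_dists = [], []
    centers_by_chrom = {
        chrom: np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
        for chrom, sub in peaks.groupby("chrom")}
    for _, g in tss.iterrows():
        centers = centers_by_chrom.get(g["chrom"])
        if centers is None:
            continue
        t = int(g["pos"])
        lo = np.searchsorted(centers, t - half_width, side="left")
        hi = np.searchsorted(centers, t + half_width, side="right")
        d = centers[lo:hi] - t
        if g["strand"] == "-":
            d = -d
        out_genes.extend([g["gene_id"]] * d.size)
        out_dists.extend(d.tolist())
    return pd.DataFrame({"gene_id": out_genes, "distance": out_dists})


def peak_counts_per_gene(tss, peaks, half_width=10_000):
    """Number of peak centers within +/- half_width of each gene's TSS."""
    dists = signed_distances(tss, peaks, half_width)
    counts = dists.groupby("gene_id").size()
    return counts.reindex(tss["gene_id"], fill_value=0)


@dataclass
class DistanceProfile:
    """Histogram of signed peak-TSS distances for one gene set."""

    label: str
    bin_edges: np.ndarray
    counts: np.ndarray
    n_genes: int
    n_peaks: int

    @property
    def per_gene_counts(self):
        return self.counts / max(self.n_genes, 1)

    def to_frame(self):
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1], "bin_right": self.bin_edges[1:],
            "count": self.counts,
            "peaks_per_gene": self.per_gene_counts})


def distance_profile(distances, n_genes, half_width=10_000, bin_width=500,
                     label="gene_set"):
    """Bin signed distances into a symmetric profile around the TSS."""
    if (2 * half_width) % bin_width:
        raise ValueError("bin_width must divide the window evenly")
    edges = np.arange(-half_width, half_width + 1, bin_width)
    d = np.asarray(distances, dtype=float)
    counts, _ = np.histogram(d, bins=edges)
    return DistanceProfile(label, edges, counts, n_genes, int(counts.sum()))


# ---------------------------------------------------------------------------
# negative sets and the resampling test
# ---------------------------------------------------------------------------

def sample_negative_genes(mode, pool, n=1000, exclude=(), seed=0):
    """Uniform without-replacement draw of negative genes.

    ``mode`` labels the construction (random genome draw vs expressed but
    unchanged genes); the caller supplies the matching pool. Excluded ids
    are never drawn; the draw is deterministic for a fixed seed.
    """
    if mode not in NEGATIVE_MODES:
        raise ValueError(f"mode must be one of {NEGATIVE_MODES}")
    exclude = set(exclude)
    candidates = sorted(set(pool) - exclude)
    if len(candidates) < n:
        raise ValueError(
            f"negative pool has {len(candidates)} genes after exclusions; "
            f"need {n}")
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(candidates, size=n, replace=False))


@dataclass
class PositionalEnrichmentResult:
    statistic: float        # mean peaks per target gene within the window
    null_mean: float
    null_sd: float
    pvalue: float
    n_resamples: int
    n_target: int
    negative_mode: str
    half_width: int
    seed: int

    @property
    def fold(self):
        return self.statistic / self.null_mean if self.null_mean > 0 else np.inf


def positional_enrichment_test(target_genes, negative_pool, peaks, tss,
                               B=999, seed=0, half_width=10_000,
                               negative_mode="genome_random",
                               exhaustive=False):
    """Resampling test of peak density near target-gene TSSs.

    statistic = mean number of peak centers within +/- half_width of the
    target genes' TSSs. The null distribution is built from ``B``
    matched-size draws from ``negative_pool`` (targets excluded);
    p = (1 + #{null >= observed}) / (B + 1). With ``exhaustive=True`` all
    C(pool, k) subsets are enumerated and p = mean(null >= observed).
    No peaks at all gives statistic 0 and p = 1.
    """
    target_genes = sorted(set(target_genes))
    if not target_genes:
        raise ValueError("empty target gene set")
    if not exhaustive and B < 99:
        raise ValueError("B must be >= 99")
    pool = sorted(set(negative_pool) - set(target_genes))
    k = len(target_genes)
    if len(pool) < k:
        raise ValueError("negative pool smaller than target set")
    needed = set(target_genes) | set(pool)
    sub_tss = tss[tss["gene_id"].isin(needed)]
    missing = needed - set(sub_tss["gene_id"])
    if missing:
        raise ValueError(f"genes without TSS records: {sorted(missing)[:5]}")
    counts = peak_counts_per_gene(sub_tss, peaks, half_width)
    observed = float(counts.loc[target_genes].mean())
    if len(peaks) == 0:
        return PositionalEnrichmentResult(0.0, 0.0, 0.0, 1.0, 0, k,
                                          negative_mode, half_width, seed)
    pool_counts = counts.loc[pool].to_numpy(dtype=float)
    if exhaustive:
        null = np.array([np.mean(c) for c in
                         itertools.combinations(pool_counts, k)])
        p = float(np.mean(null >= observed - 1e-12))
        B_eff = null.size
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((B, len(pool_counts))), axis=1)[:, :k]
        null = pool_counts[idx].mean(axis=1)
        p = float((1 + np.sum(null >= observed - 1e-12)) / (B + 1))
        B_eff = B
    return PositionalEnrichmentResult(
        observed, float(null.mean()), float(null.std(ddof=1)) if null.size > 1
        else 0.0, p, B_eff, k, negative_mode, half_width, seed)
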