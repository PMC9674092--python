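"""Synthetic input generation with planted, parameterized signal.

Every input the pipeline consumes — differential-expression tables, gene
catalogs, promoter sequences, ChIP peak sets, TSS annotations, and 3D cilium
traces — can be generated here with known ground truth, so that each
downstream stage has a parameter-recovery test: planted up-regulation of a
catalog, motifs inserted at controlled TSS-relative offsets, excess peaks
near target-gene TSSs, and two cilium populations differing in length and
tortuosity.

All randomness flows from one explicit seed; generators are byte-reproducible
for a fixed seed, and the seed is recorded in the header of every file
written.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenomeModel",
    "PlantedSignalConfig",
    "CiliumGroupParams",
    "make_genome",
    "make_de_table",
    "make_promoters",
    "make_peaks",
    "make_cilia",
    "write_de_table",
    "write_catalog",
    "write_fasta",
    "write_bed",
    "write_tss_tsv",
    "write_gff3",
    "write_cilia_csv",
]

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TSS_MARGIN = 10_000  # bp kept clear at chromosome ends so +/-10 kb windows fit


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes plus one oriented TSS per gene.

    ``genes`` has columns ``gene_id``, ``chrom``, ``tss`` (0-based bp) and
    ``strand`` (``+``/``-``). One TSS per synthetic gene by construction.
    """

    chromosomes: dict
    genes: pd.DataFrame

    def __post_init__(self):
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in genome model")
        if not g["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        for chrom, sub in g.groupby("chrom"):
            length = self.chromosomes[chrom]
            if (sub["tss"] < 0).any() or (sub["tss"] >= length).any():
                raise ValueError(f"TSS outside chromosome bounds on {chrom}")


@dataclass
class CiliumGroupParams:
    """Arc-length distribution (um) and curvature level for one genotype."""

    length_mean: float
    length_sd: float
    curvature: float  # 0 = perfectly straight; ~0.5 = visibly contorted

    def __post_init__(self):
        if self.length_mean <= 0 or self.length_sd < 0:
            raise ValueError("cilium lengths must be positive")
        if self.curvature < 0:
            raise ValueError("curvature must be >= 0")


@dataclass
class PlantedSignalConfig:
    """Parameters of the planted signal in each generated input.

    Defaults describe the study conditions the pipeline is benchmarked
    under: a strongly induced gene program covering 60% of a curated
    catalog, motifs concentrated near the TSS (sd 50 bp), a clear excess
    of ChIP peaks within a few kb of target TSSs, and a mutant cilium
    population that is longer and more contorted than control.
    """

    seed: int = 0
    # differential expression
    planted_fraction: float = 0.6      # fraction of catalog genes forced up
    effect_mean: float = 2.0           # log2FC of planted genes
    effect_sd: float = 0.5
    null_lfc_sd: float = 0.1           # log2FC scatter of unaffected genes
    # planted p ~ Beta(alpha, 1), alpha < 1; the default is extreme enough
    # that a forced gene survives BH at q < 0.1 with probability > 0.98
    planted_p_alpha: float = 0.002
    # promoter motif planting
    motif_offset_mean: float = 0.0     # bp relative to TSS
    motif_offset_sd: float = 50.0
    motif_planting_fraction: float = 1.0
    background_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    # ChIP peaks
    peak_background_density: float = 2e-5   # background peaks per bp
    peak_excess_rate: float = 2.0           # mean extra peaks per target gene
    peak_offset_sd: float = 1000.0          # bp around the target TSS
    peak_width: int = 200
    # cilium groups
    cilium_groups: dict = field(default_factory=lambda: {
        "control": CiliumGroupParams(3.8, 1.0, 0.08),
        "mutant": CiliumGroupParams(5.6, 1.4, 0.25),
    })

    def __post_init__(self):
        for name in ("planted_fraction", "motif_planting_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("peak_background_density", "peak_excess_rate",
                     "peak_offset_sd", "null_lfc_sd", "effect_sd",
                     "motif_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.planted_p_alpha < 1:
            raise ValueError("planted_p_alpha must be in (0, 1)")
        if abs(sum(self.background_freqs) - 1.0) > 1e-9:
            raise ValueError("background_freqs must sum to 1")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def make_genome(n_genes, n_chroms=1, chrom_len=1_000_000, seed=0,
                min_spacing=2_000):
    """Place ``n_genes`` oriented TSSs on ``n_chroms`` chromosomes.

    TSSs keep a 10 kb margin from chromosome ends (so +/-10 kb peak windows
    never clip) and at least ``min_spacing`` bp from each other; strands are
    drawn ~50/50. Deterministic for a fixed seed. Raises ``ValueError`` if
    the genes cannot be packed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    chrom_len = int(chrom_len)
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": chrom_len for i in range(n_chroms)}
    usable = chrom_len - 2 * TSS_MARGIN
    if usable <= 0:
        raise ValueError(
            f"chromosome length {chrom_len} leaves no room inside the "
            f"+/-{TSS_MARGIN} bp end margins")
    slots_per_chrom = usable // min_spacing + 1
    per_chrom = [n_genes // n_chroms + (i < n_genes % n_chroms)
                 for i in range(n_chroms)]
    if max(per_chrom) > slots_per_chrom:
        raise ValueError(
            f"cannot pack {max(per_chrom)} TSSs with spacing {min_spacing} "
            f"into a {chrom_len} bp chromosome")
    rows = []
    gene_idx = 0
    for chrom, k in zip(chroms, per_chrom):
        slots = np.sort(rng.choice(slots_per_chrom, size=k, replace=False))
        jitter = rng.integers(0, max(min_spacing // 2, 1), size=k)
        tss = TSS_MARGIN + slots * min_spacing + jitter
        tss = np.minimum(tss, chrom_len - TSS_MARGIN - 1)
        strand = rng.choice(["+", "-"], size=k)
        for t, s in zip(tss, strand):
            rows.append((f"gene{gene_idx:05d}", chrom, int(t), s))
            gene_idx += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return GenomeModel(chromosomes=chroms, genes=genes)


# ---------------------------------------------------------------------------
# differential-expression table
# ---------------------------------------------------------------------------

def make_de_table(genome, catalog_genes, config):
    """Differential table with a planted up-regulated subset of a catalog.

    Planted genes draw log2FC ~ Normal(effect_mean, effect_sd) and
    p ~ Beta(alpha, 1) with alpha < 1 (stochastically small); every other
    gene draws a null effect (log2FC ~ Normal(0, null_lfc_sd), p ~ U(0,1)).
    q-values are Benjamini-Hochberg-adjusted over the whole table.

    Returns ``(table, planted_ids)``.
    """
    catalog_genes = list(catalog_genes)
    all_ids = genome.genes["gene_id"].tolist()
    missing = set(catalog_genes) - set(all_ids)
    if missing:
        raise ValueError(f"catalog genes absent from genome: {sorted(missing)[:5]}")
    if config.planted_fraction > 0 and len(catalog_genes) == 0:
        raise ValueError("empty catalog with nonzero planting fraction")
    rng = np.random.default_rng(config.seed)
    n = len(all_ids)
    n_plant = int(round(config.planted_fraction * len(catalog_genes)))
    planted = sorted(rng.choice(sorted(catalog_genes), size=n_plant,
                                replace=False)) if n_plant else []
    planted_mask = pd.Index(all_ids).isin(planted)

    lfc = rng.normal(0.0, config.null_lfc_sd, size=n)
    pval = rng.uniform(0.0, 1.0, size=n)
    k = planted_mask.sum()
    lfc[planted_mask] = rng.normal(config.effect_mean, config.effect_sd, size=k)
    pval[planted_mask] = rng.beta(config.planted_p_alpha, 1.0, size=k)
    qval = multipletests(pval, method="fdr_bh")[1]
    mean_expr = np.exp(rng.normal(3.0, 1.0, size=n))

    table = pd.DataFrame({
        "feature_id": all_ids,
        "log2fc": lfc,
        "pvalue": pval,
        "qvalue": qval,
        "mean_expression": mean_expr,
        "modality": "rna",
    })
    return table, list(planted)


# ---------------------------------------------------------------------------
# promoters with planted motif occurrences
# ---------------------------------------------------------------------------

def _random_dna(rng, length, freqs):
    return "".join(_BASES[rng.choice(4, size=length, p=np.asarray(freqs))])


def reverse_complement(seq):
    return seq.translate(_COMPLEMENT)[::-1]


def make_promoters(genome, consensus, config, half_width=500,
                   plant_genes=None):
    """TSS-centered promoter sequences with a motif planted at known offsets.

    Background bases are i.i.d. from ``config.background_freqs``; for each
    gene in ``plant_genes`` (default: every gene; pass an empty collection
    to plant nothing) the consensus (or its reverse complement, on a random
    strand) is inserted with probability ``motif_planting_fraction`` so
    that its center sits at an offset drawn from
    Normal(motif_offset_mean, motif_offset_sd), clipped to fit the window.
    Position 0 of the window is the TSS.

    Returns ``(sequences, offsets)``: dicts gene_id -> sequence and
    gene_id -> planted center offset (absent if the gene was not planted).
    """
    consensus = consensus.upper()
    width = len(consensus)
    window = 2 * half_width
    if width > window:
        raise ValueError("motif longer than promoter window")
    plantable = (set(genome.genes["gene_id"]) if plant_genes is None
                 else set(plant_genes))
    rng = np.random.default_rng(config.seed)
    center_shift = width // 2
    lo, hi = center_shift - half_width, window - width + center_shift - half_width
    seqs, offsets = {}, {}
    for gene_id in genome.genes["gene_id"]:
        seq = _random_dna(rng, window, config.background_freqs)
        if gene_id in plantable and rng.random() < config.motif_planting_fraction:
            off = int(round(rng.normal(config.motif_offset_mean,
                                       config.motif_offset_sd)))
            off = int(np.clip(off, lo, hi))
            start = off - center_shift + half_width
            motif = consensus if rng.random() < 0.5 else reverse_complement(consensus)
            seq = seq[:start] + motif + seq[start + width:]
            offsets[gene_id] = off
        seqs[gene_id] = seq
    return seqs, offsets


# ---------------------------------------------------------------------------
# ChIP peak sets
# ---------------------------------------------------------------------------

def make_peaks(genome, target_genes, config, tf_label="RFX"):
    """BED-style peak set: uniform background plus excess near target TSSs.

    Background peak centers fall uniformly at ``peak_background_density``
    per bp on every chromosome; each target gene receives
    Poisson(``peak_excess_rate``) extra peaks whose centers are displaced
    from its TSS by Normal(0, ``peak_offset_sd``) bp. Intervals are 0-based
    half-open, ``peak_width`` bp wide, sorted by (chrom, start).
    """
    if config.peak_background_density < 0:
        raise ValueError("negative peak density")
    target_genes = set(target_genes)
    missing = target_genes - set(genome.genes["gene_id"])
    if missing:
        raise ValueError(f"target genes absent from genome: {sorted(missing)[:5]}")
    rng = np.random.default_rng(config.seed)
    half = config.peak_width // 2
    rows = []
    for chrom, length in genome.chromosomes.items():
        n_bg = rng.poisson(config.peak_background_density * length)
        for c in np.sort(rng.integers(half, length - half, size=n_bg)):
            rows.append((chrom, int(c) - half, int(c) - half + config.peak_width))
    tgt = genome.genes[genome.genes["gene_id"].isin(target_genes)]
    for _, g in tgt.iterrows():
        n_ex = rng.poisson(config.peak_excess_rate)
        offs = rng.normal(0.0, config.peak_offset_sd, size=n_ex)
        for o in offs:
            c = int(round(g["tss"] + o))
            c = int(np.clip(c, half, genome.chromosomes[g["chrom"]] - half))
            rows.append((g["chrom"], c - half, c - half + config.peak_width))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    peaks["name"] = tf_label
    peaks = peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return peaks


# ---------------------------------------------------------------------------
# cilium traces
# ---------------------------------------------------------------------------

def make_cilia(n_per_group, group_params, seed=0, n_points=25, n_mice=5):
    """3D polyline traces for two (or more) cilium populations.

    Each trace has the arc length drawn from its group's Normal (truncated
    at 0.5 um) and is built as a fixed-step directed walk whose direction
    receives an isotropic Gaussian kick of magnitude ``curvature`` per step:
    curvature 0 gives an exactly straight segment (tortuosity 1), larger
    values give bent-to-contorted shapes. Cilia are assigned round-robin to
    ``n_mice`` mice per genotype.

    Returns a long-format DataFrame: cilium_id, mouse_id, genotype,
    point_index, x, y, z (um).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, n in n_per_group.items():
        if n < 1:
            raise ValueError("need at least one cilium per group")
        params = group_params[genotype]
        for i in range(n):
            arc = rng.normal(params.length_mean, params.length_sd)
            arc = max(arc, 0.5)
            step = arc / (n_points - 1)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pts = np.zeros((n_points, 3))
            for k in range(1, n_points):
                if params.curvature > 0:
                    d = d + params.curvature * rng.normal(size=3)
                    d /= np.linalg.norm(d)
                pts[k] = pts[k - 1] + step * d
            pts += rng.uniform(0, 50, size=3)  # random placement in the field
            cid = f"{genotype}_c{i:04d}"
            mouse = f"{genotype}_m{i % n_mice + 1}"
            for k, (x, y, z) in enumerate(pts):
                rows.append((cid, mouse, genotype, k, x, y, z))
    return pd.DataFrame(
        rows, columns=["cilium_id", "mouse_id", "genotype", "point_index",
                       "x", "y", "z"])


# ---------------------------------------------------------------------------
# writers (plain-text formats, provenance header with the seed)
# ---------------------------------------------------------------------------

def _header(seed):
    return f"# generator=astrocilia.synthetic seed={seed}\n"


def write_de_table(table, path, seed):
    with open(path, "w") as fh:
        fh.write(_header(seed))
        table.to_csv(fh, sep="\t", index=False)


def write_catalog(catalog, path, seed, name="catalog"):
    """``catalog``: dict gene_id -> category."""
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write(f"# catalog={name}\n")
        fh.write("gene_id\tcategory\n")
        for gene, cat in catalog.items():
            fh.write(f"{gene}\t{cat}\n")


def write_fasta(seqs, path, seed):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name} seed={seed}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_bed(peaks, path, seed):
    with open(path, "w") as fh:
        fh.write(_header(seed))
        peaks.to_csv(fh, sep="\t", index=False, header=False)


def write_tss_tsv(genome, path, seed):
    with open(path, "w") as fh:
        fh.write(_header(seed))
        genome.genes.rename(columns={"tss": "pos"}).to_csv(
            fh, sep="\t", index=False)


def write_gff3(genome, path, seed):
    """Minimal GFF3: one gene + one transcript per synthetic gene.

    GFF3 is 1-based inclusive; a gene at 0-based TSS t on + covers
    [t+1, t+1000]; on - the transcript end is the TSS.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_header(seed))
        for _, g in genome.genes.iterrows():
            t = int(g["tss"])
            length = min(1000, genome.chromosomes[g["chrom"]] - t - 1)
            if g["strand"] == "+":
                start, end = t + 1, t + length
            else:
                start, end = max(1, t + 1 - length), t + 1
            gid = g["gene_id"]
            fh.write(f"{g['chrom']}\t.\tgene\t{start}\t{end}\t.\t"
                     f"{g['strand']}\t.\tID={gid}\n")
            fh.write(f"{g['chrom']}\t.\tmRNA\t{start}\t{end}\t.\t"
                     f"{g['strand']}\t.\tID={gid}.t1;Parent={gid}\n")


def write_cilia_csv(traces, path, seed):
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("# unit=um\n")
        traces.to_csv(fh, index=False)


def config_provenance(config):
    """Flat dict of a PlantedSignalConfig for run reports."""
    d = dataclasses.asdict(config)
    d["cilium_groups"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
                          for k, v in config.cilium_groups.items()}
    return d
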