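"""End-to-end orchestration: simulate -> DE programs -> motif / peaks ->
cilia -> report, with config, input validation and provenance.

A run is described by a :class:`RunConfig` (YAML file and/or CLI flags);
stages execute in dependency order, every stochastic stage derives its seed
from the run seed, and the machine-readable :class:`RunReport` (JSON)
records parameter echo, input checksums, package version and the files each
stage wrote. Identical config + seed gives byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import de_programs, morphometry, motifs, peaks, synthetic

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run", "validate_inputs"]

ALL_STAGES = ("simulate", "de_programs", "motif", "peaks", "cilia")


@dataclass
class RunConfig:
    """Every knob of a pipeline run, serializable to/from YAML."""

    seed: int = 0
    outdir: str = "astrocilia_run"
    stages: tuple = ALL_STAGES
    # generator
    n_genes: int = 2000
    n_chroms: int = 2
    chrom_len: int = 10_000_000
    catalog_size: int = 92
    planted_fraction: float = 0.6
    # thresholds (broad program rule + the stricter motif/ChIP list rules)
    lfc_min: float = 0.3
    q_max: float = 0.1
    motif_p_adj_max: float = 0.05
    chip_p_adj_max: float = 0.01
    top_n_motif: int | None = 1000
    # motif stage
    motif_consensus: str = "GTTGCCATGGCAAC"  # RFX-like palindromic consensus
    promoter_half_width: int = 500
    n_negative_motif: int = 1000
    central_w_grid: tuple = (250,)
    # peaks stage
    peak_half_width: int = 10_000
    bin_width: int = 500
    n_negative_peaks: int = 1000
    negative_mode: str = "genome_random"
    resamples: int = 999
    # cilia stage
    n_cilia_per_group: int = 150
    # external inputs (optional; synthetic stage fills them in when run)
    de_table: str | None = None
    catalog: str | None = None
    promoter_fasta: str | None = None
    peak_bed: str | None = None
    tss_tsv: str | None = None
    cilia_csv: str | None = None

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("stages", "central_w_grid"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path):
        data = dataclasses.asdict(self)
        for name in ("stages", "central_w_grid"):
            data[name] = list(data[name])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunReport:
    seed: int
    version: str
    config: dict
    stages: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed, stage):
    """Stable per-stage seed below 2**31 derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(config):
    """Schema and cross-file consistency checks; returns a failure list.

    Each failure is a dict with ``file``, ``problem`` and, where known,
    ``line``. An empty list means the declared inputs are consistent.
    """
    failures = []
    declared = {
        "de_table": config.de_table, "catalog": config.catalog,
        "promoter_fasta": config.promoter_fasta, "peak_bed": config.peak_bed,
        "tss_tsv": config.tss_tsv, "cilia_csv": config.cilia_csv}
    for name, path in declared.items():
        if path is not None and not Path(path).exists():
            failures.append({"file": str(path), "problem": f"{name} missing"})
    if config.peak_bed and Path(config.peak_bed).exists():
        with open(config.peak_bed) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split("\t")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except (IndexError, ValueError):
                    failures.append({"file": config.peak_bed, "line": lineno,
                                     "problem": "malformed BED line"})
                    continue
                if start >= end:
                    failures.append({"file": config.peak_bed, "line": lineno,
                                     "problem": f"start {start} >= end {end}"})
    # chromosome-name consistency across annotation / peaks / FASTA
    chrom_sets = {}
    if config.tss_tsv and Path(config.tss_tsv).exists():
        try:
            chrom_sets["tss"] = set(peaks.read_tss_tsv(config.tss_tsv)["chrom"])
        except Exception as exc:
            failures.append({"file": config.tss_tsv, "problem": str(exc)})
    if config.peak_bed and Path(config.peak_bed).exists():
        try:
            chrom_sets["peaks"] = set(peaks.read_bed(config.peak_bed)["chrom"])
        except Exception as exc:
            failures.append({"file": config.peak_bed, "problem": str(exc)})
    if len(chrom_sets) > 1:
        names = sorted(chrom_sets)
        ref = chrom_sets[names[0]]
        for other in names[1:]:
            if not (ref & chrom_sets[other]):
                failures.append({
                    "file": f"{names[0]}/{other}",
                    "problem": "no shared chromosome names "
                               f"({sorted(ref)[:3]} vs "
                               f"{sorted(chrom_sets[other])[:3]})"})
    return failures


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _simulate(config, outdir, report, state):
    seed = _stage_seed(config.seed, "simulate")
    genome = synthetic.make_genome(config.n_genes, config.n_chroms,
                                   config.chrom_len, seed=seed)
    gene_ids = genome.genes["gene_id"].tolist()
    rng = np.random.default_rng(_stage_seed(config.seed, "catalog"))
    catalog_genes = sorted(rng.choice(gene_ids, size=config.catalog_size,
                                      replace=False))
    categories = rng.choice(["motile-specific", "primary-specific",
                             "pan-ciliary"], size=config.catalog_size,
                            p=[0.5, 0.25, 0.25])
    catalog = dict(zip(catalog_genes, categories))
    sig = synthetic.PlantedSignalConfig(
        seed=seed, planted_fraction=config.planted_fraction)
    table, planted = synthetic.make_de_table(genome, catalog_genes, sig)
    seqs, offsets = synthetic.make_promoters(
        genome, config.motif_consensus, sig,
        half_width=config.promoter_half_width, plant_genes=planted)
    peak_df = synthetic.make_peaks(genome, planted, sig)
    traces = synthetic.make_cilia(
        {"control": config.n_cilia_per_group,
         "mutant": config.n_cilia_per_group},
        sig.cilium_groups, seed=seed)

    paths = {
        "de_table": outdir / "de_table.tsv",
        "catalog": outdir / "catalog.tsv",
        "promoter_fasta": outdir / "promoters.fasta",
        "peak_bed": outdir / "peaks.bed",
        "tss_tsv": outdir / "tss.tsv",
        "tss_gff3": outdir / "genes.gff3",
        "cilia_csv": outdir / "cilia.csv",
    }
    synthetic.write_de_table(table, paths["de_table"], seed)
    synthetic.write_catalog(catalog, paths["catalog"], seed)
    synthetic.write_fasta(seqs, paths["promoter_fasta"], seed)
    synthetic.write_bed(peak_df, paths["peak_bed"], seed)
    synthetic.write_tss_tsv(genome, paths["tss_tsv"], seed)
    synthetic.write_gff3(genome, paths["tss_gff3"], seed)
    synthetic.write_cilia_csv(traces, paths["cilia_csv"], seed)
    for name in ("de_table", "catalog", "promoter_fasta", "peak_bed",
                 "tss_tsv", "cilia_csv"):
        setattr(config, name, str(paths[name]))
    report.stages["simulate"] = {
        "seed": seed,
        "outputs": {k: str(v) for k, v in paths.items()},
        "n_planted": len(planted),
        "planted_genes_file": str(outdir / "planted_genes.txt"),
    }
    (outdir / "planted_genes.txt").write_text("\n".join(planted) + "\n")
    return {"genome": genome, "catalog": catalog, "planted": planted,
            "table": table, "promoters": seqs, "offsets": offsets,
            "peaks": peak_df, "traces": traces}


def _run_de(config, outdir, report, state):
    table = state.get("table")
    if table is None:
        table = de_programs.read_differential_table(config.de_table)
    catalog = state.get("catalog")
    if catalog is None:
        catalog = de_programs.read_catalog(config.catalog)
    policy = de_programs.ThresholdPolicy(lfc_min=config.lfc_min,
                                         q_max=config.q_max)
    lists = de_programs.build_gene_lists(table, policy)
    overall, per_cat = de_programs.score_catalog(lists, table, catalog)
    matrix = de_programs.cross_dataset_matrix({"run": table}, catalog, policy)
    lists_path = outdir / "gene_lists.json"
    with open(lists_path, "w") as fh:
        json.dump(lists, fh, indent=2)
    scores = pd.DataFrame(
        [dataclasses.asdict(overall) | {"n_changed": overall.n_changed}] +
        [dataclasses.asdict(s) | {"n_changed": s.n_changed}
         for s in per_cat.values()])
    scores_path = outdir / "catalog_scores.tsv"
    scores.to_csv(scores_path, sep="\t", index=False)
    matrix_path = outdir / "activation_matrix.tsv"
    matrix.to_csv(matrix_path, sep="\t")
    report.stages["de_programs"] = {
        "n_up": len(lists["up"]), "n_down": len(lists["down"]),
        "catalog_n_up": overall.n_up, "catalog_n_down": overall.n_down,
        "catalog_p_up": overall.p_up,
        "frac_changed": float(matrix.loc["run", "frac_changed"]),
        "outputs": [str(lists_path), str(scores_path), str(matrix_path)],
    }
    state.update({"table": table, "catalog": catalog, "lists": lists})
    return state


def _run_motif(config, outdir, report, state):
    table = state["table"]
    policy = de_programs.ThresholdPolicy(
        lfc_min=config.lfc_min, q_max=None,
        p_adj_max=config.motif_p_adj_max, top_n=config.top_n_motif)
    target = de_programs.build_gene_lists(table, policy)["up"]
    seqs = state.get("promoters")
    if seqs is None:
        seqs = _read_fasta(config.promoter_fasta)
    all_genes = sorted(seqs)
    seed = _stage_seed(config.seed, "motif")
    negative = peaks.sample_negative_genes(
        "genome_random", all_genes,
        n=min(config.n_negative_motif, len(all_genes) - len(target)),
        exclude=target, seed=seed)
    pwm = motifs.PWM.from_counts(
        "consensus", _consensus_counts(config.motif_consensus))
    windows = motifs.windows_from_sequences(
        seqs, half_width=config.promoter_half_width)
    by_gene = {w.gene_id: w for w in windows}
    t_hits = motifs.best_hits(motifs.scan_windows(
        [by_gene[g] for g in target if g in by_gene], pwm))
    n_hits = motifs.best_hits(motifs.scan_windows(
        [by_gene[g] for g in negative], pwm))
    result = motifs.central_enrichment(t_hits, n_hits,
                                       w_grid=config.central_w_grid,
                                       motif_id=pwm.motif_id)
    curve = motifs.motif_probability_curve(
        t_hits, half_width=config.promoter_half_width)
    curve_path = outdir / "motif_probability_curve.tsv"
    curve.to_csv(curve_path, sep="\t", index=False)
    result_path = outdir / "central_enrichment.json"
    with open(result_path, "w") as fh:
        json.dump(dataclasses.asdict(result), fh, indent=2,
                  default=_json_default)
    report.stages["motif"] = {
        "seed": seed, "n_target": result.n_target,
        "pvalue": result.pvalue, "fold": result.fold_concentration,
        "central_half_width": result.central_half_width,
        "outputs": [str(curve_path), str(result_path)],
    }
    state["motif_result"] = result
    return state


def _run_peaks(config, outdir, report, state):
    table = state["table"]
    policy = de_programs.ThresholdPolicy(
        lfc_min=config.lfc_min, q_max=None,
        p_adj_max=config.chip_p_adj_max)
    lists = de_programs.build_gene_lists(table, policy)
    target = lists["up"]
    peak_df = state.get("peaks")
    if peak_df is None:
        peak_df = peaks.read_bed(config.peak_bed)
    genome = state.get("genome")
    if genome is not None:
        tss = genome.genes.rename(columns={"tss": "pos"})
    else:
        tss = peaks.read_tss_tsv(config.tss_tsv)
    seed = _stage_seed(config.seed, "peaks")
    if config.negative_mode == "expressed_unchanged":
        changed = set(lists["up"]) | set(lists["down"])
        pool_source = [g for g in table["feature_id"] if g not in changed]
    else:
        pool_source = tss["gene_id"].tolist()
    pool = peaks.sample_negative_genes(
        config.negative_mode, pool_source,
        n=min(config.n_negative_peaks, len(set(pool_source) - set(target))),
        exclude=target, seed=seed)
    result = peaks.positional_enrichment_test(
        target, pool, peak_df, tss, B=config.resamples, seed=seed,
        half_width=config.peak_half_width,
        negative_mode=config.negative_mode)
    t_d = peaks.signed_distances(tss[tss["gene_id"].isin(target)], peak_df,
                                 config.peak_half_width)
    n_d = peaks.signed_distances(tss[tss["gene_id"].isin(pool)], peak_df,
                                 config.peak_half_width)
    prof_t = peaks.distance_profile(t_d["distance"], len(target),
                                    config.peak_half_width,
                                    config.bin_width, "target")
    prof_n = peaks.distance_profile(n_d["distance"], len(pool),
                                    config.peak_half_width,
                                    config.bin_width, config.negative_mode)
    prof_path = outdir / "distance_profiles.tsv"
    combined = pd.concat([prof_t.to_frame().assign(gene_set="target"),
                          prof_n.to_frame().assign(gene_set="negative")])
    combined.to_csv(prof_path, sep="\t", index=False)
    result_path = outdir / "positional_enrichment.json"
    with open(result_path, "w") as fh:
        json.dump(dataclasses.asdict(result), fh, indent=2,
                  default=_json_default)
    report.stages["peaks"] = {
        "seed": seed, "statistic": result.statistic,
        "null_mean": result.null_mean, "pvalue": result.pvalue,
        "fold": result.fold, "n_target": result.n_target,
        "outputs": [str(prof_path), str(result_path)],
    }
    state["peak_result"] = result
    return state


def _run_cilia(config, outdir, report, state):
    traces = state.get("traces")
    if traces is None:
        traces = morphometry.read_cilia_csv(config.cilia_csv)
    measures = morphometry.measure_table(traces)
    comparison = morphometry.compare_groups(measures)
    measures_path = outdir / "cilium_measures.csv"
    measures.to_csv(measures_path, index=False)
    comp_path = outdir / "group_comparison.json"
    with open(comp_path, "w") as fh:
        json.dump({
            "groups": list(comparison.groups),
            "ks_statistic": comparison.ks_statistic,
            "ks_pvalue": comparison.ks_pvalue,
            "anova_f": comparison.anova_f,
            "anova_pvalue": comparison.anova_pvalue,
            "anova_f_mouse": comparison.anova_f_mouse,
            "anova_pvalue_mouse": comparison.anova_pvalue_mouse,
            "class_proportions": comparison.class_proportions.to_dict(),
        }, fh, indent=2, default=_json_default)
    report.stages["cilia"] = {
        "ks_statistic": comparison.ks_statistic,
        "ks_pvalue": comparison.ks_pvalue,
        "anova_pvalue": comparison.anova_pvalue,
        "outputs": [str(measures_path), str(comp_path)],
    }
    state["cilia_comparison"] = comparison
    return state


def _read_fasta(path):
    seqs, name, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def _consensus_counts(consensus, weight=100):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.ones((len(consensus), 4))
    for i, base in enumerate(consensus.upper()):
        counts[i, idx[base]] = weight
    return counts


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run(config):
    """Execute the configured stages in dependency order; returns the report.

    Stage failure aborts with the stage name and cause. Re-running with the
    same config and seed reproduces every numeric output byte for byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__,
                       config=dataclasses.asdict(config))
    stages = tuple(config.stages)
    if any(s not in ALL_STAGES for s in stages):
        raise ValueError(f"unknown stages: "
                         f"{[s for s in stages if s not in ALL_STAGES]}")
    if "simulate" not in stages:
        failures = validate_inputs(config)
        if failures:
            raise ValueError(f"input validation failed: {failures}")
    state = {}
    runners = {"simulate": _simulate, "de_programs": _run_de,
               "motif": _run_motif, "peaks": _run_peaks, "cilia": _run_cilia}
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        try:
            result = runners[stage](config, outdir, report, state)
            if stage == "simulate":
                state = result
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    for name in ("de_table", "catalog", "promoter_fasta", "peak_bed",
                 "tss_tsv", "cilia_csv"):
        path = getattr(config, name)
        if path and Path(path).exists():
            report.input_checksums[name] = _sha256(path)
    report.config = dataclasses.asdict(config)
    report.to_json(outdir / "run_report.json")
    return report
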