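"""Gene-list construction and curated-catalog program scoring.

Builds up-/down-regulated gene lists from a differential-expression table
with strict threshold rules (log2FC and FDR-adjusted significance, optional
top-N truncation sorted by fold change), and scores curated gene catalogs —
ciliary (motile-specific / primary-specific / pan-ciliary), astrogliosis
markers, lipid classes, proteomic panels — for program activation:
detected / up / down / changed counts and a hypergeometric over-representation
p-value, plus a cross-dataset activation matrix and row Z-scoring for
heatmap-style summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "ThresholdPolicy",
    "CatalogScore",
    "read_differential_table",
    "read_catalog",
    "build_gene_lists",
    "score_catalog",
    "count_changed_features",
    "cross_dataset_matrix",
    "zscore_rows",
    "bh_adjust",
]

REQUIRED_COLUMNS = ("feature_id", "log2fc", "pvalue", "qvalue")


@dataclass(frozen=True)
class ThresholdPolicy:
    """Selection rule for up/down gene lists.

    Exactly one of ``q_max`` / ``p_adj_max`` is active; both apply to the
    table's adjusted-significance column. ``top_n`` truncates after sorting
    by |log2fc| (descending for up, ascending for down), ties broken by
    ascending q then gene id so outputs are deterministic.

    Defaults are the broad program rule (log2FC > 0.3, q < 0.1); the motif
    and ChIP analyses use stricter adjusted-p cutoffs (0.05 and 0.01).
    """

    lfc_min: float = 0.3
    q_max: float | None = 0.1
    p_adj_max: float | None = None
    top_n: int | None = None
    sort_key: str = "log2fc"

    def __post_init__(self):
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if (self.q_max is None) == (self.p_adj_max is None):
            raise ValueError("exactly one of q_max / p_adj_max must be set")

    @property
    def sig_max(self):
        return self.q_max if self.q_max is not None else self.p_adj_max


@dataclass
class CatalogScore:
    """Program-activation counts for one catalog (or one category of it)."""

    name: str
    n_total: int        # catalog genes
    n_detected: int     # catalog genes present in the table
    n_up: int
    n_down: int
    p_up: float         # hypergeometric upper tail for up-genes

    @property
    def n_changed(self):
        return self.n_up + self.n_down


def bh_adjust(pvalues):
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def read_differential_table(path, modality="rna"):
    """Read and validate a TSV differential table.

    Requires columns feature_id, log2fc, pvalue, qvalue; mean_expression is
    optional. Rejects duplicate ids, non-numeric fields and p/q outside
    [0, 1].
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col in ("log2fc", "pvalue", "qvalue"):
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            bad = table.loc[vals.isna(), "feature_id"].tolist()[:5]
            raise ValueError(f"non-numeric {col} for features {bad}")
        table[col] = vals
    if table["feature_id"].duplicated().any():
        dups = table.loc[table["feature_id"].duplicated(), "feature_id"]
        raise ValueError(f"duplicate feature ids: {dups.tolist()[:5]}")
    for col in ("pvalue", "qvalue"):
        if ((table[col] < 0) | (table[col] > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    table = table.copy()
    table["modality"] = modality
    return table


def read_catalog(path):
    """Read a gene catalog TSV (gene_id, category) into a dict."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in catalog")
    return dict(zip(df["gene_id"], df["category"]))


def build_gene_lists(table, policy=ThresholdPolicy()):
    """Up/down gene lists under strict threshold rules.

    up: log2fc > lfc_min and adjusted significance < the active cutoff,
    sorted by log2fc descending; down is the mirror image (log2fc <
    -lfc_min, sorted ascending). ``top_n`` truncates after sorting.
    """
    sig = table["qvalue"] < policy.sig_max
    out = {}
    for direction, keep, ascending in (
            ("up", table["log2fc"] > policy.lfc_min, False),
            ("down", table["log2fc"] < -policy.lfc_min, True)):
        sel = table[keep & sig]
        sel = sel.sort_values(
            [policy.sort_key, "qvalue", "feature_id"],
            ascending=[ascending, True, True])
        ids = sel["feature_id"].tolist()
        if policy.top_n is not None:
            ids = ids[:policy.top_n]
        out[direction] = ids
    return out


def _casefold_index(ids):
    return {str(g).casefold(): g for g in ids}


def score_catalog(lists, table, catalog, name="catalog"):
    """Score a catalog against up/down lists from one table.

    Counts are computed on the catalog-table intersection (case-insensitive
    exact id match); the hypergeometric universe is the set of features
    detected in the table. Returns ``(overall, per_category)`` where
    ``per_category`` maps category -> CatalogScore.
    """
    if not catalog:
        raise ValueError("empty catalog")
    detected = _casefold_index(table["feature_id"])
    up = {str(g).casefold() for g in lists["up"]}
    down = {str(g).casefold() for g in lists["down"]}

    def _score(genes, label):
        keys = {str(g).casefold() for g in genes}
        in_table = keys & set(detected)
        n_up = len(in_table & up)
        n_down = len(in_table & down)
        if not in_table:
            warnings.warn(f"catalog '{label}' has no genes in the table")
            return CatalogScore(label, len(keys), 0, 0, 0, 1.0)
        # draw = table's up list, successes = catalog genes in the table
        N, K, n_draw = len(detected), len(in_table), len(up)
        p = float(hypergeom.sf(n_up - 1, N, K, n_draw)) if n_up else 1.0
        return CatalogScore(label, len(keys), len(in_table), n_up, n_down,
                            min(max(p, np.nextafter(0, 1)), 1.0))

    overall = _score(catalog.keys(), name)
    per_category = {}
    categories = sorted(set(catalog.values()))
    for cat in categories:
        genes = [g for g, c in catalog.items() if c == cat]
        per_category[cat] = _score(genes, cat)
    return overall, per_category


def count_changed_features(table, grouping, policy=ThresholdPolicy()):
    """Per-group changed/total counts under the significance rule.

    ``grouping`` maps feature id -> class label (e.g., HMDB lipid class);
    features absent from the grouping are counted under ``ungrouped`` with a
    warning. "Changed" means |log2fc| > lfc_min and adjusted significance
    below the cutoff; the direction split is recorded.
    """
    lookup = {str(k).casefold(): v for k, v in grouping.items()}
    labels = []
    n_missing = 0
    for fid in table["feature_id"]:
        key = str(fid).casefold()
        if key in lookup:
            labels.append(lookup[key])
        else:
            labels.append("ungrouped")
            n_missing += 1
    if n_missing:
        warnings.warn(f"{n_missing} features missing from grouping; "
                      "counted as 'ungrouped'")
    sig = table["qvalue"] < policy.sig_max
    up = sig & (table["log2fc"] > policy.lfc_min)
    down = sig & (table["log2fc"] < -policy.lfc_min)
    df = pd.DataFrame({"group": labels, "up": up.values, "down": down.values})
    agg = df.groupby("group").agg(
        n_total=("up", "size"), n_up=("up", "sum"), n_down=("down", "sum"))
    agg["n_changed"] = agg["n_up"] + agg["n_down"]
    total = pd.DataFrame(
        {"n_total": [len(df)], "n_up": [int(up.sum())],
         "n_down": [int(down.sum())],
         "n_changed": [int(up.sum() + down.sum())]}, index=["__all__"])
    return pd.concat([agg, total])


def cross_dataset_matrix(datasets, catalog, policy=ThresholdPolicy()):
    """Per-dataset activation fractions over a catalog.

    ``datasets`` maps name -> differential table (shared gene-id namespace).
    For each dataset the catalog genes are split into up / down / unchanged /
    not-detected; fractions are over the whole catalog, so each row sums
    to 1. This is the stacked-bar view of program activation across models.
    """
    keys = sorted({str(g).casefold() for g in catalog})
    n_cat = len(keys)
    if n_cat == 0:
        raise ValueError("empty catalog")
    rows = {}
    for name, table in datasets.items():
        if len(table) == 0:
            rows[name] = {"frac_up": 0.0, "frac_down": 0.0,
                          "frac_unchanged": 0.0, "frac_not_detected": 1.0}
            continue
        lists = build_gene_lists(table, policy)
        detected = {str(g).casefold() for g in table["feature_id"]}
        up = {str(g).casefold() for g in lists["up"]}
        down = {str(g).casefold() for g in lists["down"]}
        n_up = sum(k in up for k in keys)
        n_down = sum(k in down for k in keys)
        n_det = sum(k in detected for k in keys)
        rows[name] = {
            "frac_up": n_up / n_cat,
            "frac_down": n_down / n_cat,
            "frac_unchanged": (n_det - n_up - n_down) / n_cat,
            "frac_not_detected": (n_cat - n_det) / n_cat,
        }
    out = pd.DataFrame(rows).T
    out["frac_changed"] = out["frac_up"] + out["frac_down"]
    return out


def zscore_rows(matrix):
    """Row-wise Z-scores (sample sd): each row to mean 0, sd 1.

    Zero-variance rows map to all zeros with a warning; single-column
    input is an error (sd undefined).
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 columns")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance rows set to 0")
    sd[sd == 0] = 1.0
    z = (values - mean) / sd
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z
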