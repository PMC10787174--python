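"""Differential genes, peaks, TTFs and the differential sub-network.

Differential calls contrast the focal tissue against its reference (here
rumen vs esophagus) per developmental stage.  Standard stages use a Welch
t-test on log2(FPKM + 1) with Benjamini-Hochberg control per stage; genes
pass at q < 0.05 and log2 fold change (focal over reference) strictly > 1,
peaks at q < 0.05 and |log2 FC| > 1.  A stage with a single replicate per
group (the adult stage here) cannot support a test and instead uses the
plain rule: focal FPKM > 2 and fold change > 2.

External p/FC tables (e.g. limma or edgeR output) can be supplied verbatim
through :func:`calls_from_table`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrices import validate_meta

__all__ = ["de_genes", "de_genes_single_replicate", "calls_from_table",
           "differential_ttfs", "extract_subnetwork"]

DEFAULT_Q = 0.05
DEFAULT_LOG2FC = 1.0
Y1_FPKM_MIN = 2.0
Y1_FC_MIN = 2.0
Y1_EPS = 0.01


def _group_columns(meta: pd.DataFrame, tissue: str, stage: str) -> list[str]:
    sel = (meta["tissue"] == tissue) & (meta["stage"] == stage)
    return list(meta.loc[sel, "sample_id"])


def de_genes(expr: pd.DataFrame, meta: pd.DataFrame, stage: str,
             focal: str, reference: str, mode: str = "focal-up-genes",
             q_max: float = DEFAULT_Q, log2fc_min: float = DEFAULT_LOG2FC
             ) -> pd.DataFrame:
    """Per-stage differential calls by Welch t-test on log2(FPKM + 1).

    ``mode`` selects the fold-change gate: ``focal-up-genes`` requires
    log2FC > ``log2fc_min`` (genes), ``two-sided-peaks`` requires
    \\|log2FC\\| > ``log2fc_min`` (accessibility peaks).  log2FC is the
    difference of group means on the log scale.  BH family = this stage's
    entities.  Strict inequalities throughout.
    """
    if mode not in {"focal-up-genes", "two-sided-peaks"}:
        raise ValueError(f"unknown mode {mode!r}")
    meta = validate_meta(meta)
    fc_cols = _group_columns(meta, focal, stage)
    ref_cols = _group_columns(meta, reference, stage)
    if len(fc_cols) < 2 or len(ref_cols) < 2:
        raise ValueError(
            f"stage {stage}: need >= 2 replicates per group for the "
            "standard rule; use de_genes_single_replicate")
    a = np.log2(expr[fc_cols].to_numpy(float) + 1.0)
    b = np.log2(expr[ref_cols].to_numpy(float) + 1.0)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    q = multipletests(p, method="fdr_bh")[1]
    if mode == "focal-up-genes":
        passes = (q < q_max) & (log2fc > log2fc_min)
    else:
        passes = (q < q_max) & (np.abs(log2fc) > log2fc_min)
    return pd.DataFrame({"entity": expr.index, "stage": stage,
                         "log2fc": log2fc, "p": p, "q": q,
                         "passed": passes, "rule": "standard"}
                        ).reset_index(drop=True)


def de_genes_single_replicate(expr: pd.DataFrame, meta: pd.DataFrame,
                              stage: str, focal: str, reference: str,
                              fpkm_min: float = Y1_FPKM_MIN,
                              fc_min: float = Y1_FC_MIN,
                              eps: float = Y1_EPS) -> pd.DataFrame:
    """Single-replicate rule: focal FPKM > ``fpkm_min`` and FC > ``fc_min``.

    FC = (focal + eps) / (reference + eps); the epsilon guards division by
    zero so a silent reference with an expressed focal sample passes.
    """
    meta = validate_meta(meta)
    fc_cols = _group_columns(meta, focal, stage)
    ref_cols = _group_columns(meta, reference, stage)
    if len(fc_cols) != 1 or len(ref_cols) != 1:
        raise ValueError(f"stage {stage}: single-replicate rule requires "
                         "exactly one replicate per group")
    f = expr[fc_cols[0]].to_numpy(float)
    r = expr[ref_cols[0]].to_numpy(float)
    fc = (f + eps) / (r + eps)
    passes = (f > fpkm_min) & (fc > fc_min)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(fc)
    return pd.DataFrame({"entity": expr.index, "stage": stage,
                         "log2fc": log2fc, "p": np.nan, "q": np.nan,
                         "passed": passes, "rule": "single-replicate"}
                        ).reset_index(drop=True)


def calls_from_table(table: pd.DataFrame, stage: str,
                     q_max: float = DEFAULT_Q,
                     log2fc_min: float = DEFAULT_LOG2FC,
                     two_sided: bool = False) -> pd.DataFrame:
    """Apply the pass gates to an externally computed p/FC table.

    ``table`` needs columns entity, log2fc, q (e.g. limma/edgeR output);
    the same strict thresholds as :func:`de_genes` are applied.
    """
    fc = table["log2fc"].to_numpy(float)
    gate = np.abs(fc) > log2fc_min if two_sided else fc > log2fc_min
    out = table[["entity", "log2fc", "q"]].copy()
    out["stage"] = stage
    out["p"] = table["p"] if "p" in table.columns else np.nan
    out["passed"] = (table["q"].to_numpy(float) < q_max) & gate
    out["rule"] = "external"
    return out[["entity", "stage", "log2fc", "p", "q", "passed", "rule"]]


def differential_ttfs(ttfs, de_tf_ids, enrichment: pd.DataFrame,
                      neglog10p_threshold: float = 6.0) -> list[str]:
    """TTFs that are differentially expressed AND motif-enriched in
    differential peaks.

    ``enrichment`` is the per-TF table from
    :func:`cnegrn.motif.motif_enrichment` computed on differentially
    accessible peaks against the consensus background; the enrichment gate
    is strict (-log10 p > threshold exactly at the boundary fails).
    """
    enriched = set(enrichment.loc[
        enrichment["neglog10p"] > neglog10p_threshold, "tf"])
    return sorted(set(ttfs) & set(de_tf_ids) & enriched)


def extract_subnetwork(triplets: pd.DataFrame, diff_ttfs, diff_targets
                       ) -> pd.DataFrame:
    """Retained triplets whose TTF and target are both differential.

    Elements appearing in the retained sub-network travel with the edges;
    the result is always an edge-subset of the parent network.
    """
    ttf_set, tgt_set = set(diff_ttfs), set(diff_targets)
    mask = (triplets["retained"] & triplets["ttf"].isin(ttf_set)
            & triplets["target"].isin(tgt_set))
    return triplets[mask].reset_index(drop=True)
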