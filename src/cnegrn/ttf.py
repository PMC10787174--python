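"""Toolkit transcription factor (TTF) discovery.

A TTF is a transcription factor hypothesised to orchestrate the recruitment
of gene expression in the focal organ's development.  Four conditions must
all hold:

1. the gene is both trait-specific (a member of the focal-organ-specific
   gene set) and a transcription factor (member of the TF catalog);
2. at least one active conserved non-coding element lies within ``flank``
   bp of its TSS (default 1 Mb up- or downstream);
3. it is expressed (FPKM > ``fpkm_min``) at >= 1 developmental time point
   in the focal tissue;
4. it ranks within the top ``top_k`` tissue-specificity scores in >= 1
   tissue (dense ranking, ties at the boundary kept).

The audit table records every per-condition boolean so that the filter
cascade can be inspected gene by gene.
"""

from __future__ import annotations

import logging
from collections.abc import Collection, Mapping

import pandas as pd

from .regions import GeneModel, RegionSet, window_query

logger = logging.getLogger(__name__)

__all__ = ["identify_ttfs"]


def identify_ttfs(rsegs: Collection[str], tf_catalog: Collection[str],
                  active_cnes: RegionSet,
                  gene_models: Mapping[str, GeneModel],
                  expr_dev: pd.DataFrame,
                  spec_ranks: pd.DataFrame,
                  flank: int = 1_000_000, fpkm_min: float = 1.0,
                  top_k: int = 50, anchor: str = "tss") -> pd.DataFrame:
    """Apply the four-condition TTF filter with a per-gene audit trail.

    Parameters
    ----------
    rsegs : trait-specific gene ids (candidate pool together with the TF
        catalog).
    tf_catalog : known transcription factor gene ids.
    active_cnes : globally active conserved elements.
    gene_models : gene id -> :class:`GeneModel` (TSS source).
    expr_dev : genes x developmental samples FPKM in the focal tissue.
    spec_ranks : output of :func:`cnegrn.specificity.specificity_table`
        (columns gene_id, tissue, rank).
    anchor : ``"tss"`` (default) or ``"gene_body"`` for condition 2.

    Returns
    -------
    DataFrame with columns gene_id, cond1..cond4, n_nearby_cnes,
    max_dev_fpkm, best_rank, is_ttf — sorted by gene_id; TTFs are the
    all-pass rows.
    """
    if anchor not in {"tss", "gene_body"}:
        raise ValueError("anchor must be 'tss' or 'gene_body'")
    rseg_set, tf_set = set(rsegs), set(tf_catalog)
    best_rank = (spec_ranks.groupby("gene_id")["rank"].min()
                 if len(spec_ranks) else pd.Series(dtype=int))
    rows = []
    for gene in sorted(rseg_set | tf_set):
        cond1 = gene in rseg_set and gene in tf_set
        n_near = 0
        if gene in gene_models:
            gm = gene_models[gene]
            if anchor == "tss":
                near = window_query(active_cnes, gm.chrom, gm.tss, flank)
            else:
                lo = max(0, gm.start - flank)
                near = RegionSet(active_cnes.overlapping(gm.chrom, lo,
                                                         gm.end + flank))
            n_near = len(near)
        cond2 = n_near >= 1
        if gene in expr_dev.index:
            max_fpkm = float(expr_dev.loc[gene].max())
        else:
            max_fpkm = float("nan")
            if cond1:
                logger.warning("no developmental expression for candidate %s; "
                               "condition 3 set to False", gene)
        cond3 = max_fpkm > fpkm_min if max_fpkm == max_fpkm else False
        br = int(best_rank[gene]) if gene in best_rank.index else 0
        cond4 = 0 < br <= top_k
        rows.append((gene, cond1, cond2, cond3, cond4, n_near, max_fpkm,
                     br if br else pd.NA,
                     cond1 and cond2 and cond3 and cond4))
    return pd.DataFrame(rows, columns=["gene_id", "cond1", "cond2", "cond3",
                                       "cond4", "n_nearby_cnes",
                                       "max_dev_fpkm", "best_rank", "is_ttf"])
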