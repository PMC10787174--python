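"""Tissue-specificity scoring of gene expression.

The score combines a gene's expression level in the focal tissue with how
concentrated its expression profile is there.  For a gene with per-sample
expression vector ``g`` (normalised to a probability vector ``q``) and a
tissue whose ideal-specificity control vector ``p`` puts mass 1/m on each of
the tissue's m replicate samples and 0 elsewhere,

    JMS = med**(1/3) / max(JSD(p, q), epsilon)

where ``med`` is the gene's median FPKM across the tissue's replicates and
JSD is the base-2 Jensen-Shannon divergence, in [0, 1], 0 iff the profile is
perfectly tissue-specific.  The cube root keeps numerator and denominator on
comparable magnitudes; ``epsilon`` keeps the score finite in the
perfect-specificity limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import median_by_tissue, validate_meta

__all__ = ["SpecificityScore", "jsd", "control_vector", "jms",
           "specificity_table", "rank_specificity"]

DEFAULT_EPSILON = 1e-6
_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SpecificityScore:
    gene_id: str
    tissue: str
    median_fpkm: float
    jsd: float
    jms: float
    all_zero: bool = False


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence between probability vectors.

    Symmetric; 0 iff p == q; 1 iff the supports are disjoint.  Computed as
    the mean of the two KL divergences to M = (p + q) / 2 with the
    convention 0 * log(0) = 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be non-negative")
    for name, v in (("p", p), ("q", q)):
        s = v.sum()
        if abs(s - 1.0) > _SUM_TOL:
            raise ValueError(f"{name} is not normalized (sum = {s!r})")
    m = 0.5 * (p + q)
    # 0 * log(0) := 0 — replace zeros before taking logs, then mask
    safe_p = np.where(p > 0, p, 1.0)
    safe_q = np.where(q > 0, q, 1.0)
    safe_m = np.where(m > 0, m, 1.0)
    kl_pm = np.where(p > 0, p * (np.log2(safe_p) - np.log2(safe_m)), 0.0)
    kl_qm = np.where(q > 0, q * (np.log2(safe_q) - np.log2(safe_m)), 0.0)
    val = 0.5 * kl_pm.sum() + 0.5 * kl_qm.sum()
    return float(min(max(val, 0.0), 1.0))


def control_vector(meta: pd.DataFrame, tissue: str,
                   sample_order: list[str] | None = None) -> np.ndarray:
    """Ideal-specificity profile: 1/m on the tissue's m samples, 0 elsewhere."""
    meta = validate_meta(meta)
    order = sample_order if sample_order is not None else list(meta["sample_id"])
    tissue_samples = set(meta.loc[meta["tissue"] == tissue, "sample_id"])
    if not tissue_samples:
        raise KeyError(f"unknown tissue {tissue!r}")
    m = sum(1 for s in order if s in tissue_samples)
    if m == 0:
        raise KeyError(f"tissue {tissue!r} has no samples in the given order")
    return np.array([1.0 / m if s in tissue_samples else 0.0 for s in order])


def jms(expr_row: pd.Series, meta: pd.DataFrame, tissue: str,
        epsilon: float = DEFAULT_EPSILON, exponent: float = 1.0 / 3.0
        ) -> SpecificityScore:
    """Specificity score of one gene in one tissue (see module docstring)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    values = expr_row.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression must be non-negative")
    gene_id = str(expr_row.name)
    meta = validate_meta(meta)
    order = list(expr_row.index)
    tissue_cols = [s for s in order
                   if s in set(meta.loc[meta["tissue"] == tissue, "sample_id"])]
    if not tissue_cols:
        raise KeyError(f"tissue {tissue!r} has no samples")
    med = float(expr_row[tissue_cols].median())
    total = values.sum()
    if total == 0:
        return SpecificityScore(gene_id, tissue, 0.0, 1.0, 0.0, all_zero=True)
    q = values / total
    p = control_vector(meta, tissue, sample_order=order)
    d = jsd(p, q)
    score = med ** exponent / max(d, epsilon)
    return SpecificityScore(gene_id, tissue, med, d, float(score))


def specificity_table(matrix: pd.DataFrame, meta: pd.DataFrame,
                      tissues: list[str] | None = None,
                      epsilon: float = DEFAULT_EPSILON,
                      exponent: float = 1.0 / 3.0) -> pd.DataFrame:
    """JMS for every (gene, tissue); dense rank by descending score per tissue.

    Ties share a rank; listing order breaks ties by gene id.
    """
    meta = validate_meta(meta)
    if tissues is None:
        tissues = sorted(meta["tissue"].unique())
    medians = median_by_tissue(matrix, meta, tissues)
    values = matrix.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    rows = []
    order = list(matrix.columns)
    for tissue in tissues:
        p = control_vector(meta, tissue, sample_order=order)
        for i, gene in enumerate(matrix.index):
            med = float(medians.loc[gene, tissue])
            if totals[i] == 0:
                rows.append((gene, tissue, med, 1.0, 0.0))
                continue
            d = jsd(p, values[i] / totals[i])
            rows.append((gene, tissue, med, d, med ** exponent / max(d, epsilon)))
    df = pd.DataFrame(rows, columns=["gene_id", "tissue", "median_fpkm",
                                     "jsd", "jms"])
    df = df.sort_values(["tissue", "jms", "gene_id"],
                        ascending=[True, False, True], kind="mergesort")
    df["rank"] = df.groupby("tissue")["jms"].rank(method="dense",
                                                  ascending=False).astype(int)
    return df.reset_index(drop=True)


def rank_specificity(matrix: pd.DataFrame, meta: pd.DataFrame, k: int,
                     tissues: list[str] | None = None,
                     epsilon: float = DEFAULT_EPSILON) -> dict[str, list[str]]:
    """Per-tissue gene lists with dense rank <= k (ties at k are kept)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    table = specificity_table(matrix, meta, tissues, epsilon)
    out: dict[str, list[str]] = {}
    for tissue, sub in table.groupby("tissue", sort=True):
        keep = sub[sub["rank"] <= k]
        out[tissue] = list(keep["gene_id"])
    return out
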