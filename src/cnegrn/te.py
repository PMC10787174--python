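"""Transposable-element overlap of active elements and enrichment summaries.

An element counts as TE-derived when at least ``min_overlap_frac`` of its
length is covered by annotated transposable elements (union coverage, so
several abutting TE fragments accumulate).  Summaries report element-level
and gene-level TE percentages for named sets and pairwise fold comparisons
in both common conventions: the plain ratio percent_A / percent_B and the
excess (percent_A - percent_B) / percent_B.
"""

from __future__ import annotations

from dataclasses import dataclass

from .regions import RegionSet

__all__ = ["flag_te_derived", "fold_ratio", "fold_excess",
           "SetSummary", "enrichment_summary"]


def flag_te_derived(cnes: RegionSet, te_annotation: RegionSet,
                    min_overlap_frac: float = 0.5) -> dict[str, bool]:
    """Per-element flag: union TE coverage fraction >= ``min_overlap_frac``."""
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    flags: dict[str, bool] = {}
    for r in cnes:
        ivs = sorted((max(r.start, te.start), min(r.end, te.end))
                     for te in te_annotation.overlapping(r.chrom, r.start, r.end))
        covered, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        flags[r.id] = covered / r.length >= min_overlap_frac
    return flags


def fold_ratio(pct_a: float, pct_b: float, ndigits: int = 2) -> float | None:
    """percent_A / percent_B; None when the denominator is zero."""
    if pct_b == 0:
        return None
    return round(pct_a / pct_b, ndigits)


def fold_excess(pct_a: float, pct_b: float, ndigits: int = 2) -> float | None:
    """(percent_A - percent_B) / percent_B; None when B is zero."""
    if pct_b == 0:
        return None
    return round((pct_a - pct_b) / pct_b, ndigits)


@dataclass(frozen=True)
class SetSummary:
    label: str
    n_elements: int
    n_te_derived: int
    percent: float
    n_genes: int | None = None
    n_te_regulated_genes: int | None = None
    gene_percent: float | None = None


def enrichment_summary(sets: dict[str, tuple[int, int]],
                       gene_counts: dict[str, tuple[int, int]] | None = None,
                       ndigits: int = 2) -> dict:
    """TE percentages per set plus all pairwise fold comparisons.

    ``sets`` maps label -> (n_elements, n_te_derived); ``gene_counts``
    optionally maps the same labels -> (n_genes, n_te_regulated_genes).
    Returns ``{"sets": [SetSummary...], "element_folds": {...},
    "gene_folds": {...}}`` where each fold dict keys "A_vs_B" to
    ``{"ratio": ..., "excess": ...}`` (None marks an undefined ratio).
    """
    summaries: list[SetSummary] = []
    elem_pct: dict[str, float] = {}
    gene_pct: dict[str, float] = {}
    for label, (n, n_te) in sets.items():
        if n <= 0:
            raise ValueError(f"set {label!r} is empty")
        if not 0 <= n_te <= n:
            raise ValueError(f"set {label!r}: invalid TE count {n_te}/{n}")
        pct = round(100.0 * n_te / n, ndigits)
        elem_pct[label] = pct
        g = gene_counts.get(label) if gene_counts else None
        if g is not None:
            gp = round(100.0 * g[1] / g[0], ndigits)
            gene_pct[label] = gp
            summaries.append(SetSummary(label, n, n_te, pct, g[0], g[1], gp))
        else:
            summaries.append(SetSummary(label, n, n_te, pct))

    def _pairwise(pcts: dict[str, float]) -> dict[str, dict]:
        out = {}
        labels = list(pcts)
        for a in labels:
            for b in labels:
                if a != b:
                    out[f"{a}_vs_{b}"] = {
                        "ratio": fold_ratio(pcts[a], pcts[b], ndigits),
                        "excess": fold_excess(pcts[a], pcts[b], ndigits)}
        return out

    return {"sets": summaries,
            "element_folds": _pairwise(elem_pct),
            "gene_folds": _pairwise(gene_pct)}
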