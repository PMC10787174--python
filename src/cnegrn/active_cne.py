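"""Reproducible open-chromatin consensus and active-CNE calling.

A conserved non-coding element (CNE) is "active" in a condition when it
overlaps a reproducible open-chromatin region (OCR) there.  Reproducibility
requires support from every replicate: replicate peak sets are merged into
connected components (1 bp overlap links peaks) and a component is kept only
if each replicate contributed at least one peak.  The consensus span is the
union of the contributing peaks by default (intersection-span available).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .regions import GenomicRegion, RegionSet, annotate_location

__all__ = [
    "Cne",
    "ActiveCneCall",
    "read_cnes",
    "reproducible_peaks",
    "call_active_cnes",
    "type_ratio",
    "type_composition",
]


@dataclass(frozen=True)
class Cne:
    """A conserved non-coding element with its conservation annotation.

    ``cne_type`` 'I' elements have no ortholog in outgroup species and carry
    a PhastCons conservation score in [0, 1]; type 'II' elements have
    fast-evolving outgroup orthologs and carry a PhyloP score (>= 0,
    unbounded).  The two scales are not cross-comparable.
    """

    region: GenomicRegion
    cne_type: str
    conservation: float

    def __post_init__(self) -> None:
        if self.cne_type not in {"I", "II"}:
            raise ValueError(f"cne_type must be 'I' or 'II', got {self.cne_type!r}")
        if self.conservation < 0:
            raise ValueError("conservation score must be >= 0")
        if self.cne_type == "I" and self.conservation > 1:
            raise ValueError("type I (PhastCons) conservation must be in [0, 1]")

    @property
    def id(self) -> str:
        return self.region.id


@dataclass(frozen=True)
class ActiveCneCall:
    cne_id: str
    tissue: str
    stage: str
    ocr_id: str
    overlap_bp: int
    category: str = ""


def read_cnes(bed_path: str, sidecar_path: str) -> list[Cne]:
    """CNEs from a BED file plus a TSV sidecar (id, type, conservation_score)."""
    from .regions import read_bed

    regions = read_bed(bed_path)
    side = pd.read_csv(sidecar_path, sep="\t", dtype={"id": str, "type": str})
    side = side.set_index("id")
    cnes = []
    for r in regions:
        if r.id not in side.index:
            raise KeyError(f"CNE {r.id} missing from sidecar table")
        row = side.loc[r.id]
        cnes.append(Cne(r, str(row["type"]), float(row["conservation_score"])))
    return cnes


def reproducible_peaks(replicate_peak_sets: list[RegionSet],
                       span: str = "union") -> RegionSet:
    """Consensus OCRs supported by every replicate.

    Peaks from all replicates are pooled per chromosome and grouped into
    connected components under >= 1 bp overlap.  A component becomes a
    consensus region iff every replicate contributed a peak.  ``span`` is
    ``"union"`` (min start, max end; default) or ``"intersection"``
    (max start, min end of the component's per-replicate envelopes).
    """
    if span not in {"union", "intersection"}:
        raise ValueError("span must be 'union' or 'intersection'")
    n_rep = len(replicate_peak_sets)
    if n_rep == 0:
        raise ValueError("at least one replicate peak set required")
    pooled: list[tuple[str, int, int, int]] = []  # chrom, start, end, replicate
    for idx, rs in enumerate(replicate_peak_sets):
        for r in rs:
            pooled.append((r.chrom, r.start, r.end, idx))
    pooled.sort()
    consensus: list[GenomicRegion] = []
    component: list[tuple[str, int, int, int]] = []

    def _flush() -> None:
        if not component:
            return
        reps = {c[3] for c in component}
        if len(reps) == n_rep:
            chrom = component[0][0]
            if span == "union":
                s = min(c[1] for c in component)
                e = max(c[2] for c in component)
            else:
                s = max(min(c[1] for c in component if c[3] == r) for r in reps)
                e = min(max(c[2] for c in component if c[3] == r) for r in reps)
            if e > s:
                consensus.append(GenomicRegion(chrom, s, e))

    cur_chrom, cur_end = None, -1
    for chrom, start, end, rep in pooled:
        if chrom != cur_chrom or start >= cur_end:
            _flush()
            component = []
            cur_chrom, cur_end = chrom, end
        component.append((chrom, start, end, rep))
        cur_end = max(cur_end, end)
    _flush()
    return RegionSet(consensus)


def call_active_cnes(ocrs_by_condition: dict[tuple[str, str], RegionSet],
                     cnes: list[Cne], min_overlap: int = 1,
                     gene_models=None, promoter_flank: int = 3000
                     ) -> list[ActiveCneCall]:
    """One call per (CNE, condition) with >= ``min_overlap`` bp OCR overlap.

    ``ocrs_by_condition`` maps (tissue, stage) to that condition's
    reproducible OCRs.  A CNE active in any condition is globally active.
    """
    calls: list[ActiveCneCall] = []
    for (tissue, stage), ocrs in sorted(ocrs_by_condition.items()):
        for cne in cnes:
            r = cne.region
            for ocr in ocrs.overlapping(r.chrom, r.start, r.end):
                ov = r.overlap(ocr)
                if ov >= min_overlap:
                    category = (annotate_location(r, gene_models, promoter_flank)
                                if gene_models is not None else "")
                    calls.append(ActiveCneCall(cne.id, tissue, stage, ocr.id,
                                               ov, category))
    return calls


def type_ratio(n_type_i: int, n_type_ii: int) -> float | None:
    """n_I / n_II rounded to 2 decimals; None when n_II is zero."""
    if n_type_ii == 0:
        return None
    return round(n_type_i / n_type_ii, 2)


def type_composition(calls: list[ActiveCneCall], cnes: list[Cne]
                     ) -> tuple[int, int, float | None]:
    """Counts of globally active type I and type II CNEs and their ratio."""
    if not calls:
        raise ValueError("no active-CNE calls")
    type_of = {c.id: c.cne_type for c in cnes}
    active = {c.cne_id for c in calls}
    n_i = sum(1 for a in active if type_of[a] == "I")
    n_ii = sum(1 for a in active if type_of[a] == "II")
    return n_i, n_ii, type_ratio(n_i, n_ii)


def calls_to_frame(calls: list[ActiveCneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.cne_id, c.tissue, c.stage, c.ocr_id, c.overlap_bp, c.category)
         for c in calls],
        columns=["cne_id", "tissue", "stage", "ocr_id", "overlap_bp", "category"])
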