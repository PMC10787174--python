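"""Genomic interval data model and queries.

All coordinates are stored 0-based half-open (BED convention).  Printed
coordinates in the literature (``chr1:196579342-242``) are 1-based inclusive
and are converted on ingestion by :func:`parse_region_id`.  Strand is carried
but ignored for overlap arithmetic; it matters only for TSS derivation on
gene models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicRegion",
    "RegionSet",
    "GeneModel",
    "BedParseError",
    "read_bed",
    "write_bed",
    "parse_region_id",
    "intersect",
    "window_query",
    "annotate_location",
    "read_gene_models",
]


class BedParseError(ValueError):
    """Raised on malformed interval input; carries the offending line number."""


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : chromosome name.
    start : 0-based inclusive start, ``>= 0``.
    end : 0-based exclusive end, ``> start``.
    id : stable identifier; defaults to ``chrom:start-end``.
    strand : ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicRegion") -> int:
        """Overlap in bp with another region (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class RegionSet:
    """An ordered collection of :class:`GenomicRegion` with unique ids.

    Iteration order is (chrom, start, end, id) — deterministic regardless of
    insertion order.  Lookup by id is O(1).
    """

    def __init__(self, regions: Iterable[GenomicRegion] = ()) -> None:
        regs = sorted(regions, key=lambda r: (r.chrom, r.start, r.end, r.id))
        self._regions: list[GenomicRegion] = regs
        self._by_id: dict[str, GenomicRegion] = {}
        for r in regs:
            if r.id in self._by_id:
                raise ValueError(f"duplicate region id {r.id!r}")
            self._by_id[r.id] = r
        self._trees: dict[str, IntervalTree] | None = None

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self._regions)

    def __len__(self) -> int:
        return len(self._regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def __getitem__(self, region_id: str) -> GenomicRegion:
        return self._by_id[region_id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._regions]

    def chromosomes(self) -> list[str]:
        return sorted({r.chrom for r in self._regions})

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for r in self._regions:
                trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
            self._trees = trees
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicRegion]:
        """Regions with >= 1 bp overlap of [start, end), in deterministic order."""
        hits = [iv.data for iv in self._tree(chrom).overlap(start, end)]
        return sorted(hits, key=lambda r: (r.start, r.end, r.id))


@dataclass
class GeneModel:
    """Minimal gene model: span, strand, exons; TSS derived from strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def read_bed(path: str) -> RegionSet:
    """Read BED3/BED4/BED6 into a :class:`RegionSet`.

    Column 4, when present, becomes the region id; otherwise ids default to
    ``chrom:start-end``.  Raises :class:`BedParseError` with the line number
    on malformed input.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] not in {"", "."} else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
            try:
                regions.append(GenomicRegion(fields[0], start, end, name, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(regions)


def write_bed(regions: RegionSet | Iterable[GenomicRegion], path: str,
              scores: dict[str, float] | None = None) -> None:
    """Write regions as BED4 (BED5 when per-id ``scores`` are given)."""
    with open(path, "w") as fh:
        for r in regions:
            row = [r.chrom, str(r.start), str(r.end), r.id]
            if scores is not None:
                row.append(str(scores.get(r.id, 0)))
            fh.write("\t".join(row) + "\n")


def parse_region_id(region_id: str, dialect: str) -> GenomicRegion:
    """Parse a printed region id into internal coordinates.

    Two dialects exist in the wild for ``chrom:A-B``:

    - ``start-end``: A and B are 1-based inclusive start and end.
    - ``start-length``: A is the 1-based start and B is the element length
      (the convention of the conserved-element tables this package targets,
      where e.g. ``chr1:196579342-242`` names a 242 bp element).

    The dialect is always explicit; it is never guessed from the numbers.
    """
    if dialect not in {"start-end", "start-length"}:
        raise ValueError(f"unknown region-id dialect {dialect!r}")
    try:
        chrom, span = region_id.rsplit(":", 1)
        a_str, b_str = span.split("-")
        a, b = int(a_str), int(b_str)
    except ValueError as exc:
        raise ValueError(f"cannot parse region id {region_id!r}") from exc
    if b <= 0:
        raise ValueError(f"{region_id!r}: second field must be positive")
    if dialect == "start-length":
        start, end = a - 1, a - 1 + b
    else:
        start, end = a - 1, b
    return GenomicRegion(chrom, start, end, region_id)


def intersect(a: RegionSet, b: RegionSet, min_overlap: int = 1
              ) -> list[tuple[str, str, int]]:
    """All (a_id, b_id, overlap_bp) pairs with overlap >= ``min_overlap`` bp.

    Content is symmetric under argument swap (ids trade places).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    pairs = []
    for ra in a:
        for rb in b.overlapping(ra.chrom, ra.start, ra.end):
            ov = ra.overlap(rb)
            if ov >= min_overlap:
                pairs.append((ra.id, rb.id, ov))
    return pairs


def window_query(regions: RegionSet, chrom: str, anchor: int, flank: int) -> RegionSet:
    """Regions overlapping the closed window ``[anchor - flank, anchor + flank]``."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lo = max(0, anchor - flank)
    # +1: the window is a closed interval of positions, queries are half-open
    hits = regions.overlapping(chrom, lo, anchor + flank + 1)
    return RegionSet(hits)


def annotate_location(region: GenomicRegion, genes: Sequence[GeneModel],
                      promoter_flank: int = 3000) -> str:
    """Classify a region as promoter / exon / intron / distal_intergenic.

    Priority when several apply: promoter (within ``promoter_flank`` of a
    TSS) > exon > intron (inside a gene span) > distal_intergenic.
    """
    chrom_genes = [g for g in genes if g.chrom == region.chrom]
    if not chrom_genes and genes:
        logger.warning("chromosome %s absent from gene annotation; "
                       "classifying %s as distal_intergenic", region.chrom, region.id)
    in_exon = in_intron = False
    for g in chrom_genes:
        tss = g.tss
        # closed promoter window [tss - flank, tss + flank]
        if region.start <= tss + promoter_flank and region.end > tss - promoter_flank:
            return "promoter"
        if max(region.start, g.start) < min(region.end, g.end):
            if any(max(region.start, s) < min(region.end, e) for s, e in g.exons):
                in_exon = True
            else:
                in_intron = True
    if in_exon:
        return "exon"
    if in_intron:
        return "intron"
    return "distal_intergenic"


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GTF/GFF3 via gffutils."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        exons = []
        for ex in db.region(seqid=feat.seqid, start=feat.start, end=feat.end,
                            featuretype="exon"):
            if ex.attributes.get("gene_id", [None])[0] == gid:
                exons.append((ex.start - 1, ex.end))
        genes.append(GeneModel(gid, feat.seqid, feat.start - 1, feat.end,
                               feat.strand, sorted(exons)))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes
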