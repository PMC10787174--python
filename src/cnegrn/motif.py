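"""PWM motif scanning with exact p-values and binding-strength aggregation.

A motif match's p-value is the probability, under the background nucleotide
distribution, that a random window scores at least as high as the observed
window.  The null score distribution is computed exactly by dynamic
programming: per-position log-odds scores are discretized to an integer grid
(default 1e-4 log2 units) and convolved across positions; the observed
window is scored on the same grid, so p-values are exact up to the grid and
monotone decreasing in score by construction.

Binding strength of a TF on a region is B = sum of -log10(p) over that
region's matches — the quantity that later weights the regulatory-strength
score of each element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = ["MotifModel", "MotifHit", "read_motifs", "write_jaspar", "scan",
           "aggregate_B", "read_hit_table", "motif_enrichment"]

_BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(_BASES)}
UNIFORM_BG = np.full(4, 0.25)
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_SCALE = 10_000
NEGLOG10_CAP = 10.0


@dataclass
class MotifModel:
    """A TF binding motif: probability matrix over A,C,G,T x width."""

    name: str
    counts: np.ndarray                     # raw 4 x w counts (or frequencies)
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError(f"motif {self.name}: need a 4 x w matrix, w >= 4")
        if (self.counts < 0).any():
            raise ValueError(f"motif {self.name}: negative counts")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError(f"motif {self.name}: zero-sum column")
        if abs(self.background.sum() - 1.0) > 1e-9 or (self.background <= 0).any():
            raise ValueError("background must be a positive probability vector")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def pfm(self) -> np.ndarray:
        """Probability matrix: counts plus pseudocount/4 per cell, normalised."""
        c = self.counts + self.pseudocount / 4.0
        return c / c.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(pfm / background), the per-position match score."""
        return np.log2(self.pfm / self.background[:, None])

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(self.name, self.counts[::-1, ::-1].copy(),
                          self.background[::-1].copy(), self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    position: int          # 0-based offset of the window on the given strand's +
    strand: str
    score: float           # log-odds sum
    p: float


def read_motifs(path: str, fmt: str = "JASPAR",
                background: np.ndarray | None = None,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[MotifModel]:
    """Read motifs from a JASPAR or MEME (minimal) file via Biopython."""
    from Bio import motifs as bio_motifs

    fmt_key = fmt.upper()
    if fmt_key not in {"JASPAR", "MEME"}:
        raise ValueError(f"unsupported motif format {fmt!r}")
    parser_fmt = "jaspar" if fmt_key == "JASPAR" else "minimal"
    bg = UNIFORM_BG.copy() if background is None else np.asarray(background, float)
    models = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, parser_fmt):
            counts = np.array([m.counts[b] for b in _BASES], dtype=float)
            name = m.name or getattr(m, "base_id", "") or f"motif_{len(models)}"
            models.append(MotifModel(str(name), counts, bg.copy(), pseudocount))
    return models


def write_jaspar(models: list[MotifModel], path: str) -> None:
    """Write motifs in JASPAR PFM format (full float precision)."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.name}\t{m.name}\n")
            for i, base in enumerate(_BASES):
                row = " ".join(repr(float(v)) for v in m.counts[i])
                fh.write(f"{base} [ {row} ]\n")


def score_distribution(motif: MotifModel, scale: int = DEFAULT_SCALE
                       ) -> tuple[np.ndarray, int, np.ndarray]:
    """Exact null pmf of the integer-grid window score under the background.

    Returns (pmf, min_sum, int_matrix) where pmf[k] = P(score_int ==
    min_sum + k) for an i.i.d. background window, and int_matrix is the
    4 x w integer score matrix shared with window scoring.
    """
    int_matrix = np.rint(motif.log_odds * scale).astype(np.int64)
    mins = int_matrix.min(axis=0)
    pmf = np.array([1.0])
    for j in range(motif.width):
        col = int_matrix[:, j] - mins[j]
        new = np.zeros(len(pmf) + int(col.max()))
        for b in range(4):
            new[col[b]:col[b] + len(pmf)] += motif.background[b] * pmf
        pmf = new
    return pmf, int(mins.sum()), int_matrix


class _Scanner:
    """Precomputed distribution + survival function for one motif."""

    def __init__(self, motif: MotifModel, scale: int = DEFAULT_SCALE) -> None:
        self.motif = motif
        self.scale = scale
        pmf, self.min_sum, self.int_matrix = score_distribution(motif, scale)
        # survival[k] = P(score_int >= min_sum + k)
        self.survival = np.cumsum(pmf[::-1])[::-1]

    def p_value(self, score_int: int) -> float:
        k = score_int - self.min_sum
        if k <= 0:
            return 1.0
        if k >= len(self.survival):
            return 0.0
        return float(self.survival[k])


def scan(sequence: str, motif: MotifModel,
         p_threshold: float = DEFAULT_P_THRESHOLD,
         scale: int = DEFAULT_SCALE, both_strands: bool = True
         ) -> list[MotifHit]:
    """All windows of ``sequence`` matching ``motif`` at p <= ``p_threshold``.

    Both strands are scanned (reverse-complement matrix on the + sequence);
    windows containing N are skipped; a sequence shorter than the motif
    yields no hits.
    """
    seq = sequence.upper()
    w = motif.width
    if len(seq) < w:
        return []
    idx = np.array([_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    hits: list[MotifHit] = []
    scanners = [("+", _Scanner(motif, scale))]
    if both_strands:
        scanners.append(("-", _Scanner(motif.reverse_complement(), scale)))
    for strand, sc in scanners:
        lo = sc.int_matrix
        lo_float = sc.motif.log_odds
        for pos in range(len(seq) - w + 1):
            window = idx[pos:pos + w]
            if (window < 0).any():
                continue
            cols = np.arange(w)
            score_int = int(lo[window, cols].sum())
            p = sc.p_value(score_int)
            if p <= p_threshold:
                score = float(lo_float[window, cols].sum())
                hits.append(MotifHit(pos, strand, score, p))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_regions(sequences: dict[str, str], motifs: list[MotifModel],
                 p_threshold: float = DEFAULT_P_THRESHOLD,
                 scale: int = DEFAULT_SCALE) -> list[tuple[str, str, float]]:
    """Scan many region sequences against many motifs.

    Builds each motif's null distribution once and reuses it across
    regions.  Returns (region_id, tf, p) match records ready for
    :func:`aggregate_B`.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    records: list[tuple[str, str, float]] = []
    for motif in motifs:
        scanners = [_Scanner(motif, scale),
                    _Scanner(motif.reverse_complement(), scale)]
        w = motif.width
        cols = np.arange(w)
        for region_id in sorted(sequences):
            seq = sequences[region_id].upper()
            if len(seq) < w:
                continue
            idx = np.array([_INDEX.get(c, -1) for c in seq], dtype=np.int64)
            windows = sliding_window_view(idx, w)
            valid = (windows >= 0).all(axis=1)
            if not valid.any():
                continue
            for sc in scanners:
                scores = sc.int_matrix[windows[valid], cols].sum(axis=1)
                k = np.clip(scores - sc.min_sum, 0, len(sc.survival))
                p = np.where(k <= 0, 1.0,
                             np.where(k >= len(sc.survival), 0.0,
                                      sc.survival[np.minimum(
                                          k, len(sc.survival) - 1)]))
                for pv in p[p <= p_threshold]:
                    records.append((region_id, motif.name, float(pv)))
    return records


def aggregate_B(records, cap: float = NEGLOG10_CAP) -> pd.DataFrame:
    """Aggregate per-match p-values into per-(region, TF) binding strength.

    ``records`` is an iterable of (region_id, tf, p).  B = sum of
    -log10(p); p = 0 contributes the cap (default 10) with a warning.
    Returns columns region_id, tf, B, n_hits; pairs without hits are absent
    (B treated as 0 downstream).
    """
    acc: dict[tuple[str, str], list[float]] = {}
    for region_id, tf, p in records:
        if p < 0 or p > 1:
            raise ValueError(f"p-value out of range: {p}")
        if p == 0:
            logger.warning("p = 0 for %s/%s capped at -log10 p = %s",
                           region_id, tf, cap)
            val = cap
        else:
            val = min(-np.log10(p), cap)
        acc.setdefault((str(region_id), str(tf)), []).append(val)
    rows = [(r, t, float(sum(v)), len(v)) for (r, t), v in sorted(acc.items())]
    return pd.DataFrame(rows, columns=["region_id", "tf", "B", "n_hits"])


def read_hit_table(path: str, cap: float = NEGLOG10_CAP) -> pd.DataFrame:
    """Ingest an external motif hit table (TSV).

    Two schemas are accepted: per-match rows with column ``neglog10p``
    (aggregated here), or pre-aggregated rows with column ``B`` (passed
    through).  A file carrying both columns is rejected as ambiguous.
    """
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "tf": str})
    if df.empty:
        return pd.DataFrame(columns=["region_id", "tf", "B", "n_hits"])
    has_match = "neglog10p" in df.columns
    has_agg = "B" in df.columns
    if has_match and has_agg:
        raise ValueError(f"{path}: mixed schema (both neglog10p and B present)")
    if has_match:
        recs = [(r.region_id, r.tf, 10.0 ** (-min(r.neglog10p, cap)))
                for r in df.itertuples()]
        return aggregate_B(recs, cap)
    if has_agg:
        out = df[["region_id", "tf", "B"]].copy()
        out["n_hits"] = df["n_hits"] if "n_hits" in df.columns else 1
        if (out["B"] < 0).any():
            raise ValueError(f"{path}: negative B")
        return out.reset_index(drop=True)
    raise ValueError(f"{path}: need a neglog10p or B column")


def hit_pairs(hit_table: pd.DataFrame) -> set[tuple[str, str]]:
    """The set of (region_id, tf) pairs with at least one match."""
    return set(zip(hit_table["region_id"], hit_table["tf"]))


def motif_enrichment(target_ids, background_ids, hit_table: pd.DataFrame,
                     neglog10p_threshold: float = 6.0) -> pd.DataFrame:
    """Per-TF hypergeometric enrichment of motif-bearing regions.

    The universe is target union background; the test is the upper tail of
    the hypergeometric distribution for the count of motif-bearing target
    regions.  TFs with -log10 p strictly greater than the threshold are
    flagged ``enriched``.
    """
    target = set(map(str, target_ids))
    if not target:
        raise ValueError("empty target region set")
    universe = target | set(map(str, background_ids))
    pairs = hit_pairs(hit_table)
    tfs = sorted({t for _, t in pairs})
    N, n = len(universe), len(target)
    rows = []
    for tf in tfs:
        bearing = {r for r, t in pairs if t == tf and r in universe}
        K = len(bearing)
        k = len(bearing & target)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        fold = (k / n) / (K / N) if K else float("nan")
        neglog = float(-np.log10(p)) if p > 0 else float("inf")
        rows.append((tf, k, n, K, N, fold, p, neglog,
                     neglog > neglog10p_threshold))
    return pd.DataFrame(rows, columns=["tf", "k_target", "n_target",
                                       "K_universe", "N_universe", "fold",
                                       "p", "neglog10p", "enriched"])
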