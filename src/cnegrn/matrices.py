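"""Expression and chromatin-openness matrices with sample metadata.

Matrices are plain pandas DataFrames (rows = genes or peaks, columns =
sample ids).  Sample metadata is a DataFrame with columns ``sample_id``,
``tissue``, ``stage``, ``replicate``, ``batch``, one row per matrix column.

Conventions: expression is in FPKM, openness is the fold change of reads
per base pair over the genome-wide background rate; filters operate on the
raw scale, correlations and clustering on ``log2(x + 1)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "STAGE_ORDER",
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "validate_meta",
    "compute_openness",
    "log_transform",
    "remove_batch",
    "median_by_tissue",
]

#: canonical ordering of developmental stages (embryonic day 60 through 1 year)
STAGE_ORDER = ("E60", "D1", "D7", "D28", "Y1")

META_COLUMNS = ("sample_id", "tissue", "stage", "replicate", "batch")


def read_matrix(path: str) -> pd.DataFrame:
    """Read a TSV matrix (first column = row id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing values")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated row ids")
    return df


def write_matrix(df: pd.DataFrame, path: str, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_sample_sheet(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"batch": str})
    return validate_meta(meta)


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return meta.reset_index(drop=True)


def _check_samples(df: pd.DataFrame, meta: pd.DataFrame) -> None:
    unknown = set(df.columns) - set(meta["sample_id"])
    if unknown:
        raise KeyError(f"matrix columns without metadata: {sorted(unknown)[:5]}")


def compute_openness(read_counts: pd.DataFrame, peak_lengths: pd.Series,
                     library_sizes: pd.Series,
                     effective_genome_size: float) -> pd.DataFrame:
    """Openness = (reads per bp in the peak) / (reads per bp genome-wide).

    ``openness[i, j] = (count[i, j] / length[i]) / (library_size[j] / G)``
    where ``G`` is the effective genome size.  Invariant under joint scaling
    of all library sizes and ``G``.
    """
    counts = read_counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    lengths = peak_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("peak lengths must be positive and cover all peaks")
    libs = library_sizes.reindex(counts.columns)
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be positive and cover all samples")
    if effective_genome_size <= 0:
        raise ValueError("effective_genome_size must be positive")
    per_bp = counts.div(lengths, axis=0)
    background = libs / effective_genome_size
    return per_bp.div(background, axis=1)


def log_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise ``log2(x + 1)``; requires non-negative input."""
    if (m.to_numpy() < 0).any():
        raise ValueError("log_transform requires non-negative values")
    return np.log2(m + 1.0)


def remove_batch(m: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Regress the batch effect out of a log-scale matrix.

    Per row an additive linear model with a (tissue x stage) group effect
    and a batch effect is fitted jointly for all rows by least squares, and
    the fitted batch component is subtracted.  With a single batch the
    matrix is returned unchanged.  A design in which batch is aliased with
    the group factor is rejected.
    """
    meta = validate_meta(meta)
    _check_samples(m, meta)
    meta = meta.set_index("sample_id").loc[list(m.columns)]
    batches = pd.Categorical(meta["batch"].astype(str))
    if len(batches.categories) < 2:
        return m.copy()
    group = pd.Categorical(meta["tissue"].astype(str) + "|" + meta["stage"].astype(str))
    G = pd.get_dummies(pd.Series(group, index=m.columns)).to_numpy(float)
    # treatment coding: first batch is reference, so batch columns are offsets
    B = pd.get_dummies(pd.Series(batches, index=m.columns), drop_first=True
                       ).to_numpy(float)
    X = np.hstack([G, B])
    rank_full = np.linalg.matrix_rank(X)
    if rank_full < G.shape[1] + B.shape[1]:
        raise ValueError(
            "batch is confounded with the tissue x stage group factor; "
            "batch effect is not estimable")
    coef, *_ = np.linalg.lstsq(X, m.to_numpy(float).T, rcond=None)
    batch_component = B @ coef[G.shape[1]:, :]
    return pd.DataFrame(m.to_numpy(float) - batch_component.T,
                        index=m.index, columns=m.columns)


def median_by_tissue(m: pd.DataFrame, meta: pd.DataFrame,
                     tissues: list[str] | None = None) -> pd.DataFrame:
    """Per-gene median over each tissue's replicate columns.

    Even replicate counts use the midpoint of the two central values.
    """
    meta = validate_meta(meta)
    _check_samples(m, meta)
    by_tissue = meta.groupby("tissue")["sample_id"].apply(list)
    if tissues is None:
        tissues = sorted(by_tissue.index)
    out = {}
    for tissue in tissues:
        if tissue not in by_tissue.index:
            raise KeyError(f"unknown tissue {tissue!r}")
        cols = [s for s in by_tissue[tissue] if s in m.columns]
        out[tissue] = m[cols].median(axis=1)
    return pd.DataFrame(out)
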