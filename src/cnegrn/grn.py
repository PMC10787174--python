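"""Developmental gene-regulatory-network inference.

Two models link paired expression and chromatin accessibility:

Upstream (who regulates a toolkit TF): the TTF's expression across samples
is regressed on one design column per nearby active element i,

    TTF = beta_0 + sum_i beta_i * (sum_{m in MB_i} TF_m) * O_i + eps

where MB_i is the set of TFs with a motif match on element i whose
expression also correlates with the TTF (Spearman rho > 0.6 at BH q <
0.01), and O_i is the element's openness.  Elements with significantly
non-zero beta (two-sided t-test) enter the upstream network.

Downstream (whom the TTF regulates): for each (TTF l, element k bearing
l's motif, candidate target n within the window of k) the per-sample
predictor sqrt(TTF_l * O_k) is correlated with the target's expression;
triplets with Spearman gamma strictly > 0.7 at BH q < 0.01 (family = all
tested triplets) form the downstream network.

Correlations are computed on log2(x + 1) by default; raw scale available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["UpstreamFit", "spearman_bh", "candidate_upstream_tfs",
           "fit_upstream_model", "infer_downstream"]

DEFAULT_RHO_MIN = 0.6
DEFAULT_GAMMA_MIN = 0.7
DEFAULT_Q_MAX = 0.01


@dataclass
class UpstreamTerm:
    cne_id: str
    members: list[str]
    beta: float
    p: float


@dataclass
class UpstreamFit:
    ttf_id: str
    intercept: float
    terms: list[UpstreamTerm] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.ttf_id, t.cne_id, m, t.beta, t.p,
                 t.cne_id in self.retained)
                for t in self.terms for m in t.members]
        return pd.DataFrame(rows, columns=["ttf", "cne", "tf_member", "beta",
                                           "p", "retained"])


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_bh(pairs: list[tuple[np.ndarray, np.ndarray]]
                ) -> pd.DataFrame:
    """Spearman rho + two-sided p per pair, BH q over the submitted family.

    Pairs in which either vector is constant have undefined rho; they are
    flagged (``valid = False``) and excluded from the BH family.
    """
    rows = []
    for i, (x, y) in enumerate(pairs):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError(f"pair {i}: vectors must be 1-D and equal length")
        if len(x) < 4:
            raise ValueError(f"pair {i}: need >= 4 observations")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((i, np.nan, np.nan, False))
            continue
        rho, p = _spearman(x, y)
        rows.append((i, rho, p, True))
    df = pd.DataFrame(rows, columns=["pair", "rho", "p", "valid"])
    df["q"] = np.nan
    mask = df["valid"].to_numpy()
    if mask.any():
        df.loc[mask, "q"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


def candidate_upstream_tfs(ttf_expr: pd.Series, tf_expr: pd.DataFrame,
                           hit_table: pd.DataFrame, cne_ids: list[str],
                           rho_min: float = DEFAULT_RHO_MIN,
                           q_max: float = DEFAULT_Q_MAX) -> dict[str, list[str]]:
    """MB_i per element: motif-bearing TFs whose expression tracks the TTF.

    A TF enters MB_i iff it has a motif hit on element i (hit table) and
    Spearman rho(TF, TTF) > ``rho_min`` at BH q < ``q_max`` (family = all
    motif-bearing TFs tested for this TTF).  Elements with empty MB_i are
    dropped from the mapping.
    """
    pairs_by_cne: dict[str, list[str]] = {}
    hit = hit_table[hit_table["region_id"].isin(cne_ids)]
    tfs = sorted(set(hit["tf"]) & set(tf_expr.index))
    if not tfs:
        return {}
    stats_df = spearman_bh([(tf_expr.loc[tf].to_numpy(),
                             ttf_expr.to_numpy()) for tf in tfs])
    ok = {tf for tf, row in zip(tfs, stats_df.itertuples())
          if row.valid and row.rho > rho_min and row.q < q_max}
    for cne in cne_ids:
        members = sorted(set(hit.loc[hit["region_id"] == cne, "tf"]) & ok)
        if members:
            pairs_by_cne[cne] = members
    return pairs_by_cne


def fit_upstream_model(ttf_id: str, ttf_expr: pd.Series,
                       terms: dict[str, tuple[pd.Series, pd.DataFrame]],
                       alpha: float = 0.05) -> UpstreamFit:
    """Ordinary least squares fit of the upstream model for one TTF.

    ``terms`` maps element id -> (openness vector O_i, member-TF expression
    matrix, TFs x samples).  The design column for element i is the
    elementwise product of O_i with the member-TF expression sum.  When the
    design has more columns than samples allow (> n_samples - 2), terms are
    pre-screened by absolute marginal correlation with the TTF and the
    reduction is logged.  Identically-zero columns are dropped.
    """
    y = ttf_expr.to_numpy(float)
    n = len(y)
    cols: dict[str, np.ndarray] = {}
    members: dict[str, list[str]] = {}
    dropped: list[str] = []
    for cne_id, (openness, member_expr) in sorted(terms.items()):
        x = (member_expr.sum(axis=0).to_numpy(float)
             * openness.to_numpy(float))
        if np.allclose(x, 0):
            logger.warning("upstream term %s for %s has identically zero "
                           "predictor; dropped", cne_id, ttf_id)
            dropped.append(cne_id)
            continue
        cols[cne_id] = x
        members[cne_id] = list(member_expr.index)
    max_terms = max(1, n - 2)
    if len(cols) > max_terms:
        corr = {c: abs(np.corrcoef(x, y)[0, 1]) if np.ptp(x) > 0 else 0.0
                for c, x in cols.items()}
        keep = sorted(sorted(cols), key=lambda c: -corr[c])[:max_terms]
        logger.warning("upstream design for %s reduced from %d to %d terms "
                       "by marginal correlation screening", ttf_id,
                       len(cols), len(keep))
        dropped += [c for c in cols if c not in keep]
        cols = {c: cols[c] for c in sorted(keep)}
    fit = UpstreamFit(ttf_id, intercept=float(np.mean(y)), dropped=dropped)
    if not cols:
        return fit
    X = np.column_stack([cols[c] for c in cols])
    res = OLS(y, add_constant(X, has_constant="add")).fit()
    fit.intercept = float(res.params[0])
    for j, cne_id in enumerate(cols):
        beta, p = float(res.params[j + 1]), float(res.pvalues[j + 1])
        fit.terms.append(UpstreamTerm(cne_id, members[cne_id], beta, p))
        if p < alpha:
            fit.retained.append(cne_id)
    return fit


def infer_downstream(ttf_expr: pd.DataFrame, openness: pd.DataFrame,
                     target_expr: pd.DataFrame,
                     candidate_triplets: list[tuple[str, str, str]],
                     gamma_min: float = DEFAULT_GAMMA_MIN,
                     q_max: float = DEFAULT_Q_MAX,
                     log_scale: bool = True) -> pd.DataFrame:
    """Screen (TTF, element, target) triplets by monotone coupling.

    For each candidate triplet the predictor sqrt(TTF_l * O_k) is formed
    per sample and correlated (Spearman) with the target's expression.  BH
    is applied over the whole tested family; a triplet is retained iff
    gamma strictly exceeds ``gamma_min`` and q < ``q_max``.

    All three matrices must share sample columns; negative expression or
    openness is rejected (sqrt domain).  Returns the full tested table with
    a ``retained`` flag.
    """
    samples = list(ttf_expr.columns)
    if list(openness.columns) != samples or list(target_expr.columns) != samples:
        raise ValueError("ttf_expr, openness and target_expr must share "
                         "identical sample columns")
    for name, df in (("ttf_expr", ttf_expr), ("openness", openness),
                     ("target_expr", target_expr)):
        arr = df.to_numpy(float)
        if np.isnan(arr).any():
            raise ValueError(f"{name} contains missing values")
        if (arr < 0).any():
            raise ValueError(f"{name} contains negative values (sqrt domain)")

    def _maybe_log(a: np.ndarray) -> np.ndarray:
        return np.log2(a + 1.0) if log_scale else a

    rows = []
    for ttf, cne, target in candidate_triplets:
        pred = np.sqrt(_maybe_log(ttf_expr.loc[ttf].to_numpy(float))
                       * _maybe_log(openness.loc[cne].to_numpy(float)))
        resp = _maybe_log(target_expr.loc[target].to_numpy(float))
        if np.ptp(pred) == 0 or np.ptp(resp) == 0:
            rows.append((ttf, cne, target, np.nan, np.nan, False))
            continue
        gamma, p = _spearman(resp, pred)
        rows.append((ttf, cne, target, gamma, p, True))
    df = pd.DataFrame(rows, columns=["ttf", "cne", "target", "gamma", "p",
                                     "valid"])
    df["q"] = np.nan
    mask = df["valid"].to_numpy()
    if mask.any():
        df.loc[mask, "q"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    df["retained"] = mask & (df["gamma"] > gamma_min) & (df["q"] < q_max)
    return df
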