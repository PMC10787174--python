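"""Functional-influence scoring of active conserved elements.

The regulatory strength of element k at time t sums, over the retained
downstream triplets (TTF l, element k, target n) passing through k,

    R_{k,t} = sum_{l,n} O_{k,t} * B_{k,l} * TTF_{l,t} * RSEG_{n,t} * g(gamma)

with g(gamma) = 2**gamma by default (2*gamma behind a flag; both are
monotone in gamma so rankings agree).  R_k is the maximum of R_{k,t} over
the focal tissue's time points, and the functional influence combines it
with the element's evolutionary conservation score C_k as the geometric
mean W_k = sqrt(R_k * C_k).  Because type I (PhastCons, bounded) and type
II (PhyloP, unbounded) conservation scores are not cross-comparable,
ranking is dense, descending in W, and within type only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["regulatory_strength_t", "regulatory_strength",
           "functional_influence", "rank_within_type", "influence_table"]


def _gamma_factor(gamma: float, transform: str) -> float:
    if transform == "power2":
        return float(2.0 ** gamma)
    if transform == "linear2":
        return float(2.0 * gamma)
    raise ValueError("gamma_transform must be 'power2' or 'linear2'")


def regulatory_strength_t(cne_id: str, time_samples: list[str],
                          triplets: pd.DataFrame, openness: pd.DataFrame,
                          b_table: pd.DataFrame, ttf_expr: pd.DataFrame,
                          target_expr: pd.DataFrame,
                          gamma_transform: str = "power2") -> float:
    """R_{k,t} for one element at one time point.

    ``time_samples`` is the list of sample columns belonging to the time
    point (replicates are averaged).  Every triplet through the element
    must have a binding strength B in ``b_table``; a missing B indicates an
    inconsistency between the network and the hit table and raises.
    """
    sub = triplets[(triplets["cne"] == cne_id) & triplets["retained"]]
    if sub.empty:
        return 0.0
    b_lookup = {(r, t): b for r, t, b in
                zip(b_table["region_id"], b_table["tf"], b_table["B"])}
    o_kt = float(openness.loc[cne_id, time_samples].mean())
    total = 0.0
    for row in sub.itertuples():
        key = (cne_id, row.ttf)
        if key not in b_lookup:
            raise KeyError(f"binding strength missing for {key}; network "
                           "and hit table are inconsistent")
        ttf_t = float(ttf_expr.loc[row.ttf, time_samples].mean())
        rseg_t = float(target_expr.loc[row.target, time_samples].mean())
        total += (o_kt * b_lookup[key] * ttf_t * rseg_t
                  * _gamma_factor(float(row.gamma), gamma_transform))
    return total


def regulatory_strength(r_t: dict[str, float] | pd.Series) -> float:
    """R_k = max over time points of R_{k,t}."""
    series = pd.Series(r_t, dtype=float)
    if series.empty:
        raise ValueError("no time points")
    return float(series.max())


def functional_influence(r: float, c: float) -> float:
    """W = sqrt(R * C), the geometric mean of strength and conservation."""
    if r < 0 or c < 0:
        raise ValueError("R and C must be >= 0")
    return float(np.sqrt(r * c))


def influence_table(triplets: pd.DataFrame, openness: pd.DataFrame,
                    b_table: pd.DataFrame, ttf_expr: pd.DataFrame,
                    target_expr: pd.DataFrame,
                    samples_by_time: dict[str, list[str]],
                    conservation: dict[str, tuple[str, float]],
                    gamma_transform: str = "power2") -> pd.DataFrame:
    """Per-element influence records for all elements in retained triplets.

    ``samples_by_time`` maps time-point label -> focal-tissue sample
    columns; ``conservation`` maps element id -> (type, C).  Returns
    columns cne_id, type, R_<t>..., R, C, W, rank_within_type.
    """
    cne_ids = sorted(set(triplets.loc[triplets["retained"], "cne"]))
    times = list(samples_by_time)
    rows = []
    for cne in cne_ids:
        r_t = {t: regulatory_strength_t(cne, cols, triplets, openness,
                                        b_table, ttf_expr, target_expr,
                                        gamma_transform)
               for t, cols in samples_by_time.items()}
        cne_type, c = conservation[cne]
        r = regulatory_strength(r_t)
        rows.append([cne, cne_type, *[r_t[t] for t in times], r, c,
                     functional_influence(r, c)])
    df = pd.DataFrame(rows, columns=["cne_id", "type",
                                     *[f"R_{t}" for t in times],
                                     "R", "C", "W"])
    return rank_within_type(df)


def rank_within_type(records: pd.DataFrame) -> pd.DataFrame:
    """Dense descending-W rank, separately per element type.

    Ties share a rank; listing order breaks ties by element id.  A type I
    record never affects type II ranks and vice versa.
    """
    df = records.sort_values(["type", "W", "cne_id"],
                             ascending=[True, False, True],
                             kind="mergesort").reset_index(drop=True)
    df["rank_within_type"] = (df.groupby("type")["W"]
                              .rank(method="dense", ascending=False)
                              .astype(int))
    return df
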