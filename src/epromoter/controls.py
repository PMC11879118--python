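"""Tissue specificity (tau) and expression-matched control promoters.

tau = sum_i(1 - x_i) / (N - 1) over N tissues, with x_i the expression
profile normalized by its maximal component: 0 for uniform (broad)
expression, 1 for strictly single-tissue expression.

Controls are built by assigning, to each Epromoter-associated gene, the
non-Epromoter coding gene with the nearest expression profile (Euclidean
distance over tissues), greedily and without replacement so the control set
is one-to-one with the Epromoter set.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


def tau_index(expression_row: Sequence[float]) -> float:
    """Tissue specificity index of one gene's expression profile.

    Returns NaN (with a warning) for an all-zero profile, where the
    max-normalization is undefined.
    """
    x = np.asarray(expression_row, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expression profile needs at least 2 tissues")
    if np.any(x < 0):
        raise ValueError("expression values must be non-negative")
    m = x.max()
    if m == 0:
        warnings.warn("all-zero expression profile; tau undefined", stacklevel=2)
        return float("nan")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def tau_table(expr: pd.DataFrame) -> pd.Series:
    """tau per gene for a genes x tissues matrix (NaN for all-zero rows)."""
    values = expr.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 tissues")
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    m = values.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = values / m[:, None]
        tau = np.sum(1.0 - norm, axis=1) / (values.shape[1] - 1)
    tau[m == 0] = np.nan
    if np.any(m == 0):
        warnings.warn("all-zero expression rows; tau undefined for those genes",
                      stacklevel=2)
    return pd.Series(tau, index=expr.index, name="tau")


def match_controls(
    expr: pd.DataFrame,
    epromoter_genes: Iterable[str],
    candidates: Iterable[str] | None = None,
    log1p: bool = False,
) -> pd.DataFrame:
    """Expression-nearest control gene for each Epromoter-associated gene.

    Epromoter genes are processed in lexicographic order; each takes the
    still-unassigned candidate with minimal Euclidean distance over the
    tissue profile (ties broken by lexicographic candidate id), so the
    mapping is injective. ``candidates`` defaults to all genes in ``expr``
    that are not Epromoter genes.

    Returns a DataFrame with columns epromoter_gene / control_gene /
    distance.
    """
    ep = sorted(set(epromoter_genes))
    missing = [g for g in ep if g not in expr.index]
    if missing:
        raise ValueError(f"epromoter genes absent from expression matrix: {missing[:5]}")
    if candidates is None:
        pool = sorted(set(expr.index) - set(ep))
    else:
        pool = sorted(set(candidates) - set(ep))
    if len(pool) < len(ep):
        raise ValueError(
            f"candidate pool ({len(pool)}) smaller than Epromoter set ({len(ep)})"
        )
    values = expr.to_numpy(dtype=float)
    if log1p:
        values = np.log1p(values)
    sub = pd.DataFrame(values, index=expr.index, columns=expr.columns)
    dmat = cdist(sub.loc[ep].to_numpy(), sub.loc[pool].to_numpy())
    taken = np.zeros(len(pool), dtype=bool)
    rows = []
    for i, gene in enumerate(ep):
        d = np.where(taken, np.inf, dmat[i])
        j = int(np.argmin(d))  # pool sorted lexicographically; first argmin wins ties
        taken[j] = True
        rows.append(
            {"epromoter_gene": gene, "control_gene": pool[j], "distance": float(d[j])}
        )
    return pd.DataFrame(rows)
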