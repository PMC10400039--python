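"""Expression specificity (tau) and per-pair expression divergence.

tau = sum_i (1 - x_i / max(x)) / (n - 1) over n conditions: 0 for a gene
expressed evenly everywhere, 1 for a gene expressed in a single condition.
Genes with no expression in any condition are excluded (tau undefined).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def compute_tau(x: Sequence[float] | np.ndarray, log2: bool = False) -> float:
    """Tissue/condition specificity index of one expression vector.

    Computed on linear normalized values by default; ``log2`` applies
    log2(x + 1) first. Returns NaN when the gene is silent everywhere.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector over >= 2 conditions")
    if (x < 0).any():
        raise ValueError("expression values must be nonnegative")
    if log2:
        x = np.log2(x + 1.0)
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (len(x) - 1))


def tau_table(matrix: pd.DataFrame, log2: bool = False) -> pd.DataFrame:
    """Per-gene tau over the columns of an expression matrix."""
    taus = [compute_tau(row.to_numpy(), log2=log2) for _, row in matrix.iterrows()]
    return pd.DataFrame(
        {
            "tau": taus,
            "n_conditions": matrix.shape[1],
            "max_expression": matrix.max(axis=1).to_numpy(),
        },
        index=matrix.index,
    )


def pair_expression(
    pairs: pd.DataFrame, matrix: pd.DataFrame, log2: bool = False
) -> pd.DataFrame:
    """Pearson correlation across conditions and |delta tau| per pair.

    Pairs with a gene absent from the matrix are dropped; zero-variance
    profiles give undefined r; a silent gene gives undefined |delta tau|.
    """
    taus = tau_table(matrix, log2=log2)["tau"]
    rows = []
    for g1, g2 in zip(pairs["gene1"], pairs["gene2"]):
        if g1 not in matrix.index or g2 not in matrix.index:
            continue
        x = matrix.loc[g1].to_numpy(float)
        y = matrix.loc[g2].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
            logger.info("pair (%s, %s): zero-variance profile, r undefined", g1, g2)
        else:
            r, _ = stats.pearsonr(x, y)
        t1, t2 = taus.loc[g1], taus.loc[g2]
        dt = abs(t1 - t2) if not (np.isnan(t1) or np.isnan(t2)) else np.nan
        rows.append({"gene1": g1, "gene2": g2, "pearson_r": r, "abs_delta_tau": dt})
    return pd.DataFrame(rows, columns=["gene1", "gene2", "pearson_r", "abs_delta_tau"])
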