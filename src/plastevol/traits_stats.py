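"""Complexity-index tabulation and induction-experiment statistics.

The complexity index (ci) of a species' mouthparts is the row sum of a
binary structure presence/absence matrix (scoring conventions — the <135
degree vertex rule, collapsing iterative and bilaterally duplicated
elements — are applied when the matrix is built, upstream of this module).
Environmental-induction experiments are 2x2 tables (treatment/control x
Eu/non-Eu) pooled across replicate plates and tested with Fisher's exact
test; the effect size is the conditional maximum-likelihood odds ratio of
the noncentral hypergeometric model, the estimate Fisher's-exact
frameworks report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def complexity_index(matrix: pd.DataFrame) -> pd.Series:
    """Per-species complexity index: the row sum of binary structure columns.

    Non-structure columns (e.g., a dimorphism flag named ``dimorphism``)
    should be dropped by the caller before summing.
    """
    matrix = pd.DataFrame(matrix)
    arr = matrix.to_numpy()
    bad = ~np.isin(arr, [0, 1])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary entry at row {matrix.index[i]!r}, "
            f"column {matrix.columns[j]!r}: {arr[i, j]!r}")
    return pd.Series(arr.sum(axis=1), index=matrix.index, name="ci",
                     dtype=int)


def pool_replicates(plates: pd.DataFrame) -> pd.DataFrame:
    """Pool per-plate induction counts into one 2x2 table.

    ``plates`` needs columns ``arm`` ("treatment"/"control"), ``n_eu`` and
    ``n_total``; returns a 2x2 DataFrame (rows arm, columns Eu / non-Eu).
    """
    plates = pd.DataFrame(plates)
    for col in ("arm", "n_eu", "n_total"):
        if col not in plates.columns:
            raise ValueError(f"plate table lacks column {col!r}")
    if (plates["n_eu"] < 0).any() or (plates["n_total"] < plates["n_eu"]).any():
        raise ValueError("counts must satisfy 0 <= n_eu <= n_total")
    rows = {}
    for arm in ("treatment", "control"):
        sub = plates[plates["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"no plates for arm {arm!r}")
        eu = int(sub["n_eu"].sum())
        total = int(sub["n_total"].sum())
        rows[arm] = [eu, total - eu]
    return pd.DataFrame(rows, index=["Eu", "non-Eu"]).T


def fisher_exact(table) -> tuple[float, float]:
    """Two-tailed Fisher's exact p and the conditional-ML odds ratio.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one; the
    odds ratio maximizes the noncentral hypergeometric likelihood with
    both margins fixed (infinite when the observed count sits at the edge
    of its support).
    """
    arr = np.asarray(pd.DataFrame(table).to_numpy() if hasattr(table, "columns")
                     else table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    arr = arr.astype(int)
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    orr = stats.contingency.odds_ratio(arr, kind="conditional")
    return p, float(orr.statistic)
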