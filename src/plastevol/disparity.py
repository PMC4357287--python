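"""Morphospace-occupation (disparity) metrics with rarefaction and bootstrap.

Two metrics: the sum of per-axis score variances ("multivariate variance")
and the PCA volume — the product of positive eigenvalues of the
Gower-centered pairwise distance matrix divided by the squared number of
species.  Group estimates are rarefied to a common sample size inside a
bootstrap loop; pairwise differences get two-tailed bootstrap p-values.
Neither metric corrects for phylogenetic non-independence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometrics import PCResult

logger = logging.getLogger(__name__)


def retain_axes(pc: PCResult, threshold: float = 0.05) -> pd.DataFrame:
    """Keep PC axes whose variance proportion strictly exceeds ``threshold``."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    keep = np.flatnonzero(pc.proportions > threshold)
    if keep.size == 0:
        raise ValueError(f"no axis explains more than {threshold:.0%} of variance")
    return pc.scores.iloc[:, keep]


def _scores_array(scores) -> np.ndarray:
    arr = np.asarray(pd.DataFrame(scores).to_numpy(dtype=float))
    if arr.ndim != 2:
        raise ValueError("scores must be a 2-D units x axes array")
    return arr


def sum_of_variances(scores) -> float:
    """Sum over axes of the sample variance (n-1 denominator) of scores."""
    arr = _scores_array(scores)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 units")
    return float(arr.var(axis=0, ddof=1).sum())


def pca_volume(scores, tol_factor: float = 1e-12) -> float:
    """Product of positive eigenvalues of the Gower-centered distance
    matrix, divided by the squared number of units."""
    arr = _scores_array(scores)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units")
    sq = ((arr[:, None, :] - arr[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    eig = np.linalg.eigvalsh(B)
    lead = eig.max()
    if lead <= 0:
        logger.warning("all units coincident; PCA volume is 0")
        return 0.0
    pos = eig[eig > tol_factor * lead]
    return float(np.prod(pos) / n ** 2)


_METRICS = {"sum_of_variances": sum_of_variances, "pca_volume": pca_volume}


@dataclass
class DisparityEstimate:
    metric: str
    group: str
    point: float
    boot_mean: float
    boot_sd: float
    ci_low: float
    ci_high: float
    rarefied_to: int
    n_boot: int


def _resolve_metric(metric):
    if callable(metric):
        return metric, getattr(metric, "__name__", "custom")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; options: {sorted(_METRICS)}")
    return _METRICS[metric], metric


def rarefied_bootstrap(scores, groups, metric="sum_of_variances",
                       rarefy_to: int | None = None, n_boot: int = 10_000,
                       seed: int = 0, resample: bool = True
                       ) -> dict[str, DisparityEstimate]:
    """Bootstrap disparity per group, rarefied to a common sample size.

    Each replicate resamples a group's units with replacement, then draws
    ``rarefy_to`` of them without replacement (rarefaction subsamples; the
    bootstrap resamples).  With ``resample=False`` and full rarefaction the
    point estimate is reproduced exactly.
    """
    scores = pd.DataFrame(scores)
    groups = pd.Series(groups)
    fn, metric_name = _resolve_metric(metric)
    sizes = groups.value_counts()
    if rarefy_to is None:
        rarefy_to = int(sizes.min())
    if rarefy_to > sizes.min():
        raise ValueError(
            f"rarefy_to={rarefy_to} exceeds smallest group size {sizes.min()}")
    if rarefy_to < 2:
        raise ValueError("rarefy_to must be at least 2")
    rng = np.random.default_rng(seed)
    out: dict[str, DisparityEstimate] = {}
    for g in sizes.index:
        members = scores.loc[groups.index[groups == g]].to_numpy(dtype=float)
        n = members.shape[0]
        point = fn(members)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            rows = rng.integers(0, n, size=n) if resample else np.arange(n)
            sub = rng.choice(rows, size=rarefy_to, replace=False)
            vals[b] = fn(members[sub])
        out[g] = DisparityEstimate(
            metric=metric_name, group=str(g), point=point,
            boot_mean=float(vals.mean()), boot_sd=float(vals.std(ddof=1)),
            ci_low=float(np.percentile(vals, 2.5)),
            ci_high=float(np.percentile(vals, 97.5)),
            rarefied_to=rarefy_to, n_boot=n_boot)
    return out


def disparity_difference_test(scores, groups, group_a: str, group_b: str,
                              metric="sum_of_variances",
                              n_boot: int = 100_000, seed: int = 0) -> float:
    """Two-tailed bootstrap p-value for a disparity difference.

    Replicates resample each group with replacement (rarefied to the
    smaller group's size); p = 2 * min(P(diff* <= 0), P(diff* >= 0)),
    capped at 1.
    """
    scores = pd.DataFrame(scores)
    groups = pd.Series(groups)
    fn, _ = _resolve_metric(metric)
    idx_a = groups.index[groups == group_a]
    idx_b = groups.index[groups == group_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("both groups need at least 2 units")
    if set(idx_a) & set(idx_b):
        raise ValueError("groups overlap")
    A = scores.loc[idx_a].to_numpy(dtype=float)
    B = scores.loc[idx_b].to_numpy(dtype=float)
    m = min(len(A), len(B))
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        ra = rng.choice(rng.integers(0, len(A), size=len(A)), size=m,
                        replace=False)
        rb = rng.choice(rng.integers(0, len(B), size=len(B)), size=m,
                        replace=False)
        diffs[b] = fn(A[ra]) - fn(B[rb])
    p_low = (diffs <= 0).mean()
    p_high = (diffs >= 0).mean()
    return float(min(1.0, 2.0 * min(p_low, p_high)))
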