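"""Distance-based group-difference testing.

PERMANOVA partitions the total sum of squared Euclidean distances among
and within groups and tests the pseudo-F ratio by label permutation —
appropriate here because multivariate normality is rejected for stress
data (screened with Mardia's tests), ruling out parametric MANOVA.
Pairwise group contrasts are Holm-corrected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "PermanovaResult",
    "permanova",
    "pairwise_permanova",
    "holm_adjust",
    "MardiaResult",
    "multivariate_normality",
]


@dataclass
class PermanovaResult:
    F: float
    R2: float
    p_value: float
    n_perm: int
    df_among: int
    df_within: int
    groups: tuple[str, ...] = ()


def _ss_partition(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in uniq:
        mask = labels == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    return ss_total, ss_within


def permanova(
    x: np.ndarray,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances.

    SS_total = (1/n) sum_{i<j} d_ij^2; SS_within sums the analogous
    per-group terms; F = [SS_among/(g-1)] / [SS_within/(n-g)].  The
    p-value comes from unrestricted label permutations with the
    observed statistic counted in the null set.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels must match rows of x")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        small = uniq[counts < 2]
        raise ValueError(f"groups of size 1 not allowed: {list(small)}")
    n = x.shape[0]
    g = uniq.size
    d2 = squareform(pdist(x)) ** 2
    ss_total, ss_within = _ss_partition(d2, labels, uniq)
    ss_among = ss_total - ss_within
    df_among = g - 1
    df_within = n - g
    if ss_total <= 0:
        warnings.warn("all points identical; F undefined", stacklevel=2)
        return PermanovaResult(
            F=float("nan"), R2=float("nan"), p_value=float("nan"),
            n_perm=n_perm, df_among=df_among, df_within=df_within,
            groups=tuple(str(u) for u in uniq),
        )
    f_obs = (ss_among / df_among) / (ss_within / df_within) if ss_within > 0 else float("inf")
    r2 = ss_among / ss_total
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(n)]
        sst, ssw = _ss_partition(d2, perm_labels, uniq)
        ssa = sst - ssw
        f_p = (ssa / df_among) / (ssw / df_within) if ssw > 0 else float("inf")
        if f_p >= f_obs:
            hits += 1
    return PermanovaResult(
        F=f_obs,
        R2=r2,
        p_value=hits / (n_perm + 1),
        n_perm=n_perm,
        df_among=df_among,
        df_within=df_within,
        groups=tuple(str(u) for u in uniq),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment, returned in the original order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[i]))
        adj[i] = running
    return adj


def pairwise_permanova(
    x: np.ndarray,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
) -> list[dict]:
    """PERMANOVA for every unordered group pair, Holm-adjusted.

    Returns one record per pair with the subset PERMANOVA result and
    the Holm-adjusted p-value across all pairs.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    results = []
    for g1, g2 in itertools.combinations(uniq, 2):
        mask = (labels == g1) | (labels == g2)
        res = permanova(
            x[mask], labels[mask], n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        results.append({"pair": (str(g1), str(g2)), "result": res})
    adj = holm_adjust([r["result"].p_value for r in results])
    for rec, a in zip(results, adj):
        rec["p_adjusted"] = float(a)
    return results


@dataclass
class MardiaResult:
    skewness: float
    skewness_p: float
    kurtosis: float
    kurtosis_p: float
    normal: bool
    alpha: float
    note: str = "normality screen: Mardia's multivariate skewness and kurtosis tests"


def multivariate_normality(x: np.ndarray, alpha: float = 0.05) -> MardiaResult:
    """Mardia's multivariate skewness and kurtosis tests.

    Skewness b1p = mean over pairs of (z_i' z_j)^3 with z the
    standardized data; n*b1p/6 is chi-squared with q(q+1)(q+2)/6
    degrees of freedom.  Kurtosis b2p = mean squared Mahalanobis norm;
    asymptotically normal with mean q(q+2) and variance 8q(q+2)/n.
    Normality is rejected if either test falls below alpha.
    """
    x = np.asarray(x, dtype=float)
    n, q = x.shape
    if n <= q + 1:
        raise ValueError("need n > q + 1 observations")
    centred = x - x.mean(axis=0)
    s = centred.T @ centred / n
    try:
        s_inv = np.linalg.inv(s)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance matrix") from exc
    if np.linalg.cond(s) > 1e12:
        raise ValueError("singular covariance matrix")
    gram = centred @ s_inv @ centred.T
    b1p = float((gram**3).sum()) / n**2
    b2p = float(np.mean(np.diag(gram) ** 2))
    df = q * (q + 1) * (q + 2) / 6.0
    skew_stat = n * b1p / 6.0
    skew_p = float(stats.chi2.sf(skew_stat, df))
    kurt_z = (b2p - q * (q + 2)) / np.sqrt(8.0 * q * (q + 2) / n)
    kurt_p = float(2.0 * stats.norm.sf(abs(kurt_z)))
    return MardiaResult(
        skewness=b1p,
        skewness_p=skew_p,
        kurtosis=b2p,
        kurtosis_p=kurt_p,
        normal=(skew_p >= alpha and kurt_p >= alpha),
        alpha=alpha,
    )
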