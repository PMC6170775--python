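"""Phylogenetic comparative statistics under Brownian motion.

All methods here condition on a rooted, branch-length phylogeny through
the Brownian-motion trait covariance matrix C, whose entry (i, j) is
the shared root-to-MRCA path length of tips i and j:

* ``kmult`` — multivariate phylogenetic signal, the multivariate
  generalization of Blomberg's K, with a tip-shuffling permutation test;
* ``pgls`` — multivariate generalized least squares regression with
  residual-randomization significance;
* ``two_block_pls`` / ``phylo_pls`` — two-block partial least squares
  covariation between trait blocks, with and without removal of the
  phylogenetic covariance structure;
* ``phylomorphospace`` — maximum-likelihood Brownian ancestral states
  used to project internal nodes into an ordination space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "phylo_cov",
    "inv_sqrt_psd",
    "KmultResult",
    "kmult",
    "PglsResult",
    "pgls",
    "PlsResult",
    "two_block_pls",
    "phylo_pls",
    "phylomorphospace",
]

DEFAULT_N_PERM = 9999


def _tip_depths_and_mrca(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """C[i, j] = root-to-MRCA(i, j) path length."""
    # depth of every node from the root
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = node.edge.length or 0.0
        else:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    label_to_leaf = {}
    for leaf in tree.leaf_node_iter():
        label_to_leaf[leaf.taxon.label] = leaf
    missing = [t for t in taxa if t not in label_to_leaf]
    if missing:
        raise ValueError(f"taxa not found as tips: {missing}")
    # ancestor chains (node -> index along path) per tip
    chains = []
    for t in taxa:
        chain = {}
        node = label_to_leaf[t]
        while node is not None:
            chain[id(node)] = depth[node]
            node = node.parent_node
        chains.append(chain)
    n = len(taxa)
    c = np.zeros((n, n))
    leaves = [label_to_leaf[t] for t in taxa]
    for i in range(n):
        c[i, i] = depth[leaves[i]]
        for j in range(i + 1, n):
            node = leaves[j]
            while id(node) not in chains[i]:
                node = node.parent_node
            c[i, j] = c[j, i] = depth[node]
    return c


def phylo_cov(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance matrix for the given tip ordering.

    Polytomies are handled naturally.  Zero-length terminal branches
    would make C singular, so they are raised to 1e-8 x tree depth with
    a warning.
    """
    c = _tip_depths_and_mrca(tree, taxa)
    diag = np.diag(c).copy()
    max_depth = diag.max()
    if max_depth <= 0:
        raise ValueError("tree has zero depth")
    floor = 1e-8 * max_depth
    for i in range(len(taxa)):
        off = np.max(np.delete(c[i], i)) if len(taxa) > 1 else 0.0
        if c[i, i] - off <= 0:
            warnings.warn(
                "zero-length terminal branch raised to 1e-8 x tree depth",
                stacklevel=2,
            )
            c[i, i] = off + floor
    return c


def inv_sqrt_psd(c: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition."""
    w, v = np.linalg.eigh(c)
    if np.any(w <= tol * w.max()):
        raise ValueError(
            "phylogenetic covariance is singular; consider a minimum branch length"
        )
    return (v / np.sqrt(w)) @ v.T


def _gls_root(y: np.ndarray, cinv: np.ndarray) -> np.ndarray:
    """GLS estimate of the root state (phylogenetic mean), one per column."""
    ones = np.ones(y.shape[0])
    w = cinv @ ones
    return (w @ y) / (ones @ w)


@dataclass
class KmultResult:
    statistic: float
    p_value: float
    n_perm: int


def _kmult_stat(y: np.ndarray, cinv: np.ndarray, expected: float) -> float:
    a = _gls_root(y, cinv)
    r = y - a
    num = float(np.sum(r * r))
    den = float(np.sum(r * (cinv @ r)))
    if den == 0 or num == 0:
        return float("nan")
    return (num / den) / expected


def kmult(
    y: np.ndarray,
    tree: dendropy.Tree,
    taxa: list[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> KmultResult:
    """Multivariate phylogenetic signal K relative to Brownian motion.

    K = 1 matches the Brownian expectation on the given tree; K < 1
    means less resemblance among relatives than expected, K > 1 more.
    Significance is assessed by shuffling trait rows across tips
    (upper tail, observed value counted in the null set).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != len(taxa):
        raise ValueError("rows of y must match taxa")
    if y.shape[0] < 4:
        raise ValueError("need at least four tips")
    c = phylo_cov(tree, taxa)
    cinv = np.linalg.inv(c)
    n = y.shape[0]
    expected = (np.trace(c) - n / cinv.sum()) / (n - 1)
    obs = _kmult_stat(y, cinv, expected)
    if not np.isfinite(obs):
        warnings.warn("degenerate traits (zero variance); K undefined", stacklevel=2)
        return KmultResult(statistic=float("nan"), p_value=float("nan"), n_perm=n_perm)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _kmult_stat(y[perm], cinv, expected) >= obs:
            hits += 1
    return KmultResult(statistic=obs, p_value=hits / (n_perm + 1), n_perm=n_perm)


@dataclass
class PglsResult:
    coefficients: np.ndarray  # (r+1) x q, intercept first
    f_statistic: float
    r_squared: float
    p_value: float
    n_perm: int


def pgls(
    y: np.ndarray,
    x: np.ndarray,
    tree: dendropy.Tree,
    taxa: list[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    permute_tips: bool = False,
) -> PglsResult:
    """Multivariate phylogenetic generalized least squares regression.

    Both sides are premultiplied by the inverse square root of the
    Brownian covariance; an OLS fit on the transformed data is then a
    GLS fit on the original.  The test statistic is the Procrustes-style
    ratio of model to residual sums of squares summed over trait
    columns; significance comes from residual randomization (permuting
    reduced-model residuals in the transformed space) by default, or tip
    shuffling with ``permute_tips``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.ndim == 2 and y.shape[0] == 1 and len(taxa) > 1:
        y = y.T
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(taxa)
    if y.shape[0] != n or x.shape[0] != n:
        raise ValueError("rows of y and x must match taxa")
    if n <= x.shape[1] + 1:
        raise ValueError("too few tips for the number of predictors")
    c = phylo_cov(tree, taxa)
    u = inv_sqrt_psd(c)
    yt = u @ y
    design = u @ np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    reduced = u @ np.ones((n, 1))

    def fit_ss(dsg: np.ndarray, yy: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        beta, *_ = np.linalg.lstsq(dsg, yy, rcond=None)
        fitted = dsg @ beta
        resid = yy - fitted
        return beta, resid, float(np.sum(resid**2))

    beta_r, resid_r, ss_reduced = fit_ss(reduced, yt)
    beta, resid, ss_resid = fit_ss(design, yt)
    ss_model = ss_reduced - ss_resid
    df_model = design.shape[1] - 1
    df_resid = n - design.shape[1]
    if ss_resid <= 1e-12 * max(ss_reduced, 1.0):
        f_obs = float("inf")
        r2 = 1.0
    else:
        f_obs = (ss_model / df_model) / (ss_resid / df_resid)
        r2 = ss_model / ss_reduced
    fitted_r = reduced @ beta_r

    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if permute_tips:
            y_perm = u @ y[perm]
        else:
            y_perm = fitted_r + resid_r[perm]
        _, _, ssr_full = fit_ss(design, y_perm)
        _, _, ssr_red = fit_ss(reduced, y_perm)
        ssm = ssr_red - ssr_full
        if ssr_full <= 0:
            f_p = float("inf")
        else:
            f_p = (ssm / df_model) / (ssr_full / df_resid)
        if f_p >= f_obs:
            hits += 1
    return PglsResult(
        coefficients=beta,
        f_statistic=f_obs,
        r_squared=r2,
        p_value=hits / (n_perm + 1),
        n_perm=n_perm,
    )


@dataclass
class PlsResult:
    r_pls: float
    singular_values: np.ndarray
    left_vectors: np.ndarray  # p x rank, columns are axes
    right_vectors: np.ndarray  # q x rank
    p_value: float
    n_perm: int


def _pls_core(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    cross = a.T @ b / (a.shape[0] - 1)
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    left = a @ u[:, 0]
    right = b @ vt[0]
    denom = left.std() * right.std()
    r = float(np.corrcoef(left, right)[0, 1]) if denom > 0 else float("nan")
    return abs(r), s, u, vt.T


def two_block_pls(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> PlsResult:
    """Two-block partial least squares covariation.

    SVD of the cross-covariance of the column-centred blocks; r-PLS is
    the correlation of the first pair of block scores.  The permutation
    null shuffles the rows of the second block; the test statistic is
    the first singular value (upper tail, observed included).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] != b.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    if a.shape[0] < 4:
        raise ValueError("need at least four rows")
    if np.allclose(a.std(axis=0), 0) or np.allclose(b.std(axis=0), 0):
        raise ValueError("zero-variance block")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    r, s, u, v = _pls_core(ac, bc)
    rng = np.random.default_rng(seed)
    hits = 1
    n = a.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, s_p, _, _ = _pls_core(ac, bc[perm])
        if s_p[0] >= s[0]:
            hits += 1
    return PlsResult(
        r_pls=r,
        singular_values=s,
        left_vectors=u,
        right_vectors=v,
        p_value=hits / (n_perm + 1),
        n_perm=n_perm,
    )


def phylo_pls(
    a: np.ndarray,
    b: np.ndarray,
    tree: dendropy.Tree,
    taxa: list[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> PlsResult:
    """Phylogenetic two-block PLS under Brownian motion.

    Both blocks are centred on the GLS root estimate and premultiplied
    by the inverse square root of the Brownian covariance, removing the
    expected phylogenetic covariance before the SVD.  Rows of the
    transformed second block are permuted for the null.  On a star
    phylogeny with unit branches this reduces exactly to the standard
    two-block PLS.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n = len(taxa)
    if a.shape[0] != n or b.shape[0] != n:
        raise ValueError("block rows must match taxa")
    c = phylo_cov(tree, taxa)
    cinv = np.linalg.inv(c)
    u_mat = inv_sqrt_psd(c)
    at = u_mat @ (a - _gls_root(a, cinv))
    bt = u_mat @ (b - _gls_root(b, cinv))
    # transformed rows are exchangeable under the Brownian null
    at_c = at - at.mean(axis=0)
    bt_c = bt - bt.mean(axis=0)
    if np.allclose(at_c.std(axis=0), 0) or np.allclose(bt_c.std(axis=0), 0):
        raise ValueError("zero-variance block after phylogenetic transform")
    r, s, uu, v = _pls_core(at_c, bt_c)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, s_p, _, _ = _pls_core(at_c, bt_c[perm])
        if s_p[0] >= s[0]:
            hits += 1
    return PlsResult(
        r_pls=r,
        singular_values=s,
        left_vectors=uu,
        right_vectors=v,
        p_value=hits / (n_perm + 1),
        n_perm=n_perm,
    )


def phylomorphospace(
    tree: dendropy.Tree,
    taxa: list[str],
    tip_scores: np.ndarray,
) -> dict[str, np.ndarray]:
    """Maximum-likelihood Brownian ancestral states for internal nodes.

    Solves, per ordination axis, the normal equations in which every
    internal node sits at the branch-length-weighted average of its
    neighbours (weights 1/branch length), the ML solution for ancestral
    states under Brownian motion conditioned on the tip values.

    Returns a mapping from internal node key (``node{i}`` in preorder,
    root first) to its coordinates; tips are not included.
    """
    scores = np.atleast_2d(np.asarray(tip_scores, dtype=float))
    if scores.shape[0] != len(taxa):
        raise ValueError("tip_scores rows must match taxa")
    label_to_row = {t: i for i, t in enumerate(taxa)}
    internal = []
    node_key = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf():
            continue
        node_key[id(node)] = f"node{len(internal)}"
        internal.append(node)
    m = len(internal)
    if m == 0:
        raise ValueError("tree has no internal nodes")
    idx = {id(node): j for j, node in enumerate(internal)}
    lap = np.zeros((m, m))
    rhs = np.zeros((m, scores.shape[1]))
    total_weight = 0.0
    for node in internal:
        j = idx[id(node)]
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            if bl <= 0:
                bl = 1e-8
            w = 1.0 / bl
            total_weight += w
            lap[j, j] += w
            if child.is_leaf():
                rhs[j] += w * scores[label_to_row[child.taxon.label]]
            else:
                jc = idx[id(child)]
                lap[j, jc] -= w
                lap[jc, j] -= w
                lap[jc, jc] += w
    if total_weight == 0:
        raise ValueError("tree has zero total branch length")
    sol = np.linalg.solve(lap, rhs)
    return {node_key[id(node)]: sol[idx[id(node)]] for node in internal}
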