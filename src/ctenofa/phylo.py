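"""Phylogenetic generalized least squares under an Ornstein-Uhlenbeck model.

Residual correlation between two tips decays exponentially with their
patristic distance, corr(i, j) = exp(-alpha * d_ij), the tip correlation
implied by a stationary mean-reverting (OU) model of trait evolution.
Conspecific individuals are attached to the species tree as terminal
polytomies on short branches before computing distances.  The selection
strength alpha is profiled by maximum likelihood per regression, with the
zero-signal (ordinary least squares) limit included as a candidate, so an
ordinary regression is recovered when the data carry no phylogenetic
structure.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import linalg, stats

from .stats import holm_adjust

__all__ = [
    "Phylogeny",
    "parse_newick",
    "attach_individuals",
    "ou_correlation",
    "gls_fit",
    "GLSFit",
    "fit_pgls",
    "RegressionResult",
    "holm_adjust",
]


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "length", "children")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[_Node] = []

    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labelled tips."""

    def __init__(self, root: _Node):
        self.root = root
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")
        for node, _ in self._walk():
            if node is not self.root:
                if node.length is None:
                    raise ValueError("missing branch length")
                if not math.isfinite(node.length) or node.length < 0:
                    raise ValueError(f"invalid branch length {node.length}")

    # -- traversal ---------------------------------------------------------
    def _walk(self):
        """Preorder (node, depth-from-root) pairs."""
        stack = [(self.root, 0.0)]
        while stack:
            node, depth = stack.pop()
            yield node, depth
            for child in reversed(node.children):
                stack.append((child, depth + (child.length or 0.0)))

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n, _ in self._walk() if n.is_leaf()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance."""
        return max(d for n, d in self._walk() if n.is_leaf())

    def tip_depths(self) -> dict[str, float]:
        return {n.label: d for n, d in self._walk() if n.is_leaf()}

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.tip_depths().values())
        return max(depths) - min(depths) <= tol

    # -- rescaling -----------------------------------------------------------
    def normalized(self) -> "Phylogeny":
        """Copy with every branch scaled so total height is 1."""
        h = self.height
        if h <= 0:
            raise ValueError("tree has zero height")
        return self.scaled(1.0 / h)

    def scaled(self, factor: float) -> "Phylogeny":
        def copy(node: _Node) -> _Node:
            out = _Node(node.label, None if node.length is None else node.length * factor)
            out.children = [copy(c) for c in node.children]
            return out

        return Phylogeny(copy(self.root))

    # -- distances -----------------------------------------------------------
    def distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Patristic distances between all tip pairs.

        Returns tip labels (sorted) and the matching symmetric matrix.
        Computed in one postorder sweep: the distance between two tips is
        depth_i + depth_j - 2 * depth(MRCA).
        """
        labels = sorted(self.tip_labels)
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        D = np.zeros((n, n))
        depths: dict[int, float] = {}

        def visit(node: _Node, depth: float) -> list[int]:
            if node.is_leaf():
                i = index[node.label]
                depths[i] = depth
                return [i]
            groups = [visit(c, depth + c.length) for c in node.children]
            merged: list[int] = []
            for g in groups:
                for a in merged:
                    for b in g:
                        d = depths[a] + depths[b] - 2.0 * depth
                        D[a, b] = D[b, a] = d
                merged.extend(g)
            return merged

        visit(self.root, 0.0)
        return labels, D

    # -- serialization ---------------------------------------------------------
    def to_newick(self) -> str:
        """Canonical Newick: children ordered by their smallest tip label."""

        def key(node: _Node) -> str:
            if node.is_leaf():
                return node.label
            return min(key(c) for c in node.children)

        def fmt(node: _Node) -> str:
            if node.is_leaf():
                core = node.label
            else:
                inner = ",".join(fmt(c) for c in sorted(node.children, key=key))
                core = f"({inner})"
            if node.length is None:
                return core
            return f"{core}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({self.n_tips} tips, height {self.height:.4g})"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> _Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        out = _Node(label=label, length=dnode.edge.length)
        out.children = [convert(c) for c in dnode.child_nodes()]
        if out.is_leaf() and out.label is None:
            raise ValueError("unlabelled tip in Newick input")
        return out

    root = convert(tree.seed_node)
    return Phylogeny(root)


def attach_individuals(
    tree: Phylogeny,
    mapping: Mapping[str, str],
    epsilon: float,
) -> Phylogeny:
    """Attach individuals to their species tips as terminal polytomies.

    Every species tip with at least one individual becomes an internal node
    whose children are that species' individuals on branches of length
    ``epsilon``; inter-species patristic distances are preserved up to
    +2*epsilon.  epsilon must be strictly positive, otherwise conspecific
    individuals would be perfectly correlated and the OU correlation
    singular.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0 (zero would duplicate correlation rows)")
    tips = set(tree.tip_labels)
    by_taxon: dict[str, list[str]] = {}
    for sample_id, taxon in mapping.items():
        if taxon not in tips:
            raise ValueError(f"taxon {taxon!r} (sample {sample_id!r}) is not a tip")
        by_taxon.setdefault(taxon, []).append(sample_id)

    def copy(node: _Node) -> _Node:
        out = _Node(node.label, node.length)
        out.children = [copy(c) for c in node.children]
        if out.is_leaf() and out.label in by_taxon:
            samples = sorted(by_taxon[out.label])
            out.label = None
            out.children = [_Node(s, epsilon) for s in samples]
        return out

    # species without individuals simply remain as their own tips
    return Phylogeny(copy(tree.root))


# ---------------------------------------------------------------------------
# OU correlation and GLS
# ---------------------------------------------------------------------------

def ou_correlation(distances: np.ndarray, alpha: float) -> np.ndarray:
    """Tip correlation exp(-alpha * d) from a patristic distance matrix.

    alpha = 0 returns the all-ones matrix (singular; rejected downstream);
    alpha = inf returns the identity (zero phylogenetic signal).
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if math.isinf(alpha):
        return np.eye(D.shape[0])
    C = np.exp(-alpha * D)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class GLSFit:
    coefficients: np.ndarray
    cov_coefficients: np.ndarray
    log_likelihood: float
    sigma2_ml: float
    sigma2_unbiased: float
    rss_whitened: float
    df_resid: int


def gls_fit(y: np.ndarray, X: np.ndarray, correlation: np.ndarray) -> GLSFit:
    """Generalized least squares with V = sigma^2 * correlation.

    beta = (X' V^-1 X)^-1 X' V^-1 y, computed by whitening both sides with
    the Cholesky factor of the correlation matrix (V itself is never
    inverted).  sigma^2 is profiled by maximum likelihood for the reported
    Gaussian log-likelihood; coefficient covariance uses the unbiased
    residual variance so t-tests carry n - p degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y and X have incompatible shapes")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    try:
        L = linalg.cholesky(correlation, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"correlation matrix is not positive definite: {exc}") from exc

    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)

    Q, R = np.linalg.qr(Xw)
    if np.min(np.abs(np.diag(R))) < 1e-10 * max(1.0, np.max(np.abs(np.diag(R)))):
        raise ValueError("design matrix is rank deficient")
    beta = linalg.solve_triangular(R, Q.T @ yw, lower=False)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)

    sigma2_ml = rss / n
    sigma2_unbiased = rss / (n - p)
    Rinv = linalg.solve_triangular(R, np.eye(p), lower=False)
    cov_beta = sigma2_unbiased * (Rinv @ Rinv.T)
    logdet_corr = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_ml <= 0:
        loglik = math.inf  # perfect fit; degenerate but signal it explicitly
    else:
        loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdet_corr + n)
    return GLSFit(
        coefficients=beta,
        cov_coefficients=cov_beta,
        log_likelihood=loglik,
        sigma2_ml=sigma2_ml,
        sigma2_unbiased=sigma2_unbiased,
        rss_whitened=rss,
        df_resid=n - p,
    )


@dataclass
class RegressionResult:
    """One PGLS (or OLS) fit of a lipid response on a predictor."""

    response: str
    predictor: str
    slice_name: str
    n: int
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    t_slope: float
    df: int
    p: float
    alpha_hat: float
    log_likelihood: float
    p_holm: float = field(default=float("nan"))

    @property
    def significant(self) -> bool:
        return self.p_holm < 0.05


_LN_ALPHA_BOUNDS = (-6.0, 6.0)
_GRID_POINTS = 13
_GOLDEN_TOL = 1e-4
_INVGOLD = (math.sqrt(5.0) - 1.0) / 2.0


def _profile_alpha(
    y: np.ndarray, X: np.ndarray, D: np.ndarray
) -> tuple[float, GLSFit]:
    """Maximize the GLS log-likelihood over alpha (OU selection strength).

    Coarse grid over ln(alpha) in tree-height units, golden-section
    refinement around the best grid point, plus the alpha -> infinity
    (identity correlation, ordinary regression) limit as an explicit
    candidate.
    """

    def evaluate(ln_alpha: float) -> tuple[float, GLSFit]:
        fit = gls_fit(y, X, ou_correlation(D, math.exp(ln_alpha)))
        return fit.log_likelihood, fit

    lo, hi = _LN_ALPHA_BOUNDS
    grid = np.linspace(lo, hi, _GRID_POINTS)
    evals = [evaluate(g) for g in grid]
    best_i = int(np.argmax([ll for ll, _ in evals]))

    # golden-section around the best grid point
    a = grid[max(best_i - 1, 0)]
    b = grid[min(best_i + 1, len(grid) - 1)]
    c = b - _INVGOLD * (b - a)
    d = a + _INVGOLD * (b - a)
    fc, fit_c = evaluate(c)
    fd, fit_d = evaluate(d)
    while abs(b - a) > _GOLDEN_TOL:
        if fc > fd:
            b, d, fd, fit_d = d, c, fc, fit_c
            c = b - _INVGOLD * (b - a)
            fc, fit_c = evaluate(c)
        else:
            a, c, fc, fit_c = c, d, fd, fit_d
            d = a + _INVGOLD * (b - a)
            fd, fit_d = evaluate(d)
    if fc > fd:
        ln_best, ll_best, fit_best = c, fc, fit_c
    else:
        ln_best, ll_best, fit_best = d, fd, fit_d
    if evals[best_i][0] > ll_best:
        ln_best, (ll_best, fit_best) = grid[best_i], evals[best_i]

    # ordinary-regression limit: zero phylogenetic signal
    ols_fit = gls_fit(y, X, np.eye(len(y)))
    if ols_fit.log_likelihood > ll_best:
        return math.inf, ols_fit
    return math.exp(ln_best), fit_best


def fit_pgls(
    data,
    response: str,
    predictor: str,
    tree: Phylogeny | None = None,
    mapping: Mapping[str, str] | None = None,
    *,
    distances: np.ndarray | None = None,
    tip_order: Sequence[str] | None = None,
    epsilon_frac: float = 1e-3,
    alpha: float | None = None,
    slice_name: str = "all",
) -> RegressionResult:
    """PGLS of one response column on one predictor column.

    ``data`` is a DataFrame indexed by sample id.  Either pass ``tree`` plus
    ``mapping`` (sample id -> taxon; the tree is height-normalized and
    individuals attached at epsilon = epsilon_frac * height), or pass a
    precomputed individual-level ``distances`` matrix with its ``tip_order``.
    ``alpha`` fixes the OU selection strength instead of profiling it;
    ``alpha=inf`` is an ordinary regression.
    """
    if data[predictor].isna().any() or data[response].isna().any():
        raise ValueError("missing values in regression columns")
    if len(data) < 3:
        raise ValueError(f"need >=3 observations, got {len(data)}")
    x = data[predictor].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"degenerate predictor {predictor!r}: no variance")

    if distances is None:
        if tree is None or mapping is None:
            raise ValueError("pass either (tree, mapping) or (distances, tip_order)")
        samples = set(data.index)
        sub_mapping = {s: t for s, t in mapping.items() if s in samples}
        if set(sub_mapping) != samples:
            missing = sorted(samples - set(sub_mapping))
            raise ValueError(f"samples missing from the taxon mapping: {missing}")
        norm = tree.normalized()
        expanded = attach_individuals(norm, sub_mapping, epsilon_frac * norm.height)
        tip_order, distances = expanded.distance_matrix()
    if tip_order is None:
        raise ValueError("tip_order is required with a precomputed distance matrix")
    order = list(tip_order)
    if set(order) < set(data.index):
        raise ValueError("distance matrix does not cover all samples")
    if set(order) != set(data.index):
        idx = [i for i, lab in enumerate(order) if lab in set(data.index)]
        distances = distances[np.ix_(idx, idx)]
        order = [order[i] for i in idx]

    df = data.loc[order]
    y = df[response].to_numpy(dtype=float)
    x = df[predictor].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])

    if alpha is not None:
        fit = gls_fit(y, X, ou_correlation(distances, alpha))
        alpha_hat = float(alpha)
    else:
        alpha_hat, fit = _profile_alpha(y, X, distances)

    se = np.sqrt(np.diag(fit.cov_coefficients))
    t_slope = fit.coefficients[1] / se[1]
    dof = fit.df_resid
    p = 2.0 * float(stats.t.sf(abs(t_slope), dof))
    return RegressionResult(
        response=response,
        predictor=predictor,
        slice_name=slice_name,
        n=len(y),
        slope=float(fit.coefficients[1]),
        intercept=float(fit.coefficients[0]),
        se_slope=float(se[1]),
        se_intercept=float(se[0]),
        t_slope=float(t_slope),
        df=dof,
        p=p,
        alpha_hat=alpha_hat,
        log_likelihood=fit.log_likelihood,
    )
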