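"""Regularized partial-correlation network estimation.

A network is a Gaussian graphical model: nodes are RF / GD scores, edges
are partial correlations obtained from an L1-penalized precision matrix.
The penalty is selected by minimizing the extended BIC

    EBIC = -2 loglik + E log n + 4 gamma E log p

over a log-spaced path of 100 penalties (down to 1% of the smallest
penalty that empties the network), with gamma = 0.5 by default and ties
broken toward the sparser model. Connectivity is summarized by expected
influence: the signed sum of edge weights, per node or globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glasso import glasso, glasso_path_ebic
from ._linalg import smooth_correlation
from .errors import DomainError, EstimationError
from .measurement import polychoric_correlation, polyserial_correlation
from .panels import ScorePanel

__all__ = [
    "EstimatorConfig",
    "NetworkModel",
    "EIReport",
    "correlation_matrix",
    "glasso_fit",
    "precision_to_partial",
    "ebic_score",
    "select_network_ebic",
    "expected_influence",
]

ZERO_TOL = 1e-8


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings shared by every network (re-)estimation in a comparison."""

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation_method: str = "pearson"  # or "mixed"

    def describe(self) -> dict:
        return {
            "gamma": self.gamma,
            "n_lambda": self.n_lambda,
            "lambda_min_ratio": self.lambda_min_ratio,
            "correlation_method": self.correlation_method,
        }


@dataclass
class NetworkModel:
    """Estimated network: node labels plus a symmetric weight matrix of
    regularized partial correlations (zero diagonal)."""

    node_labels: list[str]
    weights: np.ndarray
    lambda_selected: float
    gamma: float
    n: int
    correlation_method: str = "pearson"
    zero_tol: float = ZERO_TOL
    collinear: bool = False
    smoothed: bool = False

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if not np.allclose(W, W.T, atol=1e-10):
            raise DomainError("weight matrix must be symmetric")
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        self.weights = W

    @property
    def p(self) -> int:
        return len(self.node_labels)

    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.sum(np.abs(self.weights[iu]) > self.zero_tol))

    def edge(self, a: str, b: str) -> float:
        i, j = self.node_labels.index(a), self.node_labels.index(b)
        return float(self.weights[i, j])

    def edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.p, 1)
        rows = [
            (self.node_labels[i], self.node_labels[j], self.weights[i, j])
            for i, j in zip(*iu)
            if abs(self.weights[i, j]) > self.zero_tol
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


@dataclass
class EIReport:
    """Expected influence: signed edge-weight sums."""

    node_labels: list[str]
    node_ei: np.ndarray
    global_ei: float
    subset: list[str] = field(default_factory=list)


def correlation_matrix(
    scores: np.ndarray | pd.DataFrame | ScorePanel,
    method: str = "pearson",
    binary_columns: set[str] | None = None,
    group: str | None = None,
    occasion: str | None = None,
):
    """Correlation matrix of one group x occasion slice of scores.

    ``method="pearson"`` treats every column numerically (binary nodes enter
    as 0/1, which for a binary-continuous pair is the point-biserial
    correlation). ``method="mixed"`` substitutes polychoric estimates for
    ordinal-ordinal pairs and two-step polyserial estimates for
    ordinal-continuous pairs. Returns ``(R, collinear, smoothed)``.
    """
    if isinstance(scores, ScorePanel):
        binary_columns = set(scores.binary_columns)
        X = scores.matrix(group=group, occasion=occasion)
    elif isinstance(scores, pd.DataFrame):
        X = scores.to_numpy(dtype=float)
    else:
        X = np.asarray(scores, dtype=float)
    n, p = X.shape
    if n < 3:
        raise DomainError(f"need at least 3 subjects, got {n}")
    sds = X.std(axis=0, ddof=0)
    if (sds < 1e-12).any():
        raise DomainError(f"constant score column at index {int(np.argmax(sds < 1e-12))}")
    if method == "pearson":
        R = np.corrcoef(X.T)
    elif method == "mixed":
        binary_idx = set()
        if binary_columns and isinstance(scores, ScorePanel):
            binary_idx = {scores.score_columns.index(c) for c in binary_columns}
        else:
            binary_idx = {
                j for j in range(p) if np.isin(np.unique(X[:, j]), (0.0, 1.0)).all()
            }
        R = np.corrcoef(X.T)
        for i in range(p):
            for j in range(i + 1, p):
                if i in binary_idx and j in binary_idx:
                    r = polychoric_correlation(X[:, i].astype(int), X[:, j].astype(int)).rho
                elif i in binary_idx:
                    r = polyserial_correlation(X[:, j], X[:, i].astype(int))
                elif j in binary_idx:
                    r = polyserial_correlation(X[:, i], X[:, j].astype(int))
                else:
                    continue
                R[i, j] = R[j, i] = r
    else:
        raise DomainError(f"unknown correlation method {method!r}")
    off = np.abs(R - np.diag(np.diag(R)))
    collinear = bool(off.max() > 1 - 1e-10)
    R, smoothed = smooth_correlation(R)
    return R, collinear, smoothed


def glasso_fit(S: np.ndarray, lam: float, tol: float = 1e-6) -> np.ndarray:
    """Sparse precision matrix at one penalty (coordinate descent with a
    duality-gap stopping rule; ``lam = 0`` is the plain inverse)."""
    return glasso(S, lam, tol=tol)


def precision_to_partial(K: np.ndarray, zero_tol: float = ZERO_TOL) -> np.ndarray:
    """Partial correlations ``w_ij = -K_ij / sqrt(K_ii K_jj)`` with the
    diagonal zeroed and sub-tolerance entries snapped to exactly 0."""
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if (d <= 0).any():
        raise DomainError("precision matrix must have a positive diagonal")
    W = -K / np.sqrt(np.outer(d, d))
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < zero_tol] = 0.0
    return 0.5 * (W + W.T)


def ebic_score(loglik: float, n: int, p: int, edge_count: int, gamma: float = 0.5) -> float:
    """Extended BIC for a Gaussian graphical model with E free edges."""
    if n <= 0:
        raise DomainError("n must be positive")
    if edge_count < 0:
        raise DomainError("edge count must be nonnegative")
    return -2.0 * loglik + edge_count * np.log(n) + 4.0 * gamma * edge_count * np.log(p)


def gaussian_loglik(S: np.ndarray, K: np.ndarray, n: int) -> float:
    """Profile log-likelihood (n/2)(log det K - tr(S K)), constants dropped.

    The additive constant does not affect which penalty minimizes the EBIC.
    """
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise EstimationError("precision matrix is not positive definite")
    return 0.5 * n * (logdet - float(np.sum(S * K)))


def select_network_ebic(
    scores: np.ndarray | pd.DataFrame | ScorePanel,
    config: EstimatorConfig = EstimatorConfig(),
    node_labels: list[str] | None = None,
    group: str | None = None,
    occasion: str | None = None,
) -> NetworkModel:
    """Estimate an EBIC-selected graphical-lasso network from scores."""
    if isinstance(scores, ScorePanel):
        node_labels = list(scores.score_columns)
        X = scores.matrix(group=group, occasion=occasion)
    elif isinstance(scores, pd.DataFrame):
        node_labels = list(scores.columns)
        X = scores.to_numpy(dtype=float)
    else:
        X = np.asarray(scores, dtype=float)
        node_labels = node_labels or [f"v{i}" for i in range(X.shape[1])]
    R, collinear, smoothed = correlation_matrix(
        scores if isinstance(scores, ScorePanel) else X,
        method=config.correlation_method,
        group=group,
        occasion=occasion,
    )
    n = X.shape[0]
    K, lam, ebics, edges, lams = glasso_path_ebic(
        R,
        n,
        gamma=config.gamma,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    W = precision_to_partial(K)
    return NetworkModel(
        node_labels=node_labels,
        weights=W,
        lambda_selected=lam,
        gamma=config.gamma,
        n=n,
        correlation_method=config.correlation_method,
        collinear=collinear,
        smoothed=smoothed,
    )


def expected_influence(net: NetworkModel, subset: list[str] | None = None) -> EIReport:
    """Node and global expected influence.

    Node EI is the signed sum of a node's incident weights; global EI is the
    signed sum of all weights among ``subset`` (default: every node, which
    makes global EI equal to half the node-EI total).
    """
    labels = net.node_labels
    subset = list(subset) if subset is not None else list(labels)
    unknown = set(subset) - set(labels)
    if unknown:
        raise DomainError(f"unknown node(s): {sorted(unknown)}")
    node_ei = net.weights.sum(axis=1)
    idx = [labels.index(s) for s in subset]
    sub = net.weights[np.ix_(idx, idx)]
    global_ei = float(np.triu(sub, 1).sum())
    return EIReport(node_labels=list(labels), node_ei=node_ei, global_ei=global_ei, subset=subset)
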