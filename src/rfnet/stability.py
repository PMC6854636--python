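"""Bootstrap accuracy and case-dropping stability of estimated networks.

Edge accuracy: nonparametric case resampling; the network is re-estimated
per replicate and percentile confidence intervals are reported per edge.
Regularized edges are biased toward zero, so these intervals describe
sampling variability of the penalized estimate, not unbiased coverage.

Stability: the case-dropping subset bootstrap. For each drop proportion a
subsample (without replacement) is scored by the Spearman correlation
between its node expected-influence vector and the full-sample one; the
CS coefficient is the largest drop proportion at which that correlation
still reaches 0.7 with 95% probability. CS above 0.5 is conventionally
read as stable, below 0.25 as unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import rng_from_seed
from .comparison import _as_matrix
from .errors import DomainError, EstimationError
from .network import EstimatorConfig, select_network_ebic

__all__ = ["BootstrapResult", "bootstrap_edges", "casedrop_stability", "cs_coefficient"]

DEFAULT_REPLICATES = 2000
DEFAULT_DROP_GRID = tuple(np.round(np.linspace(0.05, 0.75, 15), 4))


@dataclass
class BootstrapResult:
    node_labels: list[str]
    B: int
    seed: int
    estimator: EstimatorConfig
    # edge accuracy
    edge_index: list[tuple[str, str]] = field(default_factory=list)
    edge_point: np.ndarray | None = None
    edge_ci: np.ndarray | None = None  # (n_edges, 2)
    level: float | None = None
    edge_samples: np.ndarray | None = None
    # case-dropping stability
    drop_grid: np.ndarray | None = None
    casedrop_correlations: np.ndarray | None = None  # (n_drops, B)
    cs_coefficient: float | None = None
    cs_threshold: float = 0.7
    cs_confidence: float = 0.95
    n_failed: int = 0


def bootstrap_edges(
    scores,
    B: int = DEFAULT_REPLICATES,
    level: float = 0.95,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    keep_samples: bool = False,
) -> BootstrapResult:
    """Percentile bootstrap confidence intervals for every edge weight."""
    if B < 10:
        raise DomainError("need at least 10 bootstrap replicates")
    X, labels = _as_matrix(scores)
    n, p = X.shape
    net = select_network_ebic(X, config=config, node_labels=labels)
    iu = np.triu_indices(p, 1)
    point = net.weights[iu]
    rng = rng_from_seed(seed)
    draws = np.empty((B, len(point)))
    n_failed = 0
    for b in range(B):
        for _attempt in range(3):
            idx = rng.integers(0, n, size=n)
            try:
                W = select_network_ebic(X[idx], config=config, node_labels=labels).weights
                draws[b] = W[iu]
                break
            except (EstimationError, DomainError):
                n_failed += 1
        else:
            raise EstimationError(
                f"bootstrap estimation failed repeatedly ({n_failed} failures by replicate {b})"
            )
    alpha = 1.0 - level
    ci = np.column_stack(
        [np.quantile(draws, alpha / 2, axis=0), np.quantile(draws, 1 - alpha / 2, axis=0)]
    )
    return BootstrapResult(
        node_labels=labels,
        B=B,
        seed=seed,
        estimator=config,
        edge_index=[(labels[i], labels[j]) for i, j in zip(*iu)],
        edge_point=point,
        edge_ci=ci,
        level=level,
        edge_samples=draws if keep_samples else None,
        n_failed=n_failed,
    )


def cs_coefficient(
    drop_grid: np.ndarray,
    correlations: np.ndarray,
    threshold: float = 0.7,
    confidence: float = 0.95,
) -> float:
    """Largest drop proportion whose subset-EI correlations reach
    ``threshold`` with probability ``confidence`` — requiring the condition
    to hold at every smaller tested proportion as well; 0 if even the
    smallest drop fails."""
    ok = (correlations >= threshold).mean(axis=1) >= confidence
    cs = 0.0
    for d, good in zip(drop_grid, ok):
        if good:
            cs = float(d)
        else:
            break
    return cs


def casedrop_stability(
    scores,
    drop_grid=DEFAULT_DROP_GRID,
    B: int = DEFAULT_REPLICATES,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    threshold: float = 0.7,
    confidence: float = 0.95,
) -> BootstrapResult:
    """Case-dropping subset bootstrap of node expected influence.

    Correlation between subset and full-sample EI vectors is Spearman
    (rank-based, so invariant to monotone rescaling of EI); a degenerate
    (constant) EI vector counts as a failed replicate with correlation 0.
    """
    X, labels = _as_matrix(scores)
    n, p = X.shape
    drop_grid = np.asarray(sorted(drop_grid), dtype=float)
    if ((drop_grid <= 0) | (drop_grid >= 1)).any():
        raise DomainError("drop proportions must lie in (0, 1)")
    min_keep = int(np.ceil(n * (1 - drop_grid.max())))
    if min_keep < 3 * p:
        raise DomainError(
            f"largest drop proportion leaves {min_keep} subjects; need >= {3 * p}"
        )
    full_net = select_network_ebic(X, config=config, node_labels=labels)
    full_ei = full_net.weights.sum(axis=1)
    rng = rng_from_seed(seed)
    cors = np.zeros((len(drop_grid), B))
    n_failed = 0
    for di, d in enumerate(drop_grid):
        keep = int(round(n * (1 - d)))
        for b in range(B):
            idx = rng.permutation(n)[:keep]
            try:
                W = select_network_ebic(X[idx], config=config, node_labels=labels).weights
            except (EstimationError, DomainError):
                n_failed += 1
                cors[di, b] = 0.0
                continue
            ei = W.sum(axis=1)
            if np.ptp(ei) < 1e-14 or np.ptp(full_ei) < 1e-14:
                cors[di, b] = 0.0
                continue
            rho = stats.spearmanr(ei, full_ei).statistic
            cors[di, b] = 0.0 if np.isnan(rho) else float(rho)
    cs = cs_coefficient(drop_grid, cors, threshold=threshold, confidence=confidence)
    return BootstrapResult(
        node_labels=labels,
        B=B,
        seed=seed,
        estimator=config,
        drop_grid=drop_grid,
        casedrop_correlations=cors,
        cs_coefficient=cs,
        cs_threshold=threshold,
        cs_confidence=confidence,
        n_failed=n_failed,
    )
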