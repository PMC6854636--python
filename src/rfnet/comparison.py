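"""Permutation-based comparison of two estimated networks.

Observed statistics are computed from networks estimated on the two
datasets; the permutation null re-estimates both networks after relabeling
and recomputes every statistic, with the identical estimator configuration
throughout. Two designs are supported:

* independent — subjects are pooled and group labels permuted, preserving
  group sizes (for exposed vs non-exposed comparisons);
* paired — each subject's two occasion rows are swapped independently with
  probability 1/2 (for occasion-1 vs occasion-2 comparisons, valid when
  the joint distribution is exchangeable over time).

Statistics: the maximum absolute edge difference M (structure invariance),
the global expected-influence difference, and per-edge differences with
Benjamini-Hochberg adjusted permutation p-values. Pathway statistics from
:mod:`rfnet.paths` plug into the same engine. p-values use the add-one
rule (1 + exceedances) / (K + 1), two-tailed on the statistic magnitude,
so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rng import rng_from_seed
from .errors import DomainError, EstimationError
from .groupstats import bh_fdr
from .network import EstimatorConfig, NetworkModel, expected_influence, select_network_ebic
from .panels import ScorePanel

__all__ = [
    "NCTResult",
    "max_edge_difference",
    "nct_independent",
    "nct_paired",
    "edge_difference_tests",
]

DEFAULT_PERMUTATIONS = 5000


@dataclass
class NCTResult:
    """Observed statistics, permutation distributions and p-values."""

    variant: str
    node_labels: list[str]
    observed: dict[str, float]
    p_values: dict[str, float]
    perm: dict[str, np.ndarray]
    edge_diff: np.ndarray
    edge_p: np.ndarray | None
    edge_p_adjusted: np.ndarray | None
    K: int
    K_effective: int
    seed: int
    estimator: EstimatorConfig
    n_failed: int = 0
    network_a: NetworkModel | None = None
    network_b: NetworkModel | None = None

    def edge_table(self) -> pd.DataFrame:
        """Tidy per-edge differences with raw and adjusted p-values."""
        iu = np.triu_indices(len(self.node_labels), 1)
        rows = []
        for k, (i, j) in enumerate(zip(*iu)):
            rows.append(
                {
                    "node_a": self.node_labels[i],
                    "node_b": self.node_labels[j],
                    "difference": self.edge_diff[i, j],
                    "p": None if self.edge_p is None else self.edge_p[k],
                    "p_adjusted": None if self.edge_p_adjusted is None else self.edge_p_adjusted[k],
                }
            )
        return pd.DataFrame(rows)


def max_edge_difference(net_a: NetworkModel, net_b: NetworkModel) -> float:
    """Largest absolute edge-weight difference between two networks."""
    if net_a.node_labels != net_b.node_labels:
        raise DomainError("networks must share an identical node set")
    return float(np.abs(net_a.weights - net_b.weights).max())


StatFn = Callable[[np.ndarray, np.ndarray], dict[str, float]]


def _default_stats(labels: Sequence[str]) -> StatFn:
    p = len(labels)
    iu = np.triu_indices(p, 1)

    def fn(WA: np.ndarray, WB: np.ndarray) -> dict[str, float]:
        diff = WA - WB
        ei_a = float(np.triu(WA, 1).sum())
        ei_b = float(np.triu(WB, 1).sum())
        return {
            "M": float(np.abs(diff[iu]).max()),
            "global_ei_a": ei_a,
            "global_ei_b": ei_b,
            "delta_global_ei": ei_a - ei_b,
        }

    return fn


def _as_matrix(scores, group=None, occasion=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(scores, ScorePanel):
        return scores.matrix(group=group, occasion=occasion), list(scores.score_columns)
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=float), list(scores.columns)
    X = np.asarray(scores, dtype=float)
    return X, [f"v{i}" for i in range(X.shape[1])]


def _estimate_weights(X: np.ndarray, config: EstimatorConfig) -> np.ndarray:
    return select_network_ebic(X, config=config).weights


def permutation_network_test(
    XA: np.ndarray,
    XB: np.ndarray,
    variant: str,
    node_labels: list[str],
    K: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    stat_fn: StatFn | None = None,
    edge_tests: bool = True,
    pathway_target: str | None = None,
) -> NCTResult:
    """Generic two-network permutation engine (see module docstring).

    ``stat_fn`` maps two weight matrices to named statistics; difference
    statistics must be antisymmetric in (A, B) for the two-tailed rule to
    be meaningful. Names starting with ``global_ei_``, ``dp_`` or ``sp_``
    are treated as descriptive (no p-value). Setting ``pathway_target``
    additionally computes the direct- and shortest-pathway statistics to
    that node in the same permutation pass, which costs far less than a
    separate pathway comparison.
    """
    if K < 1:
        raise DomainError("need at least one permutation")
    if variant not in ("independent", "paired"):
        raise DomainError(f"unknown variant {variant!r}")
    if XA.shape[1] != XB.shape[1]:
        raise DomainError("score matrices must share columns")
    if variant == "paired" and XA.shape[0] != XB.shape[0]:
        raise DomainError("paired comparison needs matched subjects")
    stat_fn = stat_fn or _default_stats(node_labels)
    if pathway_target is not None:
        from .paths import _pathway_stat_fn  # deferred: paths imports this module

        base_fn, path_fn = stat_fn, _pathway_stat_fn(node_labels, pathway_target, "inverse-absolute")

        def stat_fn(WA, WB):  # noqa: F811 - deliberate shadowing
            return {**base_fn(WA, WB), **path_fn(WA, WB)}
    p = len(node_labels)
    iu = np.triu_indices(p, 1)

    net_a = select_network_ebic(XA, config=config, node_labels=list(node_labels))
    net_b = select_network_ebic(XB, config=config, node_labels=list(node_labels))
    WA, WB = net_a.weights, net_b.weights
    observed = stat_fn(WA, WB)
    D_obs = WA - WB

    rng = rng_from_seed(seed)
    nA = XA.shape[0]
    pooled = np.vstack([XA, XB]) if variant == "independent" else None
    perm_stats: dict[str, list[float]] = {k: [] for k in observed}
    edge_abs: list[np.ndarray] = []
    n_failed = 0
    for _ in range(K):
        if variant == "independent":
            idx = rng.permutation(pooled.shape[0])
            PA, PB = pooled[idx[:nA]], pooled[idx[nA:]]
        else:
            swap = rng.random(nA) < 0.5
            PA, PB = XA.copy(), XB.copy()
            PA[swap], PB[swap] = XB[swap], XA[swap]
        try:
            WPA = _estimate_weights(PA, config)
            WPB = _estimate_weights(PB, config)
        except EstimationError:
            n_failed += 1
            continue
        s = stat_fn(WPA, WPB)
        for key, val in s.items():
            perm_stats[key].append(val)
        if edge_tests:
            edge_abs.append(np.abs((WPA - WPB)[iu]))
    if n_failed > max(1, int(0.01 * K)):
        raise EstimationError(
            f"network estimation failed in {n_failed}/{K} permutations (> 1% tolerated)"
        )
    K_eff = K - n_failed
    perm = {k: np.asarray(v) for k, v in perm_stats.items()}

    p_values: dict[str, float] = {}
    for key, obs in observed.items():
        if key.startswith(("global_ei_", "dp_", "sp_")):
            continue  # per-network descriptives, not difference statistics
        exceed = int(np.sum(np.abs(perm[key]) >= abs(obs)))
        p_values[key] = (1 + exceed) / (K_eff + 1)

    edge_p = edge_p_adj = None
    if edge_tests:
        E = np.vstack(edge_abs) if edge_abs else np.empty((0, len(iu[0])))
        obs_abs = np.abs(D_obs[iu])
        exceed = (E >= obs_abs[None, :]).sum(axis=0)
        edge_p = (1 + exceed) / (K_eff + 1)
        edge_p_adj = bh_fdr(edge_p)

    return NCTResult(
        variant=variant,
        node_labels=list(node_labels),
        observed=observed,
        p_values=p_values,
        perm=perm,
        edge_diff=D_obs,
        edge_p=edge_p,
        edge_p_adjusted=edge_p_adj,
        K=K,
        K_effective=K_eff,
        seed=seed,
        estimator=config,
        n_failed=n_failed,
        network_a=net_a,
        network_b=net_b,
    )


def nct_independent(
    scores_a,
    scores_b,
    K: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    edge_tests: bool = True,
) -> NCTResult:
    """Independent-sample network comparison (group labels permuted)."""
    XA, labels_a = _as_matrix(scores_a)
    XB, labels_b = _as_matrix(scores_b)
    if labels_a != labels_b:
        raise DomainError("score columns differ between the two groups")
    return permutation_network_test(
        XA, XB, "independent", labels_a, K=K, seed=seed, config=config, edge_tests=edge_tests
    )


def nct_paired(
    scores_t1,
    scores_t2,
    K: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    edge_tests: bool = True,
) -> NCTResult:
    """Paired (occasion-swap) network comparison.

    Rows of the two inputs must describe the same subjects in the same
    order; pass a :class:`ScorePanel` through
    :meth:`~rfnet.panels.ScorePanel.paired_matrices` to guarantee matching.
    """
    XA, labels_a = _as_matrix(scores_t1)
    XB, labels_b = _as_matrix(scores_t2)
    if labels_a != labels_b:
        raise DomainError("score columns differ between occasions")
    if XA.shape[0] != XB.shape[0]:
        raise DomainError("unmatched subjects between occasions")
    return permutation_network_test(
        XA, XB, "paired", labels_a, K=K, seed=seed, config=config, edge_tests=edge_tests
    )


def edge_difference_tests(result: NCTResult) -> pd.DataFrame:
    """Per-edge permutation tests from a comparison result (raw + BH)."""
    if result.edge_p is None:
        raise DomainError("edge distributions were not retained; rerun with edge_tests=True")
    return result.edge_table()
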