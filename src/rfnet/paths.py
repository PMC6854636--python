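"""Pathways between resilience factors and general distress.

Two complementary summaries of how each RF connects to the GD node in an
estimated network:

* direct pathways — the RF-GD edge weight itself, summed (signed) over RFs
  into the DP statistic; more negative means stronger direct
  distress-dampening associations;
* shortest pathways — the minimal-length route from each RF to GD with
  edge length ``1/|w|``, so strong associations are short; the SP
  statistic sums the path lengths over RFs (lower = stronger), and each
  RF is classified direct / indirect / none depending on whether the
  optimal route is the single edge, a multi-edge route, or no route.

Unreachable RFs contribute a finite penalty (by default twice the largest
finite shortest-path length in the comparison) so SP stays defined on
disconnected permuted networks. Group and temporal comparisons of DP and
SP reuse the permutation engine of :mod:`rfnet.comparison`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._shortest import dijkstra, edge_lengths
from .errors import DomainError
from .comparison import NCTResult, _as_matrix, permutation_network_test
from .network import EstimatorConfig, NetworkModel

__all__ = [
    "PathwayResult",
    "direct_pathways",
    "shortest_pathways",
    "compare_pathways",
]

GD_DEFAULT = "GD"


@dataclass
class PathwayResult:
    """Per-RF pathway summaries for a single network."""

    target: str
    rf_labels: list[str]
    direct_weight: np.ndarray
    dp: float
    path_length: np.ndarray | None = None
    path_nodes: list[list[str] | None] | None = None
    classification: list[str] | None = None
    sp: float | None = None
    transform: str | None = None
    unreachable_penalty: float | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for i, rf in enumerate(self.rf_labels):
            row = {"rf": rf, "direct_weight": self.direct_weight[i]}
            if self.path_length is not None:
                row["length"] = self.path_length[i]
                row["class"] = self.classification[i]
                nodes = self.path_nodes[i]
                row["path"] = "->".join(nodes) if nodes else ""
            rows.append(row)
        return pd.DataFrame(rows)


def _target_index(net: NetworkModel, target: str) -> int:
    if target not in net.node_labels:
        raise DomainError(f"target node {target!r} not in network")
    return net.node_labels.index(target)


def direct_pathways(net: NetworkModel, target: str = GD_DEFAULT) -> PathwayResult:
    """Direct RF-target edge weights and their signed sum DP."""
    t = _target_index(net, target)
    rf_idx = [i for i in range(net.p) if i != t]
    w = net.weights[rf_idx, t]
    return PathwayResult(
        target=target,
        rf_labels=[net.node_labels[i] for i in rf_idx],
        direct_weight=w,
        dp=float(w.sum()),
    )


def _sp_lengths(W: np.ndarray, t: int, transform: str) -> np.ndarray:
    """Shortest-path lengths from every node to the target (undirected, so a
    single Dijkstra from the target suffices); inf if unreachable."""
    L = edge_lengths(W, transform=transform)
    dist, _ = dijkstra(L, t)
    return np.delete(dist, t)


def shortest_pathways(
    net: NetworkModel,
    target: str = GD_DEFAULT,
    transform: str = "inverse-absolute",
    unreachable_penalty: float | None = None,
) -> PathwayResult:
    """Shortest pathway from each RF to the target.

    ``unreachable_penalty`` defaults to twice the largest finite path
    length in this network (use :func:`joint_unreachable_penalty` to share
    a penalty across two networks under comparison); with no finite path at
    all the penalty falls back to 0.
    """
    t = _target_index(net, target)
    L = edge_lengths(net.weights, transform=transform)
    dist, paths_from_t = dijkstra(L, t)
    rf_idx = [i for i in range(net.p) if i != t]
    lengths = dist[rf_idx]
    finite = lengths[np.isfinite(lengths)]
    if unreachable_penalty is None:
        unreachable_penalty = float(2.0 * finite.max()) if len(finite) else 0.0
    nodes_out: list[list[str] | None] = []
    classes: list[str] = []
    total = 0.0
    direct = direct_pathways(net, target)
    for k, i in enumerate(rf_idx):
        if not np.isfinite(lengths[k]):
            nodes_out.append(None)
            classes.append("none")
            total += unreachable_penalty
            continue
        seq = list(reversed(paths_from_t[i]))  # undirected: reverse target->rf
        nodes_out.append([net.node_labels[v] for v in seq])
        classes.append("direct" if len(seq) == 2 else "indirect")
        total += float(lengths[k])
    lengths = np.where(np.isfinite(lengths), lengths, unreachable_penalty)
    return PathwayResult(
        target=target,
        rf_labels=direct.rf_labels,
        direct_weight=direct.direct_weight,
        dp=direct.dp,
        path_length=lengths,
        path_nodes=nodes_out,
        classification=classes,
        sp=float(total),
        transform=transform,
        unreachable_penalty=float(unreachable_penalty),
    )


def _pathway_stat_fn(node_labels: list[str], target: str, transform: str):
    if target not in node_labels:
        raise DomainError(f"target node {target!r} not among score columns")
    t = node_labels.index(target)

    def fn(WA: np.ndarray, WB: np.ndarray) -> dict[str, float]:
        wa = np.delete(WA[:, t], t)
        wb = np.delete(WB[:, t], t)
        la = _sp_lengths(WA, t, transform)
        lb = _sp_lengths(WB, t, transform)
        finite = np.concatenate([la[np.isfinite(la)], lb[np.isfinite(lb)]])
        # penalty shared by the pair so the SP difference is well defined
        penalty = float(2.0 * finite.max()) if len(finite) else 0.0
        sa = float(np.where(np.isfinite(la), la, penalty).sum())
        sb = float(np.where(np.isfinite(lb), lb, penalty).sum())
        dpa, dpb = float(wa.sum()), float(wb.sum())
        return {
            "dp_a": dpa,
            "dp_b": dpb,
            "delta_dp": dpa - dpb,
            "sp_a": sa,
            "sp_b": sb,
            "delta_sp": sa - sb,
        }

    return fn


def compare_pathways(
    scores_a,
    scores_b,
    variant: str = "independent",
    target: str = GD_DEFAULT,
    transform: str = "inverse-absolute",
    K: int = 5000,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
) -> NCTResult:
    """Permutation comparison of DP and SP between two datasets.

    ``variant="independent"`` permutes group labels; ``"paired"`` swaps
    occasions within subject (inputs must be row-matched). Both statistics
    are computed in the same permutation pass; p-values are two-tailed with
    the add-one rule.
    """
    XA, labels_a = _as_matrix(scores_a)
    XB, labels_b = _as_matrix(scores_b)
    if labels_a != labels_b:
        raise DomainError("score columns differ between the two datasets")
    return permutation_network_test(
        XA,
        XB,
        variant,
        labels_a,
        K=K,
        seed=seed,
        config=config,
        stat_fn=_pathway_stat_fn(labels_a, target, transform),
        edge_tests=False,
    )
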