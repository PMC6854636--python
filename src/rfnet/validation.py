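"""Synthetic-design calibration experiments.

These routines validate the whole pipeline against its own synthetic
ground truth: type-I error of the permutation comparisons under the null
scenario, power under the reduced-connectivity scenario, structural and
measurement recovery, and the behavior of the stability coefficient in
the strong-network and pure-noise extremes. They are what the test suite
and the reproduction script run; problem sizes default to the scaled-down
study sizes documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from ._rng import rng_from_seed
from .cohort import build_ground_truth, partial_to_correlation, sample_item_panel, sample_score_panel
from .comparison import permutation_network_test
from .measurement import (
    compute_factor_scores,
    estimate_thresholds,
    fit_single_factor_uls,
    polychoric_matrix,
    pool_measurement,
)
from .network import EstimatorConfig, select_network_ebic
from .panels import GROUPS, OCCASIONS
from .stability import casedrop_stability

__all__ = [
    "type_i_error_suite",
    "power_delta_ei",
    "edge_sign_recovery",
    "factor_score_recovery",
    "threshold_recovery",
    "stability_extremes",
]

MC_CONFIG = EstimatorConfig(n_lambda=25)

STATS = ("M", "delta_global_ei", "delta_dp", "delta_sp")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def type_i_error_suite(
    n_replicates: int = 200,
    K: int = 200,
    n_per_group: int = 300,
    seed: int = 0,
    config: EstimatorConfig = MC_CONFIG,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Rejection rates of every comparison statistic under the null.

    Both groups and both occasions share one network and equal means, so
    every detected difference is a false positive. Returns rates keyed
    ``independent_<stat>`` and ``paired_<stat>``.
    """
    truth = build_ground_truth("null")
    rejections = {f"{v}_{s}": 0 for v in ("independent", "paired") for s in STATS}
    seeds = _child_seeds(seed, n_replicates)
    for r, s in enumerate(seeds):
        panel = sample_score_panel(truth, {"CA+": n_per_group, "CA-": n_per_group}, seed=s)
        XA = panel.matrix(group="CA+", occasion="t1")
        XB = panel.matrix(group="CA-", occasion="t1")
        res = permutation_network_test(
            XA, XB, "independent", list(panel.score_columns),
            K=K, seed=s + 1, config=config, edge_tests=False, pathway_target="GD",
        )
        for stat in STATS:
            rejections[f"independent_{stat}"] += res.p_values[stat] < alpha
        x1, x2, _ = panel.paired_matrices(group="CA-")
        res = permutation_network_test(
            x1, x2, "paired", list(panel.score_columns),
            K=K, seed=s + 2, config=config, edge_tests=False, pathway_target="GD",
        )
        for stat in STATS:
            rejections[f"paired_{stat}"] += res.p_values[stat] < alpha
    return {k: v / n_replicates for k, v in rejections.items()}


def power_delta_ei(
    n_replicates: int = 100,
    K: int = 200,
    n_per_group: int = 500,
    seed: int = 0,
    config: EstimatorConfig = MC_CONFIG,
    alpha: float = 0.05,
) -> float:
    """Detection rate of the occasion-1 connectivity deficit.

    Under the reduced-connectivity scenario the exposed group's occasion-1
    positive edges are shrunk by the scenario factor (default 0.7); the
    global expected-influence comparison should flag this.
    """
    truth = build_ground_truth("adversity")
    hits = 0
    for s in _child_seeds(seed, n_replicates):
        panel = sample_score_panel(truth, {"CA+": n_per_group, "CA-": n_per_group}, seed=s)
        res = permutation_network_test(
            panel.matrix(group="CA+", occasion="t1"),
            panel.matrix(group="CA-", occasion="t1"),
            "independent",
            list(panel.score_columns),
            K=K,
            seed=s + 1,
            config=config,
            edge_tests=False,
        )
        hits += res.p_values["delta_global_ei"] < alpha
    return hits / n_replicates


def edge_sign_recovery(
    n_per_group: int = 5000,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(),
    min_weight: float = 0.15,
) -> float:
    """Fraction of strong true edges whose sign the estimated networks
    recover, pooled over the four group x occasion cells."""
    truth = build_ground_truth("adversity")
    panel = sample_score_panel(truth, {"CA+": n_per_group, "CA-": n_per_group}, seed=seed)
    good = total = 0
    for grp in GROUPS:
        for occ in OCCASIONS:
            W_true = truth.partial[(grp, occ)]
            net = select_network_ebic(panel, config=config, group=grp, occasion=occ)
            iu = np.triu_indices(len(truth.node_labels), 1)
            strong = np.abs(W_true[iu]) >= min_weight
            total += int(strong.sum())
            good += int(
                (np.sign(net.weights[iu][strong]) == np.sign(W_true[iu][strong])).sum()
            )
    return good / total


def factor_score_recovery(
    n_per_group: int = 1000,
    seed: int = 0,
    scale: str = "friendship_support",
    loading: float = 0.7,
) -> float:
    """Correlation between estimated factor scores and the true latents.

    Runs the full ordinal chain (thresholds -> polychorics -> ULS fit per
    occasion -> pooled parameters -> regression scores) on one scale with
    all loadings set to ``loading``.
    """
    truth = build_ground_truth("null")
    truth.loadings[scale] = np.full_like(truth.loadings[scale], loading)
    panel, latents = sample_item_panel(
        truth, {"CA+": n_per_group, "CA-": n_per_group}, seed=seed, return_latents=True
    )
    items = [i for i, m in truth.item_meta.items() if m.scale == scale]
    fits, ns = [], []
    for occ in OCCASIONS:
        sl = panel.slice(occasion=occ)
        R, _ = polychoric_matrix(sl, items)
        fit = fit_single_factor_uls(R, scale=scale, items=items)
        fit.thresholds = {i: estimate_thresholds(sl[i].to_numpy()) for i in items}
        fits.append(fit)
        ns.append(len(sl))
    pooled = pool_measurement(fits[0], fits[1], ns[0], ns[1])
    scores = compute_factor_scores(panel, pooled)
    return float(np.corrcoef(scores.to_numpy(), latents[scale].to_numpy())[0, 1])


def threshold_recovery(
    n_per_group: int = 5000, seed: int = 0, scale: str = "family_support"
) -> float:
    """Largest absolute threshold estimation error over one scale's items
    (the graded model leaves item propensities standard normal, so the
    marginal inverse-normal estimator is consistent)."""
    truth = build_ground_truth("null")
    panel = sample_item_panel(truth, {"CA+": n_per_group, "CA-": n_per_group}, seed=seed)
    items = [i for i, m in truth.item_meta.items() if m.scale == scale]
    worst = 0.0
    sl = panel.slice(occasion="t1")
    for item in items:
        est = estimate_thresholds(sl[item].to_numpy())
        true = truth.thresholds[item]
        if len(est) == len(true):
            worst = max(worst, float(np.abs(est - true).max()))
    return worst


def _strong_network(p: int = 11, weight: float = 0.3, seed: int = 7) -> np.ndarray:
    rng = rng_from_seed(seed)
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < 0.5:
                W[i, j] = W[j, i] = weight
    eig = np.linalg.eigvalsh(W).max()
    if eig > 0.9:
        W *= 0.9 / eig
    return W


def stability_extremes(
    n: int = 10000,
    B: int = 200,
    seed: int = 0,
    config: EstimatorConfig = EstimatorConfig(n_lambda=40),
) -> dict[str, float]:
    """CS coefficient in the two reference regimes: a strongly connected
    network sampled at large n (stability should saturate the tested grid)
    and pure noise (expected influence is degenerate, CS collapses)."""
    rng = rng_from_seed(seed)
    W = _strong_network()
    R = partial_to_correlation(W)
    X = rng.standard_normal((n, W.shape[0])) @ np.linalg.cholesky(R).T
    strong = casedrop_stability(X, B=B, seed=seed + 1, config=config)
    noise = rng.standard_normal((n, W.shape[0]))
    flat = casedrop_stability(noise, B=B, seed=seed + 2, config=config)
    return {"strong": strong.cs_coefficient, "noise": flat.cs_coefficient}
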