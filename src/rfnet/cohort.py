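"""Synthetic two-group, two-occasion cohort generator.

The generator encodes the study design the package targets: adolescents
with (CA+) and without (CA-) childhood adversity, measured at two occasions
(around ages 14 and 17), with ten resilience-factor (RF) nodes plus one
general-distress (GD) node. Ground truth is parameterized directly on the
partial-correlation scale (the Gaussian graphical model the downstream
estimators try to recover): a symmetric zero-diagonal matrix ``W`` per
group x occasion defines the precision matrix ``K = I - W`` whose inverse,
standardized, is the sampling correlation matrix.

Two scenarios are built in:

* ``"null"`` — one shared network and zero mean differences everywhere;
  used for type-I-error calibration of the permutation tests.
* ``"adversity"`` — the CA+ occasion-1 network has all positive edges
  shrunk by a constant factor (default 0.7) relative to the shared base
  network, CA+ means are shifted down on RFs and up on GD, and two nodes
  (aggression, expressive suppression) are binarized. This emulates the
  qualitative findings of the study design: lower RF levels and lower
  positive connectivity in the exposed group at the first occasion only.

Occasions are coupled through a Gaussian copula with a per-node
autocorrelation (default 0.5 — a free scenario parameter, not an empirical
value), so marginal group x occasion structure is exactly the truth matrix
while within-subject dependence is controlled separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import is_positive_definite
from ._rng import rng_from_seed
from .errors import DomainError
from .panels import GROUPS, OCCASIONS, ItemMeta, ItemPanel, ScorePanel

RF_NODES = [
    "friendship_support",
    "family_support",
    "family_cohesion",
    "negative_self_esteem",
    "positive_self_esteem",
    "reflective_rumination",
    "ruminative_brooding",
    "distress_tolerance",
    "aggression",
    "expressive_suppression",
]
GD_NODE = "GD"
DEFAULT_NODES = RF_NODES + [GD_NODE]

# item counts mirror the questionnaire structure of the target design
DEFAULT_ITEM_COUNTS = {
    "friendship_support": 5,
    "family_support": 5,
    "family_cohesion": 7,
    "negative_self_esteem": 5,
    "positive_self_esteem": 5,
    "reflective_rumination": 5,
    "ruminative_brooding": 5,
    "distress_tolerance": 5,
    "aggression": 4,
    "expressive_suppression": 1,
    GD_NODE: 41,
}
# scales whose raw items point away from the protective pole
REVERSED_SCALES = {
    "negative_self_esteem",
    "reflective_rumination",
    "ruminative_brooding",
    "aggression",
    "expressive_suppression",
}
DEFAULT_BINARIZE_CUT = {"aggression": -0.8, "expressive_suppression": -0.4}
DEFAULT_N_PER_GROUP = {"CA+": 631, "CA-": 499}


@dataclass
class GroundTruth:
    """True data-generating structure for a two-group, two-occasion cohort."""

    node_labels: list[str]
    partial: dict[tuple[str, str], np.ndarray]
    means: dict[tuple[str, str], np.ndarray]
    cross_occasion_rho: np.ndarray
    loadings: dict[str, np.ndarray] = field(default_factory=dict)
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    item_meta: dict[str, ItemMeta] = field(default_factory=dict)
    binarized_nodes: set[str] = field(default_factory=lambda: set(DEFAULT_BINARIZE_CUT))
    binarize_cut: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BINARIZE_CUT))
    seed: int | None = None
    repaired: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = len(self.node_labels)
        for cell in [(g, o) for g in GROUPS for o in OCCASIONS]:
            if cell not in self.partial:
                raise DomainError(f"partial matrix missing for cell {cell}")
            if cell not in self.means:
                raise DomainError(f"mean vector missing for cell {cell}")
            W = np.asarray(self.partial[cell], dtype=float)
            if W.shape != (p, p):
                raise DomainError(f"partial matrix for {cell} has shape {W.shape}, expected {(p, p)}")
            if not np.allclose(W, W.T):
                raise DomainError(f"partial matrix for {cell} is not symmetric")
            if np.abs(np.diag(W)).max() > 0:
                raise DomainError(f"partial matrix for {cell} has nonzero diagonal")
            if np.abs(W).max() >= 1:
                raise DomainError(f"partial correlations must lie in (-1, 1) for {cell}")
            if not is_positive_definite(np.eye(p) - W):
                raise DomainError(
                    f"implied precision matrix for group {cell[0]!r}, occasion {cell[1]!r} "
                    "is not positive definite"
                )
            self.partial[cell] = W
            self.means[cell] = np.asarray(self.means[cell], dtype=float)
        rho = np.asarray(self.cross_occasion_rho, dtype=float)
        if rho.ndim == 0:
            rho = np.full(p, float(rho))
        if rho.shape != (p,):
            raise DomainError("cross_occasion_rho must be scalar or one value per node")
        if (rho < 0).any() or (rho >= 1).any():
            raise DomainError("cross_occasion_rho must lie in [0, 1)")
        self.cross_occasion_rho = rho
        for item, th in self.thresholds.items():
            th = np.asarray(th, dtype=float)
            if th.ndim != 1 or (np.diff(th) <= 0).any():
                raise DomainError(f"thresholds for item {item!r} must be strictly increasing")
            self.thresholds[item] = th
        unknown = self.binarized_nodes - set(self.node_labels)
        if unknown:
            raise DomainError(f"binarized nodes not among node labels: {sorted(unknown)}")

    def correlation(self, group: str, occasion: str) -> np.ndarray:
        """Marginal correlation matrix implied by the cell's partial matrix."""
        return partial_to_correlation(self.partial[(group, occasion)])


def partial_to_correlation(W: np.ndarray) -> np.ndarray:
    """Map a partial-correlation matrix to the implied correlation matrix.

    Precision is parameterized as unit diagonal with off-diagonal ``-w_ij``,
    then inverted and standardized.
    """
    W = np.asarray(W, dtype=float)
    K = np.eye(W.shape[0]) - W
    np.fill_diagonal(K, 1.0)
    Sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(Sigma))
    R = Sigma / np.outer(d, d)
    return 0.5 * (R + R.T)


def _rescale_to_pd(W: np.ndarray, margin: float = 0.05) -> tuple[np.ndarray, bool]:
    """Shrink off-diagonal weights proportionally until I - W has its
    smallest eigenvalue >= ``margin``. Proportional rescaling preserves the
    sparsity pattern and relative edge strengths of a user matrix."""
    eig_max = np.linalg.eigvalsh(W).max()
    if eig_max <= 1.0 - margin:
        return W, False
    return W * ((1.0 - margin) / eig_max), True


def _base_network(
    rng: np.random.Generator,
    density: float,
    weight_range: tuple[float, float],
    gd_edge_prob: float,
    gd_weight_range: tuple[float, float],
) -> np.ndarray:
    p = len(DEFAULT_NODES)
    W = np.zeros((p, p))
    n_rf = len(RF_NODES)
    for i in range(n_rf):
        for j in range(i + 1, n_rf):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(*weight_range)
    gd = p - 1
    for i in range(n_rf):
        if rng.random() < gd_edge_prob:
            W[i, gd] = W[gd, i] = -rng.uniform(*gd_weight_range)
    return W


def _default_measurement(rng: np.random.Generator, loading: float = 0.7):
    """Per-scale loadings, per-item thresholds and item metadata."""
    loadings: dict[str, np.ndarray] = {}
    thresholds: dict[str, np.ndarray] = {}
    item_meta: dict[str, ItemMeta] = {}
    # restricted-range scales: raw items are harmful-oriented (reverse-coded)
    # and rarely endorsed, so the raw codes pile up in the lowest category
    skewed_cum_last = {"aggression": 0.08, "expressive_suppression": 0.34}
    for scale, n_items in DEFAULT_ITEM_COUNTS.items():
        lam = np.clip(loading + rng.uniform(-0.05, 0.05, size=n_items), 0.3, 0.95)
        loadings[scale] = lam
        for idx in range(n_items):
            item = f"{scale}__i{idx + 1}"
            k = 3 + (idx % 4)  # 3..6 answer categories
            if scale in skewed_cum_last:
                cum = np.linspace(0.25 * skewed_cum_last[scale], skewed_cum_last[scale], k - 1)
            else:
                cum = np.arange(1, k) / k
            thresholds[item] = stats.norm.ppf(cum)
            if scale in skewed_cum_last:
                reverse = True
            else:
                reverse = scale in REVERSED_SCALES and idx == n_items - 1
            item_meta[item] = ItemMeta(scale=scale, n_categories=k, reverse=reverse)
    return loadings, thresholds, item_meta


def build_ground_truth(config: dict[str, Any] | str | None = None) -> GroundTruth:
    """Build a :class:`GroundTruth` from a scenario name or config mapping.

    Config keys (all optional): ``scenario`` ("adversity", "null" or
    "empty"), ``seed`` (structure seed, default 0), ``density``,
    ``weight_range``, ``gd_edge_prob``, ``gd_weight_range``, ``shrink``
    (positive-edge shrink factor for the CA+ occasion-1 network),
    ``cross_occasion_rho``, ``effects`` (mapping with ``rf_shift``,
    ``gd_shift`` group mean effects), ``partial`` (user-supplied mapping of
    (group, occasion) to matrices, overrides generation).
    """
    if config is None:
        config = {}
    if isinstance(config, str):
        config = {"scenario": config}
    cfg = dict(config)
    scenario = cfg.pop("scenario", "adversity")
    seed = int(cfg.pop("seed", 0))
    rng = rng_from_seed(seed)
    density = float(cfg.pop("density", 0.35))
    weight_range = tuple(cfg.pop("weight_range", (0.1, 0.3)))
    gd_edge_prob = float(cfg.pop("gd_edge_prob", 0.6))
    gd_weight_range = tuple(cfg.pop("gd_weight_range", (0.1, 0.25)))
    shrink = float(cfg.pop("shrink", 0.7))
    rho = cfg.pop("cross_occasion_rho", 0.5)
    effects = dict(cfg.pop("effects", {}))
    rf_shift = float(effects.get("rf_shift", -0.25))
    gd_shift = float(effects.get("gd_shift", 0.35))
    user_partial = cfg.pop("partial", None)
    if cfg:
        raise DomainError(f"unknown ground-truth config keys: {sorted(cfg)}")

    p = len(DEFAULT_NODES)
    repaired: dict[tuple[str, str], bool] = {}
    cells = [(g, o) for g in GROUPS for o in OCCASIONS]

    if user_partial is not None:
        partial = {}
        for cell in cells:
            W = np.asarray(user_partial[cell], dtype=float)
            if not np.isfinite(W).all():
                raise DomainError(
                    f"user partial matrix for group {cell[0]!r}, occasion {cell[1]!r} "
                    "contains non-finite entries"
                )
            W, fixed = _rescale_to_pd(W)
            if not is_positive_definite(np.eye(p) - W):
                raise DomainError(
                    f"user partial matrix for group {cell[0]!r}, occasion {cell[1]!r} "
                    "is not positive definite even after proportional rescaling"
                )
            partial[cell] = W
            repaired[cell] = fixed
    elif scenario == "empty":
        partial = {cell: np.zeros((p, p)) for cell in cells}
    else:
        base = _base_network(rng, density, weight_range, gd_edge_prob, gd_weight_range)
        base, fixed = _rescale_to_pd(base)
        partial = {cell: base.copy() for cell in cells}
        repaired = {cell: fixed for cell in cells}
        if scenario == "adversity":
            shrunk = base.copy()
            pos = shrunk > 0
            shrunk[pos] *= shrink
            partial[("CA+", "t1")] = shrunk
        elif scenario != "null":
            raise DomainError(f"unknown scenario {scenario!r}")

    means = {cell: np.zeros(p) for cell in cells}
    if scenario == "adversity" and user_partial is None:
        gd = p - 1
        for occ in OCCASIONS:
            means[("CA+", occ)][:gd] = rf_shift
            means[("CA+", occ)][gd] = gd_shift
        # occasion effects shared by both groups: rumination worsens,
        # distress tolerance improves between occasions
        for grp in GROUPS:
            m = means[(grp, "t2")]
            m[DEFAULT_NODES.index("ruminative_brooding")] -= 0.15
            m[DEFAULT_NODES.index("reflective_rumination")] -= 0.15
            m[DEFAULT_NODES.index("distress_tolerance")] += 0.15

    loadings, thresholds, item_meta = _default_measurement(rng)
    return GroundTruth(
        node_labels=list(DEFAULT_NODES),
        partial=partial,
        means=means,
        cross_occasion_rho=np.asarray(rho, dtype=float),
        loadings=loadings,
        thresholds=thresholds,
        item_meta=item_meta,
        seed=seed,
        repaired=repaired,
    )


def _joint_covariance(R1: np.ndarray, R2: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """22x22 covariance coupling the two occasions via a Gaussian copula with
    per-node autocorrelation ``rho`` (cross-covariance diag equals rho)."""
    p = R1.shape[0]
    d = np.sqrt(rho)
    M = 0.5 * (R1 + R2)
    C = np.outer(d, d) * M
    full = np.block([[R1, C], [C.T, R2]])
    vals = np.linalg.eigvalsh(full)
    if vals.min() <= 1e-10:
        # attenuate the cross block just enough to restore PSD; marginals
        # stay exact, within-subject correlation shrinks slightly
        lo, hi = 0.0, 1.0
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            test = np.block([[R1, mid * C], [mid * C.T, R2]])
            if np.linalg.eigvalsh(test).min() > 1e-10:
                lo = mid
            else:
                hi = mid
        full = np.block([[R1, lo * C], [lo * C.T, R2]])
    return full


def _draw_latents(
    truth: GroundTruth, group: str, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw continuous latent node values for both occasions of one group."""
    p = len(truth.node_labels)
    R1 = truth.correlation(group, OCCASIONS[0])
    R2 = truth.correlation(group, OCCASIONS[1])
    full = _joint_covariance(R1, R2, truth.cross_occasion_rho)
    L = np.linalg.cholesky(full + 1e-12 * np.eye(2 * p))
    Z = rng.standard_normal((n, 2 * p)) @ L.T
    out = {}
    for oi, occ in enumerate(OCCASIONS):
        out[occ] = Z[:, oi * p : (oi + 1) * p] + truth.means[(group, occ)]
    return out


def _subject_ids(group: str, n: int) -> list[str]:
    tag = "A" if group == GROUPS[0] else "B"
    return [f"{tag}{i + 1:05d}" for i in range(n)]


def sample_score_panel(
    truth: GroundTruth,
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
) -> ScorePanel:
    """Sample a factor-score panel from the ground truth.

    Continuous nodes carry the latent values directly; binarized nodes are
    thresholded at the configured cut with 1 = protective (above the cut,
    since all nodes are oriented so that high = protective).
    """
    n_per_group = dict(n_per_group or DEFAULT_N_PER_GROUP)
    for grp in GROUPS:
        if n_per_group.get(grp, 0) < 2:
            raise DomainError(f"need at least 2 subjects in group {grp!r}")
    rng = rng_from_seed(seed)
    rows = []
    for grp in GROUPS:
        n = int(n_per_group[grp])
        ids = _subject_ids(grp, n)
        latents = _draw_latents(truth, grp, n, rng)
        for occ in OCCASIONS:
            Z = latents[occ].copy()
            for node in truth.binarized_nodes:
                j = truth.node_labels.index(node)
                Z[:, j] = (Z[:, j] > truth.binarize_cut[node]).astype(float)
            frame = pd.DataFrame(Z, columns=truth.node_labels)
            frame.insert(0, "occasion", occ)
            frame.insert(0, "group", grp)
            frame.insert(0, "subject_id", ids)
            rows.append(frame)
    data = pd.concat(rows, ignore_index=True)
    return ScorePanel(
        data=data,
        score_columns=list(truth.node_labels),
        binary_columns=set(truth.binarized_nodes),
    )


def sample_item_panel(
    truth: GroundTruth,
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
    return_latents: bool = False,
):
    """Sample ordinal item responses by graded discretization of the latents.

    For an item with standardized loading ``lam`` the response propensity is
    ``lam * latent + sqrt(1 - lam^2) * noise``; the category code counts the
    item thresholds lying below it, and reverse-coded items are flipped.
    """
    if not truth.loadings or not truth.thresholds:
        raise DomainError("ground truth carries no loadings/thresholds for item sampling")
    n_per_group = dict(n_per_group or DEFAULT_N_PER_GROUP)
    for grp in GROUPS:
        if n_per_group.get(grp, 0) < 2:
            raise DomainError(f"need at least 2 subjects in group {grp!r}")
    rng = rng_from_seed(seed)
    scales: dict[str, list[str]] = {}
    for item, meta in truth.item_meta.items():
        scales.setdefault(meta.scale, []).append(item)

    rows = []
    latent_rows = []
    for grp in GROUPS:
        n = int(n_per_group[grp])
        ids = _subject_ids(grp, n)
        latents = _draw_latents(truth, grp, n, rng)
        for occ in OCCASIONS:
            Z = latents[occ]
            cols: dict[str, np.ndarray] = {}
            for scale, items in scales.items():
                j = truth.node_labels.index(scale)
                f = Z[:, j]
                lam = truth.loadings[scale]
                for idx, item in enumerate(items):
                    l = float(lam[idx])
                    x = l * f + np.sqrt(1.0 - l * l) * rng.standard_normal(n)
                    code = np.searchsorted(truth.thresholds[item], x)
                    meta = truth.item_meta[item]
                    if meta.reverse:
                        code = (meta.n_categories - 1) - code
                    cols[item] = code.astype(int)
            frame = pd.DataFrame(cols)
            frame.insert(0, "occasion", occ)
            frame.insert(0, "group", grp)
            frame.insert(0, "subject_id", ids)
            rows.append(frame)
            lf = pd.DataFrame(Z, columns=truth.node_labels)
            lf.insert(0, "occasion", occ)
            lf.insert(0, "group", grp)
            lf.insert(0, "subject_id", ids)
            latent_rows.append(lf)
    data = pd.concat(rows, ignore_index=True)
    panel = ItemPanel(data=data, item_meta=dict(truth.item_meta))
    if return_latents:
        return panel, pd.concat(latent_rows, ignore_index=True)
    return panel
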