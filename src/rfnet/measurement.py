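"""Ordinal measurement layer: from item panels to factor scores.

The scoring chain is deliberately simple and fully transparent:

1. per-item thresholds from the inverse-normal of cumulative marginal
   proportions,
2. pairwise polychoric correlations (two-step maximum likelihood with the
   thresholds fixed),
3. a single-factor unweighted-least-squares fit to the polychoric matrix,
4. sample-size-weighted pooling of the occasion-specific fits so scores
   are comparable over time (a lightweight stand-in for measurement
   invariance constraints), and
5. Thurstone regression factor scores applied to standardized numeric
   item codes.

Scales with a restricted response range can instead be collapsed to a
binary protective / non-protective indicator (:func:`binarize_scale`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._linalg import smooth_correlation
from .errors import DegenerateItemError, DomainError, EstimationError
from .panels import ItemPanel, OCCASIONS

__all__ = [
    "PolychoricResult",
    "MeasurementModel",
    "estimate_thresholds",
    "polychoric_correlation",
    "polyserial_correlation",
    "polychoric_matrix",
    "fit_single_factor_uls",
    "pool_measurement",
    "compute_factor_scores",
    "binarize_scale",
]

HEYWOOD_COMMUNALITY = 0.998
_GL_NODES = 48  # Gauss-Legendre nodes per threshold interval; rectangle
# probabilities are then accurate to well below 1e-7 for |rho| <= 0.999
_CLIP = 8.0


@dataclass
class PolychoricResult:
    rho: float
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    loglik: float
    converged: bool


@dataclass
class MeasurementModel:
    """Single-factor measurement parameters for one scale."""

    scale: str
    items: list[str]
    loadings: np.ndarray
    thresholds: dict[str, np.ndarray]
    pooled: bool = False
    heywood_adjusted: bool = False
    degenerate: bool = False
    smoothed: bool = False

    @property
    def uniquenesses(self) -> np.ndarray:
        return 1.0 - self.loadings**2


def estimate_thresholds(codes: np.ndarray) -> np.ndarray:
    """Thresholds as inverse-normal cumulative proportions of the observed
    categories. Categories are re-indexed to the observed support so empty
    trailing categories do not produce infinities."""
    codes = np.asarray(codes)
    values, counts = np.unique(codes, return_counts=True)
    if len(values) < 2:
        raise DegenerateItemError(
            f"item has a single observed category ({values[0] if len(values) else 'empty'})"
        )
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return stats.norm.ppf(cum)


def _cell_probabilities(rho: float, tx: np.ndarray, ty: np.ndarray) -> np.ndarray:
    """Bivariate-normal rectangle probabilities for every contingency cell.

    The x-axis is integrated by Gauss-Legendre within each threshold
    interval against the conditional normal CDF in y.
    """
    ax = np.concatenate(([-_CLIP], np.clip(tx, -_CLIP, _CLIP), [_CLIP]))
    by = np.concatenate(([-_CLIP], np.clip(ty, -_CLIP, _CLIP), [_CLIP]))
    kx, ky = len(ax) - 1, len(by) - 1
    nodes, weights = np.polynomial.legendre.leggauss(_GL_NODES)
    s = np.sqrt(max(1.0 - rho * rho, 1e-12))
    P = np.empty((kx, ky))
    for i in range(kx):
        lo, hi = ax[i], ax[i + 1]
        mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        x = mid + half * nodes
        w = half * weights * stats.norm.pdf(x)
        cdf = stats.norm.cdf((by[None, :] - rho * x[:, None]) / s)
        P[i] = w @ (cdf[:, 1:] - cdf[:, :-1])
    return P


def polychoric_correlation(x: np.ndarray, y: np.ndarray) -> PolychoricResult:
    """Two-step polychoric correlation between two ordinal variables.

    Thresholds are fixed from the marginals; the correlation maximizes the
    bivariate-normal multinomial log-likelihood by bounded 1-D search.
    Non-convergence is flagged on the result instead of raising.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise DomainError("paired observations required")
    tx = estimate_thresholds(x)
    ty = estimate_thresholds(y)
    xv = np.unique(x)
    yv = np.unique(y)
    table = np.zeros((len(xv), len(yv)))
    for i, xi in enumerate(xv):
        for j, yj in enumerate(yv):
            table[i, j] = np.sum((x == xi) & (y == yj))

    def negll(rho: float) -> float:
        P = np.clip(_cell_probabilities(rho, tx, ty), 1e-12, None)
        return -float(np.sum(table * np.log(P)))

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded")
    converged = bool(res.success)
    return PolychoricResult(
        rho=float(res.x),
        thresholds_x=tx,
        thresholds_y=ty,
        loglik=-float(res.fun),
        converged=converged,
    )


def polyserial_correlation(cont: np.ndarray, ordinal: np.ndarray) -> float:
    """Two-step moment polyserial estimate between a continuous and an
    ordinal variable: Pearson r rescaled by sd(y) / sum of threshold
    densities (for a binary item this is the classic biserial correction)."""
    cont = np.asarray(cont, dtype=float)
    ordinal = np.asarray(ordinal)
    tau = estimate_thresholds(ordinal)
    codes = ordinal.astype(float)
    r = np.corrcoef(cont, codes)[0, 1]
    rho = r * codes.std(ddof=0) / stats.norm.pdf(tau).sum()
    return float(np.clip(rho, -0.999, 0.999))


def polychoric_matrix(panel: pd.DataFrame | np.ndarray, items: list[str] | None = None):
    """Pairwise polychoric correlation matrix for a set of ordinal items.

    Returns ``(R, smoothed)``; the matrix is eigenvalue-clipped back to
    positive definiteness when the pairwise estimates are incompatible.
    """
    if isinstance(panel, np.ndarray):
        frame = pd.DataFrame(panel, columns=items or [f"x{i}" for i in range(panel.shape[1])])
    else:
        frame = panel[items] if items is not None else panel
    cols = list(frame.columns)
    if len(cols) < 2:
        raise DomainError("need at least 2 items for a correlation matrix")
    for c in cols:
        vals = np.unique(frame[c].to_numpy())
        if len(vals) < 2:
            raise DegenerateItemError(f"item {c!r} has a single observed category")
    p = len(cols)
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            res = polychoric_correlation(frame[cols[i]].to_numpy(), frame[cols[j]].to_numpy())
            R[i, j] = R[j, i] = res.rho
    R, smoothed = smooth_correlation(R)
    return R, smoothed


def fit_single_factor_uls(R: np.ndarray, scale: str = "", items: list[str] | None = None) -> MeasurementModel:
    """Single-factor fit minimizing squared off-diagonal residuals of
    ``R - a a^T`` (unweighted least squares).

    The loading sign is fixed so the mean loading is positive. Communalities
    at or above the Heywood bound are clamped to 0.998 and flagged. An
    identity-like input yields zero loadings with ``degenerate=True``.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if p < 2:
        raise DomainError("single-factor fit needs at least 2 items")
    items = items or [f"x{i}" for i in range(p)]
    mask = ~np.eye(p, dtype=bool)
    if p == 2:
        # identified only under an equal-loading constraint
        r = R[0, 1]
        a = np.full(2, np.sign(r) * np.sqrt(min(abs(r), HEYWOOD_COMMUNALITY)))
        heywood = abs(r) > HEYWOOD_COMMUNALITY
        a = np.abs(a) if a.sum() < 0 else a
        return MeasurementModel(
            scale=scale, items=list(items), loadings=a, thresholds={},
            heywood_adjusted=bool(heywood), degenerate=bool(abs(r) < 1e-12),
        )

    if np.abs(R[mask]).max() < 1e-8:
        # no common variance to explain; any one-spike solution would be an
        # equally good ULS optimum, so report the zero solution and flag it
        return MeasurementModel(
            scale=scale, items=list(items), loadings=np.zeros(p), thresholds={},
            degenerate=True,
        )
    vals, vecs = np.linalg.eigh(R)
    a0 = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))

    def resid(a: np.ndarray) -> np.ndarray:
        return (R - np.outer(a, a))[mask]

    sol = optimize.least_squares(resid, a0, method="lm", xtol=1e-12, ftol=1e-12)
    if not sol.success:  # pragma: no cover - LM on smooth quartic rarely fails
        raise EstimationError(f"ULS factor fit failed: {sol.message}")
    a = sol.x
    if a.mean() < 0:
        a = -a
    heywood = np.abs(a) ** 2 > HEYWOOD_COMMUNALITY
    if heywood.any():
        a = np.sign(a) * np.minimum(np.abs(a), np.sqrt(HEYWOOD_COMMUNALITY))
    degenerate = bool(np.abs(a).max() < 1e-6)
    return MeasurementModel(
        scale=scale,
        items=list(items),
        loadings=a,
        thresholds={},
        heywood_adjusted=bool(heywood.any()),
        degenerate=degenerate,
    )


def pool_measurement(
    fit_t1: MeasurementModel, fit_t2: MeasurementModel, n_t1: int, n_t2: int
) -> MeasurementModel:
    """Sample-size-weighted pooling of two occasion-specific fits.

    Equating loadings and thresholds across occasions keeps factor scores on
    one scale so mean-level change is interpretable.
    """
    if fit_t1.items != fit_t2.items:
        raise DomainError(
            f"item mismatch between occasions: {fit_t1.items} vs {fit_t2.items}"
        )
    w1 = n_t1 / (n_t1 + n_t2)
    w2 = 1.0 - w1
    loadings = w1 * fit_t1.loadings + w2 * fit_t2.loadings
    thresholds = {}
    for item in fit_t1.thresholds:
        t1 = fit_t1.thresholds[item]
        t2 = fit_t2.thresholds[item]
        if t1.shape == t2.shape:
            thresholds[item] = w1 * t1 + w2 * t2
        else:  # observed support differed between occasions; keep the richer one
            thresholds[item] = t1 if len(t1) >= len(t2) else t2
    return MeasurementModel(
        scale=fit_t1.scale,
        items=list(fit_t1.items),
        loadings=loadings,
        thresholds=thresholds,
        pooled=True,
        heywood_adjusted=fit_t1.heywood_adjusted or fit_t2.heywood_adjusted,
        smoothed=fit_t1.smoothed or fit_t2.smoothed,
    )


def compute_factor_scores(
    panel: ItemPanel,
    model: MeasurementModel,
    R: np.ndarray | None = None,
    standardize: bool = True,
) -> pd.Series:
    """Thurstone regression factor scores for one scale.

    Weights are ``R^{-1} a`` applied to numeric item codes standardized with
    occasion-pooled means and SDs (so genuine mean-level change between
    occasions survives scoring). Reverse-coded items are flipped first so
    that high always means protective. The returned series is standardized
    to mean 0, SD 1 over the full panel (disable with ``standardize=False``
    to keep the raw linear composite).
    """
    missing = [i for i in model.items if i not in panel.data.columns]
    if missing:
        raise DomainError(f"model items missing from panel: {missing}")
    X = panel.data[model.items].to_numpy(dtype=float)
    for idx, item in enumerate(model.items):
        meta = panel.item_meta[item]
        if meta.reverse:
            X[:, idx] = (meta.n_categories - 1) - X[:, idx]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if (sd < 1e-12).any():
        bad = model.items[int(np.argmax(sd < 1e-12))]
        raise DomainError(f"constant item column {bad!r}")
    Z = (X - mu) / sd
    if R is None:
        R = np.corrcoef(Z.T) if len(model.items) > 1 else np.ones((1, 1))
        R, _ = smooth_correlation(R)
    weights = np.linalg.solve(R, model.loadings)
    scores = Z @ weights
    if standardize:
        s = scores.std(ddof=0)
        if s < 1e-12:
            raise DomainError(f"degenerate factor scores for scale {model.scale!r}")
        scores = (scores - scores.mean()) / s
    return pd.Series(scores, index=panel.data.index, name=model.scale)


def binarize_scale(values, rule="any-endorsement") -> tuple[np.ndarray, bool]:
    """Collapse a restricted-range scale to a 0/1 protective indicator.

    ``rule`` is either the string ``"any-endorsement"`` (any response above
    the lowest category marks the non-protective class — e.g. endorsing any
    aggression item) or a numeric cut-point (values strictly above the cut
    are protective, matching the orientation where high = protective).
    Returns ``(binary, warn)`` where ``warn`` flags an all-one-class output.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if isinstance(rule, str):
        if rule != "any-endorsement":
            raise DomainError(f"unknown binarization rule {rule!r}")
        binary = (arr.max(axis=1) <= 0).astype(int)
    else:
        if arr.shape[1] != 1:
            raise DomainError("cut-point rule expects a single score column")
        binary = (arr[:, 0] > float(rule)).astype(int)
    warn = bool(binary.min() == binary.max())
    return binary, warn


def score_item_panel(panel: ItemPanel, binarize: dict[str, object] | None = None):
    """Score every scale of an item panel into factor scores.

    Multi-item scales go through the polychoric -> ULS -> pooled ->
    regression-score chain (fit separately per occasion, then pooled);
    single-item scales use the standardized (reverse-corrected) item code.
    ``binarize`` maps scale names to :func:`binarize_scale` rules applied to
    the items of that scale. Returns ``(ScorePanel, models)``.
    """
    from .panels import ScorePanel  # local import to avoid cycle at module load

    binarize = dict(binarize or {})
    scores: dict[str, pd.Series | np.ndarray] = {}
    models: dict[str, MeasurementModel] = {}
    binary_cols: set[str] = set()
    for scale, item_list in panel.scales.items():
        if scale in binarize:
            # any-endorsement needs harmful-oriented codes: raw for
            # reverse-coded items, flipped otherwise
            sub = panel.data[item_list].to_numpy(dtype=float)
            for idx, item in enumerate(item_list):
                meta = panel.item_meta[item]
                if not meta.reverse:
                    sub[:, idx] = (meta.n_categories - 1) - sub[:, idx]
            binary, warn = binarize_scale(sub, binarize[scale])
            scores[scale] = binary.astype(float)
            binary_cols.add(scale)
            continue
        if len(item_list) == 1:
            item = item_list[0]
            meta = panel.item_meta[item]
            col = panel.data[item].to_numpy(dtype=float)
            if meta.reverse:
                col = (meta.n_categories - 1) - col
            sd = col.std(ddof=0)
            if sd < 1e-12:
                raise DomainError(f"constant single-item scale {scale!r}")
            scores[scale] = (col - col.mean()) / sd
            continue
        fits = []
        ns = []
        for occ in OCCASIONS:
            sl = panel.slice(occasion=occ)
            R, smoothed = polychoric_matrix(sl, item_list)
            fit = fit_single_factor_uls(R, scale=scale, items=item_list)
            fit.smoothed = smoothed
            fit.thresholds = {
                item: estimate_thresholds(sl[item].to_numpy()) for item in item_list
            }
            fits.append(fit)
            ns.append(len(sl))
        pooled = pool_measurement(fits[0], fits[1], ns[0], ns[1])
        models[scale] = pooled
        scores[scale] = compute_factor_scores(panel, pooled)
    data = panel.data[["subject_id", "group", "occasion"]].copy()
    for scale in panel.scales:
        data[scale] = np.asarray(scores[scale])
    return (
        ScorePanel(data=data, score_columns=list(panel.scales), binary_columns=binary_cols),
        models,
    )
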