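"""Measurement layer: thresholds, polychorics, ULS factor fits, pooling,
regression factor scores and binarization, checked against closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rfnet.errors import DegenerateItemError, DomainError
from rfnet.measurement import (
    MeasurementModel,
    binarize_scale,
    compute_factor_scores,
    estimate_thresholds,
    fit_single_factor_uls,
    polychoric_correlation,
    polychoric_matrix,
    pool_measurement,
    score_item_panel,
)
from rfnet.panels import ItemMeta, ItemPanel


# --- thresholds -----------------------------------------------------------

def test_thresholds_inverse_normal_of_cumulative_proportions():
    assert estimate_thresholds(np.repeat([0, 1], [50, 50])) == pytest.approx([0.0])
    np.testing.assert_allclose(
        estimate_thresholds(np.repeat([0, 1, 2], [250, 500, 250])),
        [-0.6744897501960817, 0.6744897501960817],
    )


def test_thresholds_single_category_errors():
    with pytest.raises(DegenerateItemError):
        estimate_thresholds(np.zeros(1000, dtype=int))


# --- polychoric -----------------------------------------------------------

def test_tetrachoric_closed_form_zero_thresholds():
    x = np.repeat([0, 0, 1, 1], [350, 150, 150, 350])
    y = np.repeat([0, 1, 0, 1], [350, 150, 150, 350])
    res = polychoric_correlation(x, y)
    assert res.converged
    assert res.thresholds_x == pytest.approx([0.0])
    assert res.rho == pytest.approx(np.sin(2 * np.pi * (0.35 - 0.25)), abs=1e-3)


def test_polychoric_independent_table_is_zero():
    # outer product of margins: 600x0.5 / 400x0.5 split
    x = np.repeat([0, 0, 1, 1], [300, 300, 200, 200])
    y = np.repeat([0, 1, 0, 1], [300, 300, 200, 200])
    assert abs(polychoric_correlation(x, y).rho) < 1e-3


def test_polychoric_recovers_simulated_correlation(rng):
    z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=10000)
    x = np.digitize(z[:, 0], [-0.6, 0.6])
    y = np.digitize(z[:, 1], [-0.3, 0.8])
    assert 0.45 < polychoric_correlation(x, y).rho < 0.55


def test_polychoric_matrix_consistency_and_smoothing(rng):
    z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=2000)
    x = np.digitize(z[:, 0], [0.0])
    y = np.digitize(z[:, 1], [0.2])
    R, smoothed = polychoric_matrix(pd.DataFrame({"a": x, "b": y}))
    assert R[0, 1] == pytest.approx(polychoric_correlation(x, y).rho)
    # near-singular pairwise input gets clipped back to PD
    bad = np.array([[1, 0.99, -0.99], [0.99, 1, 0.9], [-0.99, 0.9, 1]])
    from rfnet._linalg import smooth_correlation

    fixed, did = smooth_correlation(bad)
    assert did and np.linalg.eigvalsh(fixed).min() >= 1e-4 - 1e-12


def test_polychoric_matrix_names_degenerate_item():
    frame = pd.DataFrame({"ok": [0, 1] * 50, "flat": [2] * 100})
    with pytest.raises(DegenerateItemError, match="flat"):
        polychoric_matrix(frame)


# --- single-factor ULS ----------------------------------------------------

def test_uls_equicorrelation_closed_form():
    R = np.full((5, 5), 0.49)
    np.fill_diagonal(R, 1.0)
    fit = fit_single_factor_uls(R)
    np.testing.assert_allclose(fit.loadings, 0.7, atol=1e-6)


def test_uls_identity_is_degenerate():
    fit = fit_single_factor_uls(np.eye(4))
    np.testing.assert_array_equal(fit.loadings, 0.0)
    assert fit.degenerate


def test_uls_exact_on_noiseless_rank_one_input():
    a = np.array([0.9, 0.8, 0.5])
    R = np.outer(a, a)
    np.fill_diagonal(R, 1.0)
    fit = fit_single_factor_uls(R)
    np.testing.assert_allclose(fit.loadings, a, atol=1e-4)


def test_uls_heywood_clamped_and_flagged():
    a = np.array([0.999999, 0.8, 0.7, 0.6])
    R = np.outer(a, a)
    np.fill_diagonal(R, 1.0)
    fit = fit_single_factor_uls(R)
    assert fit.heywood_adjusted
    assert (np.abs(fit.loadings) ** 2 <= 0.998 + 1e-12).all()


# --- pooling --------------------------------------------------------------

def _model(loadings, items=None, thresholds=None):
    loadings = np.asarray(loadings, dtype=float)
    items = items or [f"i{k}" for k in range(len(loadings))]
    return MeasurementModel(
        scale="s", items=items, loadings=loadings, thresholds=thresholds or {}
    )


def test_pooling_weighted_means():
    m1, m2 = _model([0.6, 0.6]), _model([0.8, 0.8])
    np.testing.assert_allclose(pool_measurement(m1, m2, 100, 100).loadings, 0.7)
    np.testing.assert_allclose(pool_measurement(m1, m2, 100, 300).loadings, 0.75)
    same = pool_measurement(m1, m1, 50, 70)
    np.testing.assert_allclose(same.loadings, m1.loadings)
    assert same.pooled


def test_pooling_item_mismatch_errors():
    with pytest.raises(DomainError):
        pool_measurement(_model([0.5], ["a"]), _model([0.5], ["b"]), 10, 10)


# --- factor scores --------------------------------------------------------

def _equicorr_panel():
    """Panel whose standardized item codes are exactly +/-1 per subject."""
    items = [f"i{k}" for k in range(5)]
    rows = []
    for occ in ("t1", "t2"):
        for s, val in zip("abcd", [2, 2, 0, 0]):
            rows.append({"subject_id": s, "group": "CA+", "occasion": occ, **{i: val for i in items}})
    meta = {i: ItemMeta(scale="s", n_categories=3) for i in items}
    return ItemPanel(data=pd.DataFrame(rows), item_meta=meta), items


def test_regression_scores_equicorrelation_closed_form():
    panel, items = _equicorr_panel()
    R = np.full((5, 5), 0.49)
    np.fill_diagonal(R, 1.0)
    model = _model([0.7] * 5, items)
    raw = compute_factor_scores(panel, model, R=R, standardize=False)
    # weight per item 0.7/2.96; a subject at +1 SD on every item scores 5x that
    expected = 5 * 0.7 / 2.96
    up = raw[panel.data["subject_id"] == "a"]
    down = raw[panel.data["subject_id"] == "c"]
    np.testing.assert_allclose(up, expected, atol=1e-10)
    np.testing.assert_allclose(down, -expected, atol=1e-10)  # symmetric subjects


def test_scores_invariant_to_item_reversal():
    panel, items = _equicorr_panel()
    R = np.full((5, 5), 0.49)
    np.fill_diagonal(R, 1.0)
    base = compute_factor_scores(panel, _model([0.7] * 5, items), R=R)
    flipped = panel.data.copy()
    flipped[items[0]] = 2 - flipped[items[0]]
    meta = dict(panel.item_meta)
    meta[items[0]] = ItemMeta(scale="s", n_categories=3, reverse=True)
    panel2 = ItemPanel(data=flipped, item_meta=meta)
    again = compute_factor_scores(panel2, _model([0.7] * 5, items), R=R)
    np.testing.assert_allclose(base.to_numpy(), again.to_numpy(), atol=1e-12)


def test_constant_item_column_errors():
    panel, items = _equicorr_panel()
    data = panel.data.copy()
    data[items[2]] = 1
    panel2 = ItemPanel(data=data, item_meta=panel.item_meta)
    with pytest.raises(DomainError, match="i2"):
        compute_factor_scores(panel2, _model([0.7] * 5, items))


# --- binarization ---------------------------------------------------------

def test_binarize_any_endorsement():
    binary, warn = binarize_scale(np.array([0, 0, 2, 3]), "any-endorsement")
    np.testing.assert_array_equal(binary, [1, 1, 0, 0])
    assert not warn


def test_binarize_constant_warns():
    binary, warn = binarize_scale(np.zeros(5), "any-endorsement")
    assert warn and binary.all()


def test_binarize_cut_rule():
    binary, _ = binarize_scale(np.array([-1.0, -0.2, 0.4]), rule=-0.5)
    np.testing.assert_array_equal(binary, [0, 1, 1])


# --- end-to-end scoring ---------------------------------------------------

def test_protective_class_is_majority_on_restricted_scales(adversity_truth):
    """Rarely-endorsed harmful behaviors put most subjects in the
    protective (=1) class, mirroring the coding convention where the
    larger 'Low' class scores 1."""
    from rfnet.cohort import sample_item_panel

    panel = sample_item_panel(adversity_truth, {"CA+": 400, "CA-": 400}, seed=21)
    scored, _ = score_item_panel(
        panel,
        binarize={"aggression": "any-endorsement", "expressive_suppression": "any-endorsement"},
    )
    for node in ("aggression", "expressive_suppression"):
        assert scored.data[node].mean() > 0.5
        assert set(np.unique(scored.data[node])) <= {0.0, 1.0}
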