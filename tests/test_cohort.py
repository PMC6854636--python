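"""Synthetic-cohort generator: scenario structure, sampling fidelity,
determinism and the graded item-discretization rule."""

import numpy as np
import pytest

from rfnet.cohort import (
    DEFAULT_NODES,
    GD_NODE,
    build_ground_truth,
    partial_to_correlation,
    sample_item_panel,
    sample_score_panel,
)
from rfnet.errors import DomainError
from rfnet.measurement import polychoric_correlation
from rfnet.panels import GROUPS, OCCASIONS
from scipy import stats


def test_null_scenario_has_identical_cells(null_truth):
    cells = [(g, o) for g in GROUPS for o in OCCASIONS]
    base = null_truth.partial[cells[0]]
    for cell in cells[1:]:
        np.testing.assert_array_equal(null_truth.partial[cell], base)
        np.testing.assert_array_equal(null_truth.means[cell], null_truth.means[cells[0]])


def test_adversity_scenario_lowers_positive_connectivity_at_occasion_one(adversity_truth):
    def global_ei(W):
        return np.triu(W, 1).sum()

    ei = {cell: global_ei(adversity_truth.partial[cell]) for cell in adversity_truth.partial}
    assert ei[("CA+", "t1")] < ei[("CA-", "t1")]
    # remaining cells share the base network
    np.testing.assert_array_equal(
        adversity_truth.partial[("CA+", "t2")], adversity_truth.partial[("CA-", "t2")]
    )
    np.testing.assert_array_equal(
        adversity_truth.partial[("CA-", "t1")], adversity_truth.partial[("CA-", "t2")]
    )


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_random_truth_implies_positive_definite_precision(seed):
    truth = build_ground_truth({"scenario": "adversity", "seed": seed, "density": 0.3})
    for W in truth.partial.values():
        K = np.eye(len(DEFAULT_NODES)) - W
        assert np.linalg.eigvalsh(K).min() > 0  # eigenvalue oracle


def test_user_matrix_failing_repair_names_cell():
    p = len(DEFAULT_NODES)
    bad = np.full((p, p), np.nan)
    np.fill_diagonal(bad, 0.0)
    cells = {(g, o): np.zeros((p, p)) for g in GROUPS for o in OCCASIONS}
    cells[("CA+", "t2")] = bad
    with pytest.raises(DomainError, match="CA\\+"):
        build_ground_truth({"partial": cells})


def test_score_panel_seed_determinism(null_truth):
    a = sample_score_panel(null_truth, {"CA+": 2, "CA-": 2}, seed=7)
    b = sample_score_panel(null_truth, {"CA+": 2, "CA-": 2}, seed=7)
    assert a.data.equals(b.data)
    c = sample_score_panel(null_truth, {"CA+": 2, "CA-": 2}, seed=8)
    assert not a.data.equals(c.data)


def test_sampled_partials_converge_to_truth(null_truth):
    """Monte-Carlo check: subsystem partial correlations of the continuous
    nodes match the truth-implied values at n = 5000."""
    panel = sample_score_panel(null_truth, {"CA+": 5000, "CA-": 5000}, seed=3)
    cont = [n for n in null_truth.node_labels if n not in null_truth.binarized_nodes]
    idx = [null_truth.node_labels.index(n) for n in cont]
    R_true = partial_to_correlation(null_truth.partial[("CA-", "t1")])[np.ix_(idx, idx)]
    K_true = np.linalg.inv(R_true)
    d = np.sqrt(np.diag(K_true))
    P_true = -K_true / np.outer(d, d)
    X = panel.matrix(group="CA-", occasion="t1")[:, idx]
    K_hat = np.linalg.inv(np.corrcoef(X.T))
    dh = np.sqrt(np.diag(K_hat))
    P_hat = -K_hat / np.outer(dh, dh)
    iu = np.triu_indices(len(cont), 1)
    err = np.abs(P_hat[iu] - P_true[iu])
    assert (err < 0.05).mean() >= 0.95


def test_zero_cross_occasion_rho_gives_independent_occasions(null_truth):
    truth = build_ground_truth({"scenario": "null", "cross_occasion_rho": 0.0})
    panel = sample_score_panel(truth, {"CA+": 5000, "CA-": 5000}, seed=5)
    x1, x2, _ = panel.paired_matrices(group="CA-")
    cont_idx = [
        truth.node_labels.index(n)
        for n in truth.node_labels
        if n not in truth.binarized_nodes
    ]
    for j in cont_idx:
        assert abs(np.corrcoef(x1[:, j], x2[:, j])[0, 1]) < 0.05


def test_binarized_prevalence_matches_threshold(null_truth):
    """Prevalence of the protective class equals Phi(-cut) within 99%
    binomial bounds on the zero-mean cells."""
    n = 4000
    panel = sample_score_panel(null_truth, {"CA+": n, "CA-": n}, seed=9)
    d = panel.slice("CA-", "t1")
    for node in sorted(null_truth.binarized_nodes):
        p_expect = stats.norm.cdf(-null_truth.binarize_cut[node])
        se = np.sqrt(p_expect * (1 - p_expect) / n)
        assert abs(d[node].mean() - p_expect) < 2.576 * se * 1.5


def test_minimum_group_size_enforced(null_truth):
    with pytest.raises(DomainError):
        sample_score_panel(null_truth, {"CA+": 1, "CA-": 5}, seed=0)


def test_item_codes_count_thresholds_below_propensity(adversity_truth):
    """With loadings forced to ~1 the item code is exactly the number of
    thresholds below the latent value (noise variance ~ 0)."""
    truth = build_ground_truth("adversity")
    scale = "friendship_support"
    truth.loadings[scale] = np.full_like(truth.loadings[scale], 0.999999)
    panel, latents = sample_item_panel(
        truth, {"CA+": 50, "CA-": 50}, seed=2, return_latents=True
    )
    items = [i for i, m in truth.item_meta.items() if m.scale == scale]
    f = latents[scale].to_numpy()
    for item in items:
        expected = np.searchsorted(truth.thresholds[item], f)
        np.testing.assert_array_equal(panel.data[item].to_numpy(), expected)


def test_reverse_coded_items_are_flipped(adversity_truth):
    truth = build_ground_truth("adversity")
    scale = "ruminative_brooding"  # last item reverse-coded
    truth.loadings[scale] = np.full_like(truth.loadings[scale], 0.999999)
    panel, latents = sample_item_panel(
        truth, {"CA+": 40, "CA-": 40}, seed=4, return_latents=True
    )
    items = [i for i, m in truth.item_meta.items() if m.scale == scale]
    rev = items[-1]
    meta = truth.item_meta[rev]
    assert meta.reverse
    f = latents[scale].to_numpy()
    expected = (meta.n_categories - 1) - np.searchsorted(truth.thresholds[rev], f)
    np.testing.assert_array_equal(panel.data[rev].to_numpy(), expected)


def test_same_scale_items_recover_implied_polychoric():
    """Two items with loadings 0.7 on one factor imply an inter-item
    polychoric correlation of 0.49."""
    truth = build_ground_truth("null")
    scale = "family_support"
    truth.loadings[scale] = np.full_like(truth.loadings[scale], 0.7)
    panel = sample_item_panel(truth, {"CA+": 2500, "CA-": 2500}, seed=6)
    items = [i for i, m in truth.item_meta.items() if m.scale == scale][:2]
    sl = panel.slice(occasion="t1")
    rho = polychoric_correlation(sl[items[0]].to_numpy(), sl[items[1]].to_numpy()).rho
    assert abs(rho - 0.49) < 0.05


def test_item_panel_seed_determinism(null_truth):
    a = sample_item_panel(null_truth, {"CA+": 5, "CA-": 5}, seed=1)
    b = sample_item_panel(null_truth, {"CA+": 5, "CA-": 5}, seed=1)
    assert a.data.equals(b.data)
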