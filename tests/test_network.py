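"""Network estimation: glasso closed forms and independent-oracle checks,
EBIC selection behavior, expected influence identities."""

import warnings

import numpy as np
import pytest
from sklearn.covariance import graphical_lasso as sk_glasso

from rfnet.cohort import partial_to_correlation
from rfnet.errors import DomainError
from rfnet.network import (
    EstimatorConfig,
    correlation_matrix,
    ebic_score,
    expected_influence,
    glasso_fit,
    precision_to_partial,
    select_network_ebic,
)
from tests.conftest import make_network


# --- correlation input ----------------------------------------------------

def test_identical_columns_flagged_collinear(rng):
    x = rng.standard_normal(200)
    R, collinear, smoothed = correlation_matrix(np.column_stack([x, x]))
    assert collinear and smoothed


def test_independent_columns_near_zero(rng):
    X = rng.standard_normal((5000, 4))
    R, collinear, _ = correlation_matrix(X)
    iu = np.triu_indices(4, 1)
    assert np.abs(R[iu]).max() < 0.05 and not collinear


def test_point_biserial_matches_closed_form(rng):
    b = (rng.random(3000) < 0.4).astype(float)
    y = 0.5 * b + rng.standard_normal(3000)
    R, _, _ = correlation_matrix(np.column_stack([b, y]))
    p = b.mean()
    expected = (y[b == 1].mean() - y[b == 0].mean()) * np.sqrt(p * (1 - p)) / y.std(ddof=0)
    assert R[0, 1] == pytest.approx(expected, abs=1e-12)


def test_constant_column_errors(rng):
    X = np.column_stack([np.ones(100), rng.standard_normal(100)])
    with pytest.raises(DomainError):
        correlation_matrix(X)


# --- glasso ---------------------------------------------------------------

def test_two_variable_soft_threshold_closed_form():
    S = np.array([[1.0, 0.5], [0.5, 1.0]])
    W = precision_to_partial(glasso_fit(S, 0.2))
    assert W[0, 1] == pytest.approx(0.3, abs=1e-6)


def test_lambda_zero_matches_direct_inverse(rng):
    X = rng.standard_normal((300, 6))
    S = np.corrcoef(X.T)
    assert np.abs(glasso_fit(S, 0.0) - np.linalg.inv(S)).max() < 1e-5


def test_full_shrinkage_empties_network(rng):
    X = rng.standard_normal((300, 6))
    S = np.corrcoef(X.T)
    lam = np.abs(S - np.eye(6)).max() + 1e-9
    W = precision_to_partial(glasso_fit(S, lam))
    assert np.abs(W).max() == 0.0


@pytest.mark.parametrize("lam", [0.05, 0.1, 0.25])
def test_glasso_matches_sklearn_oracle(rng, lam):
    """Independent-implementation check against scikit-learn's estimator."""
    X = rng.standard_normal((400, 8)) @ rng.uniform(-0.5, 0.5, size=(8, 8))
    S, _, _ = correlation_matrix(X)
    K = glasso_fit(S, lam, tol=1e-9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, K_sk = sk_glasso(np.ascontiguousarray(S), alpha=lam, tol=1e-10, max_iter=2000)
    assert np.abs(K - K_sk).max() < 5e-4


def test_negative_penalty_rejected():
    with pytest.raises(Exception):
        glasso_fit(np.eye(2), -0.1)


# --- precision -> partial -------------------------------------------------

def test_partial_from_diagonal_precision_is_zero():
    assert np.abs(precision_to_partial(np.diag([2.0, 3.0, 4.0]))).max() == 0.0


def test_equicorrelation_partials_one_third():
    R = np.full((3, 3), 0.5)
    np.fill_diagonal(R, 1.0)
    W = precision_to_partial(np.linalg.inv(R))
    iu = np.triu_indices(3, 1)
    np.testing.assert_allclose(W[iu], 1.0 / 3.0, atol=1e-12)


def test_partial_sign_flips_precision_sign():
    K = np.array([[1.0, -0.3], [-0.3, 1.0]])
    assert precision_to_partial(K)[0, 1] > 0


# --- EBIC -----------------------------------------------------------------

def test_ebic_direct_evaluation():
    val = ebic_score(-100.0, n=200, p=10, edge_count=5, gamma=0.5)
    assert val == pytest.approx(200 + 5 * np.log(200) + 10 * np.log(10))
    assert val == pytest.approx(249.52, abs=0.01)
    assert ebic_score(-50.0, 100, 10, 0) == 100.0
    assert ebic_score(-50.0, 100, 10, 3, gamma=0.0) == pytest.approx(100 + 3 * np.log(100))


def test_gamma_monotone_in_selected_edges(small_panel, fast_config):
    import dataclasses

    counts = []
    for g in (0.0, 0.5, 1.0):
        cfg = dataclasses.replace(fast_config, gamma=g)
        counts.append(select_network_ebic(small_panel, cfg, group="CA-", occasion="t1").edge_count())
    assert counts[0] >= counts[1] >= counts[2]


def test_null_data_selects_nearly_empty_network(fast_config):
    spurious = []
    for seed in range(100):
        X = np.random.default_rng(seed).standard_normal((1000, 11))
        net = select_network_ebic(X, fast_config)
        spurious.append(net.edge_count())
    assert np.mean(np.asarray(spurious) <= 1) >= 0.90


def test_chain_recovery_with_correct_signs(fast_config):
    W = np.zeros((4, 4))
    for i in range(3):
        W[i, i + 1] = W[i + 1, i] = 0.3
    R = partial_to_correlation(W)
    X = np.random.default_rng(1).standard_normal((2000, 4)) @ np.linalg.cholesky(R).T
    net = select_network_ebic(X, fast_config)
    for i in range(3):
        assert net.weights[i, i + 1] > 0
    assert abs(net.weights[0, 2]) < 0.05 and abs(net.weights[0, 3]) < 0.05


# --- expected influence ---------------------------------------------------

def test_global_ei_signed_sum():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.3
    W[0, 2] = W[2, 0] = -0.1
    W[1, 2] = W[2, 1] = 0.2
    rep = expected_influence(make_network(W))
    assert rep.global_ei == pytest.approx(0.4)


def test_empty_network_zero_ei():
    rep = expected_influence(make_network(np.zeros((4, 4))))
    assert rep.global_ei == 0.0 and np.abs(rep.node_ei).max() == 0.0


def test_handshake_identity_random_network(rng):
    A = rng.uniform(-0.2, 0.3, size=(8, 8))
    W = np.triu(A, 1)
    W = W + W.T
    rep = expected_influence(make_network(W))
    assert rep.global_ei == pytest.approx(rep.node_ei.sum() / 2)


def test_subset_ei_and_unknown_node():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    net = make_network(W, labels=["a", "b", "c"])
    assert expected_influence(net, subset=["a", "b"]).global_ei == pytest.approx(0.5)
    assert expected_influence(net, subset=["a", "c"]).global_ei == 0.0
    with pytest.raises(DomainError):
        expected_influence(net, subset=["a", "zz"])
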