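"""Model-layer checks: the inclusive-or quadratic, the testing-effect curve,
and the correlated-strengths (Gaussian copula) extension against independent
numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualmem import (
    ModelPrediction,
    correlated_pt_closed,
    correlated_pt_mc,
    inclusive_or_prob,
    predict_pt,
    predict_te,
)

# Independent double-quadrature of the bivariate normal density over the
# rejection orthant at (pc_r, rho) = (0.47, 0.334), computed with
# scipy.integrate.dblquad before the implementation existed (abs err < 1e-8).
QUADRATURE_ORACLE_047_0334 = 0.6651646533

GRID = np.linspace(0.0, 1.0, 1001)


@pytest.mark.parametrize(
    "p_s, p_t, expected",
    [(0.5, 0.5, 0.75), (0.0, 0.0, 0.0), (1.0, 0.3, 1.0), (0.3, 1.0, 1.0)],
)
def test_inclusive_or_examples(p_s, p_t, expected):
    assert inclusive_or_prob(p_s, p_t) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("p, expected", [(0.0, 0.0), (1.0, 1.0), (0.3, 0.51)])
def test_predict_pt_examples(p, expected):
    assert predict_pt(p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "p, expected",
    [(0.3, 0.21), (0.7, 0.21), (0.5, 0.25), (0.8, 0.16), (0.0, 0.0)],
)
def test_predict_te_examples(p, expected):
    """Worked examples: equal predicted TEs at complementary restudy levels."""
    assert predict_te(p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan, np.inf])
@pytest.mark.parametrize(
    "func",
    [predict_pt, predict_te, lambda p: inclusive_or_prob(p, 0.5),
     lambda p: correlated_pt_closed(p, 0.3)],
)
def test_out_of_range_probability_rejected(func, bad):
    with pytest.raises(ValueError):
        func(bad)


@pytest.mark.parametrize("bad_rho", [-0.01, 1.01, np.nan])
def test_out_of_range_rho_rejected(bad_rho):
    with pytest.raises(ValueError):
        correlated_pt_closed(0.5, bad_rho)


def test_te_equals_pt_minus_p_on_grid():
    assert np.allclose(predict_pt(GRID) - GRID, predict_te(GRID), atol=1e-15)


def test_te_symmetric_about_half():
    assert np.allclose(predict_te(GRID), predict_te(1.0 - GRID), atol=1e-15)


def test_te_maximum_quarter_at_half():
    fine = np.linspace(0.0, 1.0, 1_000_001)  # 1e-6 grid resolution
    te = predict_te(fine)
    k = int(np.argmax(te))
    assert te[k] == pytest.approx(0.25, abs=1e-12)
    assert fine[k] == pytest.approx(0.5, abs=1e-6)


def test_predict_pt_is_inclusive_or_of_equal_routes():
    assert np.allclose(predict_pt(GRID), inclusive_or_prob(GRID, GRID), atol=1e-15)


def test_correlated_independence_limit():
    assert np.allclose(correlated_pt_closed(GRID, 0.0), 2 * GRID - GRID**2, atol=1e-6)


def test_correlated_perfect_correlation_limit():
    assert np.allclose(correlated_pt_closed(GRID, 1.0), GRID, atol=1e-6)


def test_correlated_monotone_nonincreasing_in_rho():
    rhos = np.linspace(0.0, 1.0, 21)
    prev = correlated_pt_closed(GRID, rhos[0])
    for rho in rhos[1:]:
        cur = correlated_pt_closed(GRID, rho)
        assert np.all(cur <= prev + 1e-12)
        prev = cur


def test_correlated_matches_frozen_quadrature_oracle():
    assert correlated_pt_closed(0.47, 0.334) == pytest.approx(
        QUADRATURE_ORACLE_047_0334, abs=1e-8
    )


@pytest.mark.parametrize("p", [0.1, 0.47, 0.8])
@pytest.mark.parametrize("rho", [0.1, 0.334, 0.75])
def test_correlated_matches_bivariate_normal_cdf(p, rho):
    """Cross-check the Owen's T identity against scipy's BVN CDF routine."""
    from scipy.special import ndtri
    from scipy.stats import multivariate_normal

    z = ndtri(1.0 - p)
    orthant = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([z, z])
    assert correlated_pt_closed(p, rho) == pytest.approx(1.0 - orthant, abs=1e-6)


def test_small_rho_te_shift_is_negligible():
    """TE curves at rho = 0 and rho = 0.1 differ by < 0.02 everywhere."""
    p = np.linspace(0.0, 1.0, 20001)
    shift = np.abs(predict_pt(p) - correlated_pt_closed(p, 0.1))
    assert float(np.max(shift)) < 0.02


def test_mc_deterministic_given_seed():
    a = correlated_pt_mc(0.47, 0.334, n_draws=10_000, seed=3)
    b = correlated_pt_mc(0.47, 0.334, n_draws=10_000, seed=3)
    assert a == b
    assert correlated_pt_mc(0.47, 0.334, n_draws=10_000, seed=4) != a


@pytest.mark.parametrize("rho", [0.0, 0.5, 1.0])
def test_mc_boundary_probabilities(rho):
    assert correlated_pt_mc(0.0, rho, n_draws=100, seed=0) == 0.0
    assert correlated_pt_mc(1.0, rho, n_draws=100, seed=0) == 1.0


def test_mc_independence_limit():
    est = correlated_pt_mc(0.5, 0.0, n_draws=1_000_000, seed=11)
    assert est == pytest.approx(0.75, abs=0.002)


def test_mc_agrees_with_closed_form_at_fitted_rho():
    closed = correlated_pt_closed(0.47, 0.334)
    est = correlated_pt_mc(0.47, 0.334, n_draws=1_000_000, seed=12)
    se = np.sqrt(closed * (1 - closed) / 1_000_000)
    assert abs(est - closed) < 3 * se


def test_mc_rejects_bad_draw_count():
    with pytest.raises(ValueError):
        correlated_pt_mc(0.5, 0.0, n_draws=0, seed=0)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    p_s=st.floats(0.0, 1.0, allow_nan=False),
    p_t=st.floats(0.0, 1.0, allow_nan=False),
)
def test_inclusive_or_properties(p_s, p_t):
    v = inclusive_or_prob(p_s, p_t)
    assert max(p_s, p_t) - 1e-12 <= v <= 1.0 + 1e-12
    assert v == pytest.approx(inclusive_or_prob(p_t, p_s), abs=1e-12)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(p=st.floats(0.0, 1.0, allow_nan=False), rho=st.floats(0.0, 1.0, allow_nan=False))
def test_correlated_prediction_bounded_by_limits(p, rho):
    v = correlated_pt_closed(p, rho)
    assert p - 1e-9 <= v <= predict_pt(p) + 1e-9


def test_model_prediction_consistency():
    mp = ModelPrediction.from_pc_r(0.3)
    assert mp.pc_t_pred == pytest.approx(0.51)
    assert mp.te_pred == pytest.approx(0.21)
    with pytest.raises(ValueError):
        ModelPrediction(pc_r=0.3, pc_t_pred=0.51, te_pred=0.5)
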