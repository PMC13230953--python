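"""Dual-memory model of the testing effect.

The model holds that a retrieval-practice (test-with-feedback) trial both
strengthens the memory formed at initial study ("study memory") and lays down
a second, separate memory of the test event ("test memory"), so a tested item
can be recalled on the final test through either route.  If the two routes
are stochastically independent and identically distributed, recall in the
test condition follows the probabilistic inclusive-or of the two routes and
reduces to a parameter-free quadratic function of restudy performance:

    PC_T = 2 PC_R - PC_R**2            (independent routes)
    TE   = PC_T - PC_R = PC_R - PC_R**2

The correlated-strengths extension relaxes route independence with a single
free parameter ``rho``, the correlation between study- and test-memory
strengths.  Strengths are modelled as standard bivariate normal with
correlation ``rho`` and the item is recalled if either strength exceeds the
threshold ``z = Phi^-1(1 - p)`` that individually yields recall probability
``p`` (a Gaussian copula with identical marginals).  Then

    PC_T(p, rho) = 1 - Phi2(z, z; rho) = p + 2 T(z, sqrt((1-rho)/(1+rho)))

where ``Phi2`` is the bivariate normal CDF and ``T`` is Owen's T function.
``rho = 0`` recovers the independent-routes quadratic exactly; ``rho = 1``
collapses both routes into one, giving PC_T = PC_R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike
from scipy.special import ndtri, owens_t

__all__ = [
    "ModelPrediction",
    "inclusive_or_prob",
    "predict_pt",
    "predict_te",
    "correlated_pt_closed",
    "correlated_pt_mc",
]


def _as_prob(x: ArrayLike, name: str) -> np.ndarray:
    """Validate and return ``x`` as a float array of probabilities."""
    arr = np.asarray(x, dtype=float)
    if arr.size and (not np.all(np.isfinite(arr)) or np.any((arr < 0) | (arr > 1))):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")
    return arr


def _check_rho(rho: float) -> float:
    rho = float(rho)
    if not np.isfinite(rho) or not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho!r}")
    return rho


def _scalar_or_array(out: np.ndarray, like) -> float | np.ndarray:
    if np.isscalar(like) or getattr(like, "ndim", None) == 0:
        return float(out)
    return out


def inclusive_or_prob(p_s: ArrayLike, p_t: ArrayLike) -> float | np.ndarray:
    """Probability of success through at least one of two independent routes.

    Parameters
    ----------
    p_s, p_t
        Retrieval probabilities through study memory and test memory.

    Returns
    -------
    ``p_s + p_t - p_s * p_t``, elementwise.
    """
    a = _as_prob(p_s, "p_s")
    b = _as_prob(p_t, "p_t")
    return _scalar_or_array(a + b - a * b, p_s if np.ndim(p_s) else p_t)


def predict_pt(pc_r: ArrayLike) -> float | np.ndarray:
    """Parameter-free prediction of test-condition proportion correct.

    ``predict_pt(p) == inclusive_or_prob(p, p) == 2p - p**2``.
    """
    p = _as_prob(pc_r, "pc_r")
    return _scalar_or_array(p * (2.0 - p), pc_r)


def predict_te(pc_r: ArrayLike) -> float | np.ndarray:
    """Predicted testing effect ``predict_pt(p) - p = p - p**2``.

    Lies in [0, 0.25]; maximal at ``pc_r = 0.5``, symmetric about it.
    """
    p = _as_prob(pc_r, "pc_r")
    return _scalar_or_array(p * (1.0 - p), pc_r)


def correlated_pt_closed(pc_r: ArrayLike, rho: float) -> float | np.ndarray:
    """Test-condition prediction under correlated route strengths.

    Computes ``1 - Phi2(z, z; rho)`` with ``z = Phi^-1(1 - pc_r)`` — the
    probability that at least one of two standard-normal strengths with
    correlation ``rho`` exceeds the threshold that alone yields recall
    probability ``pc_r`` — via the exact equal-coordinate identity
    ``Phi2(z, z; rho) = Phi(z) - 2 T(z, sqrt((1 - rho)/(1 + rho)))``.

    Monotone non-increasing in ``rho``; equals ``predict_pt(pc_r)`` at
    ``rho = 0`` and ``pc_r`` at ``rho = 1``.
    """
    p = _as_prob(pc_r, "pc_r")
    rho = _check_rho(rho)
    a = np.sqrt((1.0 - rho) / (1.0 + rho))
    out = np.empty_like(p)
    interior = (p > 0.0) & (p < 1.0)
    # thresholds at p in {0, 1} are +-inf; short-circuit the boundaries
    out[~interior] = p[~interior]
    z = ndtri(1.0 - p[interior])
    out[interior] = np.clip(p[interior] + 2.0 * owens_t(z, a), 0.0, 1.0)
    return _scalar_or_array(out, pc_r)


def correlated_pt_mc(
    pc_r: float,
    rho: float,
    n_draws: int = 1_000_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo estimate of :func:`correlated_pt_closed`.

    Draws ``n_draws`` bivariate standard-normal strength pairs with
    correlation ``rho`` and scores recall when either component exceeds
    ``Phi^-1(1 - pc_r)``.  Deterministic given ``seed``.  Reserved for
    validating the closed form; never used inside estimation.
    """
    p = float(_as_prob(pc_r, "pc_r"))
    rho = _check_rho(rho)
    n_draws = int(n_draws)
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    if p in (0.0, 1.0):
        return p
    rng = np.random.default_rng(seed)
    z = ndtri(1.0 - p)
    x = rng.standard_normal(n_draws)
    y = rho * x + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n_draws)
    return float(np.mean((x > z) | (y > z)))


@dataclass(frozen=True)
class ModelPrediction:
    """Model prediction for one restudy proportion correct.

    Attributes
    ----------
    pc_r
        Restudy proportion correct.
    pc_t_pred
        Predicted test-condition proportion correct.
    te_pred
        Predicted testing effect, ``pc_t_pred - pc_r``.
    rho
        Strength correlation used (0 = independent routes).
    """

    pc_r: float
    pc_t_pred: float
    te_pred: float
    rho: float = 0.0

    def __post_init__(self):
        _as_prob(self.pc_r, "pc_r")
        _as_prob(self.pc_t_pred, "pc_t_pred")
        _check_rho(self.rho)
        if abs(self.te_pred - (self.pc_t_pred - self.pc_r)) > 1e-9:
            raise ValueError("te_pred must equal pc_t_pred - pc_r")

    @classmethod
    def from_pc_r(cls, pc_r: float, rho: float = 0.0) -> "ModelPrediction":
        pt = float(correlated_pt_closed(pc_r, rho))
        return cls(pc_r=float(pc_r), pc_t_pred=pt, te_pred=pt - float(pc_r), rho=float(rho))
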