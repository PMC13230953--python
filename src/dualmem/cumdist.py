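"""Cumulative-distribution matching of observed and predicted performance.

Restudy and test proportions correct are each sorted across participants —
independently, so a participant's two values share a quantile only by
chance — and placed on an equally spaced quantile axis scaled to (0, 1].
The model prediction at each quantile is the transform of the sorted
restudy value at that same quantile.  A systematic negative signed
deviation (observed minus predicted test performance) across quantiles is
the signature of reduced testing efficacy relative to the
independent-routes model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .model import correlated_pt_closed, predict_pt

__all__ = [
    "CumulativeCurve",
    "DeviationMetrics",
    "build_curve",
    "deviation_metrics",
    "range_fraction",
    "interpolate_curve",
    "curve_to_frame",
]


@dataclass(frozen=True)
class CumulativeCurve:
    """Quantile-aligned sorted distributions for one group of participants."""

    quantiles: np.ndarray
    pc_r_sorted: np.ndarray
    pc_t_sorted: np.ndarray
    pc_t_pred: np.ndarray
    group: str | None = None
    transform: str = "independent"
    rho: float | None = None

    def __post_init__(self):
        n = len(self.quantiles)
        for name in ("pc_r_sorted", "pc_t_sorted", "pc_t_pred"):
            v = getattr(self, name)
            if len(v) != n:
                raise DataError(f"{name} has length {len(v)}, expected {n}")
        for name in ("pc_r_sorted", "pc_t_sorted"):
            v = getattr(self, name)
            if np.any(np.diff(v) < 0):
                raise DataError(f"{name} must be nondecreasing")

    def __len__(self) -> int:
        return len(self.quantiles)


@dataclass(frozen=True)
class DeviationMetrics:
    """Observed-minus-predicted deviation summaries over quantiles."""

    mean_signed_dev: float
    mean_abs_dev: float
    max_abs_dev: float


def _sorted_by(values: np.ndarray, ids: np.ndarray) -> np.ndarray:
    # stable sort on (value, participant_id) so ties resolve identically
    # across platforms; proportions are multiples of 1/n_items, so ties abound
    order = np.lexsort((ids, values))
    return values[order]


def build_curve(
    summaries: pd.DataFrame,
    transform: str = "independent",
    rho: float | None = None,
    group: str | None = None,
) -> CumulativeCurve:
    """Build the cumulative-distribution curve from participant summaries.

    Parameters
    ----------
    summaries
        Output of :func:`dualmem.synth.summarize_participants`.
    transform
        ``"independent"`` (parameter-free quadratic) or ``"correlated"``
        (requires ``rho``); applied pointwise to the sorted restudy values.
    group
        Optional group filter (``"low"`` / ``"high"``); default uses all rows.
    """
    df = summaries if group is None else summaries[summaries["group"] == group]
    if len(df) < 2:
        raise DataError("need at least 2 participants to build a cumulative curve")
    if transform not in ("independent", "correlated"):
        raise ValueError(f"unknown transform {transform!r}")
    if transform == "correlated":
        if rho is None:
            raise ValueError("transform='correlated' requires rho")
    ids = df["participant_id"].to_numpy(dtype=str)
    pc_r = _sorted_by(df["pc_r"].to_numpy(dtype=float), ids)
    pc_t = _sorted_by(df["pc_t"].to_numpy(dtype=float), ids)
    n = len(df)
    quantiles = np.arange(1, n + 1) / n
    if transform == "independent":
        pred = np.asarray(predict_pt(pc_r))
    else:
        pred = np.asarray(correlated_pt_closed(pc_r, rho))
    return CumulativeCurve(
        quantiles=quantiles,
        pc_r_sorted=pc_r,
        pc_t_sorted=pc_t,
        pc_t_pred=pred,
        group=group,
        transform=transform,
        rho=None if transform == "independent" else float(rho),
    )


def deviation_metrics(curve: CumulativeCurve) -> DeviationMetrics:
    """Signed and absolute deviations of observed from predicted PC_T.

    The signed deviation is observed minus predicted, averaged over
    quantiles; a negative mean beyond sampling error indicates the model
    systematically overpredicts test performance.
    """
    dev = curve.pc_t_sorted - curve.pc_t_pred
    return DeviationMetrics(
        mean_signed_dev=float(np.mean(dev)),
        mean_abs_dev=float(np.mean(np.abs(dev))),
        max_abs_dev=float(np.max(np.abs(dev))),
    )


def range_fraction(values, lo: float, hi: float, closed: bool = True) -> float:
    """Fraction of values inside [lo, hi] (or (lo, hi) with ``closed=False``).

    Used for the share of participants whose restudy accuracy falls in the
    peak-testing-effect band (0.4–0.6 of the quadratic).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("range_fraction requires at least one value")
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    if closed:
        inside = (v >= lo) & (v <= hi)
    else:
        inside = (v > lo) & (v < hi)
    return float(np.mean(inside))


def interpolate_curve(curve: CumulativeCurve, n_points: int = 101) -> pd.DataFrame:
    """Linearly interpolate a curve onto a common equally spaced quantile grid.

    Lets curves from groups of unequal size be compared at matched
    quantiles.  Returns a DataFrame with columns
    ``quantile, pc_r, pc_t, pc_t_pred``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(curve.quantiles[0], 1.0, n_points)
    return pd.DataFrame(
        {
            "quantile": grid,
            "pc_r": np.interp(grid, curve.quantiles, curve.pc_r_sorted),
            "pc_t": np.interp(grid, curve.quantiles, curve.pc_t_sorted),
            "pc_t_pred": np.interp(grid, curve.quantiles, curve.pc_t_pred),
        }
    )


def curve_to_frame(curve: CumulativeCurve) -> pd.DataFrame:
    """Tabular view of a curve (one row per quantile), for TSV export."""
    return pd.DataFrame(
        {
            "quantile": curve.quantiles,
            "pc_r": curve.pc_r_sorted,
            "pc_t": curve.pc_t_sorted,
            "pc_t_pred": curve.pc_t_pred,
        }
    )
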