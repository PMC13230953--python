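"""Observed-vs-predicted inference: mixed ANOVA, t tests, JZS Bayes factors.

Two 2x2 mixed designs are used.  The conventional one crosses Training Task
(restudy vs. test, within participants) with Relatedness (low vs. high,
between participants) on observed proportion correct.  The model-based one
replaces Training Task with Data Type (observed test accuracy vs. the
model's prediction from restudy accuracy): its interaction with Relatedness
asks whether the model's fit differs across relatedness levels, which is
interpretable even when the conventional interaction is not.

Bayes factors for t tests use the default JZS prior — a Cauchy prior with
scale ``r`` (default 0.707) on standardised effect size, equivalently a
normal prior with an inverse-gamma(1/2, r^2/2) mixing variance — evaluated
by one-dimensional quadrature.  Evidence strength is labelled with the
Raftery bins: 1-3 weak, 3-20 positive, 20-150 strong, >150 very strong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import integrate
from scipy import stats as sps

from .exceptions import StatsError

__all__ = ["TestResult", "mixed_anova_2x2", "t_tests", "jzs_bf_t", "raftery_label"]

RAFTERY_BINS = ((1.0, 3.0, "weak"), (3.0, 20.0, "positive"), (20.0, 150.0, "strong"))


@dataclass(frozen=True)
class TestResult:
    """One inferential result (F or t)."""

    statistic: float
    df: float | tuple
    p_value: float
    effect_size: float | None = None
    bf10: float | None = None
    evidence_label: str | None = None

    def __post_init__(self):
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise StatsError(f"p_value out of [0, 1]: {self.p_value}")
        if self.bf10 is not None and self.bf10 <= 0:
            raise StatsError(f"bf10 must be positive: {self.bf10}")


def mixed_anova_2x2(
    summaries: pd.DataFrame,
    within: tuple[str, str],
    group_col: str = "group",
    subject_col: str = "participant_id",
) -> dict[str, TestResult]:
    """2x2 mixed ANOVA: one within-participant pair of measures x one
    between-participant group factor.

    ``within`` names two columns of ``summaries`` holding the paired
    measures — e.g. ``("pc_r", "pc_t")`` for Training Task x Relatedness, or
    ``("pc_t", "pc_t_pred")`` for Data Type x Relatedness.  Returns the
    classical decomposition (between-subject and within-subject strata) as
    ``{"between": ..., "within": ..., "interaction": ...}`` with partial
    eta-squared effect sizes.  Groups may be unbalanced; every participant
    must have both measures.
    """
    a, b = within
    for col in (a, b, group_col, subject_col):
        if col not in summaries.columns:
            raise StatsError(f"missing column {col!r}")
    if summaries[[a, b]].isna().any().any():
        raise StatsError("within-measure values contain missing data")
    groups = summaries[group_col].unique()
    if len(groups) != 2:
        raise StatsError(f"expected exactly 2 groups, found {list(groups)}")
    if summaries[subject_col].duplicated().any():
        raise StatsError("one row per participant expected")

    long = summaries.melt(
        id_vars=[subject_col, group_col],
        value_vars=[a, b],
        var_name="measure",
        value_name="score",
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table = pg.mixed_anova(
            data=long,
            dv="score",
            within="measure",
            subject=subject_col,
            between=group_col,
        ).set_index("Source")

    # identical within measures: the within and interaction strata are
    # exactly null (0/0 in the decomposition); report the zero-effect limit
    if (summaries[a] == summaries[b]).all():
        for source in ("measure", "Interaction"):
            table.loc[source, ["F", "p_unc", "np2"]] = [0.0, 1.0, 0.0]

    def row(source: str) -> TestResult:
        r = table.loc[source]
        return TestResult(
            statistic=float(r["F"]),
            df=(float(r["DF1"]), float(r["DF2"])),
            p_value=float(r["p_unc"]),
            effect_size=float(r["np2"]),
        )

    return {
        "between": row(group_col),
        "within": row("measure"),
        "interaction": row("Interaction"),
    }


def t_tests(a, b, paired: bool = False) -> TestResult:
    """Two-sided t test between two samples.

    Paired tests operate on difference scores (identical to a one-sample t
    on ``a - b``).  Zero-variance input with a zero mean difference returns
    the no-effect limit ``t = 0, p = 1``; zero variance with a nonzero
    difference is degenerate and raises :class:`StatsError` (proportion
    data pinned at floor/ceiling can produce this).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise StatsError("paired test requires equal lengths")
        if len(a) < 2:
            raise StatsError("need at least 2 pairs")
        d = a - b
        if np.var(d, ddof=1) == 0.0:
            if np.mean(d) == 0.0:
                return TestResult(0.0, float(len(d) - 1), 1.0)
            raise StatsError("zero-variance difference scores with nonzero mean")
        t, p = sps.ttest_rel(a, b)
        df = float(len(a) - 1)
    else:
        if len(a) < 2 or len(b) < 2:
            raise StatsError("need at least 2 observations per sample")
        if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
            if np.mean(a) == np.mean(b):
                return TestResult(0.0, float(len(a) + len(b) - 2), 1.0)
            raise StatsError("zero-variance samples with unequal means")
        t, p = sps.ttest_ind(a, b)
        df = float(len(a) + len(b) - 2)
    return TestResult(float(t), df, float(p))


def jzs_bf_t(t: float, n1: int, n2: int | None = None, r_scale: float = 0.707) -> float:
    """Default JZS Bayes factor BF10 for a t statistic.

    One-sample / paired when ``n2`` is None (effective N = n1, df = n1 - 1),
    two-sample otherwise (N = n1*n2/(n1+n2), df = n1 + n2 - 2).  BF01 is the
    reciprocal.  Monotone increasing in |t| at fixed sample size.
    """
    t = float(t)
    if not np.isfinite(t):
        raise ValueError(f"t must be finite, got {t}")
    if r_scale <= 0:
        raise ValueError("r_scale must be positive")
    if n2 is None:
        if n1 < 2:
            raise ValueError("n1 must be >= 2")
        n_eff, nu = float(n1), float(n1 - 1)
    else:
        if n1 < 2 or n2 < 2:
            raise ValueError("both sample sizes must be >= 2")
        n_eff, nu = n1 * n2 / (n1 + n2), float(n1 + n2 - 2)

    r2 = r_scale * r_scale

    def integrand(g: float) -> float:
        shrink = 1.0 + n_eff * g
        return (
            shrink ** -0.5
            * (1.0 + t * t / (shrink * nu)) ** (-(nu + 1.0) / 2.0)
            * r_scale / np.sqrt(2.0 * np.pi)
            * g ** -1.5
            * np.exp(-r2 / (2.0 * g))
        )

    marginal_h1, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    marginal_h0 = (1.0 + t * t / nu) ** (-(nu + 1.0) / 2.0)
    return float(marginal_h1 / marginal_h0)


def raftery_label(bf: float) -> str:
    """Evidence-strength label for a directional Bayes factor (>= 1).

    Callers pass ``max(BF10, BF01)``; values below 1 mean the evidence
    points the other way and the caller should invert before labelling.
    """
    bf = float(bf)
    if not np.isfinite(bf) or bf < 1.0:
        raise ValueError(
            f"raftery_label expects a Bayes factor >= 1 (got {bf}); "
            "pass max(BF10, BF01) — invert the BF if it favours the other hypothesis"
        )
    for lo, hi, label in RAFTERY_BINS:
        if lo <= bf < hi:
            return label
    return "very strong"
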