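"""End-to-end analysis pipeline and the JSON report it produces.

Stage order mirrors the analysis chain: load (or simulate) trials →
participant summaries → condition means → mixed ANOVAs and paired t tests
with JZS Bayes factors → cumulative-distribution curves and deviation
metrics → rho fit and efficacy reduction → serialised report.  The report
is a pydantic model; its JSON schema ships with the package
(``report.schema.json``) and every report validates against it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as dm_io
from .cumdist import build_curve, deviation_metrics, range_fraction
from .exceptions import DataError, PipelineError
from .fit import efficacy_reduction, fit_rho
from .stats import jzs_bf_t, mixed_anova_2x2, raftery_label, t_tests
from .synth import CohortConfig, generate_cohort, summarize_participants

__all__ = [
    "AnalysisReport",
    "run_pipeline",
    "report_schema",
    "validate_report",
    "write_report",
]

log = logging.getLogger(__name__)

PEAK_TE_BAND = (0.4, 0.6)  # restudy range where the quadratic TE peaks


class TestResultModel(BaseModel):
    statistic: float
    df: float | list[float]
    p_value: float
    effect_size: Optional[float] = None
    bf10: Optional[float] = None
    bf01: Optional[float] = None
    evidence_label: Optional[str] = None


class MeansModel(BaseModel):
    n: int = Field(ge=1)
    pc_r: float = Field(ge=0, le=1)
    pc_t: float = Field(ge=0, le=1)
    pc_t_pred: float = Field(ge=0, le=1)
    te: float
    te_pred: float


class DeviationModel(BaseModel):
    mean_signed_dev: float
    mean_abs_dev: float
    max_abs_dev: float


class FitModel(BaseModel):
    rho_hat: float = Field(ge=0, le=1)
    objective: float = Field(ge=0)
    converged: bool
    boundary: Optional[str] = None
    n_draws: int = 0
    seed: Optional[int] = None


class GroupBlockModel(BaseModel):
    means: MeansModel
    deviation_independent: DeviationModel
    fit: FitModel
    deviation_fitted: DeviationModel
    efficacy_reduction: float
    pc_r_range_fraction_closed: float = Field(ge=0, le=1)
    pc_r_range_fraction_open: float = Field(ge=0, le=1)


class ProvenanceModel(BaseModel):
    package: str
    version: str
    config_hash: str = Field(min_length=1)
    seed: Optional[int] = None
    created: str = Field(min_length=1)


class AnalysisReport(BaseModel):
    """Full analysis output; see module docstring for the stage order."""

    provenance: ProvenanceModel
    model: str
    rho: Optional[float] = None
    groups: dict[str, GroupBlockModel]
    anova_training_task: Optional[dict[str, TestResultModel]] = None
    anova_data_type: Optional[dict[str, TestResultModel]] = None
    t_data_type: dict[str, TestResultModel] = Field(default_factory=dict)
    notes: list[str] = Field(default_factory=list)


def _test_result_model(res, bf10: float | None = None) -> TestResultModel:
    d = dict(
        statistic=res.statistic,
        df=list(res.df) if isinstance(res.df, tuple) else res.df,
        p_value=res.p_value,
        effect_size=res.effect_size,
    )
    if bf10 is not None:
        d["bf10"] = bf10
        d["bf01"] = 1.0 / bf10
        d["evidence_label"] = raftery_label(max(bf10, 1.0 / bf10))
    return TestResultModel(**d)


def _stage(name: str):
    """Context manager: log timing and re-raise failures tagged with the stage."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                if isinstance(exc, PipelineError):
                    return False
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %-10s %.3fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_pipeline(
    config: CohortConfig | None = None,
    trials: pd.DataFrame | str | Path | None = None,
    *,
    transform: str = "independent",
    rho: float | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    figures: bool = False,
) -> AnalysisReport:
    """Run the full analysis and return (and optionally write) the report.

    Exactly one of ``config`` (simulate a cohort) or ``trials`` (path or
    DataFrame of scored trials) supplies the data.  ``transform`` selects
    the prediction applied on the cumulative curves' own report fields
    (the independent-model deviations and the per-group rho fit are always
    computed).  With ``out_dir`` set, writes ``report.json`` and per-group
    curve TSVs (plus figures when requested).  Deterministic given data and
    seed, timestamps aside.
    """
    from . import __version__

    if (config is None) == (trials is None):
        raise PipelineError("load", "provide exactly one of config or trials")
    if transform not in ("independent", "correlated"):
        raise PipelineError("load", f"unknown transform {transform!r}")
    if transform == "correlated" and rho is None:
        raise PipelineError("load", "transform='correlated' requires rho")

    with _stage("load"):
        if config is not None:
            if seed is not None:
                config = config.with_seed(seed)
            table = generate_cohort(config)
            cfg_repr = json.dumps(config.to_dict(), sort_keys=True)
            used_seed = config.seed
        else:
            table = dm_io.read_trials(trials) if isinstance(trials, (str, Path)) else trials.copy()
            if len(table) == 0:
                raise DataError("trial table is empty")
            cfg_repr = table.to_csv(index=False)
            used_seed = seed
        config_hash = hashlib.sha256(cfg_repr.encode()).hexdigest()

    with _stage("summarize"):
        summaries = summarize_participants(table)
        present_groups = [g for g in ("low", "high") if (summaries["group"] == g).any()]

    with _stage("groups"):
        group_blocks: dict[str, GroupBlockModel] = {}
        for g in present_groups:
            sub = summaries[summaries["group"] == g]
            pc_r = sub["pc_r"].to_numpy()
            te_obs = float(np.mean(sub["pc_t"] - sub["pc_r"]))
            te_pred = float(np.mean(sub["pc_t_pred"] - sub["pc_r"]))
            means = MeansModel(
                n=len(sub),
                pc_r=float(np.mean(sub["pc_r"])),
                pc_t=float(np.mean(sub["pc_t"])),
                pc_t_pred=float(np.mean(sub["pc_t_pred"])),
                te=te_obs,
                te_pred=te_pred,
            )
            indep_curve = build_curve(summaries, transform="independent", group=g)
            dev_ind = deviation_metrics(indep_curve)
            mfit = fit_rho(summaries, group=g)
            fitted_curve = build_curve(summaries, transform="correlated", rho=mfit.rho_hat, group=g)
            dev_fit = deviation_metrics(fitted_curve)
            group_blocks[g] = GroupBlockModel(
                means=means,
                deviation_independent=DeviationModel(**dev_ind.__dict__),
                fit=FitModel(
                    rho_hat=mfit.rho_hat,
                    objective=mfit.objective,
                    converged=mfit.converged,
                    boundary=mfit.boundary,
                    n_draws=mfit.n_draws,
                    seed=mfit.seed,
                ),
                deviation_fitted=DeviationModel(**dev_fit.__dict__),
                efficacy_reduction=efficacy_reduction(te_obs, te_pred),
                pc_r_range_fraction_closed=range_fraction(pc_r, *PEAK_TE_BAND, closed=True),
                pc_r_range_fraction_open=range_fraction(pc_r, *PEAK_TE_BAND, closed=False),
            )

    anova_tt = anova_dt = None
    if len(present_groups) == 2:
        with _stage("anova"):
            tt = mixed_anova_2x2(summaries, within=("pc_r", "pc_t"))
            dt = mixed_anova_2x2(summaries, within=("pc_t", "pc_t_pred"))
            anova_tt = {k: _test_result_model(v) for k, v in tt.items()}
            anova_dt = {k: _test_result_model(v) for k, v in dt.items()}

    with _stage("ttests"):
        t_blocks: dict[str, TestResultModel] = {}
        for g in present_groups:
            sub = summaries[summaries["group"] == g]
            res = t_tests(sub["pc_t"].to_numpy(), sub["pc_t_pred"].to_numpy(), paired=True)
            bf10 = jzs_bf_t(res.statistic, len(sub))
            t_blocks[g] = _test_result_model(res, bf10=bf10)

    with _stage("report"):
        report = AnalysisReport(
            provenance=ProvenanceModel(
                package="dualmem",
                version=__version__,
                config_hash=config_hash,
                seed=used_seed,
                created=datetime.now(timezone.utc).isoformat(),
            ),
            model=transform,
            rho=rho if transform == "correlated" else None,
            groups=group_blocks,
            anova_training_task=anova_tt,
            anova_data_type=anova_dt,
            t_data_type=t_blocks,
            notes=[
                "Bayes factors are reported for t tests only (JZS, Cauchy scale 0.707); "
                "ANOVA-effect Bayes factors are out of scope for this package."
            ],
        )

    if out_dir is not None:
        with _stage("write"):
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_report(report, out_dir / "report.json")
            for g in present_groups:
                curve = build_curve(
                    summaries,
                    transform=transform,
                    rho=rho if transform == "correlated" else None,
                    group=g,
                )
                dm_io.write_curve_tsv(curve, out_dir / f"curve_{g}.tsv")
                if figures:
                    _plot_curve(curve, group_blocks[g].fit.rho_hat, summaries, g,
                                out_dir / f"curve_{g}.png")
    return report


def _plot_curve(curve, rho_hat: float, summaries: pd.DataFrame, group: str, path: Path) -> None:
    """Cumulative-distribution figure: sorted observed and predicted values."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fitted = build_curve(summaries, transform="correlated", rho=rho_hat, group=group)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.quantiles, curve.pc_r_sorted, "o", ms=3, label="restudy (observed)")
    ax.plot(curve.quantiles, curve.pc_t_sorted, "s", ms=3, label="test (observed)")
    ax.plot(curve.quantiles, curve.pc_t_pred, "k-", lw=1.5, label="test (predicted)")
    ax.plot(fitted.quantiles, fitted.pc_t_pred, "r--", lw=1.2,
            label=f"test (correlated, rho={rho_hat:.3f})")
    ax.set(xlabel="quantile", ylabel="proportion correct", ylim=(0, 1),
           title=f"{group} relatedness group")
    ax.legend(fontsize=7, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_report(report: AnalysisReport, path: str | Path) -> None:
    """Serialise a report to JSON (stable key order)."""
    Path(path).write_text(report.model_dump_json(indent=2) + "\n")


def report_schema() -> dict:
    """The published JSON schema the report validates against."""
    text = resources.files("dualmem").joinpath("report.schema.json").read_text()
    return json.loads(text)


def validate_report(data: dict | str | Path) -> AnalysisReport:
    """Validate a report dict (or JSON file) against the report model."""
    if isinstance(data, (str, Path)):
        data = json.loads(Path(data).read_text())
    return AnalysisReport.model_validate(data)
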