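"""Reading and writing the package's file formats.

The canonical input is a long-format trial CSV with header
``participant_id,group,condition,item_id,correct``; one row per final-test
outcome, pre-scored 0/1.  Curves export as TSV, configs as YAML or JSON.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .cumdist import CumulativeCurve, curve_to_frame
from .exceptions import DataError
from .synth import CONDITIONS, GROUPS, TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "read_summaries", "write_curve_tsv"]

log = logging.getLogger(__name__)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    Rejects unknown group/condition tokens and non-binary ``correct``
    values, reporting 1-based data row numbers; duplicated
    (participant, condition, item) triples are an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as e:
        raise DataError(f"{path}: file is empty") from e
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing} (header must be {','.join(TRIAL_COLUMNS)})")
    if len(df) == 0:
        raise DataError(f"{path}: no data rows")

    problems: list[str] = []

    def flag(mask, what: str) -> None:
        rows = (df.index[mask] + 1).tolist()
        if rows:
            shown = ", ".join(map(str, rows[:10])) + (" ..." if len(rows) > 10 else "")
            problems.append(f"{what} at row(s) {shown}")

    flag(~df["group"].isin(GROUPS), f"group not in {GROUPS}")
    flag(~df["condition"].isin(CONDITIONS), f"condition not in {CONDITIONS}")
    flag(~df["correct"].isin(("0", "1")), "correct must be 0 or 1")
    flag(df["participant_id"].str.len() == 0, "empty participant_id")
    flag(df["item_id"].str.len() == 0, "empty item_id")
    if problems:
        raise DataError(f"{path}: " + "; ".join(problems))

    dup = df.duplicated(subset=["participant_id", "condition", "item_id"])
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        raise DataError(f"{path}: duplicated (participant, condition, item) at row(s) {rows[:10]}")

    df = df.copy()
    df["correct"] = df["correct"].astype("int64")
    log.info("read %d trials from %s", len(df), path)
    return df[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV with the canonical header."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise DataError(f"trial table missing columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_summaries(path: str | Path) -> pd.DataFrame:
    """Read a participant-level summary CSV (for users with proportions only).

    Requires columns ``participant_id, group, pc_r, pc_t``; fills
    ``pc_t_pred`` and (if absent) the trial counts with 0 to mark them
    unknown.
    """
    from .model import predict_pt

    path = Path(path)
    df = pd.read_csv(path)
    required = ["participant_id", "group", "pc_r", "pc_t"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        raise DataError(f"{path}: group not in {GROUPS} at row(s) {(df.index[bad] + 1).tolist()[:10]}")
    for col in ("pc_r", "pc_t"):
        v = df[col]
        if ((v < 0) | (v > 1)).any() or v.isna().any():
            raise DataError(f"{path}: {col} must lie in [0, 1]")
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["pc_t_pred"] = predict_pt(df["pc_r"].to_numpy(dtype=float))
    for col in ("n_r", "n_t"):
        if col not in df.columns:
            df[col] = 0
    return df[["participant_id", "group", "pc_r", "pc_t", "pc_t_pred", "n_r", "n_t"]]


def write_curve_tsv(curve: CumulativeCurve, path: str | Path) -> None:
    """Export a cumulative curve as TSV (quantile, pc_r, pc_t, pc_t_pred)."""
    curve_to_frame(curve).to_csv(path, sep="\t", index=False, float_format="%.10g")
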