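"""Synthetic cued-recall cohorts with the study's statistical structure.

Emulates a two-group (low / high semantic relatedness) within-participant
restudy-vs-test design: each participant contributes ``items_per_condition``
Bernoulli final-test outcomes per training condition after a 24-h retention
interval.  A participant's baseline recall probability ``p_i`` is drawn from
a group-specific ability law; the same ``p_i`` drives both conditions
(study-memory equivalence across conditions).  Restudy outcomes are
Bernoulli(``p_i``); test outcomes are scored from a correlated bivariate
normal strength pair — recall succeeds if either the study-memory or
test-memory strength exceeds ``Phi^-1(1 - p_i)`` — so the expected test
proportion correct is ``correlated_pt_closed(p_i, rho)`` for the group's
strength correlation ``rho``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from .exceptions import ConfigError, DataError
from .model import predict_pt

__all__ = ["AbilityLaw", "CohortConfig", "generate_cohort", "summarize_participants"]

TRIAL_COLUMNS = ["participant_id", "group", "condition", "item_id", "correct"]
GROUPS = ("low", "high")
CONDITIONS = ("restudy", "test")


@dataclass(frozen=True)
class AbilityLaw:
    """Distribution of per-participant baseline recall probability.

    ``beta``: Beta with the given mean and concentration ``kappa``
    (shape parameters ``mean * kappa`` and ``(1 - mean) * kappa``), which
    spans the full unit interval for small ``kappa``.  ``point``: degenerate
    at ``mean`` (every participant identical) — useful for exact checks.
    """

    name: str = "beta"
    mean: float = 0.5
    concentration: float = 4.0

    def __post_init__(self):
        if self.name not in ("beta", "point"):
            raise ConfigError(f"unknown ability law {self.name!r}")
        if not 0.0 <= self.mean <= 1.0:
            raise ConfigError(f"ability mean must lie in [0, 1], got {self.mean}")
        if self.name == "beta":
            if not 0.0 < self.mean < 1.0:
                raise ConfigError("beta ability law requires mean strictly inside (0, 1)")
            if self.concentration <= 0:
                raise ConfigError("beta concentration must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.name == "point":
            return np.full(n, self.mean)
        a = self.mean * self.concentration
        b = (1.0 - self.mean) * self.concentration
        return rng.beta(a, b, size=n)


@dataclass(frozen=True)
class CohortConfig:
    """Full generative specification of a synthetic cohort.

    Defaults mirror the study design: 118 low- and 113 high-relatedness
    participants, 40 items per training condition, group-mean restudy
    accuracy near 0.47 (high) and 0.30 (low), and a strength correlation of
    0.334 in the high group (0 in the low group).
    """

    n_low: int = 118
    n_high: int = 113
    items_per_condition: int = 40
    ability_low: AbilityLaw = field(default_factory=lambda: AbilityLaw("beta", 0.30, 4.0))
    ability_high: AbilityLaw = field(default_factory=lambda: AbilityLaw("beta", 0.47, 4.0))
    rho_low: float = 0.0
    rho_high: float = 0.334
    item_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_low < 0 or self.n_high < 0 or self.n_low + self.n_high < 1:
            raise ConfigError("group sizes must be non-negative with at least one participant")
        if self.items_per_condition < 1:
            raise ConfigError("items_per_condition must be positive")
        for rho in (self.rho_low, self.rho_high):
            if not 0.0 <= rho <= 1.0:
                raise ConfigError(f"rho must lie in [0, 1], got {rho}")
        if self.item_effect_sd < 0:
            raise ConfigError("item_effect_sd must be non-negative")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("ability_low", "ability_high"):
            if key in d and isinstance(d[key], dict):
                d[key] = AbilityLaw(**d[key])
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), sort_keys=True, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


def _simulate_group(
    group: str,
    n: int,
    law: AbilityLaw,
    rho: float,
    m: int,
    item_effect_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    prefix = "L" if group == "low" else "H"
    p_i = law.sample(n, rng)

    # per-(participant, item) recall probability; optional additive item
    # effect on the latent (probit) scale, shared across participants
    if item_effect_sd > 0:
        b = rng.normal(0.0, item_effect_sd, size=2 * m)  # restudy items then test items
        interior = (p_i > 0) & (p_i < 1)
        lat = np.where(interior, ndtri(np.clip(p_i, 1e-12, 1 - 1e-12)), 0.0)
        pij = ndtr(lat[:, None] + b[None, :])
        pij[~interior, :] = p_i[~interior, None]
        p_restudy, p_test = pij[:, :m], pij[:, m:]
    else:
        p_restudy = p_test = np.repeat(p_i[:, None], m, axis=1)

    restudy_correct = rng.random((n, m)) < p_restudy

    # bivariate-normal strengths with correlation rho; threshold at
    # Phi^-1(1 - p), +-inf at the boundaries
    with np.errstate(divide="ignore"):
        z = np.where(p_test <= 0, np.inf, np.where(p_test >= 1, -np.inf, ndtri(1.0 - np.clip(p_test, 1e-300, 1 - 1e-16))))
    x = rng.standard_normal((n, m))
    y = rho * x + np.sqrt(1.0 - rho * rho) * rng.standard_normal((n, m))
    test_correct = (x > z) | (y > z)

    pid = np.array([f"{prefix}{i + 1:04d}" for i in range(n)])
    item_r = np.array([f"r{j + 1:03d}" for j in range(m)])
    item_t = np.array([f"t{j + 1:03d}" for j in range(m)])

    frames = []
    for cond, items, correct in (
        ("restudy", item_r, restudy_correct),
        ("test", item_t, test_correct),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pid, m),
                    "group": group,
                    "condition": cond,
                    "item_id": np.tile(items, n),
                    "correct": correct.astype(np.int64).ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "condition", "item_id"], kind="stable", ignore_index=True)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a trial-level table for one synthetic cohort.

    Returns a long-format DataFrame with columns
    ``participant_id, group, condition, item_id, correct`` and exactly
    ``items_per_condition`` rows per (participant, condition) stratum.
    Byte-identical for identical configs (including the seed).
    """
    rng = np.random.default_rng(config.seed)
    m = config.items_per_condition
    frames = []
    for group, n, law, rho in (
        ("low", config.n_low, config.ability_low, config.rho_low),
        ("high", config.n_high, config.ability_high, config.rho_high),
    ):
        if n > 0:
            frames.append(_simulate_group(group, n, law, rho, m, config.item_effect_sd, rng))
    return pd.concat(frames, ignore_index=True)


def summarize_participants(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant proportions correct by training condition.

    Returns one row per participant with ``pc_r``, ``pc_t``, the
    parameter-free model prediction ``pc_t_pred = 2 pc_r - pc_r**2``, and the
    trial counts ``n_r`` / ``n_t``.  Raises :class:`DataError` naming the
    participant if either condition stratum is missing.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise DataError(f"trial table missing columns: {missing}")
    if len(trials) == 0:
        raise DataError("trial table is empty")

    agg = (
        trials.groupby(["participant_id", "group", "condition"], sort=True)["correct"]
        .agg(["mean", "count"])
        .reset_index()
    )
    wide = agg.pivot(index=["participant_id", "group"], columns="condition", values=["mean", "count"])
    for cond in CONDITIONS:
        if ("mean", cond) not in wide.columns:
            bad = wide.index.get_level_values("participant_id")[0]
            raise DataError(f"participant {bad!r} missing condition {cond!r}")
        absent = wide[("mean", cond)].isna()
        if absent.any():
            bad = wide.index.get_level_values("participant_id")[absent.to_numpy()][0]
            raise DataError(f"participant {bad!r} missing condition {cond!r}")

    out = pd.DataFrame(
        {
            "participant_id": wide.index.get_level_values("participant_id"),
            "group": wide.index.get_level_values("group"),
            "pc_r": wide[("mean", "restudy")].to_numpy(dtype=float),
            "pc_t": wide[("mean", "test")].to_numpy(dtype=float),
            "n_r": wide[("count", "restudy")].to_numpy(dtype=np.int64),
            "n_t": wide[("count", "test")].to_numpy(dtype=np.int64),
        }
    )
    out["pc_t_pred"] = predict_pt(out["pc_r"].to_numpy())
    out = out[["participant_id", "group", "pc_r", "pc_t", "pc_t_pred", "n_r", "n_t"]]
    return out.sort_values("participant_id", kind="stable", ignore_index=True)
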