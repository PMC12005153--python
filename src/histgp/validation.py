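"""Expanding-window forward validation across target years.

For each selection environment and target year, the model is trained on the
k years immediately preceding the target (k = 1 uses the single-year GBLUP,
k >= 2 the genotype-by-year model), the target cohort's GEBVs are predicted
through the relationship matrix, and accuracy is the Pearson correlation
between GEBVs and the target year's BLUEs. The correlation standard error
uses the (1 - r^2) / sqrt(n - 3) approximation.

Checks phenotyped in both training and target years are excluded from the
scored intersection by default — they are not unphenotyped candidates, and
scoring them would flatter the accuracy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blues import detect_checks
from .exceptions import DataError
from .genomics import GMatrix
from .models import fit_gblup, fit_gxy, predict_gebv

__all__ = [
    "WindowPlan", "make_window_plan", "prediction_accuracy", "correlation_se",
    "run_forward_validation", "improvement_summary",
]

RESULT_COLUMNS = ["env", "target_year", "k", "accuracy", "se", "n", "model", "seed"]


@dataclass(frozen=True)
class WindowPlan:
    target_year: object
    k: int
    training_years: tuple


def make_window_plan(all_years, target_year, k: int) -> WindowPlan:
    """The k years immediately preceding the target, chronological order."""
    years = list(all_years)
    if target_year not in years:
        raise DataError(f"target year {target_year!r} not in year list")
    if k < 1:
        raise DataError("k must be >= 1")
    pos = years.index(target_year)
    if k > pos:
        raise DataError(
            f"only {pos} years precede {target_year!r}; maximum k is {pos}")
    return WindowPlan(target_year=target_year, k=k,
                      training_years=tuple(years[pos - k:pos]))


def prediction_accuracy(gebv, blues) -> tuple[float, int]:
    """Pearson correlation between GEBVs and BLUEs over shared ids."""
    gebv = pd.Series(gebv)
    blues = pd.Series(blues)
    shared = gebv.index.intersection(blues.index)
    if len(shared) < 3:
        raise DataError(f"only {len(shared)} shared ids; need >= 3")
    a = gebv.loc[shared].to_numpy(float)
    b = blues.loc[shared].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise DataError("zero variance: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, len(shared)


def correlation_se(r: float, n: int) -> float:
    """Approximate standard error of a Pearson correlation,
    se = (1 - r^2) / sqrt(n - 3)."""
    if n < 4:
        raise DataError("correlation SE needs n >= 4")
    if abs(r) > 1:
        raise DataError("|r| must be <= 1")
    return float((1.0 - r * r) / np.sqrt(n - 3))


def _cell_rng_seed(master_seed, env, target, k) -> int:
    return zlib.crc32(f"{env}|{target}|{k}".encode()) ^ (int(master_seed) & 0x7FFFFFFF)


def run_forward_validation(blues: pd.DataFrame, grm: GMatrix, envs=None,
                           targets=None, max_k: int | None = None, ks=None,
                           model_config: dict | None = None,
                           exclude_checks: bool = True, check_ids=None,
                           seed: int = 0) -> pd.DataFrame:
    """Accuracy grid over (environment, target year, window length).

    ``blues`` is the stacked BlueTable (year, env, gid, blue). Every cell is
    fitted with its own deterministic substream of ``seed`` so cells can be
    recomputed in isolation; failed cells are recorded in
    ``result.attrs["failures"]`` and the run continues.
    """
    cfg = dict(model_config or {})
    years = sorted(blues["year"].unique())
    if envs is None:
        envs = sorted(blues["env"].unique())
    if targets is None:
        targets = [y for y in years if years.index(y) >= 1]
    if check_ids is None:
        check_ids = detect_checks(blues) if exclude_checks else []
    check_set = set(check_ids) if exclude_checks else set()

    rows, failures = [], []
    for env in envs:
        env_blues = blues[blues["env"] == env]
        for target in targets:
            avail = years.index(target)
            if avail < 1:
                failures.append({"env": env, "target_year": target, "k": None,
                                 "reason": "no preceding years"})
                continue
            cell_ks = ks if ks is not None else range(1, min(max_k or avail, avail) + 1)
            target_slice = env_blues[env_blues["year"] == target]
            target_blues = target_slice.set_index("gid")["blue"]
            score_ids = [g for g in target_blues.index if g not in check_set]
            for k in cell_ks:
                if k > avail:
                    continue
                try:
                    plan = make_window_plan(years, target, k)
                    train = env_blues[env_blues["year"].isin(plan.training_years)]
                    cell_seed = _cell_rng_seed(seed, env, target, k)
                    if k == 1:
                        fit = fit_gblup(train[["gid", "blue"]], grm,
                                        random_state=cell_seed, **cfg)
                    else:
                        fit = fit_gxy(train[["year", "gid", "blue"]], grm,
                                      random_state=cell_seed, **cfg)
                    gebv = predict_gebv(fit, score_ids)
                    r, n = prediction_accuracy(gebv, target_blues.loc[score_ids])
                    rows.append((env, target, k, r, correlation_se(r, n), n,
                                 fit.model, seed))
                except Exception as exc:   # record and continue
                    failures.append({"env": env, "target_year": target, "k": k,
                                     "reason": f"{type(exc).__name__}: {exc}"})
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out.attrs["failures"] = failures
    out.attrs["excluded_checks"] = sorted(check_set)
    return out


def improvement_summary(result: pd.DataFrame) -> pd.DataFrame:
    """Accuracy gain of each window over the single-year baseline,
    delta(k) = accuracy(k) - accuracy(k=1) per (env, target year)."""
    frames = []
    for (env, target), grp in result.groupby(["env", "target_year"]):
        base = grp.loc[grp["k"] == 1, "accuracy"]
        if base.empty:
            raise DataError(f"no k=1 baseline for ({env}, {target})")
        g = grp[["env", "target_year", "k", "accuracy"]].copy()
        g["delta"] = g["accuracy"] - float(base.iloc[0])
        frames.append(g)
    return pd.concat(frames, ignore_index=True).sort_values(
        ["env", "target_year", "k"], ignore_index=True)
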