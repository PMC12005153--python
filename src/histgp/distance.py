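"""Single-training-year accuracies against training-target genetic distance.

Trains the single-year GBLUP on each year strictly before a target year,
scores the target cohort, attaches the mean pairwise Euclidean distance
between training and target genotypes (raw dosage rows), and regresses
accuracy on distance per (environment, target year). In a program whose
cohorts grow apart over time this regression is expected to slope downward:
the further back the single training year, the larger the mean distance and
the lower the accuracy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .blues import detect_checks
from .exceptions import DataError
from .genomics import GMatrix, MarkerMatrix, mean_pairwise_distance
from .models import fit_gblup, predict_gebv
from .validation import _cell_rng_seed, prediction_accuracy

__all__ = ["single_year_accuracy_grid", "regress_pa_on_distance",
           "plot_distance_accuracy"]


def single_year_accuracy_grid(blues: pd.DataFrame, grm: GMatrix,
                              markers: MarkerMatrix, envs=None, targets=None,
                              model_config: dict | None = None,
                              exclude_checks: bool = True, check_ids=None,
                              seed: int = 0) -> pd.DataFrame:
    """One row per (env, target year, single training year before it).

    Distances are computed on the supplied marker matrix (use the QC'd and
    imputed matrix that produced the relationship matrix) over all genotypes
    of each cohort; accuracies are scored on candidates only when
    ``exclude_checks`` (checks are phenotyped in training, so they are not a
    prediction target).
    """
    cfg = dict(model_config or {})
    years = sorted(blues["year"].unique())
    if envs is None:
        envs = sorted(blues["env"].unique())
    if targets is None:
        targets = years[1:]
    if check_ids is None:
        check_ids = detect_checks(blues) if exclude_checks else []
    check_set = set(check_ids) if exclude_checks else set()

    cohort_ids = {y: sorted(blues.loc[blues["year"] == y, "gid"].unique())
                  for y in years}
    dist_cache = {}
    rows, failures = [], []
    for env in envs:
        env_blues = blues[blues["env"] == env]
        for target in targets:
            t_pos = years.index(target)
            target_slice = env_blues[env_blues["year"] == target]
            target_blues = target_slice.set_index("gid")["blue"]
            score_ids = [g for g in target_blues.index if g not in check_set]
            for train_year in years[:t_pos]:
                try:
                    key = (train_year, target)
                    if key not in dist_cache:
                        dist_cache[key] = mean_pairwise_distance(
                            markers, cohort_ids[train_year], cohort_ids[target])
                    train = env_blues[env_blues["year"] == train_year]
                    cell_seed = _cell_rng_seed(seed, env, target, train_year)
                    fit = fit_gblup(train[["gid", "blue"]], grm,
                                    random_state=cell_seed, **cfg)
                    gebv = predict_gebv(fit, score_ids)
                    r, n = prediction_accuracy(gebv, target_blues.loc[score_ids])
                    rows.append((env, target, train_year, r, dist_cache[key], n))
                except Exception as exc:
                    failures.append({"env": env, "target_year": target,
                                     "training_year": train_year,
                                     "reason": f"{type(exc).__name__}: {exc}"})
    out = pd.DataFrame(rows, columns=["env", "target_year", "training_year",
                                      "accuracy", "mean_distance", "n"])
    out.attrs["failures"] = failures
    return out


def _degenerate(x):
    return np.std(x) <= 1e-12 * max(1.0, float(np.max(np.abs(x), initial=0.0)))


def _regress_group(acc, dist):
    if len(acc) < 3:
        raise DataError("need >= 3 points for the regression")
    if _degenerate(dist):
        raise DataError("zero variance in distances: regression undefined")
    if _degenerate(acc):
        raise DataError("constant accuracy: correlation undefined")
    res = stats.linregress(dist, acc)
    return res.slope, res.intercept, res.rvalue


def regress_pa_on_distance(table: pd.DataFrame, pooled: bool = False) -> pd.DataFrame:
    """OLS of prediction accuracy on mean genetic distance.

    One summary row per (env, target year); with ``pooled=True`` an extra row
    per environment pools all its target years. Columns: env, target_year,
    slope, intercept, pearson_r, n_points.
    """
    rows = []
    for (env, target), grp in table.groupby(["env", "target_year"]):
        slope, intercept, r = _regress_group(
            grp["accuracy"].to_numpy(float), grp["mean_distance"].to_numpy(float))
        rows.append((env, target, slope, intercept, r, len(grp)))
    if pooled:
        for env, grp in table.groupby("env"):
            slope, intercept, r = _regress_group(
                grp["accuracy"].to_numpy(float),
                grp["mean_distance"].to_numpy(float))
            rows.append((env, "pooled", slope, intercept, r, len(grp)))
    return pd.DataFrame(rows, columns=["env", "target_year", "slope",
                                       "intercept", "pearson_r", "n_points"])


def plot_distance_accuracy(table: pd.DataFrame, path) -> None:
    """Scatter accuracy against mean distance per environment, with the
    pooled fitted line; writes one figure to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    envs = sorted(table["env"].unique())
    fig, axes = plt.subplots(1, len(envs), squeeze=False,
                             figsize=(4 * len(envs), 3.2), sharey=True)
    for ax, env in zip(axes[0], envs):
        grp = table[table["env"] == env]
        for target, sub in grp.groupby("target_year"):
            ax.scatter(sub["mean_distance"], sub["accuracy"], s=18,
                       label=str(target))
        slope, intercept, r = _regress_group(
            grp["accuracy"].to_numpy(float), grp["mean_distance"].to_numpy(float))
        xs = np.linspace(grp["mean_distance"].min(), grp["mean_distance"].max(), 20)
        ax.plot(xs, intercept + slope * xs, color="black", lw=1.2)
        ax.set_title(f"{env} (pooled r = {r:.2f})")
        ax.set_xlabel("mean training-target distance")
    axes[0][0].set_ylabel("prediction accuracy")
    axes[0][-1].legend(fontsize=7, title="target")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
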