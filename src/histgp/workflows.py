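"""End-to-end simulation studies built from the package's own stages.

These are the reproducible experiments the package ships with: calibrate the
stage-one heritability estimator, check the samplers against the closed-form
mixed-model oracle, recover the multi-year variance components, and
reproduce — at desk scale — the two qualitative phenomena the pipeline
exists to measure: accuracy growing with the training window when cohorts
are related, and accuracy falling with training–target genetic distance.

Problem sizes here are deliberate scaled-down analogues of a real program
(8 years x 432 candidate lines, 600 markers); chains for the validation
grids are shortened to 2,500 iterations because posterior-mean point
predictions stabilize long before the variance components do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blues import estimate_h2, fit_stage_one_by
from .distance import regress_pa_on_distance, single_year_accuracy_grid
from .genomics import GMatrix, MarkerMatrix, compute_grm, impute_missing, qc_filter_markers
from .models import fit_gblup, solve_mme, GxYRegressor
from .simdata import FieldDesign, SimConfig, simulate_breeding_program, simulate_study
from .validation import run_forward_validation

__all__ = [
    "scaled_program_config", "AnalysisInputs", "simulate_analysis_inputs",
    "h2_recovery_experiment", "snp_blup_equivalence", "sampler_oracle_agreement",
    "gxy_variance_recovery", "forward_validation_experiment", "distance_experiment",
    "accuracy_slope", "FAST_CHAIN",
]

#: shortened chain used for the validation/distance accuracy grids
FAST_CHAIN = {"n_iter": 2500, "burn_in": 500, "thin": 5}


def scaled_program_config(seed: int, n_years: int = 8, n_subtrials: int = 8,
                          unrelated: bool = False, **overrides) -> SimConfig:
    """Desk-scale breeding program: ``n_subtrials`` x 54 candidates per year."""
    field = FieldDesign()
    defaults = dict(
        n_years=n_years,
        lines_per_year=n_subtrials * field.candidates_per_subtrial,
        n_markers=1000,
        n_chromosomes=10,
        n_qtl=200,
        relatedness_halflife=2.0,
        unrelated_cohorts=unrelated,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class AnalysisInputs:
    """Everything stage two needs, derived from one simulated program."""

    config: SimConfig
    markers: MarkerMatrix      # QC'd and imputed
    grm: GMatrix
    blues: pd.DataFrame        # stacked BlueTable (year, env, gid, blue, se)
    truth: object


def simulate_analysis_inputs(config: SimConfig, env: str = "E1") -> AnalysisInputs:
    """Simulate plots, run stage one per year, build the relationship matrix."""
    markers, truth, plots = simulate_study(config, envs=(env,))
    blues = fit_stage_one_by(plots, by=("year", "env"))
    m = qc_filter_markers(markers)
    m = impute_missing(m)
    grm = compute_grm(m)
    return AnalysisInputs(config=config, markers=m, grm=grm, blues=blues,
                          truth=truth)


# ---------------------------------------------------------------------------
# calibration experiments
# ---------------------------------------------------------------------------

def h2_recovery_experiment(n_sims: int = 50, n_genotypes: int = 500,
                           sigma2_g: float = 1.0, sigma2_e: float = 1.0,
                           n_reps: int = 2, seed: int = 0) -> np.ndarray:
    """Estimated H2 per simulated replicate of a two-rep trial.

    Each replicate draws genotype effects ~ N(0, sigma_g^2) and iid plot
    errors; the REML estimate should average sigma_g^2/(sigma_g^2 +
    sigma_e^2 / r).
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_sims)
    gids = [f"G{i:04d}" for i in range(n_genotypes)]
    for s in range(n_sims):
        g = rng.normal(0.0, np.sqrt(sigma2_g), n_genotypes)
        rows = []
        for rep in range(n_reps):
            eps = rng.normal(0.0, np.sqrt(sigma2_e), n_genotypes)
            for i, gid in enumerate(gids):
                rows.append(("T1", f"R{rep + 1}", "B1", gid, g[i] + eps[i]))
        rec = pd.DataFrame(rows, columns=["trial", "rep", "block", "gid", "value"])
        out[s] = estimate_h2(rec, random_terms=("rep",), n_reps=n_reps)
    return out


def _random_dosage(rng, n, m):
    p = rng.uniform(0.1, 0.5, m)
    return rng.binomial(2, p, size=(n, m)).astype(float)


def snp_blup_equivalence(seed: int = 0, n: int = 100, m: int = 300,
                         sigma2_g: float = 1.0, sigma2_e: float = 1.0) -> float:
    """Max |GBLUP - marker-ridge| over genomic values (should be ~0).

    With G = W W' / c, solving the mixed-model equations at fixed variances
    is identical to ridge regression on the centered markers with penalty
    lambda = c sigma_e^2 / sigma_g^2 followed by W a_hat.
    """
    from sklearn.linear_model import Ridge

    rng = np.random.default_rng(seed)
    dos = _random_dosage(rng, n, m)
    p = dos.mean(axis=0) / 2.0
    w = dos - 2.0 * p
    c = 2.0 * np.sum(p * (1.0 - p))
    g_mat = w @ w.T / c
    beta = rng.normal(0.0, 0.1, m)
    y = w @ beta + rng.normal(0.0, 1.0, n)
    y = y - y.mean()

    sol = solve_mme(y, [("g", g_mat, sigma2_g)], sigma2_e, mu=0.0)
    lam = c * sigma2_e / sigma2_g
    ridge = Ridge(alpha=lam, fit_intercept=False).fit(w, y)
    g_ridge = w @ ridge.coef_
    return float(np.max(np.abs(sol.effects["g"] - g_ridge)))


def sampler_oracle_agreement(seed: int = 0, n: int = 200, m: int = 400,
                             **mcmc) -> float:
    """Correlation between sampled GBLUP genomic values and the exact BLUP
    at the posterior-mean variance components."""
    rng = np.random.default_rng(seed)
    dos = _random_dosage(rng, n, m)
    ids = np.array([f"I{i:03d}" for i in range(n)], dtype=object)
    mm = MarkerMatrix(ids=ids, dosage=dos, markers=pd.DataFrame(
        {"chrom": 1, "pos": np.arange(1, m + 1)},
        index=[f"M{j:04d}" for j in range(m)]))
    grm = compute_grm(mm)
    chol = np.linalg.cholesky(grm.values + 1e-6 * np.eye(n))
    g = chol @ rng.normal(size=n) * np.sqrt(0.5)
    y = pd.Series(4.0 + g + rng.normal(0.0, np.sqrt(0.5), n), index=ids)

    fit = fit_gblup(y, grm, random_state=seed, **mcmc)
    oracle = solve_mme(
        y.to_numpy(), [("g", grm.values, fit.var_components["genomic"]["mean"])],
        fit.residual_var["all"])
    r = np.corrcoef(fit.genomic_values.loc[ids].to_numpy(),
                    oracle.effects["g"])[0, 1]
    return float(r)


def gxy_variance_recovery(seeds, n_years: int = 3, lines_per_year: int = 300,
                          var_g: float = 0.5, var_gy: float = 0.3,
                          var_e: float = 0.7, n_iter: int = 6000,
                          burn_in: int = 1000) -> pd.DataFrame:
    """Recover sigma_g^2 and sigma_Yg^2 from data generated under the
    multi-year model's own assumptions.

    Genomic values are drawn ~ N(0, var_g G) over a simulated related
    program's relationship matrix, interaction deviations ~ N(0, var_gy G_y)
    independently per year, residuals homoscedastic at ``var_e``. The iid
    line term is left out of both simulation and fit (nothing generates it
    here); the year effect stays in the fit as in the full model.
    """
    rows = []
    for seed in seeds:
        cfg = SimConfig(n_years=n_years, lines_per_year=lines_per_year,
                        n_markers=500, n_chromosomes=10, n_qtl=150,
                        n_checks=0, var_gy=0.0, var_year=0.0, var_line=0.0,
                        relatedness_halflife=2.0, seed=seed)
        markers, _ = simulate_breeding_program(cfg)
        grm = compute_grm(markers)
        rng = np.random.default_rng(seed + 1)
        ids = list(markers.ids)
        years = np.asarray(markers.years, dtype=object)
        k = grm.values
        g = np.linalg.cholesky(k + 1e-8 * np.eye(len(ids))) @ rng.normal(size=len(ids))
        g *= np.sqrt(var_g)
        gy = np.zeros(len(ids))
        for ylab in cfg.year_labels():
            idx = np.where(years == ylab)[0]
            kb = k[np.ix_(idx, idx)] + 1e-8 * np.eye(len(idx))
            gy[idx] = np.sqrt(var_gy) * (np.linalg.cholesky(kb) @ rng.normal(size=len(idx)))
        y = g + gy + rng.normal(0.0, np.sqrt(var_e), len(ids))

        est = GxYRegressor(n_iter=n_iter, burn_in=burn_in, thin=5,
                           include_line_effect=False, random_state=seed)
        est.fit(k, y, years=years, gids=np.asarray(ids, dtype=object))
        rows.append((seed, est.sigma2_g_, est.sigma2_gy_,
                     float(np.mean(list(est.residual_vars_.values())))))
    return pd.DataFrame(rows, columns=["seed", "sigma2_g", "sigma2_gy",
                                       "sigma2_e_mean"])


# ---------------------------------------------------------------------------
# forward-validation and distance phenomena
# ---------------------------------------------------------------------------

def forward_validation_experiment(inputs, ks=(1, 2, 3, 4),
                                  model_config: dict | None = None) -> pd.DataFrame:
    """Forward validation of the final year for each simulated program.

    ``inputs`` is a sequence of :class:`AnalysisInputs`; returns stacked
    accuracy rows with a ``sim_seed`` column.
    """
    cfg = dict(FAST_CHAIN if model_config is None else model_config)
    frames = []
    for inp in inputs:
        target = inp.config.year_labels()[-1]
        res = run_forward_validation(inp.blues, inp.grm, targets=[target],
                                     ks=list(ks), model_config=cfg,
                                     seed=inp.config.seed)
        res = res.copy()
        res["sim_seed"] = inp.config.seed
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def accuracy_slope(result: pd.DataFrame) -> pd.Series:
    """Per-seed OLS slope of accuracy on window length k."""
    out = {}
    for seed, grp in result.groupby("sim_seed"):
        out[seed] = stats.linregress(grp["k"], grp["accuracy"]).slope
    return pd.Series(out, name="slope")


def distance_experiment(inputs, n_targets: int = 3,
                        model_config: dict | None = None) -> pd.DataFrame:
    """Single-year-training accuracy vs distance regressions.

    For each simulated program the last ``n_targets`` years serve as target
    years; the returned table stacks the per-(env, target) regression
    summaries plus the pooled-per-environment row (``target_year ==
    "pooled"``), with a ``sim_seed`` column. The pooled correlation is the
    steadier per-program statistic — individual target years have few points
    and bounce, exactly as per-year regressions do on real data.
    """
    cfg = dict(FAST_CHAIN if model_config is None else model_config)
    rows = []
    for inp in inputs:
        targets = inp.config.year_labels()[-n_targets:]
        grid = single_year_accuracy_grid(inp.blues, inp.grm, inp.markers,
                                         targets=targets, model_config=cfg,
                                         seed=inp.config.seed)
        summ = regress_pa_on_distance(grid, pooled=True)
        summ = summ.copy()
        summ["sim_seed"] = inp.config.seed
        rows.append(summ)
    return pd.concat(rows, ignore_index=True)
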