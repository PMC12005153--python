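"""Stage-one phenotypic analysis: per year x environment BLUEs and H2.

The plot model has the genotype effect fixed and the field-design factors
random:

    y = mu + g_i + t_k + r_j(k) + b_l(kj) + eps,   eps ~ iid N(0, sigma_e^2)

BLUEs are the generalized-least-squares genotype estimates at the REML
variance components; broad-sense heritability refits the same model with the
genotype random and reports, on an entry-mean basis,

    H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / r)

with r the number of replications.

REML is profiled over the variance *ratios* lambda_k = sigma_k^2 / sigma_e^2
on the sparse mixed-model equations; with the genotype coded as cell means
the fixed block of the coefficient matrix is diagonal, so a sparse LU gives
both the restricted log-likelihood (via the log-determinant identity
log|V| + log|X'V^-1 X| = n log sigma_e^2 + sum_k q_k log sigma_k^2 + log|C|)
and the solutions in one factorization per evaluation. This stays fast with
a thousand genotype fixed effects, which general-purpose mixed-model
routines do not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .exceptions import ConvergenceError, DataError

__all__ = ["StageOneFit", "fit_stage_one", "estimate_h2", "fit_stage_one_by",
           "h2_from_components", "detect_checks"]

_REQUIRED = ["trial", "rep", "block", "gid", "value"]


@dataclass
class StageOneFit:
    """Result of one stage-one fit (one year x environment)."""

    blues: pd.DataFrame               # columns gid, blue, se
    var_components: dict              # factor -> sigma^2 (incl. "residual")
    h2: float | None
    n_reps_used: float
    converged: bool
    loglik: float
    n_obs: int


def _factor_codes(df):
    """Nested factor codings: trial, rep-in-trial, block-in-rep-in-trial."""
    trial = df["trial"].astype(str)
    rep = trial + "|" + df["rep"].astype(str)
    block = rep + "|" + df["block"].astype(str)
    return {"trial": trial, "rep": rep, "block": block}


def _indicator(labels) -> tuple[sp.csr_matrix, np.ndarray]:
    codes, uniques = pd.factorize(labels, sort=True)
    z = sp.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), len(uniques)),
    )
    return z, uniques


def _reml(y, X, z_blocks, tol=1e-8, max_iter=200):
    """Profiled REML over log variance ratios.

    Returns (theta, sigma2_e, lambdas, loglik, lu, converged, trace) where
    theta stacks fixed-effect estimates then random-effect BLUPs in the
    order of ``z_blocks``.
    """
    n, p = X.shape
    if n <= p:
        raise DataError("fewer observations than fixed effects")
    names = list(z_blocks)
    Zs = [z_blocks[k] for k in names]
    q = [z.shape[1] for z in Zs]
    W = sp.hstack([X] + Zs, format="csc") if Zs else sp.csc_matrix(X)
    WtW = (W.T @ W).tocsc()
    Wty = W.T @ y
    yty = float(y @ y)
    trace = []

    def assemble(lam):
        d = np.concatenate([np.zeros(p)] +
                           [np.full(qk, 1.0 / lk) for qk, lk in zip(q, lam)])
        return (WtW + sp.diags(d)).tocsc()

    def objective(log_lam):
        lam = np.exp(np.clip(log_lam, -30, 30))
        C = assemble(lam)
        try:
            lu = splu(C)
        except RuntimeError as exc:        # singular system
            return 1e12
        theta = lu.solve(Wty)
        quad = yty - float(theta @ Wty)
        if quad <= 0:
            return 1e12
        sigma2_e = quad / (n - p)
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        val = (n - p) * np.log(sigma2_e) \
            + float(np.sum(np.array(q) * np.log(lam))) + logdet
        trace.append((lam.copy(), val))
        return val

    if names:
        x0 = np.full(len(names), np.log(0.1))
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": tol,
                                "maxiter": max_iter * max(1, len(names)),
                                "maxfev": max_iter * 10})
        log_lam = res.x
        converged = bool(res.success)
        if not converged and len(trace) >= 2:
            # accept a flat likelihood surface (boundary variance ratios)
            vals = [v for _, v in trace[-5:]]
            converged = (max(vals) - min(vals)) < 1e-4
        if not converged:
            raise ConvergenceError("REML did not converge", trace=trace)
    else:
        log_lam = np.array([])
        converged = True
    lam = np.exp(np.clip(log_lam, -30, 30))
    C = assemble(lam)
    lu = splu(C)
    theta = lu.solve(Wty)
    quad = yty - float(theta @ Wty)
    sigma2_e = max(quad, 1e-300) / (n - p)
    loglik = -0.5 * objective(log_lam) if names else np.nan
    return theta, sigma2_e, lam, loglik, lu, converged, trace, names, q, p


def _check_connectivity(df):
    """Warn when trials are not linked by shared genotypes (checks)."""
    gid_codes, gids = pd.factorize(df["gid"], sort=True)
    tr_codes, trials = pd.factorize(df["trial"], sort=True)
    if len(trials) <= 1:
        return
    n = len(gids) + len(trials)
    adj = sp.coo_matrix(
        (np.ones(len(df)), (gid_codes, len(gids) + tr_codes)), shape=(n, n)
    )
    ncomp, _ = connected_components(adj + adj.T, directed=False)
    if ncomp > 1:
        warnings.warn(
            "trials are not connected through shared genotypes; "
            "BLUEs are only comparable within trials", stacklevel=3
        )


def fit_stage_one(records: pd.DataFrame, random_terms=("trial", "rep", "block"),
                  compute_h2: bool = True, n_reps: float | None = None,
                  tol: float = 1e-8, max_iter: int = 200) -> StageOneFit:
    """Fit the plot model for one year x environment and return BLUEs.

    Genotype is fixed (cell-means coding, so a BLUE shifts one-for-one with a
    constant added to all plot values); trial, rep-within-trial and
    block-within-rep are random by default. Factors with a single level are
    dropped from the random part (their variance is not identifiable).
    """
    df = records.reset_index(drop=True)
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise DataError(f"records missing columns {missing_cols}")
    if df["value"].isna().any() or not np.isfinite(df["value"]).all():
        raise DataError("plot values must be finite")
    if df["gid"].nunique() < 2:
        raise DataError("need at least 2 genotypes")
    _check_connectivity(df)

    y = df["value"].to_numpy(float)
    X, gids = _indicator(df["gid"])
    codes = _factor_codes(df)
    z_blocks = {}
    for term in random_terms:
        z, levels = _indicator(codes[term])
        if len(levels) > 1:
            z_blocks[term] = z

    theta, sigma2_e, lam, loglik, lu, converged, trace, names, q, p = _reml(
        y, X, z_blocks, tol=tol, max_iter=max_iter)

    blue = theta[:p]
    # standard errors: sigma_e^2 * diag of the fixed block of C^-1
    rhs = np.zeros((X.shape[1] + sum(q), p))
    rhs[:p, :] = np.eye(p)
    cinv_cols = lu.solve(rhs)
    se = np.sqrt(np.maximum(sigma2_e * cinv_cols[np.arange(p), np.arange(p)], 0.0))

    counts = df.groupby("gid", sort=True)["gid"].count()
    r_used = float(n_reps) if n_reps is not None else float(np.median(counts))

    var_components = {k: float(l * sigma2_e) for k, l in zip(names, lam)}
    var_components["residual"] = float(sigma2_e)

    h2 = None
    if compute_h2:
        h2 = estimate_h2(df, random_terms=random_terms, n_reps=r_used,
                         tol=tol, max_iter=max_iter)

    blues = pd.DataFrame({"gid": gids, "blue": blue, "se": se})
    return StageOneFit(blues=blues, var_components=var_components, h2=h2,
                       n_reps_used=r_used, converged=converged,
                       loglik=loglik, n_obs=len(df))


def h2_from_components(sigma2_g: float, sigma2_e: float, r: float) -> float:
    """Entry-mean broad-sense heritability sigma_g^2/(sigma_g^2+sigma_e^2/r)."""
    denom = sigma2_g + sigma2_e / r
    if denom <= 0:
        return np.nan
    return float(np.clip(sigma2_g / denom, 0.0, 1.0))


def estimate_h2(records: pd.DataFrame, random_terms=("trial", "rep", "block"),
                n_reps: float | None = None, tol: float = 1e-8,
                max_iter: int = 200) -> float:
    """Broad-sense heritability from the plot model with genotype random.

    Returns ``NaN`` (with a warning) when the data carry no variance at all —
    an undefined ratio, deliberately distinct from a true H2 of 0.
    """
    df = records.reset_index(drop=True)
    y = df["value"].to_numpy(float)
    if np.var(y) == 0:
        warnings.warn("zero total variance: H2 undefined", stacklevel=2)
        return np.nan
    X = sp.csc_matrix(np.ones((len(df), 1)))
    z_blocks = {}
    zg, _ = _indicator(df["gid"])
    z_blocks["genotype"] = zg
    codes = _factor_codes(df)
    for term in random_terms:
        z, levels = _indicator(codes[term])
        if len(levels) > 1:
            z_blocks[term] = z
    theta, sigma2_e, lam, *_rest, names, q, p = _reml(
        y, X, z_blocks, tol=tol, max_iter=max_iter)
    sigma2_g = float(lam[names.index("genotype")] * sigma2_e)
    if n_reps is None:
        counts = df.groupby("gid")["gid"].count()
        n_reps = float(np.median(counts))
    return h2_from_components(sigma2_g, sigma2_e, n_reps)


def fit_stage_one_by(records: pd.DataFrame, by=("year", "env"),
                     compute_h2: bool = False, **kwargs) -> pd.DataFrame:
    """Stage-one fits per group; returns the stacked BlueTable.

    Columns: the grouping labels, gid, blue, se. This is the table the
    stage-two genomic models consume.
    """
    frames = []
    for key, grp in records.groupby(list(by), sort=True):
        fit = fit_stage_one(grp, compute_h2=compute_h2, **kwargs)
        out = fit.blues.copy()
        key = key if isinstance(key, tuple) else (key,)
        for col, val in zip(by, key):
            out.insert(0, col, val)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def detect_checks(blues: pd.DataFrame) -> list:
    """Genotypes present in more than one year are the repeated checks."""
    seen = blues.groupby("gid")["year"].nunique()
    return sorted(seen.index[seen > 1])
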