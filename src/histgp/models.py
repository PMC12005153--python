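"""Stage-two genomic prediction models on BLUEs.

Two Bayesian mixed models, both Gibbs-sampled with conjugate updates:

* :class:`GBLUPRegressor` — single-year GBLUP,
  ``y = mu 1 + g + eps`` with ``g ~ N(0, sigma_g^2 G)``.

* :class:`GxYRegressor` — the multi-year reaction-norm extension,
  ``y_ij = mu + Y_i + L_j + g_j + Yg_ij + eps_ij`` where the interaction
  covariance is the Hadamard product of the genomic kernel and the
  year-incidence kernel, ``(Zg G Zg') # (Zy Zy') sigma_Yg^2``, and the
  residual variance is heterogeneous across years.

Both are scikit-learn style estimators over precomputed kernels (or raw
dosage with ``kernel="vanraden"``); :func:`fit_gblup` / :func:`fit_gxy` wrap
them with id bookkeeping and return a :class:`ModelFit`. Prediction for
genotypes without phenotypes flows through the relationship matrix
(kernel extension); year and interaction effects for an unobserved year have
prior mean zero and contribute nothing, so a new-year GEBV is the main
genomic term alone.

:func:`solve_mme` is the closed-form mixed-model-equations oracle at fixed
variance components used to validate the samplers.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

from ._gibbs import sweep_eigen_coeffs
from .exceptions import ConfigurationError, DataError
from .genomics import GMatrix, compute_grm, MarkerMatrix

__all__ = [
    "build_gxy_kernel", "solve_mme", "MMESolution",
    "GBLUPRegressor", "GxYRegressor", "ModelFit",
    "fit_gblup", "fit_gxy", "predict_gebv",
]

_RIDGE = 1e-8


# ---------------------------------------------------------------------------
# kernels and the closed-form oracle
# ---------------------------------------------------------------------------

def build_gxy_kernel(g: GMatrix, year_labels, record_gids) -> np.ndarray:
    """Record-level genotype-by-year interaction covariance.

    K[r, s] = G[gid_r, gid_s] if year_r == year_s else 0 — the Hadamard
    product of the record-level genomic kernel with the year-block indicator.
    """
    year_labels = np.asarray(year_labels, dtype=object)
    record_gids = list(record_gids)
    if len(year_labels) != len(record_gids):
        raise DataError("year_labels and record_gids must have equal length")
    kg = g.submatrix(record_gids)
    same_year = (year_labels[:, None] == year_labels[None, :])
    return kg * same_year


@dataclass
class MMESolution:
    mu: float
    effects: dict
    dual: np.ndarray      # V^-1 (y - mu): predicts any kernel term via var * K_cross @ dual


def solve_mme(y, kernels, resid_var, mu=None, ridge: float = _RIDGE) -> MMESolution:
    """Exact BLUP at fixed variance components.

    Parameters
    ----------
    y : (n,) response.
    kernels : sequence of (name, K, variance) with K an (n, n) covariance
        structure and variance its (fixed, positive) component.
    resid_var : scalar or (n,) per-record residual variance.
    mu : fixed intercept; estimated by GLS when None.

    For a single kernel with identity incidence this is
    ``g_hat = sigma_g^2 G (sigma_g^2 G + R)^-1 (y - mu)``.
    """
    y = np.asarray(y, float)
    n = len(y)
    r = np.full(n, float(resid_var)) if np.isscalar(resid_var) \
        else np.asarray(resid_var, float)
    if any(v <= 0 for _, _, v in kernels):
        raise ConfigurationError("kernel variances must be > 0")
    v = np.diag(r + ridge)
    for _, k, var in kernels:
        v = v + var * np.asarray(k, float)
    try:
        cf = cho_factor(v)
    except np.linalg.LinAlgError as exc:
        raise DataError("singular covariance after ridge") from exc
    if mu is None:
        ones = np.ones(n)
        vi1 = cho_solve(cf, ones)
        mu = float(vi1 @ y / (ones @ vi1))
    dual = cho_solve(cf, y - mu)
    effects = {name: var * (np.asarray(k, float) @ dual)
               for name, k, var in kernels}
    return MMESolution(mu=float(mu), effects=effects, dual=dual)


# ---------------------------------------------------------------------------
# shared sampler pieces
# ---------------------------------------------------------------------------

def _eigen_kernel(k, rel_tol=1e-10, mass=0.9999):
    """Truncated eigendecomposition of a PSD kernel (ridge-tolerant)."""
    s, u = np.linalg.eigh((k + k.T) / 2.0)
    s = s[::-1]
    u = u[:, ::-1]
    smax = max(s[0], 0.0)
    if smax <= 0:
        raise DataError("kernel is not positive semi-definite")
    if s[-1] < -1e-6 * smax:
        raise DataError("kernel has large negative eigenvalues")
    keep = s > rel_tol * smax
    cum = np.cumsum(s[keep]) / np.sum(s[keep])
    r = int(np.searchsorted(cum, mass) + 1)
    r = min(r, keep.sum())
    return u[:, :r], s[:r]


def _scaled_inv_chi2(rng, df, scale_sum):
    return scale_sum / rng.chisquare(df)


def _prior_scale(var_y, r2, df0, mean_diag=1.0):
    """Scaled-inverse-chi-squared scale so the prior mode sits at
    var(y) * R^2 / mean(diag(K)) (the usual variance-partition heuristic)."""
    return max(var_y * r2 * (df0 + 2.0) / df0 / mean_diag, 1e-10)


def _ess(chain):
    """Effective sample size via initial-positive-sequence autocorrelation."""
    x = np.asarray(chain, float)
    n = len(x)
    if n < 10 or np.var(x) < 1e-30 * max(1.0, np.max(np.abs(x)) ** 2):
        return float(n)
    x = x - x.mean()
    denom = np.arange(n, 0, -1, dtype=float) * np.var(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        acf = np.nan_to_num(np.correlate(x, x, mode="full")[n - 1:] / denom)
    rho_sum = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        rho_sum += acf[k]
    return float(n / (1.0 + 2.0 * rho_sum))


def _as_rng(random_state):
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


# ---------------------------------------------------------------------------
# single-kernel GBLUP
# ---------------------------------------------------------------------------

class GBLUPRegressor(RegressorMixin, BaseEstimator):
    """Bayesian GBLUP over a genomic kernel.

    Parameters
    ----------
    kernel : {"precomputed", "vanraden"}
        With "precomputed", ``fit`` receives the (n, n) training kernel and
        ``predict`` the (n_new, n_train) cross-kernel. With "vanraden" both
        receive raw dosage matrices and the relationship matrix is built from
        the training allele frequencies.
    n_iter, burn_in, thin : Gibbs chain settings.
    df0, r2 : scaled-inverse-chi-squared prior degrees of freedom and the
        variance-partition heuristic for the prior scales.
    ridge : diagonal ridge applied before factorizations.
    random_state : int, Generator or None.

    Attributes (after fit)
    ----------------------
    mu_ : posterior-mean intercept.
    g_ : (n,) posterior-mean genomic values of the training records.
    sigma2_g_, sigma2_e_ : posterior-mean variance components.
    var_components_ : {"genomic": {...}, "residual": {...}} with mean/sd/ess.
    dual_coef_ : (n,) coefficients for kernel extension to new genotypes.
    """

    def __init__(self, kernel="precomputed", n_iter=12000, burn_in=2000,
                 thin=5, df0=5.0, r2=0.5, ridge=_RIDGE, random_state=None):
        self.kernel = kernel
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.df0 = df0
        self.r2 = r2
        self.ridge = ridge
        self.random_state = random_state

    def _validate(self):
        if self.n_iter <= self.burn_in:
            raise ConfigurationError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.kernel not in ("precomputed", "vanraden"):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")

    def _training_kernel(self, X):
        if self.kernel == "precomputed":
            k = np.asarray(X, float)
            if k.ndim != 2 or k.shape[0] != k.shape[1]:
                raise DataError("precomputed kernel must be square")
            return k
        m = X if isinstance(X, MarkerMatrix) else MarkerMatrix(
            ids=np.array([f"I{i}" for i in range(len(X))], dtype=object),
            dosage=np.asarray(X, float),
            markers=pd.DataFrame({"chrom": 0, "pos": np.arange(1, np.asarray(X).shape[1] + 1)},
                                 index=[f"M{j}" for j in range(np.asarray(X).shape[1])]),
        )
        self._train_freqs_ = m.allele_freq()
        self._train_w_ = m.dosage - 2.0 * self._train_freqs_[None, :]
        self._train_denom_ = 2.0 * np.sum(self._train_freqs_ * (1 - self._train_freqs_))
        return compute_grm(m).values

    def fit(self, X, y):
        self._validate()
        y = np.asarray(y, float).ravel()
        k = self._training_kernel(X)
        n = len(y)
        if k.shape[0] != n:
            raise DataError("kernel size does not match response length")
        if np.isnan(y).any():
            raise DataError("response contains NaN")
        rng = _as_rng(self.random_state)

        u, s = _eigen_kernel(k + self.ridge * np.eye(n))
        r = u.shape[1]
        var_y = float(np.var(y))
        s0_g = _prior_scale(var_y, self.r2, self.df0, float(np.mean(np.diag(k))) or 1.0)
        s0_e = _prior_scale(var_y, 1.0 - self.r2, self.df0)

        mu = float(np.mean(y))
        alpha = np.zeros(r)
        sigma2_g = max(var_y * self.r2, 1e-8)
        sigma2_e = max(var_y * (1 - self.r2), 1e-8)
        uty = u.T @ y
        ut1 = u.T @ np.ones(n)

        keep = []
        sums = {"mu": 0.0, "alpha": np.zeros(r)}
        chains = {"sigma2_g": [], "sigma2_e": [], "mu": []}
        n_kept = 0
        for it in range(self.n_iter):
            # eigen-coefficients: orthonormal design -> diagonal joint update
            e_a = uty - mu * ut1
            prec = 1.0 / sigma2_e + 1.0 / (sigma2_g * s)
            mean = (e_a / sigma2_e) / prec
            alpha = mean + rng.normal(size=r) / np.sqrt(prec)
            g = u @ alpha
            # intercept (flat prior)
            mu = rng.normal(float(np.mean(y - g)), np.sqrt(sigma2_e / n))
            resid = y - mu - g
            # variances
            sigma2_g = _scaled_inv_chi2(
                rng, self.df0 + r, self.df0 * s0_g + float(np.sum(alpha**2 / s)))
            sigma2_e = _scaled_inv_chi2(
                rng, self.df0 + n, self.df0 * s0_e + float(resid @ resid))
            if not (np.isfinite(sigma2_g) and np.isfinite(sigma2_e)):
                raise DataError(f"divergent chain at iteration {it}")
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                n_kept += 1
                sums["mu"] += mu
                sums["alpha"] += alpha
                chains["sigma2_g"].append(sigma2_g)
                chains["sigma2_e"].append(sigma2_e)
                chains["mu"].append(mu)

        self.mu_ = sums["mu"] / n_kept
        self.g_ = u @ (sums["alpha"] / n_kept)
        self.sigma2_g_ = float(np.mean(chains["sigma2_g"]))
        self.sigma2_e_ = float(np.mean(chains["sigma2_e"]))
        self.var_components_ = {
            "genomic": {"mean": self.sigma2_g_,
                        "sd": float(np.std(chains["sigma2_g"])),
                        "ess": _ess(chains["sigma2_g"])},
            "residual": {"mean": self.sigma2_e_,
                         "sd": float(np.std(chains["sigma2_e"])),
                         "ess": _ess(chains["sigma2_e"])},
        }
        self.chains_ = {k_: np.asarray(v) for k_, v in chains.items()}
        self.n_kept_ = n_kept
        kr = k + self.ridge * np.eye(n)
        self.dual_coef_ = np.linalg.solve(kr, self.g_)
        self._k_train_shape_ = n
        return self

    def _cross_kernel(self, X):
        if self.kernel == "precomputed":
            kc = np.asarray(X, float)
            if kc.shape[1] != self._k_train_shape_:
                raise DataError("cross-kernel column count must match training size")
            return kc
        dos = X.dosage if isinstance(X, MarkerMatrix) else np.asarray(X, float)
        w_new = dos - 2.0 * self._train_freqs_[None, :]
        return (w_new @ self._train_w_.T) / self._train_denom_

    def predict(self, X):
        """Posterior-mean prediction mu + genomic value via kernel extension."""
        return self.mu_ + self._cross_kernel(X) @ self.dual_coef_

    def gebv(self, X=None):
        """Genomic values only (no intercept); training values when X is None."""
        if X is None:
            return self.g_.copy()
        return self._cross_kernel(X) @ self.dual_coef_


# ---------------------------------------------------------------------------
# multi-year G x Y model
# ---------------------------------------------------------------------------

class GxYRegressor(RegressorMixin, BaseEstimator):
    """Year + line + genomic + genotype-by-year model on multi-year BLUEs.

    ``fit(K, y, years=..., gids=...)`` takes the record-level genomic kernel
    ``K`` (K[r, s] = G between the lines of records r and s), the response
    and the per-record year labels; ``gids`` (defaulting to one line per
    record) identifies repeated lines such as checks. The interaction kernel
    is derived internally as K masked to same-year pairs. Residual variances
    are per-year by default.
    """

    def __init__(self, n_iter=12000, burn_in=2000, thin=5, df0=5.0, r2=0.5,
                 include_line_effect=True, include_year_effect=True,
                 heterogeneous_residuals=True, ridge=_RIDGE, random_state=None):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.df0 = df0
        self.r2 = r2
        self.include_line_effect = include_line_effect
        self.include_year_effect = include_year_effect
        self.heterogeneous_residuals = heterogeneous_residuals
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, K, y, years, gids=None):
        if self.n_iter <= self.burn_in:
            raise ConfigurationError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        y = np.asarray(y, float).ravel()
        k = np.asarray(K, float)
        n = len(y)
        years = np.asarray(years, dtype=object)
        if k.shape != (n, n) or len(years) != n:
            raise DataError("K, y and years are not aligned")
        year_levels, year_codes = np.unique(years, return_inverse=True)
        n_years = len(year_levels)
        if n_years < 2 and self.include_year_effect:
            raise DataError(
                "a single year cannot identify a year effect; use GBLUPRegressor")
        if self.heterogeneous_residuals:
            if np.bincount(year_codes).min() < 2:
                raise DataError(
                    "heterogeneous residuals need >= 2 records per year")
        if gids is None:
            gids = np.array([f"rec{i}" for i in range(n)], dtype=object)
        gids = np.asarray(gids, dtype=object)
        line_levels, line_codes = np.unique(gids, return_inverse=True)
        n_lines = len(line_levels)
        rng = _as_rng(self.random_state)

        # eigenbases: main genomic kernel over all records; interaction
        # kernel is block-diagonal by year, one eigenbasis per block
        u_g, s_g = _eigen_kernel(k + self.ridge * np.eye(n))
        ut_g = np.ascontiguousarray(u_g.T)
        r_g = len(s_g)
        year_idx = [np.where(year_codes == c)[0] for c in range(n_years)]
        blocks = []
        for idx in year_idx:
            kb = k[np.ix_(idx, idx)] + self.ridge * np.eye(len(idx))
            ub, sb = _eigen_kernel(kb)
            blocks.append((idx, ub, sb))
        r_gy = sum(len(sb) for _, _, sb in blocks)

        var_y = float(np.var(y))
        mean_diag = float(np.mean(np.diag(k))) or 1.0
        s0_g = _prior_scale(var_y, self.r2, self.df0, mean_diag)
        s0_gy = _prior_scale(var_y, self.r2, self.df0, mean_diag)
        s0_e = _prior_scale(var_y, 1.0 - self.r2, self.df0)
        s0_yr = _prior_scale(var_y, self.r2, self.df0)
        s0_l = _prior_scale(var_y, self.r2, self.df0)

        mu = float(np.mean(y))
        year_eff = np.zeros(n_years)
        line_eff = np.zeros(n_lines)
        alpha_g = np.zeros(r_g)
        alpha_b = [np.zeros(len(sb)) for _, _, sb in blocks]
        sigma2_g = max(var_y * 0.25, 1e-8)
        sigma2_gy = max(var_y * 0.15, 1e-8)
        sigma2_yr = max(var_y * 0.1, 1e-8)
        sigma2_l = max(var_y * 0.1, 1e-8)
        resid_vars = np.full(n_years, max(var_y * 0.5, 1e-8))

        resid = y - mu  # running residual: y minus ALL current terms
        sums = {
            "mu": 0.0, "year": np.zeros(n_years), "line": np.zeros(n_lines),
            "alpha_g": np.zeros(r_g),
            "alpha_b": [np.zeros(len(sb)) for _, _, sb in blocks],
        }
        chains = {"sigma2_g": [], "sigma2_gy": [], "sigma2_year": [],
                  "sigma2_line": [], "mu": []}
        resid_chain = []
        n_kept = 0

        line_counts = np.bincount(line_codes, minlength=n_lines)
        for it in range(self.n_iter):
            w = 1.0 / resid_vars[year_codes]          # per-record precision
            w_sum_year = np.bincount(year_codes, weights=w, minlength=n_years)

            # intercept
            tot_w = w.sum()
            m_mu = float(np.sum(w * (resid + mu)) / tot_w)
            mu_new = rng.normal(m_mu, 1.0 / np.sqrt(tot_w))
            resid -= (mu_new - mu)
            mu = mu_new

            # year effects
            if self.include_year_effect:
                e_y = np.bincount(year_codes, weights=w * resid,
                                  minlength=n_years) + w_sum_year * year_eff
                prec_y = w_sum_year + 1.0 / sigma2_yr
                new_y = e_y / prec_y + rng.normal(size=n_years) / np.sqrt(prec_y)
                resid -= (new_y - year_eff)[year_codes]
                year_eff = new_y
                sigma2_yr = _scaled_inv_chi2(
                    rng, self.df0 + n_years,
                    self.df0 * s0_yr + float(np.sum(year_eff**2)))

            # iid line effects
            if self.include_line_effect:
                wl = np.bincount(line_codes, weights=w, minlength=n_lines)
                e_l = np.bincount(line_codes, weights=w * resid,
                                  minlength=n_lines) + wl * line_eff
                prec_l = wl + 1.0 / sigma2_l
                new_l = e_l / prec_l + rng.normal(size=n_lines) / np.sqrt(prec_l)
                resid -= (new_l - line_eff)[line_codes]
                line_eff = new_l
                sigma2_l = _scaled_inv_chi2(
                    rng, self.df0 + n_lines,
                    self.df0 * s0_l + float(np.sum(line_eff**2)))

            # genomic main effect: single-site sweep (heteroscedastic R)
            ssq_g = sweep_eigen_coeffs(ut_g, s_g, w, sigma2_g, resid,
                                       alpha_g, rng.normal(size=r_g))
            sigma2_g = _scaled_inv_chi2(
                rng, self.df0 + r_g, self.df0 * s0_g + ssq_g)

            # interaction: per-year blocks, homoscedastic within year ->
            # exact diagonal joint update in each block eigenbasis
            ssq_gy = 0.0
            for bi, (idx, ub, sb) in enumerate(blocks):
                wy = w[idx[0]]
                ab = alpha_b[bi]
                e_b = ub.T @ resid[idx] + ab
                prec_b = wy + 1.0 / (sigma2_gy * sb)
                new_b = (wy * e_b) / prec_b + rng.normal(size=len(sb)) / np.sqrt(prec_b)
                resid[idx] -= ub @ (new_b - ab)
                alpha_b[bi] = new_b
                ssq_gy += float(np.sum(new_b**2 / sb))
            sigma2_gy = _scaled_inv_chi2(
                rng, self.df0 + r_gy, self.df0 * s0_gy + ssq_gy)

            # residual variances
            if self.heterogeneous_residuals:
                rss = np.bincount(year_codes, weights=resid**2, minlength=n_years)
                n_y = np.bincount(year_codes, minlength=n_years)
                for c in range(n_years):
                    resid_vars[c] = _scaled_inv_chi2(
                        rng, self.df0 + n_y[c], self.df0 * s0_e + rss[c])
            else:
                resid_vars[:] = _scaled_inv_chi2(
                    rng, self.df0 + n, self.df0 * s0_e + float(resid @ resid))
            if not np.all(np.isfinite(resid_vars)) or not np.isfinite(sigma2_g):
                raise DataError(f"divergent chain at iteration {it}")

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                n_kept += 1
                sums["mu"] += mu
                sums["year"] += year_eff
                sums["line"] += line_eff
                sums["alpha_g"] += alpha_g
                for bi in range(len(blocks)):
                    sums["alpha_b"][bi] += alpha_b[bi]
                chains["sigma2_g"].append(sigma2_g)
                chains["sigma2_gy"].append(sigma2_gy)
                chains["sigma2_year"].append(sigma2_yr)
                chains["sigma2_line"].append(sigma2_l)
                chains["mu"].append(mu)
                resid_chain.append(resid_vars.copy())

        self.mu_ = sums["mu"] / n_kept
        self.year_levels_ = year_levels
        self.year_effects_ = sums["year"] / n_kept
        self.line_levels_ = line_levels
        self.line_effects_ = sums["line"] / n_kept
        self.g_ = u_g @ (sums["alpha_g"] / n_kept)     # record-level genomic values
        gy = np.zeros(n)
        for bi, (idx, ub, sb) in enumerate(blocks):
            gy[idx] = ub @ (sums["alpha_b"][bi] / n_kept)
        self.gy_ = gy
        self.sigma2_g_ = float(np.mean(chains["sigma2_g"]))
        self.sigma2_gy_ = float(np.mean(chains["sigma2_gy"]))
        self.residual_vars_ = dict(zip(year_levels,
                                       np.mean(resid_chain, axis=0)))
        self.var_components_ = {
            name: {"mean": float(np.mean(v)), "sd": float(np.std(v)),
                   "ess": _ess(v)}
            for name, v in (("genomic", chains["sigma2_g"]),
                            ("gxy", chains["sigma2_gy"]),
                            ("year", chains["sigma2_year"]),
                            ("line", chains["sigma2_line"]))
        }
        self.chains_ = {k_: np.asarray(v) for k_, v in chains.items()}
        self.n_kept_ = n_kept

        # line-level genomic values and extension coefficients
        first_rec = np.full(n_lines, -1, dtype=int)
        for i in range(n - 1, -1, -1):
            first_rec[line_codes[i]] = i
        # average g over a line's records (identical kernel rows -> identical values)
        g_line = np.bincount(line_codes, weights=self.g_, minlength=n_lines) / line_counts
        self.line_g_ = g_line
        k_lines = k[np.ix_(first_rec, first_rec)] + self.ridge * np.eye(n_lines)
        self.dual_coef_ = np.linalg.solve(k_lines, g_line)
        self._n_train_lines_ = n_lines
        return self

    def predict(self, K_cross):
        """mu + main genomic term for new genotypes.

        ``K_cross`` is (n_new, n_train_lines) — relationships between the new
        genotypes and the unique training lines in ``line_levels_`` order.
        Year and interaction effects of an unobserved year have prior mean
        zero and are omitted.
        """
        kc = np.asarray(K_cross, float)
        if kc.shape[1] != self._n_train_lines_:
            raise DataError("cross-kernel column count must match training lines")
        return self.mu_ + kc @ self.dual_coef_

    def gebv(self, K_cross=None):
        if K_cross is None:
            return self.line_g_.copy()
        return np.asarray(K_cross, float) @ self.dual_coef_


# ---------------------------------------------------------------------------
# functional wrappers with id bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Fitted stage-two model: variance components and genomic values."""

    mu: float
    var_components: dict
    genomic_values: pd.Series            # gid -> posterior-mean GEBV (all kernel ids)
    residual_var: dict
    gxy_values: pd.Series | None = None  # (year, gid) -> posterior-mean Yg
    diagnostics: dict = dc_field(default_factory=dict)
    model: str = "gblup"


def _align_records(blues, grm):
    if isinstance(blues, pd.Series):
        df = blues.rename("blue").rename_axis("gid").reset_index()
    else:
        df = blues.copy()
    missing = [g for g in df["gid"] if g not in grm._lookup]
    if missing:
        raise DataError(f"gids absent from the relationship matrix: {missing[:5]}")
    return df


def _extend_to_all_ids(grm, train_gids, dual, g_train):
    k_cross = grm.values[:, grm.indexer(train_gids)]
    g_all = pd.Series(k_cross @ dual, index=grm.ids)
    g_all.loc[list(train_gids)] = g_train   # exact sampled means for trained ids
    return g_all


def fit_gblup(blues, grm: GMatrix, **params) -> ModelFit:
    """Single-year GBLUP on a BlueTable slice (columns gid, blue).

    Genomic values are returned for every id in the relationship matrix;
    unphenotyped ids receive them through the kernel.
    """
    df = _align_records(blues, grm)
    if len(df) < 10:
        import warnings
        warnings.warn("fewer than 10 records; GBLUP will be prior-dominated",
                      stacklevel=2)
    est = GBLUPRegressor(kernel="precomputed", **params)
    k = grm.submatrix(df["gid"].tolist())
    est.fit(k, df["blue"].to_numpy(float))
    g_all = _extend_to_all_ids(grm, df["gid"].tolist(), est.dual_coef_, est.g_)
    return ModelFit(
        mu=est.mu_,
        var_components=est.var_components_,
        genomic_values=g_all,
        residual_var={"all": est.sigma2_e_},
        diagnostics={"n_kept": est.n_kept_,
                     "ess": {k_: v["ess"] for k_, v in est.var_components_.items()}},
        model="gblup",
    )


def fit_gxy(blues: pd.DataFrame, grm: GMatrix, **params) -> ModelFit:
    """Multi-year genotype-by-year model on a BlueTable (year, gid, blue)."""
    df = _align_records(blues, grm)
    if df["year"].nunique() < 2:
        raise DataError("G x Y model needs >= 2 training years; use fit_gblup")
    est = GxYRegressor(**params)
    gids = df["gid"].tolist()
    k = grm.submatrix(gids)
    est.fit(k, df["blue"].to_numpy(float), years=df["year"].to_numpy(object),
            gids=np.asarray(gids, dtype=object))
    g_line = pd.Series(est.line_g_, index=est.line_levels_)
    g_all = _extend_to_all_ids(grm, list(est.line_levels_), est.dual_coef_,
                               g_line.to_numpy())
    gxy = pd.Series(
        est.gy_,
        index=pd.MultiIndex.from_arrays([df["year"], df["gid"]],
                                        names=["year", "gid"]),
    )
    return ModelFit(
        mu=est.mu_,
        var_components=est.var_components_,
        genomic_values=g_all,
        residual_var={k_: float(v) for k_, v in est.residual_vars_.items()},
        gxy_values=gxy,
        diagnostics={"n_kept": est.n_kept_,
                     "ess": {k_: v["ess"] for k_, v in est.var_components_.items()}},
        model="gxy",
    )


def predict_gebv(fit: ModelFit, target_ids) -> pd.Series:
    """Posterior-mean GEBVs for the requested ids (must be kernel ids)."""
    target_ids = list(target_ids)
    known = fit.genomic_values.index
    unknown = [g for g in target_ids if g not in known]
    if unknown:
        raise DataError(f"ids not in the fitted kernel: {unknown[:5]}")
    return fit.genomic_values.loc[target_ids]
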