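"""Numba kernel for single-site Gibbs updates of kernel eigen-coefficients.

The genomic main effect of the multi-year model has covariance
sigma_g^2 * K over records while the residual variance differs between
years, so its conditional posterior is not diagonal in the eigenbasis of K.
A systematic-scan single-site sweep over the eigen-coefficients is exact and
costs O(n * m) per iteration; the residual vector is updated in place.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_eigen_coeffs(Ut, s, w, var_comp, resid, alpha, z):
    """One Gibbs sweep over eigen-coefficients alpha of a kernel term.

    Parameters
    ----------
    Ut : (m, n) array
        Transposed eigenvector matrix (row j = eigenvector j over records).
    s : (m,) eigenvalues of the kernel.
    w : (n,) per-record residual precisions 1 / sigma_eps^2(record).
    var_comp : float, current variance component of the term.
    resid : (n,) current residual vector (updated in place).
    alpha : (m,) current coefficients (updated in place).
    z : (m,) standard-normal draws for this sweep.

    Returns the updated sum of alpha_j^2 / s_j (for the variance update).
    """
    m, n = Ut.shape
    ssq = 0.0
    for j in range(m):
        a_old = alpha[j]
        c1 = 0.0
        c2 = 0.0
        for i in range(n):
            u = Ut[j, i]
            wu = w[i] * u
            c1 += wu * u
            c2 += wu * resid[i]
        prec = c1 + 1.0 / (var_comp * s[j])
        mean = (c2 + c1 * a_old) / prec
        a_new = mean + z[j] / np.sqrt(prec)
        diff = a_new - a_old
        for i in range(n):
            resid[i] -= Ut[j, i] * diff
        alpha[j] = a_new
        ssq += a_new * a_new / s[j]
    return ssq
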