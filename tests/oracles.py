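"""Independent reference implementations used to check the package.

These deliberately take different numerical routes from the library code:
the spline oracle solves the classical tridiagonal natural-interpolation
system, the GLM oracle maximizes the Poisson log-likelihood with a generic
Newton optimizer, and the PACF oracle solves successive lagged regressions
through explicit normal equations.
"""

import numpy as np
from scipy import linalg, optimize, special


def natural_interp_oracle(knots, fvals, xs):
    """Evaluate the natural cubic interpolant of (knots, fvals) at xs.

    Solves the standard tridiagonal system for the interior second
    derivatives (M_0 = M_K = 0), then evaluates the piecewise cubic; points
    outside the knot range continue linearly with the boundary slope.
    """
    t = np.asarray(knots, float)
    y = np.asarray(fvals, float)
    k = t.size - 1
    h = np.diff(t)
    m = np.zeros(k + 1)
    if k >= 2:
        A = np.zeros((k - 1, k - 1))
        b = np.zeros(k - 1)
        for i in range(1, k):
            r = i - 1
            A[r, r] = (h[i - 1] + h[i]) / 3.0
            if r > 0:
                A[r, r - 1] = h[i - 1] / 6.0
            if r < k - 2:
                A[r, r + 1] = h[i] / 6.0
            b[r] = (y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1]
        m[1:k] = np.linalg.solve(A, b)

    xs = np.asarray(xs, float)
    out = np.empty_like(xs)
    for n, x in np.ndenumerate(xs):
        xc = min(max(x, t[0]), t[-1])
        i = min(np.searchsorted(t, xc, side="right") - 1, k - 1)
        hi = h[i]
        a1 = t[i + 1] - xc
        a2 = xc - t[i]
        val = (
            m[i] * a1**3 / (6 * hi)
            + m[i + 1] * a2**3 / (6 * hi)
            + (y[i] / hi - m[i] * hi / 6) * a1
            + (y[i + 1] / hi - m[i + 1] * hi / 6) * a2
        )
        if x != xc:  # linear continuation with the boundary slope
            j = 0 if x < t[0] else k - 1
            hj = h[j]
            edge = t[0] if x < t[0] else t[-1]
            # derivative of the boundary piece at the boundary knot
            if x < t[0]:
                slope = -m[j] * hj / 2 - (y[j] / hj - m[j] * hj / 6) + (y[j + 1] / hj - m[j + 1] * hj / 6)
            else:
                slope = m[j + 1] * hj / 2 - (y[j] / hj - m[j] * hj / 6) + (y[j + 1] / hj - m[j + 1] * hj / 6)
            val += slope * (x - edge)
        out[n] = val
    return out


def poisson_mle_oracle(X, y, beta0=None):
    """Maximize the Poisson log-likelihood with a generic Newton optimizer."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)

    def nll(b):
        eta = X @ b
        return -(y @ eta - np.exp(eta).sum() - special.gammaln(y + 1).sum())

    def grad(b):
        return -(X.T @ (y - np.exp(X @ b)))

    def hess(b):
        return (X * np.exp(X @ b)[:, None]).T @ X

    if beta0 is None:
        beta0 = np.zeros(X.shape[1])
        beta0[np.argmax(np.all(X == 1.0, axis=0))] = np.log(y.mean() + 0.1)
    res = optimize.minimize(nll, beta0, jac=grad, hess=hess, method="Newton-CG", options={"xtol": 1e-14})
    return res.x


def pacf_ols_oracle(x, max_lag):
    """PACF by successive lagged regressions via explicit normal equations."""
    x = np.asarray(x, float)
    n = x.size
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        y = x[k:]
        cols = [np.ones(n - k)] + [x[k - j : n - j] for j in range(1, k + 1)]
        A = np.column_stack(cols)
        coef = linalg.solve(A.T @ A, A.T @ y, assume_a="sym")
        out[k - 1] = coef[-1]
    return out
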