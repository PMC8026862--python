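"""Independent reference implementations used only to cross-check piprtrack.

Nothing here imports the package's own filter/smoother internals: the
textbook Kalman filter and RTS smoother below are written directly from the
standard matrix equations, and the statsmodels local-level model provides a
third-party reference for the same random-walk state space.
"""

from __future__ import annotations

import numpy as np


def textbook_filter(zs, q, r, x0, p0):
    """Kalman filter for a random-walk state observed directly.

    ``zs`` is (T, k); the state at t=0 is fixed to (x0, p0) as a posterior
    and observations are assimilated from t=1 on.  Returns filtered means,
    filtered covs, one-step prior means and prior covs (each length T).
    """
    zs = np.asarray(zs, dtype=float)
    T, k = zs.shape
    eye = np.eye(k)
    xf = np.zeros((T, k))
    pf = np.zeros((T, k, k))
    xp = np.zeros((T, k))
    pp = np.zeros((T, k, k))
    p0 = p0 * eye if np.isscalar(p0) else np.asarray(p0, dtype=float)
    xf[0] = x0
    pf[0] = p0
    xp[0] = x0
    pp[0] = p0
    for t in range(1, T):
        xp[t] = xf[t - 1]
        pp[t] = pf[t - 1] + q * eye
        s = pp[t] + r * eye
        gain = pp[t] @ np.linalg.inv(s)
        xf[t] = xp[t] + gain @ (zs[t] - xp[t])
        pf[t] = (eye - gain) @ pp[t]
    return xf, pf, xp, pp


def textbook_rts(xf, pf, xp, pp):
    """Fixed-interval Rauch-Tung-Striebel smoother (identity transition)."""
    T, k = xf.shape
    xs = xf.copy()
    ps = pf.copy()
    for t in range(T - 2, -1, -1):
        c = pf[t] @ np.linalg.inv(pp[t + 1])
        xs[t] = xf[t] + c @ (xs[t + 1] - xp[t + 1])
        ps[t] = pf[t] + c @ (ps[t + 1] - pp[t + 1]) @ c.T
    return xs, ps


def statsmodels_local_level(zs_1d, q, r, a0, p0):
    """Filtered and smoothed states from statsmodels for one dimension.

    ``a0``/``p0`` must be the one-step *prior* at the first observation
    (statsmodels applies the measurement update to the supplied initial
    state before any transition).
    """
    from statsmodels.tsa.statespace.mlemodel import MLEModel

    class _RandomWalk(MLEModel):
        def __init__(self, endog):
            super().__init__(
                endog,
                k_states=1,
                initialization="known",
                initial_state=[a0],
                initial_state_cov=[[p0]],
            )
            self["design", 0, 0] = 1.0
            self["transition", 0, 0] = 1.0
            self["selection", 0, 0] = 1.0
            self["state_cov", 0, 0] = q
            self["obs_cov", 0, 0] = r

        def update(self, params, **kwargs):
            pass

    res = _RandomWalk(np.asarray(zs_1d, dtype=float)).smooth([])
    return res.filtered_state[0], res.smoothed_state[0]


def riccati_steady_state(q, r):
    """Closed-form steady state of the scalar random-walk Riccati equation.

    Posterior variance P* solves P = (P + Q) R / (P + Q + R); the steady
    gain is K* = (P* + Q) / (P* + Q + R).
    """
    p_star = (-q + np.sqrt(q * q + 4.0 * q * r)) / 2.0
    k_star = (p_star + q) / (p_star + q + r)
    return p_star, k_star


def pooled_t_test(a, b):
    """Two-sample pooled-variance t-test from the textbook formulas."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * tdist.sf(abs(t_stat), df)
    return t_stat, p


def pearson_with_t_p(x, y):
    """Pearson r and its two-sided t-distribution p-value, by hand."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    n = len(x)
    t_stat = r * np.sqrt((n - 2) / max(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * tdist.sf(abs(t_stat), n - 2)
    return r, p
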