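"""Independent reference implementations used only to cross-check the package.

These are deliberately written with different algorithms than the library:
SIMPLS instead of NIPALS for the PLS regression vector, explicit per-compound
loops for the sMC sums of squares, and full enumeration for the small-sample
Mann-Whitney test.
"""

from itertools import combinations

import numpy as np


def simpls_regression_vector(X, y, n_lv):
    """SIMPLS (de Jong 1993) for a single response on centered/scaled data.

    Returns b such that yhat = X b + mean(y).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    s = Xc.T @ yc
    p_dim = X.shape[1]
    R = np.zeros((p_dim, n_lv))
    Q = np.zeros(n_lv)
    V = np.zeros((p_dim, n_lv))
    for a in range(n_lv):
        r = s.copy()
        t = Xc @ r
        t = t - t.mean()
        normt = np.linalg.norm(t)
        if normt == 0:
            return R[:, :a] @ Q[:a]
        t /= normt
        r /= normt
        p_load = Xc.T @ t
        q_load = yc @ t
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        v /= np.linalg.norm(v)
        s -= v * (v @ s)
        R[:, a], Q[a], V[:, a] = r, q_load, v
    return R @ Q


def smc_f_bruteforce(Xs, b):
    """Per-compound sMC F statistics via explicit residual loops.

    For each compound, regress its scaled column on the prediction direction
    yhat = X b by scalar least squares and form F = SSR / (SSE / (n - 2)).
    """
    Xs = np.asarray(Xs, dtype=float)
    b = np.asarray(b, dtype=float)
    n, p = Xs.shape
    yhat = np.zeros(n)
    for i in range(n):
        for k in range(p):
            yhat[i] += Xs[i, k] * b[k]
    tt = sum(v * v for v in yhat)
    F = np.zeros(p)
    for j in range(p):
        ct = 0.0
        for i in range(n):
            ct += yhat[i] * Xs[i, j]
        slope = ct / tt
        ssr = 0.0
        sse = 0.0
        for i in range(n):
            xhat_ij = slope * yhat[i]
            ssr += xhat_ij**2
            sse += (Xs[i, j] - xhat_ij) ** 2
        F[j] = ssr / (sse / (n - 2))
    return F


def mann_whitney_exact_enumeration(a, b):
    """Two-tailed exact Mann-Whitney p by enumerating all group assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    n_total = len(pooled)

    def u_stat(idx_a):
        mask = np.zeros(n_total, dtype=bool)
        mask[list(idx_a)] = True
        va, vb = pooled[mask], pooled[~mask]
        greater = sum(np.sum(x > vb) + 0.5 * np.sum(x == vb) for x in va)
        return greater

    u_obs = u_stat(range(n1))
    mid = n1 * (n_total - n1) / 2.0
    dev = abs(u_obs - mid)
    count = 0
    total = 0
    for idx in combinations(range(n_total), n1):
        total += 1
        if abs(u_stat(idx) - mid) >= dev - 1e-12:
            count += 1
    return u_obs, count / total


def vip_scores(model):
    """Variable importance in projection, as an independent selector sanity check."""
    W, T, q = model.W, model.T, model.q
    p = W.shape[0]
    ssy = np.array([(q[a] ** 2) * (T[:, a] @ T[:, a]) for a in range(len(q))])
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn**2 @ ssy) / ssy.sum())
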