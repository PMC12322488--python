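"""Independent brute-force oracles used by the test suite.

Each oracle deliberately takes a different computational path from the
implementation it checks: the REML oracle maximizes the unprofiled
restricted likelihood over raw variance parameters with a generic
simplex optimizer; the DTW oracle enumerates every monotone alignment
path; the hull oracle finds hull edges by testing all point pairs.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def reml_loglik_direct(variances, y, X, Zs, method="reml"):
    """Restricted (or full ML) log-likelihood at raw variance parameters.

    ``variances`` = (sigma2, s2_1, ..., s2_K) for K random terms with
    indicator matrices ``Zs``.
    """
    n, p = X.shape
    sigma2, comps = variances[0], variances[1:]
    V = sigma2 * np.eye(n)
    for s2, Z in zip(comps, Zs):
        V += s2 * (Z @ Z.T)
    sign, logdet_V = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet_V + quad)
    if method == "reml":
        sign2, logdet_X = np.linalg.slogdet(XtViX)
        ll += -0.5 * (logdet_X - p * np.log(2 * np.pi))
    return ll


def brute_force_reml(y, X, codes_list, method="reml", n_starts=6, seed=0):
    """Maximize the (restricted) likelihood directly over log-variances.

    Returns (beta, sigma2, variance components, loglik).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Zs = []
    for codes in codes_list:
        codes = np.asarray(codes)
        Z = np.zeros((len(codes), codes.max() + 1))
        Z[np.arange(len(codes)), codes] = 1.0
        Zs.append(Z)
    k = len(Zs)

    def neg(theta):
        v = np.exp(theta)
        return -reml_loglik_direct(v, y, X, Zs, method)

    rng = np.random.default_rng(seed)
    best = None
    starts = [np.zeros(k + 1), np.full(k + 1, -1.5), np.full(k + 1, 0.7)]
    while len(starts) < n_starts:
        starts.append(rng.uniform(-2.5, 1.0, size=k + 1))
    for x0 in starts:
        res = minimize(
            neg, x0, method="Nelder-Mead",
            options={"maxiter": 6000, "xatol": 1e-12, "fatol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    v = np.exp(best.x)
    sigma2, comps = v[0], v[1:]
    n = len(y)
    V = sigma2 * np.eye(n)
    for s2, Z in zip(comps, Zs):
        V += s2 * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return beta, float(sigma2), comps.tolist(), -float(best.fun)


def brute_force_dtw(a, b):
    """Minimum over all monotone boundary-to-boundary alignment paths of the
    weighted cost (diagonal steps weighted 2), normalized by n + m."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    n, m = len(a), len(b)
    cost = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))

    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n:
            walk(i + 1, j, acc + cost[i + 1, j])
        if j + 1 < m:
            walk(i, j + 1, acc + cost[i, j + 1])
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc + 2.0 * cost[i + 1, j + 1])

    walk(0, 0, cost[0, 0])
    return best[0] / (n + m)


def brute_force_hull_area(points):
    """Convex hull area by O(n^3) edge detection plus the shoelace formula."""
    pts = np.asarray(points, float)
    n = len(pts)
    edges = []
    for i, j in itertools.permutations(range(n), 2):
        a, b = pts[i], pts[j]
        d = b - a
        cross = d[0] * (pts[:, 1] - a[1]) - d[1] * (pts[:, 0] - a[0])
        if (cross >= -1e-12).all():
            edges.append((i, j))
    nxt = dict(edges)
    start = edges[0][0]
    order = [start]
    while True:
        nxt_pt = nxt[order[-1]]
        if nxt_pt == start:
            break
        order.append(nxt_pt)
    hull = pts[order]
    x, y = hull[:, 0], hull[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)
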