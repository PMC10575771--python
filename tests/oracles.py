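"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the package's own algorithms:

* :func:`dip_lp` minimises the sup-norm band half-width over piecewise-linear
  unimodal CDFs (atom allowed at the mode) by direct linear programming, one
  LP per candidate mode position.
* :func:`grid_reml` maximises the restricted log-likelihood of the
  normal-normal model over a dense tau^2 grid.
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp(x):
    """Exact dip of a small sample by LP over unimodal CDFs."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    t, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts) / n
    b = np.concatenate(([0.0], c[:-1]))
    m = t.size
    if m == 1:
        return 1.0 / (2 * n)
    best = np.inf
    for pk in range(m):
        nv = m + 2                       # v_0..v_{m-1}, L (left limit), d
        iL, id_ = m, m + 1
        A, rhs = [], []

        def con(coefs, r):
            row = np.zeros(nv)
            for idx, cf in coefs:
                row[idx] += cf
            A.append(row)
            rhs.append(r)

        for j in range(m):
            if j == pk:
                con([(j, -1.0), (id_, -1.0)], -c[j])     # v_pk >= c_pk - d
                con([(j, 1.0), (id_, -1.0)], c[j])       # v_pk <= c_pk + d
                con([(iL, 1.0), (id_, -1.0)], b[j])      # L <= b_pk + d
                con([(iL, -1.0), (id_, -1.0)], -b[j])    # L >= b_pk - d
            else:
                con([(j, -1.0), (id_, -1.0)], -c[j])
                con([(j, 1.0), (id_, -1.0)], b[j])
        for j in range(m - 1):
            con([(j, 1.0), (j + 1, -1.0)], 0.0)          # monotone
        con([(iL, 1.0), (pk, -1.0)], 0.0)                # L <= v_pk
        if pk > 0:
            con([(pk - 1, 1.0), (iL, -1.0)], 0.0)        # v_{pk-1} <= L
        left = [(t[j], j) for j in range(pk)] + [(t[pk], iL)]
        for a in range(1, len(left) - 1):                # convex to the left
            (ti, ii), (tj, jj), (tk, kk) = left[a - 1], left[a], left[a + 1]
            con([(jj, tk - ti), (ii, -(tk - tj)), (kk, -(tj - ti))], 0.0)
        right = [(t[j], j) for j in range(pk, m)]
        for a in range(1, len(right) - 1):               # concave to the right
            (ti, ii), (tj, jj), (tk, kk) = right[a - 1], right[a], right[a + 1]
            con([(jj, -(tk - ti)), (ii, tk - tj), (kk, tj - ti)], 0.0)
        cvec = np.zeros(nv)
        cvec[id_] = 1.0
        res = linprog(cvec, A_ub=np.array(A), b_ub=np.array(rhs),
                      bounds=[(0.0, 1.0)] * (m + 1) + [(0.0, None)],
                      method="highs")
        if res.status == 0:
            best = min(best, res.fun)
    return best


def grid_reml(y, v, tau2_max=1.0, step=1e-5):
    """arg max over a tau^2 grid of the restricted log-likelihood (intercept model)."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    taus = np.arange(0.0, tau2_max + 1e-12, step)
    W = 1.0 / (v[None, :] + taus[:, None])
    sw = W.sum(axis=1)
    mu = (W * y[None, :]).sum(axis=1) / sw
    r = y[None, :] - mu[:, None]
    ll = -0.5 * (np.log(v[None, :] + taus[:, None]).sum(axis=1)
                 + np.log(sw) + (W * r * r).sum(axis=1))
    return float(taus[int(np.argmax(ll))])
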