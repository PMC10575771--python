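"""Numerical core of the dip statistic (numba-accelerated).

The dip of an empirical CDF is the smallest sup-norm band half-width d such
that some unimodal CDF — convex to the left of its mode, concave to the
right, with an atom permitted at the mode — stays within d of the ecdf.

Working on the distinct sorted values t_j with ecdf heights c_j (at t_j) and
b_j (just below t_j), a candidate mode position pk admits a fit at band d
iff three feasibility conditions hold:

* left:   a convex function fits between max(c-d, 0) and min(b+d, 1) on the
          points up to pk (the value at t_pk being the left limit of the
          CDF, bounded by b_pk +/- d);
* right:  a concave function fits on the points from pk on (the mode value
          itself bounded by c_pk +/- d);
* junction: the smallest left limit achievable at t_pk does not exceed the
          largest mode value achievable from the right.  Both envelopes are
          maxima/minima over support lines through one clipped upper point
          and one clipped lower point.

Cheap per-mode lower bounds (greatest convex minorant / least concave
majorant deviations) order the candidate modes; the exact minimum is then
found by bisection on the feasibility test, visiting only modes whose bound
undercuts the current best.  Validated against direct LP minimisation over
piecewise-linear unimodal CDFs (see the test suite).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _cheap_terms(t, c, b, Lterm, Rterm, hull, hv):
    """Unclipped per-mode lower bounds, in band-width (2d) units."""
    m = t.size
    # forward: GCM of the b-points; Lterm[pk] = max_{j<pk} (c_j - gcm(t_j))
    for j in range(m):
        hv[j] = b[j]
    hull[0] = 0
    hn = 1
    gmax = c[0] - b[0]
    Lterm[0] = 0.0
    for pk in range(1, m):
        while hn >= 2:
            i1 = hull[hn - 2]
            i2 = hull[hn - 1]
            if (b[i2] - b[i1]) * (t[pk] - t[i2]) <= (b[pk] - b[i2]) * (t[i2] - t[i1]):
                break
            hn -= 1
        pred = hull[hn - 1]
        if pk - pred > 1:
            for j in range(pred + 1, pk):
                hvj = b[pred] + (b[pk] - b[pred]) * (t[j] - t[pred]) / (t[pk] - t[pred])
                hv[j] = hvj
                if c[j] - hvj > gmax:
                    gmax = c[j] - hvj
        Lterm[pk] = gmax
        hull[hn] = pk
        hn += 1
        hv[pk] = b[pk]
        if c[pk] - b[pk] > gmax:
            gmax = c[pk] - b[pk]
    # backward: LCM of the c-points; Rterm[pk] = max_{j>pk} (lcm(t_j) - b_j)
    for j in range(m):
        hv[j] = c[j]
    hull[0] = m - 1
    hn = 1
    gmax = c[m - 1] - b[m - 1]
    Rterm[m - 1] = 0.0
    for pk in range(m - 2, -1, -1):
        while hn >= 2:
            i1 = hull[hn - 2]
            i2 = hull[hn - 1]
            if (c[i2] - c[pk]) * (t[i1] - t[i2]) >= (c[i1] - c[i2]) * (t[i2] - t[pk]):
                break
            hn -= 1
        pred = hull[hn - 1]
        if pred - pk > 1:
            for j in range(pk + 1, pred):
                hvj = c[pk] + (c[pred] - c[pk]) * (t[j] - t[pk]) / (t[pred] - t[pk])
                hv[j] = hvj
                if hvj - b[j] > gmax:
                    gmax = hvj - b[j]
        Rterm[pk] = gmax
        hull[hn] = pk
        hn += 1
        hv[pk] = c[pk]
        if c[pk] - b[pk] > gmax:
            gmax = c[pk] - b[pk]


@njit(cache=True)
def _feasible(t, c, b, pk, d, hull):
    m = t.size
    # ---- left region: convex fit on points 0..pk-1 plus the left limit at t_pk
    if pk > 0:
        hn = 0
        for j in range(pk + 1):
            uj = b[j] + d
            if uj > 1.0:
                uj = 1.0
            while hn >= 2:
                i1 = hull[hn - 2]
                i2 = hull[hn - 1]
                u1 = b[i1] + d
                if u1 > 1.0:
                    u1 = 1.0
                u2 = b[i2] + d
                if u2 > 1.0:
                    u2 = 1.0
                if (u2 - u1) * (t[j] - t[i2]) <= (uj - u2) * (t[i2] - t[i1]):
                    break
                hn -= 1
            hull[hn] = j
            hn += 1
        for s in range(hn - 1):
            i1 = hull[s]
            i2 = hull[s + 1]
            u1 = b[i1] + d
            if u1 > 1.0:
                u1 = 1.0
            u2 = b[i2] + d
            if u2 > 1.0:
                u2 = 1.0
            for j in range(i1, i2 + 1):
                if j == pk:
                    continue
                loj = c[j] - d
                if loj < 0.0:
                    loj = 0.0
                hvj = u1 + (u2 - u1) * (t[j] - t[i1]) / (t[i2] - t[i1])
                if loj > hvj + 1e-14:
                    return False
    # ---- right region: concave fit on points pk..m-1
    if pk < m - 1:
        hn = 0
        for j in range(m - 1, pk - 1, -1):
            lj = c[j] - d
            if lj < 0.0:
                lj = 0.0
            while hn >= 2:
                i1 = hull[hn - 2]
                i2 = hull[hn - 1]
                l1 = c[i1] - d
                if l1 < 0.0:
                    l1 = 0.0
                l2 = c[i2] - d
                if l2 < 0.0:
                    l2 = 0.0
                if (l2 - l1) * (t[j] - t[i2]) <= (lj - l2) * (t[i2] - t[i1]):
                    break
                hn -= 1
            hull[hn] = j
            hn += 1
        for s in range(hn - 1):
            i1 = hull[s]          # i1 > i2: built right to left
            i2 = hull[s + 1]
            l1 = c[i1] - d
            if l1 < 0.0:
                l1 = 0.0
            l2 = c[i2] - d
            if l2 < 0.0:
                l2 = 0.0
            for j in range(i2, i1 + 1):
                if j == pk:
                    uj = c[j] + d
                else:
                    uj = b[j] + d
                if uj > 1.0:
                    uj = 1.0
                hvj = l2 + (l1 - l2) * (t[j] - t[i2]) / (t[i1] - t[i2])
                if hvj > uj + 1e-14:
                    return False
    # ---- junction: min achievable left limit vs max achievable mode value
    RE = c[pk] + d
    if RE > 1.0:
        RE = 1.0
    if pk < m - 1:
        up1 = b[pk + 1] + d
        if up1 > 1.0:
            up1 = 1.0
        if up1 < RE:
            RE = up1
        hn = 0
        for j in range(m - 1, pk, -1):
            if j <= m - 2:
                uj = b[j] + d
                if uj > 1.0:
                    uj = 1.0
                for s in range(hn):
                    k = hull[s]
                    lk = c[k] - d
                    if lk < 0.0:
                        lk = 0.0
                    sl = (lk - uj) / (t[k] - t[j])
                    vv = uj - sl * (t[j] - t[pk])
                    if vv < RE:
                        RE = vv
            lj = c[j] - d
            if lj < 0.0:
                lj = 0.0
            while hn >= 2:
                i1 = hull[hn - 2]
                i2 = hull[hn - 1]
                l1 = c[i1] - d
                if l1 < 0.0:
                    l1 = 0.0
                l2 = c[i2] - d
                if l2 < 0.0:
                    l2 = 0.0
                if (l2 - l1) * (t[j] - t[i2]) <= (lj - l2) * (t[i2] - t[i1]):
                    break
                hn -= 1
            hull[hn] = j
            hn += 1
    LE = b[pk] - d
    if LE < 0.0:
        LE = 0.0
    if LE > RE + 1e-14:
        return False
    if pk > 0:
        lo1 = c[pk - 1] - d
        if lo1 < 0.0:
            lo1 = 0.0
        if lo1 > LE:
            LE = lo1
        if LE > RE + 1e-14:
            return False
        hn = 0
        for j in range(pk):
            if j >= 1:
                loj = c[j] - d
                if loj < 0.0:
                    loj = 0.0
                for s in range(hn):
                    i = hull[s]
                    ui = b[i] + d
                    if ui > 1.0:
                        ui = 1.0
                    sl = (loj - ui) / (t[j] - t[i])
                    vv = loj + sl * (t[pk] - t[j])
                    if vv > LE:
                        LE = vv
                        if LE > RE + 1e-14:
                            return False
            uj = b[j] + d
            if uj > 1.0:
                uj = 1.0
            while hn >= 2:
                i1 = hull[hn - 2]
                i2 = hull[hn - 1]
                u1 = b[i1] + d
                if u1 > 1.0:
                    u1 = 1.0
                u2 = b[i2] + d
                if u2 > 1.0:
                    u2 = 1.0
                if (u2 - u1) * (t[j] - t[i2]) <= (uj - u2) * (t[i2] - t[i1]):
                    break
                hn -= 1
            hull[hn] = j
            hn += 1
    return LE <= RE + 1e-14


@njit(cache=True)
def _dip_distinct(t, c, b, n):
    m = t.size
    if m == 1:
        return 1.0 / (2.0 * n)
    Lterm = np.empty(m)
    Rterm = np.empty(m)
    hull = np.empty(m + 2, np.int64)
    hv = np.empty(m)
    _cheap_terms(t, c, b, Lterm, Rterm, hull, hv)
    cheap = np.empty(m)
    for j in range(m):
        lt = Lterm[j]
        rt = Rterm[j]
        cheap[j] = 0.5 * (lt if lt > rt else rt)
    order = np.argsort(cheap)
    best = 0.2500000001
    for oi in range(m):
        pk = order[oi]
        lo = cheap[pk]
        if lo >= best:
            break
        if _feasible(t, c, b, pk, lo, hull):
            best = lo
            continue
        if not _feasible(t, c, b, pk, best, hull):
            continue
        hi = best
        it = 0
        while hi - lo > 1e-13 and it < 60:
            mid = 0.5 * (lo + hi)
            if _feasible(t, c, b, pk, mid, hull):
                hi = mid
            else:
                lo = mid
            it += 1
        if hi < best:
            best = hi
    return best


@njit(cache=True)
def _dip_sorted(x):
    """Dip of a sorted 1-d sample (ties allowed)."""
    n = x.size
    m = 1
    for i in range(1, n):
        if x[i] != x[i - 1]:
            m += 1
    t = np.empty(m)
    c = np.empty(m)
    b = np.empty(m)
    j = 0
    cnt = 1
    for i in range(1, n):
        if x[i] != x[i - 1]:
            t[j] = x[i - 1]
            c[j] = cnt / n
            j += 1
        cnt += 1
    t[m - 1] = x[n - 1]
    c[m - 1] = 1.0
    b[0] = 0.0
    for j in range(1, m):
        b[j] = c[j - 1]
    return _dip_distinct(t, c, b, float(n))


@njit(cache=True)
def _dip_batch_sorted(X):
    """Dip of each (sorted) row of a 2-d array."""
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        out[i] = _dip_sorted(X[i])
    return out


@njit(cache=True)
def _dip_ge(x, dref):
    """True iff the dip of the sorted sample x is >= dref.

    Equivalent to ``_dip_sorted(x) >= dref`` but needs no bisection: the dip
    is < dref exactly when some mode admits a fit at band dref (up to the
    knife-edge tolerance shared with :func:`_dip_sorted`).
    """
    n = x.size
    m = 1
    for i in range(1, n):
        if x[i] != x[i - 1]:
            m += 1
    if m == 1:
        return 1.0 / (2.0 * n) >= dref
    t = np.empty(m)
    c = np.empty(m)
    b = np.empty(m)
    j = 0
    cnt = 1
    for i in range(1, n):
        if x[i] != x[i - 1]:
            t[j] = x[i - 1]
            c[j] = cnt / n
            j += 1
        cnt += 1
    t[m - 1] = x[n - 1]
    c[m - 1] = 1.0
    b[0] = 0.0
    for j in range(1, m):
        b[j] = c[j - 1]
    Lterm = np.empty(m)
    Rterm = np.empty(m)
    hull = np.empty(m + 2, np.int64)
    hv = np.empty(m)
    _cheap_terms(t, c, b, Lterm, Rterm, hull, hv)
    cheap = np.empty(m)
    for j in range(m):
        lt = Lterm[j]
        rt = Rterm[j]
        cheap[j] = 0.5 * (lt if lt > rt else rt)
    d = dref - 1e-12
    order = np.argsort(cheap)
    for oi in range(m):
        pk = order[oi]
        if cheap[pk] >= d:
            break
        if _feasible(t, c, b, pk, d, hull):
            return False          # a unimodal CDF fits inside band < dref
    return True


@njit(cache=True)
def _count_ge_batch(X, dref):
    """Number of (sorted) rows of X whose dip is >= dref."""
    cnt = 0
    for i in range(X.shape[0]):
        if _dip_ge(X[i], dref):
            cnt += 1
    return cnt
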