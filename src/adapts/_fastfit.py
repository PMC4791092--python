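"""Numba-compiled fitting engine shared by the public modules.

Everything in here operates on plain float64 arrays so that the
Monte-Carlo experiment harness can run hundreds of thousands of
curve fits per minute on a single core.  The public, documented
interfaces live in :mod:`adapts.signal_models` and :mod:`adapts.core`;
this module is an implementation detail.

Model ids
---------
0  monoexponential            S(TE) = PD * exp(-TE/T2*)           (2 params)
1  offset model               S(TE) = PD * exp(-TE/T2*) + C       (3 params)
2  second moment, free floor  M^2(TE) = S(TE)^2 + K               (3 params)
3  second moment, fixed floor M^2(TE) = S(TE)^2 + K_fixed         (2 params)

Models 2 and 3 are fitted against squared magnitudes; callers pass
``y**2`` as the data vector.

Constraints (T2* in (0, cap], PD/C/K >= 0) are enforced through a
large, sloped penalty so the simplex is pushed back into the feasible
region instead of wandering into negative decay constants.
"""

import numpy as np
from numba import njit

# T2* upper clamp, as a multiple of the longest echo time.  Beyond this
# the data carry essentially no curvature information and the truncation
# rule would keep every echo anyway.
T2_CAP_FACTOR = 10.0

# Simplex settings: relative tolerances on parameters and SSE,
# standard reflection/expansion/contraction coefficients (1, 2, 0.5, 0.5).
_XTOL = 1e-8
_FTOL = 1e-8
_MAXITER = 2000

_PENALTY = 1e12

BRANCH_TRUNCATION = 0
BRANCH_NOISE_CORRECTED = 1


@njit(cache=True)
def _sse(x, te, yd, model_id, fixed_k, t2_cap):
    pd = x[0]
    t2 = x[1]
    pen = 0.0
    if pd < 0.0:
        pen += 1.0 - pd
    if t2 <= 0.0:
        pen += 1.0 - t2
    elif t2 > t2_cap:
        pen += t2 - t2_cap
    third = 0.0
    if x.size > 2:
        third = x[2]
        if third < 0.0:
            pen += 1.0 - third
    if pen > 0.0:
        return _PENALTY * (1.0 + pen)
    s = 0.0
    for i in range(te.size):
        m = pd * np.exp(-te[i] / t2)
        if model_id == 0:
            pred = m
        elif model_id == 1:
            pred = m + third
        elif model_id == 2:
            pred = m * m + third
        else:
            pred = m * m + fixed_k
        r = yd[i] - pred
        s += r * r
    return s


@njit(cache=True)
def _nelder_mead(x0, te, yd, model_id, fixed_k, t2_cap):
    """Minimise ``_sse`` from ``x0``; returns (x, sse, n_iter, converged).

    The initial point is a simplex vertex and the best vertex never
    worsens, so the returned SSE is always <= the SSE at ``x0``.
    """
    n = x0.size
    sim = np.empty((n + 1, n))
    fv = np.empty(n + 1)
    sim[0] = x0
    fv[0] = _sse(x0, te, yd, model_id, fixed_k, t2_cap)
    for i in range(n):
        v = x0.copy()
        if v[i] != 0.0:
            v[i] *= 1.05
        else:
            v[i] = 0.00025
        sim[i + 1] = v
        fv[i + 1] = _sse(v, te, yd, model_id, fixed_k, t2_cap)

    it = 0
    converged = False
    while it < _MAXITER:
        order = np.argsort(fv)
        sim = sim[order]
        fv = fv[order]
        # convergence: simplex collapsed in both parameters and SSE
        dx = 0.0
        xscale = 0.0
        for j in range(n):
            a = abs(sim[0, j])
            if a > xscale:
                xscale = a
            for i in range(1, n + 1):
                d = abs(sim[i, j] - sim[0, j])
                if d > dx:
                    dx = d
        if dx <= _XTOL * (1.0 + xscale) and (fv[n] - fv[0]) <= _FTOL * (1.0 + abs(fv[0])):
            converged = True
            break
        it += 1

        xbar = np.zeros(n)
        for i in range(n):
            xbar += sim[i]
        xbar /= n
        xr = 2.0 * xbar - sim[n]
        fr = _sse(xr, te, yd, model_id, fixed_k, t2_cap)
        if fr < fv[0]:
            xe = xbar + 2.0 * (xbar - sim[n])
            fe = _sse(xe, te, yd, model_id, fixed_k, t2_cap)
            if fe < fr:
                sim[n] = xe
                fv[n] = fe
            else:
                sim[n] = xr
                fv[n] = fr
        elif fr < fv[n - 1]:
            sim[n] = xr
            fv[n] = fr
        else:
            shrink = False
            if fr < fv[n]:
                xc = xbar + 0.5 * (xr - xbar)
                fc = _sse(xc, te, yd, model_id, fixed_k, t2_cap)
                if fc <= fr:
                    sim[n] = xc
                    fv[n] = fc
                else:
                    shrink = True
            else:
                xc = xbar + 0.5 * (sim[n] - xbar)
                fc = _sse(xc, te, yd, model_id, fixed_k, t2_cap)
                if fc < fv[n]:
                    sim[n] = xc
                    fv[n] = fc
                else:
                    shrink = True
            if shrink:
                for i in range(1, n + 1):
                    sim[i] = sim[0] + 0.5 * (sim[i] - sim[0])
                    fv[i] = _sse(sim[i], te, yd, model_id, fixed_k, t2_cap)

    order = np.argsort(fv)
    return sim[order[0]].copy(), fv[order[0]], it, converged


@njit(cache=True)
def _wlsl(te, y, t2_cap):
    """Weighted least squares on the signal logarithm, weights w = S^2.

    Returns (pd, t2).  A non-negative slope (no measurable decay) maps
    to the T2* clamp ceiling.  Values are floored at a tiny positive
    number before the log; the public wrapper rejects non-positive
    signals instead.
    """
    sw = 0.0
    swx = 0.0
    swy = 0.0
    swxx = 0.0
    swxy = 0.0
    for i in range(te.size):
        yi = y[i]
        if yi < 1e-12:
            yi = 1e-12
        w = yi * yi
        ly = np.log(yi)
        sw += w
        swx += w * te[i]
        swy += w * ly
        swxx += w * te[i] * te[i]
        swxy += w * te[i] * ly
    det = sw * swxx - swx * swx
    if det <= 0.0:
        return y[0] if y[0] > 1e-12 else 1e-12, t2_cap
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    if intercept > 700.0:
        intercept = 700.0
    pd = np.exp(intercept)
    if slope >= 0.0:
        t2 = t2_cap
    else:
        t2 = -1.0 / slope
        if t2 > t2_cap:
            t2 = t2_cap
    return pd, t2


@njit(cache=True)
def _fit_second_moment_free(te, y, t2_cap):
    """Three-parameter noise-corrected fit on squared magnitudes."""
    ysq = y * y
    pd0, t20 = _wlsl(te, y, t2_cap)
    kmin = ysq[0]
    for i in range(1, ysq.size):
        if ysq[i] < kmin:
            kmin = ysq[i]
    x0 = np.empty(3)
    x0[0] = pd0
    x0[1] = t20
    x0[2] = kmin
    return _nelder_mead(x0, te, ysq, 2, 0.0, t2_cap)


@njit(cache=True)
def _adapts_core(te, y, p1, p2):
    """One full ADAPTS pass on a single decay vector.

    Returns (t2, branch, t2_initial, n_kept, sse, n_iter, converged)
    where ``converged`` covers the final fit only.
    """
    t2_cap = T2_CAP_FACTOR * te[te.size - 1]

    # step 1: three-parameter offset pre-fit on all echoes, WLSL start
    pd0, t20 = _wlsl(te, y, t2_cap)
    ymin = y[0]
    for i in range(1, y.size):
        if y[i] < ymin:
            ymin = y[i]
    x0 = np.empty(3)
    x0[0] = pd0
    x0[1] = t20
    x0[2] = ymin
    xo, _, _, _ = _nelder_mead(x0, te, y, 1, 0.0, t2_cap)
    t2_initial = xo[1]

    # step 2: drop echoes beyond P1 * initial T2* (inclusive boundary kept)
    thr = p1 * t2_initial
    kept = 0
    for i in range(te.size):
        if te[i] <= thr:
            kept += 1

    # step 3: branch on the surviving echo count
    if kept >= p2 and kept >= 2:
        pdk, t2k = _wlsl(te[:kept], y[:kept], t2_cap)
        xi = np.empty(2)
        xi[0] = pdk
        xi[1] = t2k
        xf, sse, it, conv = _nelder_mead(xi, te[:kept], y[:kept], 0, 0.0, t2_cap)
        return xf[1], BRANCH_TRUNCATION, t2_initial, kept, sse, it, conv, xf[0], 0.0
    xf, sse, it, conv = _fit_second_moment_free(te, y, t2_cap)
    return xf[1], BRANCH_NOISE_CORRECTED, t2_initial, kept, sse, it, conv, xf[0], xf[2]


@njit(cache=True)
def _batch_adapts(te, Y, p1, p2):
    """ADAPTS over the rows of ``Y`` (n_signals x n_echoes)."""
    m = Y.shape[0]
    t2 = np.empty(m)
    branch = np.empty(m, dtype=np.int64)
    conv = np.empty(m, dtype=np.bool_)
    for i in range(m):
        t2i, br, _, _, _, _, cv, _, _ = _adapts_core(te, Y[i], p1, p2)
        t2[i] = t2i
        branch[i] = br
        conv[i] = cv
    return t2, branch, conv


@njit(cache=True)
def _batch_second_moment_fixed(te, Ysq, fixed_k):
    """Two-parameter noise-corrected fit with a known noise floor.

    ``Ysq`` rows are already in the squared-signal domain (e.g. ROI
    means of squared magnitudes, whose expectation is exactly
    S^2 + 2 L sigma^2).  The WLSL start uses the floor-subtracted
    square root of the data.
    """
    m = Ysq.shape[0]
    t2_cap = T2_CAP_FACTOR * te[te.size - 1]
    t2 = np.empty(m)
    conv = np.empty(m, dtype=np.bool_)
    for i in range(m):
        ysq = Ysq[i]
        y0 = np.empty(ysq.size)
        for j in range(ysq.size):
            d = ysq[j] - fixed_k
            y0[j] = np.sqrt(d) if d > 1e-12 else 1e-6
        pd0, t20 = _wlsl(te, y0, t2_cap)
        x0 = np.empty(2)
        x0[0] = pd0
        x0[1] = t20
        xf, _, _, cv = _nelder_mead(x0, te, ysq, 3, fixed_k, t2_cap)
        t2[i] = xf[1]
        conv[i] = cv
    return t2, conv


@njit(cache=True)
def _batch_second_moment_free(te, Y):
    """Three-parameter noise-corrected fit (free floor) over rows of Y."""
    m = Y.shape[0]
    t2_cap = T2_CAP_FACTOR * te[te.size - 1]
    t2 = np.empty(m)
    conv = np.empty(m, dtype=np.bool_)
    for i in range(m):
        xf, _, _, cv = _fit_second_moment_free(te, Y[i], t2_cap)
        t2[i] = xf[1]
        conv[i] = cv
    return t2, conv
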