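"""Compiled Rosenbrock(2,3) stepper for the conservation-reduced kinetic ODEs.

Both conservation laws are exact in the scheme, so the five species reduce to
three independent variables (enc, final, I) with

    P*  = P_total - enc - final
    I*  = I_total - I - enc - final

The stepper is the L-stable Rosenbrock pair of Shampine & Reichelt (the
``ode23s`` pair), with the analytic 3x3 Jacobian solved by explicit Gaussian
elimination.  It exists because the global fit evaluates thousands of stiff
integrations per optimisation; the scipy integrator in :mod:`kinbind.kinetics`
remains the reference path and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

_D = 1.0 / (2.0 + math.sqrt(2.0))
_E32 = 6.0 + math.sqrt(2.0)


@njit(cache=False)
def _rhs(y, p):
    k1, km1, kb, kmb, kr, kmr, Pt, It = p
    e, g, i = y
    pstar = Pt - e - g
    istar = It - i - e - g
    bind = kb * pstar * istar - kmb * e
    rearr = kr * e - kmr * g
    f = np.empty(3)
    f[0] = bind - rearr
    f[1] = rearr
    f[2] = km1 * istar - k1 * i
    return f


@njit(cache=False)
def _jac(y, p):
    k1, km1, kb, kmb, kr, kmr, Pt, It = p
    e, g, i = y
    pstar = Pt - e - g
    istar = It - i - e - g
    J = np.empty((3, 3))
    # d(bind)/de = kb*(-istar - pstar) - kmb ; d(bind)/dg = kb*(-istar - pstar)
    dbind = -kb * (istar + pstar)
    J[0, 0] = dbind - kmb - kr
    J[0, 1] = dbind + kmr
    J[0, 2] = -kb * pstar
    J[1, 0] = kr
    J[1, 1] = -kmr
    J[1, 2] = 0.0
    J[2, 0] = -km1
    J[2, 1] = -km1
    J[2, 2] = -km1 - k1
    return J


@njit(cache=False)
def _solve3(A, b):
    """Solve a 3x3 system by Gaussian elimination with partial pivoting."""
    M = A.copy()
    x = b.copy()
    for c in range(2):
        piv = c
        best = abs(M[c, c])
        for r in range(c + 1, 3):
            if abs(M[r, c]) > best:
                best = abs(M[r, c])
                piv = r
        if piv != c:
            for k in range(3):
                M[c, k], M[piv, k] = M[piv, k], M[c, k]
            x[c], x[piv] = x[piv], x[c]
        for r in range(c + 1, 3):
            m = M[r, c] / M[c, c]
            for k in range(c, 3):
                M[r, k] -= m * M[c, k]
            x[r] -= m * x[c]
    x[2] /= M[2, 2]
    x[1] = (x[1] - M[1, 2] * x[2]) / M[1, 1]
    x[0] = (x[0] - M[0, 1] * x[1] - M[0, 2] * x[2]) / M[0, 0]
    return x


@njit(cache=False)
def _ros23(p, y0, t_eval, rtol, atol):
    n = t_eval.shape[0]
    out = np.empty((n, 3))
    y = y0.copy()
    out[0] = y
    t = t_eval[0]
    thresh = atol / rtol
    # initial step: resolve the fastest first-order rate
    rmax = max(p[0], p[1], p[3], p[4], p[5], p[2] * max(p[6], p[7]), 1e-6)
    h = min(1e-3, 0.1 / rmax)
    I3 = np.eye(3)
    for idx in range(1, n):
        t_next = t_eval[idx]
        while t < t_next:
            if h < 1e-14 * max(t_next, 1.0):
                return out, False
            h_step = min(h, t_next - t)
            J = _jac(y, p)
            W = I3 - (h_step * _D) * J
            f0 = _rhs(y, p)
            k1 = _solve3(W, f0)
            f1 = _rhs(y + 0.5 * h_step * k1, p)
            k2 = _solve3(W, f1 - k1) + k1
            ynew = y + h_step * k2
            f2 = _rhs(ynew, p)
            k3 = _solve3(W, f2 - _E32 * (k2 - f1) - 2.0 * (k1 - f0))
            # error estimate
            errnorm = 0.0
            for j in range(3):
                err = (h_step / 6.0) * (k1[j] - 2.0 * k2[j] + k3[j])
                sc = max(max(abs(y[j]), abs(ynew[j])), thresh)
                e = abs(err) / sc
                if e > errnorm:
                    errnorm = e
            if errnorm <= rtol or h_step <= 1e-13 * max(t_next, 1.0):
                t += h_step
                y = ynew
                fac = 5.0
                if errnorm > 0.0:
                    fac = 0.8 * (rtol / errnorm) ** (1.0 / 3.0)
                    if fac > 5.0:
                        fac = 5.0
                    elif fac < 0.2:
                        fac = 0.2
                h = h_step * fac
            else:
                fac = 0.8 * (rtol / errnorm) ** (1.0 / 3.0)
                if fac < 0.1:
                    fac = 0.1
                h = h_step * fac
        out[idx] = y
    return out, True


def integrate_reduced(rates, P_total, I_total, y0_full, t_eval, rtol, atol):
    """Integrate the reduced system and expand back to the five species.

    Parameters mirror :func:`kinbind.kinetics.simulate`; ``rates`` is the
    6-vector (k1, k_minus1, kb, k_minusb, kr, k_minusr).  Returns
    ``(states, ok)`` with ``states`` of shape (n_times, 5).
    """
    p = np.empty(8)
    p[:6] = rates
    p[6] = P_total
    p[7] = I_total
    # reduced state is (enc, final, I); y0_full order is (P*, I, I*, enc, final)
    y0 = np.array([y0_full[3], y0_full[4], y0_full[1]])
    red, ok = _ros23(p, y0, np.asarray(t_eval, float), rtol, atol)
    enc, fin, i = red[:, 0], red[:, 1], red[:, 2]
    states = np.empty((red.shape[0], 5))
    states[:, 0] = P_total - enc - fin
    states[:, 1] = i
    states[:, 2] = I_total - i - enc - fin
    states[:, 3] = enc
    states[:, 4] = fin
    return states, ok
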