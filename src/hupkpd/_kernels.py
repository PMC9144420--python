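"""Fixed-step RK4 kernels for the pharmacodynamic models.

Daily average drug exposure is piecewise constant per day, so the ODEs are
smooth within each day and a classical RK4 with an integer number of
substeps per day integrates them accurately while landing exactly on the
day boundaries where observations live.  The kernels are compiled with
numba when available (the optimizers call them thousands of times); the
pure-Python definitions are identical and serve as a fallback.

Each kernel returns the state at every day boundary 0..n_days (shape
``(n_days+1, n_state)``).  Substep counts are chosen by the callers from
the fastest linear rate in the parameter set to keep RK4 in its stable,
accurate regime.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


_EPS_CELLS = 1.0  # cells/L floor for the MCV equation denominator


@njit(cache=False)
def _erythro_rhs(y, c, p, dy):
    # p = [kpe_max, psi_e, gamma_e, kdse_max, Kdse50, kte, kde_max, Kde50, alpha, Vm0]
    nse, ne1, ne2, ne3, ne, vm = y[0], y[1], y[2], y[3], y[4], y[5]
    kpe = p[0] / (1.0 + (max(ne, 0.0) / p[1]) ** p[2])
    kdse = p[3] * c / (p[4] + c) if c > 0.0 else 0.0
    kde = p[6] * (1.0 - c / (p[7] + c)) if c > 0.0 else p[6]
    kte = p[5]
    dy[0] = kpe - kte * nse - kdse * nse
    dy[1] = kte * (nse - ne1)
    dy[2] = kte * (ne1 - ne2)
    dy[3] = kte * (ne2 - ne3)
    dy[4] = kte * ne3 - kde * ne
    dy[5] = (p[8] * c + p[9] - vm) * kte * ne3 / max(ne, _EPS_CELLS)


@njit(cache=False)
def _leuko_rhs(y, c, p, dy):
    # p = [kpl_max, psi_l, gamma_l, kdsl_max, Kdsl50, ktl, kdl]
    nsl, nl1, nl2, nl3, nl = y[0], y[1], y[2], y[3], y[4]
    kpl = p[0] / (1.0 + (max(nl, 0.0) / p[1]) ** p[2])
    kdsl = p[3] * c / (p[4] + c) if c > 0.0 else 0.0
    ktl = p[5]
    dy[0] = kpl - ktl * nsl - kdsl * nsl
    dy[1] = ktl * (nsl - nl1)
    dy[2] = ktl * (nl1 - nl2)
    dy[3] = ktl * (nl2 - nl3)
    dy[4] = ktl * nl3 - p[6] * nl


@njit(cache=False)
def _hbf_rhs(y, c, p, dy):
    # p = [kmet, Kmet, kdi, kbf, kaf, Kaf_n (already raised to n), n, kdf]
    ci, fm = y[0], y[1]
    dy[0] = (p[0] * c / (p[1] + c) if c > 0.0 else 0.0) - p[2] * ci
    act = 0.0
    if ci > 0.0:
        cin = ci ** p[6]
        act = p[4] * cin / (p[5] + cin)
    dy[1] = p[3] + act - p[7] * fm


def _make_integrator(rhs):
    @njit(cache=False)
    def integrate(p, cbar, y0, sub):
        n_days = cbar.shape[0]
        ny = y0.shape[0]
        out = np.empty((n_days + 1, ny))
        y = y0.copy()
        out[0] = y
        dt = 1.0 / sub
        k1 = np.empty(ny)
        k2 = np.empty(ny)
        k3 = np.empty(ny)
        k4 = np.empty(ny)
        yt = np.empty(ny)
        for d in range(n_days):
            c = cbar[d]
            for _ in range(sub):
                rhs(y, c, p, k1)
                for i in range(ny):
                    yt[i] = y[i] + 0.5 * dt * k1[i]
                rhs(yt, c, p, k2)
                for i in range(ny):
                    yt[i] = y[i] + 0.5 * dt * k2[i]
                rhs(yt, c, p, k3)
                for i in range(ny):
                    yt[i] = y[i] + dt * k3[i]
                rhs(yt, c, p, k4)
                for i in range(ny):
                    y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                    if y[i] < 0.0:
                        y[i] = 0.0
            out[d + 1] = y
        return out

    return integrate


erythro_integrate = _make_integrator(_erythro_rhs)
leuko_integrate = _make_integrator(_leuko_rhs)
hbf_integrate = _make_integrator(_hbf_rhs)
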