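"""Adaptive Cash-Karp integration kernel for per-organism kinetic systems.

The state vector is laid out as ``[proteins | metabolite pools | flux
accumulators]``.  Protein i obeys d[E]/dt = beta_i - phi*[E].  Reaction j reads
enzyme concentration at ``prot_idx[j]`` and substrate pool at ``sub_idx[j]``
and moves Michaelis-Menten flux ``kcat_j * [E] * [S] / (km_j + [S])`` from the
substrate pool to the product pool (``prod_idx[j]``), also accumulating it into
``acc_idx[j]`` when >= 0.  ``kcat`` values are magnitudes; direction is encoded
in the index arrays.

The stepper is the embedded 4th/5th-order Runge-Kutta-Cash-Karp pair with
standard error-per-step control.  All Runge-Kutta methods conserve linear
invariants exactly, so total metabolite mass is preserved to round-off.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NEGATIVE = 1
STATUS_STEP_UNDERFLOW = 2

# Cash-Karp tableau
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 3.0 / 10.0, -9.0 / 10.0, 6.0 / 5.0
_A51, _A52, _A53, _A54 = -11.0 / 54.0, 5.0 / 2.0, -70.0 / 27.0, 35.0 / 27.0
_A61, _A62, _A63, _A64, _A65 = (1631.0 / 55296.0, 175.0 / 512.0, 575.0 / 13824.0,
                                44275.0 / 110592.0, 253.0 / 4096.0)
# 5th order weights
_B1, _B3, _B4, _B6 = 37.0 / 378.0, 250.0 / 621.0, 125.0 / 594.0, 512.0 / 1771.0
# 4th order weights
_D1, _D3, _D4, _D5, _D6 = (2825.0 / 27648.0, 18575.0 / 48384.0, 13525.0 / 55296.0,
                           277.0 / 14336.0, 1.0 / 4.0)


@njit(cache=True)
def _rhs(y, beta, phi, prot_idx, sub_idx, prod_idx, kcat, km):
    dy = np.zeros_like(y)
    n_prot = beta.shape[0]
    for i in range(n_prot):
        dy[i] = beta[i] - phi * y[i]
    for j in range(kcat.shape[0]):
        s = y[sub_idx[j]]
        if s <= 0.0:
            continue
        flux = kcat[j] * y[prot_idx[j]] * s / (km[j] + s)
        dy[sub_idx[j]] -= flux
        dy[prod_idx[j]] += flux
    return dy


@njit(cache=True)
def _rhs_acc(y, beta, phi, prot_idx, sub_idx, prod_idx, acc_idx, kcat, km):
    dy = np.zeros_like(y)
    n_prot = beta.shape[0]
    for i in range(n_prot):
        dy[i] = beta[i] - phi * y[i]
    for j in range(kcat.shape[0]):
        s = y[sub_idx[j]]
        if s <= 0.0:
            continue
        flux = kcat[j] * y[prot_idx[j]] * s / (km[j] + s)
        dy[sub_idx[j]] -= flux
        dy[prod_idx[j]] += flux
        a = acc_idx[j]
        if a >= 0:
            dy[a] += flux
    return dy


@njit(cache=True)
def integrate_rkck(y0, t_total, beta, phi, prot_idx, sub_idx, prod_idx, acc_idx,
                   kcat, km, rtol, atol, h0, neg_floor, n_pools):
    """Advance the system over ``t_total`` (centi-time-steps).

    ``n_pools`` counts the leading state entries subject to the non-negativity
    guard (proteins and metabolite pools; flux accumulators are excluded).
    Returns ``(y, status)``.
    """
    y = y0.copy()
    t = 0.0
    h = min(h0, t_total)
    max_iter = 10_000_000
    for _ in range(max_iter):
        if t >= t_total:
            return y, STATUS_OK
        if t + h > t_total:
            h = t_total - t

        k1 = _rhs_acc(y, beta, phi, prot_idx, sub_idx, prod_idx, acc_idx, kcat, km)
        k2 = _rhs_acc(y + h * (_A21 * k1), beta, phi, prot_idx, sub_idx, prod_idx,
                      acc_idx, kcat, km)
        k3 = _rhs_acc(y + h * (_A31 * k1 + _A32 * k2), beta, phi, prot_idx, sub_idx,
                      prod_idx, acc_idx, kcat, km)
        k4 = _rhs_acc(y + h * (_A41 * k1 + _A42 * k2 + _A43 * k3), beta, phi, prot_idx,
                      sub_idx, prod_idx, acc_idx, kcat, km)
        k5 = _rhs_acc(y + h * (_A51 * k1 + _A52 * k2 + _A53 * k3 + _A54 * k4), beta,
                      phi, prot_idx, sub_idx, prod_idx, acc_idx, kcat, km)
        k6 = _rhs_acc(y + h * (_A61 * k1 + _A62 * k2 + _A63 * k3 + _A64 * k4
                               + _A65 * k5), beta, phi, prot_idx, sub_idx, prod_idx,
                      acc_idx, kcat, km)

        y5 = y + h * (_B1 * k1 + _B3 * k3 + _B4 * k4 + _B6 * k6)
        y4 = y + h * (_D1 * k1 + _D3 * k3 + _D4 * k4 + _D5 * k5 + _D6 * k6)

        err_norm = 0.0
        for i in range(y.shape[0]):
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = abs(y5[i] - y4[i]) / sc
            if e > err_norm:
                err_norm = e

        if err_norm <= 1.0:
            t += h
            y = y5
            for i in range(n_pools):
                if y[i] < 0.0:
                    if y[i] > -neg_floor:
                        y[i] = 0.0
                    else:
                        return y, STATUS_NEGATIVE
            if err_norm == 0.0:
                h *= 5.0
            else:
                h *= min(5.0, max(0.2, 0.9 * err_norm ** -0.2))
        else:
            h *= max(0.1, 0.9 * err_norm ** -0.25)
        if h < 1e-12:
            return y, STATUS_STEP_UNDERFLOW
    return y, STATUS_STEP_UNDERFLOW
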