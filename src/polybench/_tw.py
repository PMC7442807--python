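"""Tracy-Widom (beta = 1) distribution via the Painleve II representation.

F2(s) = exp(-int_s^inf (x - s) q(x)^2 dx) and
F1(s)^2 = F2(s) * exp(-int_s^inf q(x) dx), where q is the Hastings-McLeod
solution of q'' = s q + 2 q^3.  Shooting from +inf is numerically unstable,
so q is obtained as a boundary-value problem with its asymptotic behaviour
pinned at both ends: q(s) ~ Ai(s) on the right and
q(s) ~ sqrt(-s/2)(1 + s^-3/8 - 73 s^-6/128) on the left.  The CDF is cached
as an interpolation table; beyond the table the tails are numerically 0/1.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.integrate import solve_bvp
from scipy.special import airy

_S_HI = 8.0
_S_LO = -12.0


def _left_asymptote(s: float) -> float:
    return np.sqrt(-s / 2.0) * (1.0 + s**-3 / 8.0 - 73.0 / 128.0 * s**-6)


@lru_cache(maxsize=1)
def _table():
    ai_hi = airy(_S_HI)[0]

    def rhs(s, u):
        return np.vstack([u[1], s * u[0] + 2.0 * u[0] ** 3])

    def bc(ua, ub):
        return np.array([ua[0] - _left_asymptote(_S_LO), ub[0] - ai_hi])

    mesh = np.linspace(_S_LO, _S_HI, 801)
    guess = np.where(mesh < 0.0,
                     np.sqrt(np.maximum(-mesh, 1e-9) / 2.0),
                     airy(np.maximum(mesh, 0.0))[0])
    sol = solve_bvp(rhs, bc, mesh, np.vstack([guess, np.gradient(guess, mesh)]),
                    tol=1e-10, max_nodes=200_000)
    if sol.status != 0:
        raise RuntimeError("Painleve II boundary-value solve failed")
    s = np.linspace(_S_LO, _S_HI, 8001)
    q = sol.sol(s)[0]
    q2 = q * q
    ds = np.diff(s)

    def tailint(f):
        # int_s^{S_HI} f dx by trapezoid, returned on the full grid
        inc = 0.5 * (f[1:] + f[:-1]) * ds
        c = np.concatenate([[0.0], np.cumsum(inc)])
        return c[-1] - c

    I_q = tailint(q)
    I2 = tailint(s * q2) - s * tailint(q2)  # int (x - s) q^2 dx
    logF1 = 0.5 * (-I2 - I_q)  # tail above S_HI negligible (q ~ Ai)
    return s, np.exp(logF1)


def tw1_cdf(x):
    """CDF of the Tracy-Widom beta=1 law."""
    s, cdf = _table()
    return np.clip(np.interp(x, s, cdf, left=0.0, right=1.0), 0.0, 1.0)


def tw1_sf(x):
    """Upper-tail probability of the Tracy-Widom beta=1 law."""
    return 1.0 - tw1_cdf(x)
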