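"""Independent brute-force implementations used as test oracles.

Everything here is deliberately naive -- explicit Python loops, adaptive
quadrature instead of closed forms, a high-accuracy explicit integrator
instead of the stiff solver -- so agreement with the package is a real
cross-check, not a tautology.
"""

import numpy as np
from scipy.integrate import quad, solve_ivp

from nanomill.kernels import agglomeration_rate, breakage_rate, daughter_density


def naive_tables(grid, params):
    """Discrete kernel tables recomputed by loops and adaptive quadrature."""
    x = grid.pivots
    M = x.size
    beta = np.zeros((M, M))
    for j in range(M):
        for k in range(M):
            beta[j, k] = 0.5 * (
                agglomeration_rate(x[j], x[k], params)
                + agglomeration_rate(x[k], x[j], params)
            )
    a = np.array([breakage_rate(float(xi), params) for xi in x])
    a[0] = 0.0
    frag = np.zeros((M, M))
    if params.K1 > 0:
        for j in range(1, M):
            eps = x[j]
            m_sub, _ = quad(
                lambda v: v * daughter_density(v, eps, params),
                0.0, x[0], epsabs=1e-13, epsrel=1e-12,
            )
            frag[0, j] += m_sub / x[0]
            for i in range(j):
                lo, hi = x[i], min(x[i + 1], eps)
                n0, _ = quad(
                    lambda v: daughter_density(v, eps, params),
                    lo, hi, epsabs=1e-13, epsrel=1e-12,
                )
                m1, _ = quad(
                    lambda v: v * daughter_density(v, eps, params),
                    lo, hi, epsabs=1e-13, epsrel=1e-12,
                )
                frag[i, j] += (x[i + 1] * n0 - m1) / (x[i + 1] - x[i])
                frag[i + 1, j] += (m1 - x[i] * n0) / (x[i + 1] - x[i])
    return beta, a, frag


def naive_rhs(N, x, beta, a, frag):
    """Triple-loop evaluation of the discrete population balance."""
    M = x.size
    dN = np.zeros(M)
    for j in range(M):
        for k in range(M):
            s = x[j] + x[k]
            rate = 0.5 * beta[j, k] * N[j] * N[k]
            if s >= x[-1]:
                dN[-1] += rate * s / x[-1]
            else:
                i = int(np.searchsorted(x, s, side="right")) - 1
                w = (s - x[i]) / (x[i + 1] - x[i])
                dN[i] += rate * (1.0 - w)
                dN[i + 1] += rate * w
    for i in range(M):
        dN[i] -= N[i] * sum(beta[i, j] * N[j] for j in range(M))
        dN[i] += sum(a[j] * frag[i, j] * N[j] for j in range(i, M))
        dN[i] -= a[i] * N[i]
    return dN


def naive_simulate(N0, grid, params, times):
    """High-accuracy explicit (non-stiff) integration of the naive RHS."""
    beta, a, frag = naive_tables(grid, params)
    x = grid.pivots
    sol = solve_ivp(
        lambda t, N: naive_rhs(N, x, beta, a, frag),
        (0.0, times[-1]),
        N0,
        method="RK45",
        rtol=1e-10,
        atol=1e-13,
        t_eval=times,
    )
    assert sol.success
    return sol.y
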