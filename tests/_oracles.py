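"""Independent numerical oracles used by the tests.

These deliberately avoid the closed forms and iteration paths implemented in
the package: the steady reaction-diffusion problem is solved by a sparse
finite-difference discretisation, boundary fluxes are read off with
high-order one-sided stencils, and the discrete lattice fixed point is
obtained by direct linear solve.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spl


def solve_steady_bvp(
    b_minus: float,
    b_plus: float,
    F_base: float,
    F_x: float,
    params,
    n_nodes: int = 20001,
):
    """Finite-difference solve of D n'' = -lambda1*rho*s(x) + lambda2*n, n(b±)=0.

    Returns (x, n, J_minus, J_plus) with fluxes from 5-point one-sided
    derivative stencils (O(h^4)).
    """
    x = np.linspace(b_minus, b_plus, n_nodes)
    h = x[1] - x[0]
    D, lam2, rho, lam1 = params.D, params.lambda2, params.rho, params.lambda1
    s = (F_base + F_x * x) * params.L_ref / ((b_plus - b_minus) * params.F_ref)

    main = np.full(n_nodes, -2.0 / h**2 - lam2 / D)
    main[0] = main[-1] = 1.0
    lower = np.full(n_nodes - 1, 1.0 / h**2)
    upper = np.full(n_nodes - 1, 1.0 / h**2)
    lower[-1] = 0.0
    upper[0] = 0.0
    A = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
    rhs = -rho * lam1 / D * s
    rhs[0] = rhs[-1] = 0.0
    n = spl.spsolve(A, rhs)

    d_minus = (-25 * n[0] + 48 * n[1] - 36 * n[2] + 16 * n[3] - 3 * n[4]) / (12 * h)
    d_plus = (25 * n[-1] - 48 * n[-2] + 36 * n[-3] - 16 * n[-4] + 3 * n[-5]) / (12 * h)
    return x, n, D * d_minus, -D * d_plus


def discrete_fixed_point_flux(params, n_sites: int):
    """Exact steady state of the fixed-boundary lattice update by linear solve.

    Uniform reference stress; returns (occupancies, J_out_per_side).
    """
    q = params.q_left
    assert params.q_left == params.q_right
    q0 = params.q_stay
    lam1, lam2, dt = params.lambda1, params.lambda2, params.dt
    A = np.zeros((n_sites, n_sites))
    for i in range(n_sites):
        A[i, i] = q0 - lam2 * dt
        if i > 0:
            A[i, i - 1] = q
        if i < n_sites - 1:
            A[i, i + 1] = q
    N = np.linalg.solve(np.eye(n_sites) - A, np.full(n_sites, lam1 * dt))
    return N, q * N[-1] / dt
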