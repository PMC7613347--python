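"""Independent numerical oracles used by the test suite.

These deliberately avoid the analytic solution paths of the package:
the plate-stack oracle composes discrete plates by the adding method,
the canopy oracle solves the four-stream boundary-value problem by
finite differences, and the slab transmissivity oracle integrates the
defining angular integral by quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.sparse import csc_matrix, lil_matrix
from scipy.sparse.linalg import spsolve

from prosailgpr.canopy import ViewGeometry, suits_coefficients


def transmissivity_quadrature(k: float) -> float:
    """theta(k) = int exp(-k/cos a) 2 cos a sin a da over the hemisphere."""
    val, _ = quad(
        lambda a: np.exp(-k / np.cos(a)) * 2.0 * np.cos(a) * np.sin(a),
        0.0,
        np.pi / 2,
        limit=200,
    )
    return val


def stack_plates_adding(r1: np.ndarray, t1: np.ndarray, r: np.ndarray,
                        t: np.ndarray, n_below: int):
    """Adding method: top plate (r1, t1) over n_below identical symmetric
    plates (r, t).  Returns total (R, T)."""
    Rs, Ts = np.zeros_like(r), np.ones_like(t)
    for _ in range(n_below):
        dn = 1.0 - Rs * r
        Rs, Ts = Rs + Ts * Ts * r / dn, Ts * t / dn
    # combine top plate (asymmetric: from below it behaves like (r, t))
    dn = 1.0 - Rs * r
    T = t1 * Ts / dn
    R = r1 + t1 * Rs * t / dn
    return R, T


def sail_numerical(rho, tau, lai, lidf, geom: ViewGeometry, rsoil,
                   n=1500, diffuse=False) -> float:
    """Finite-difference (Crank-Nicolson) solution of the SAIL
    four-stream BVP with the hot spot off; returns the observer-direction
    reflectance factor for direct (or diffuse) unit irradiance."""
    ks, ko, bf, sob, sof = suits_coefficients(lidf, geom)
    sdb = 0.5 * (ks + bf); sdf = 0.5 * (ks - bf)
    dob = 0.5 * (ko + bf); dof = 0.5 * (ko - bf)
    ddb = 0.5 * (1 + bf); ddf = 0.5 * (1 - bf)
    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1 - sigf
    sb = sdb * rho + sdf * tau; sf = sdf * rho + sdb * tau
    vb = dob * rho + dof * tau; vf = dof * rho + dob * tau
    w = sob * rho + sof * tau

    x = np.linspace(0, lai, n + 1)
    h = x[1] - x[0]
    Es = np.zeros_like(x) if diffuse else np.exp(-ks * x)
    N = n + 1
    A = lil_matrix((2 * N, 2 * N))
    b = np.zeros(2 * N)
    for i in range(n):
        A[i, i + 1] += 1 / h + att / 2
        A[i, i] += -1 / h + att / 2
        A[i, N + i + 1] += -sigb / 2
        A[i, N + i] += -sigb / 2
        b[i] = sf * (Es[i] + Es[i + 1]) / 2
        r = n + i
        A[r, N + i + 1] += 1 / h - att / 2
        A[r, N + i] += -1 / h - att / 2
        A[r, i + 1] += sigb / 2
        A[r, i] += sigb / 2
        b[r] = -sb * (Es[i] + Es[i + 1]) / 2
    A[2 * n, 0] = 1.0
    b[2 * n] = 1.0 if diffuse else 0.0
    A[2 * n + 1, N + n] = 1.0
    A[2 * n + 1, n] = -rsoil
    b[2 * n + 1] = rsoil * Es[n]
    sol = spsolve(csc_matrix(A), b)
    Em, Ep = sol[:N], sol[N:]
    src = w * Es + vb * Em + vf * Ep
    return float(
        np.trapezoid(np.exp(-ko * x) * src, x)
        + np.exp(-ko * lai) * rsoil * (Es[n] + Em[n])
    )


def sail_analytic_direct(leaf_r, leaf_t, lai, lidf, geom, rsoil):
    """Observer-direction reflectance for pure direct irradiance from the
    package's analytic components (hot spot off), for oracle comparison."""
    from prosailgpr.canopy import sail_components

    c = sail_components(np.atleast_1d(leaf_r), np.atleast_1d(leaf_t),
                        lai, lidf, 0.0, geom)
    dn = 1 - rsoil * c["rdd"]
    rsot = (
        c["rso"]
        + ((c["tss"] + c["tsd"]) * c["tdo"]
           + (c["tsd"] + c["tss"] * rsoil * c["rdd"]) * c["too"]) * rsoil / dn
        + c["tsstoo"] * rsoil
    )
    return float(rsot[0])
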