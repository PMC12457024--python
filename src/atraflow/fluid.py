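"""Two-layer Darcy flow with Starling filtration and the Goldmann closure.

Pressure obeys d2p/dx2 = -(mu/K_C) q_C in the choroid (q_C the Starling
transmural source, localized to the choriocapillaris by the density a(x))
and d2p/dx2 = 0 in the sclera. The intraocular pressure IOP enters three
ways -- choroidal blood pressure p_B = IOP + dP_blood, the suprachoroidal
pressure anchor p(L_C) = IOP - dP_SCS, and the unconventional outflow
Q_u(IOP) = Q_prod - C*(IOP - EVP) injected at the interface -- and is
solved for *jointly* with the pressure field: the problem is linear in
(p, IOP) for a frozen albumin profile, so one augmented sparse system
yields both at once, with no shooting iteration.

Sign convention: velocities positive outward (RPE -> orbit); q_C > 0 is
fluid filtering out of capillaries into the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import Grid
from .params import MMHG_PA, ParameterSet, capillary_density

__all__ = [
    "FluidSolution",
    "SolverError",
    "goldmann_unconventional_flow",
    "starling_source",
    "solve_fluid",
    "partition_outflow",
]


class SolverError(RuntimeError):
    """Raised when a linear/nonlinear solve fails or is inconsistent."""


def goldmann_unconventional_flow(iop: float, params: ParameterSet) -> float:
    """Unconventional (uveoscleral + uveovortex) outflow Q_u in m^3/s.

    Goldmann balance: aqueous production splits between the pressure-
    dependent conventional route and the remainder, Q_u = Q_prod -
    C*(IOP - EVP).
    """
    return params.Q_prod - params.C_fac * (iop - params.EVP)


def starling_source(x, p_C, c_total_C, params: ParameterSet, iop: float):
    """Starling transmural filtration source q_C (1/s) in the choroid.

    q_C = a(x) * Lp_star * [(p_B - p_C) - sigma*R*T*(c_B_tot - c_tot)]
    with p_B = IOP + dP_blood. Positive values mean net fluid loss from
    the capillaries into the extravascular tissue.
    """
    a = capillary_density(x, params)
    p_B = iop + params.dP_blood
    osm = params.sigma * params.R_gas * params.T_abs * (
        params.c_SA_blood_total - np.asarray(c_total_C, dtype=float))
    return a * params.Lp_star * ((p_B - np.asarray(p_C, dtype=float)) - osm)


@dataclass
class FluidSolution:
    """Converged pressure/velocity field with its scalar closure values."""

    grid: Grid
    p: np.ndarray          # pressure at nodes (Pa)
    u: np.ndarray          # superficial velocity at nodes (m/s); the
                           # interface node carries the choroid-side value
    q_C: np.ndarray        # Starling source at nodes (1/s), 0 in sclera
    iop: float             # Pa
    Q_u: float             # m^3/s
    u_sclera: float        # constant scleral velocity (m/s)
    uCC: float             # integral of q_C over the choroid (m/s, signed)

    p_B: float = 0.0       # choroidal blood pressure (Pa)

    @property
    def iop_mmHg(self) -> float:
        return self.iop / MMHG_PA

    def u_choroid_at_interface(self) -> float:
        return float(self.u[self.grid.i_interface])

    def velocity_profile(self) -> np.ndarray:
        """u(x) with the sclera-side value at nodes beyond the interface."""
        return self.u

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_m": self.grid.x,
            "p_mmHg": self.p / MMHG_PA,
            "u_m_per_s": self.u,
            "q_C_per_s": self.q_C,
        })


def _one_sided_d1(h1: float, h2: float) -> tuple[float, float, float]:
    """Second-order forward first-derivative weights (node, +1, +2)."""
    return (-(2 * h1 + h2) / (h1 * (h1 + h2)),
            (h1 + h2) / (h1 * h2),
            -h1 / (h2 * (h1 + h2)))


def solve_fluid(params: ParameterSet, grid: Grid,
                c_total: np.ndarray | None = None,
                density: Callable[[np.ndarray], np.ndarray] | None = None,
                ) -> FluidSolution:
    """Solve the pressure BVP and the Goldmann IOP closure in one shot.

    Parameters
    ----------
    c_total
        Tissue albumin-pool concentration (c2 + c3, mol/m^3) on the grid
        nodes, entering the Starling osmotic term. ``None`` means equal to
        blood (zero osmotic gradient); an all-zero profile is allowed.
    density
        Override for the capillary density a(x) on the choroid (used by
        verification against the sharp-step analytic solution).
    """
    x = grid.x
    n = x.size
    k = grid.i_interface
    if c_total is None:
        c_tot = np.full(n, params.c_SA_blood_total)
    else:
        c_tot = np.asarray(c_total, dtype=float)
        if c_tot.shape != (n,):
            raise ValueError("c_total must be defined on the grid nodes")

    if density is None:
        a = np.zeros(n)
        a[: k + 1] = capillary_density(x[: k + 1], params)
    else:
        a = np.zeros(n)
        a[: k + 1] = density(x[: k + 1])

    osm = params.sigma * params.R_gas * params.T_abs * (
        params.c_SA_blood_total - c_tot)

    h = np.diff(x)
    b = np.zeros(n + 1)
    I = n  # column index of the IOP unknown
    rows, cols, vals = [], [], []

    def put(r, c, v):
        rows.append(np.asarray(r, dtype=int))
        cols.append(np.asarray(c, dtype=int))
        vals.append(np.asarray(v, dtype=float))

    # RPE flux BC (second-order one-sided): p'(0) = -mu*u_RPE/K_C
    c0, c1, c2 = _one_sided_d1(h[0], h[1])
    put([0, 0, 0], [0, 1, 2], [c0, c1, c2])
    b[0] = -params.mu * params.u_RPE / params.K_C

    # interior nodes: p'' (+ Starling coupling in the choroid)
    i = np.arange(1, n - 1)
    i = i[i != k]
    hl, hr = h[i - 1], h[i]
    wl = 2.0 / (hl * (hl + hr))
    wc = -2.0 / (hl * hr)
    wr = 2.0 / (hr * (hl + hr))
    g = np.where(i < k, params.mu / params.K_C * a[i] * params.Lp_star, 0.0)
    put(i, i - 1, wl)
    put(i, i, wc - g)
    put(i, i + 1, wr)
    put(i, np.full(i.size, I), g)
    b[i] = g * (osm[i] - params.dP_blood)

    # interface: -K_C/mu p'(LC-) + Qu(IOP)/A_S = -K_S/mu p'(LC+)
    g1, g2 = h[k - 1], h[k - 2]
    bw = ((2 * g1 + g2) / (g1 * (g1 + g2)),
          -(g1 + g2) / (g1 * g2),
          g1 / (g2 * (g1 + g2)))
    fw = _one_sided_d1(h[k], h[k + 1])
    KCu = params.K_C / params.mu
    KSu = params.K_S / params.mu
    put([k] * 6, [k, k - 1, k - 2, k + 1, k + 2, I],
        [-KCu * bw[0] + KSu * fw[0], -KCu * bw[1], -KCu * bw[2],
         KSu * fw[1], KSu * fw[2], -params.C_fac / params.A_S])
    b[k] = -(params.Q_prod + params.C_fac * params.EVP) / params.A_S

    # outer Dirichlet; scalar closure p(L_C) = IOP - dP_SCS
    put([n - 1, n, n], [n - 1, k, I], [1.0, 1.0, -1.0])
    b[n - 1] = params.p_orbit
    b[n] = -params.dP_SCS

    A = sp.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + 1, n + 1)).tocsr()
    z = spla.spsolve(A, b)
    if not np.all(np.isfinite(z)):
        raise SolverError("fluid solve produced non-finite values")
    p, iop = z[:n], float(z[n])

    Q_u = goldmann_unconventional_flow(iop, params)
    p_B = iop + params.dP_blood
    q = np.zeros(n)
    q[: k + 1] = a[: k + 1] * params.Lp_star * (
        (p_B - p[: k + 1]) - osm[: k + 1])

    # conservative velocity: du/dx = q_C in the choroid, jump Qu/A_S at
    # the interface, constant in the sclera
    xc = x[: k + 1]
    u = np.empty(n)
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (q[:k] + q[1: k + 1]) * np.diff(xc))])
    u[: k + 1] = params.u_RPE + cum
    u_if = u[k]
    u_scl = u_if + Q_u / params.A_S
    u[k + 1:] = u_scl
    uCC = float(cum[-1])

    sol = FluidSolution(grid=grid, p=p, u=u, q_C=q, iop=iop, Q_u=Q_u,
                        u_sclera=float(u_scl), uCC=uCC, p_B=p_B)
    # global mass balance must close by construction; verify anyway
    lhs = params.A_S * u_scl - params.A_S * uCC
    rhs = params.A_S * params.u_RPE + Q_u
    if abs(lhs - rhs) > 1e-3 * max(abs(rhs), 1e-30):
        raise SolverError(f"fluid mass balance violated: {lhs} vs {rhs}")
    return sol


def partition_outflow(sol: FluidSolution, params: ParameterSet) -> dict:
    """Split the drained fluid between the uveovortex (choroidal-vessel)
    and uveoscleral (trans-scleral) routes.

    Total drainage equals RPE inflow plus unconventional inflow; the
    choriocapillaris share is the net Starling reabsorption -uCC (zero if
    the capillaries are net filtering).
    """
    uveoscleral = params.A_S * sol.u_sclera
    uveovortex = -params.A_S * min(sol.uCC, 0.0)
    total = uveoscleral + uveovortex
    f_vortex = uveovortex / total if total > 0 else 0.0
    ratio = (uveovortex / uveoscleral) if uveoscleral > 0 else np.inf
    return {
        "uveoscleral_flow": uveoscleral,
        "uveovortex_flow": uveovortex,
        "uveovortex_fraction": f_vortex,
        "uveoscleral_fraction": 1.0 - f_vortex,
        "drainage_ratio": ratio,
    }
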