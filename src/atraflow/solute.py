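"""Steady transport of serum albumin (SA) and the atRA:SA complex.

Both species obey d(u c)/dx - D d2c/dx2 = r + b on the two-layer domain.
In the choroid, atRA synthesis converts free SA to complex at rate
k_prod*a(x) and both species exchange with blood at rate beta*a(x)
(b = beta*(c_B - c)*a). In the sclera, scleral cells take up and degrade
atRA at a rate proportional to the complex concentration and to the
induced CYP26 level, releasing free SA.

Free atRA is never a transported state: with binding at equilibrium the
net binding term equals the synthesis rate, so it is eliminated exactly;
the unbound fraction 1/(1 + Ka*c2) is exposed only as a diagnostic.

Discretization: a conservative finite-volume scheme on the fluid grid,
central interpolation at faces (face Peclet numbers are order 1 here).
Total solute flux is continuous across the choroid-sclera interface even
though the velocity jumps by Q_u/A_S there, because the aqueous inflow at
the suprachoroidal space carries no albumin; the scheme conserves this
automatically. The nonlinear degradation sink is resolved by Picard
iteration on the induction factor with under-relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la

from .fluid import FluidSolution, SolverError
from .grid import Grid
from .params import ParameterSet, capillary_density

__all__ = [
    "SoluteSolution",
    "unbound_fraction",
    "degradation_rate",
    "induction_factor",
    "transmural_exchange",
    "solve_solute",
]


def unbound_fraction(Ka: float, c2: float) -> float:
    """Equilibrium fraction of atRA not bound to albumin.

    Parameters
    ----------
    Ka : association constant (M^-1)
    c2 : free albumin concentration (mol m^-3)

    With Ka*[SA] >> 1 nearly all atRA travels as the atRA:SA complex;
    at typical tissue SA levels (~2e-4 M) only ~0.2-1.5% is unbound.
    """
    if Ka < 0 or c2 < 0:
        raise ValueError("Ka and c2 must be nonnegative")
    return 1.0 / (1.0 + Ka * (c2 * 1e-3))  # mol/m^3 -> M


def induction_factor(c3_S, params: ParameterSet):
    """Saturating CYP26 induction level Ind_max*s/(Ind_C50 + s),
    s = c3/f_u_inc (dimensionless fold induction, in [0, Ind_max))."""
    s = np.asarray(c3_S, dtype=float) / params.f_u_inc
    return params.Ind_max * s / (params.Ind_C50 + s)


def degradation_rate(c3_S, params: ParameterSet):
    """Scleral atRA:SA consumption magnitude (mol m^-3 s^-1).

    r = k_CYP_deg * Ind(c3) * c3: superlinear at low concentration
    (enzyme induction), asymptotically linear with slope
    k_CYP_deg*Ind_max once induction saturates.
    """
    c3 = np.asarray(c3_S, dtype=float)
    if np.any(c3 < 0):
        raise ValueError("concentration must be nonnegative")
    out = params.k_CYP_deg * induction_factor(c3, params) * c3
    return out if out.ndim else float(out)


def transmural_exchange(x, c_i_C, c_i_B: float, params: ParameterSet):
    """Blood-tissue exchange source b_i = beta*(c_B - c_C)*a(x) in the
    choroid (mol m^-3 s^-1); zero in the sclera (no leaky vessels)."""
    x = np.asarray(x, dtype=float)
    a = np.where(x <= params.L_C,
                 capillary_density(np.minimum(x, params.L_C), params), 0.0)
    return params.beta * (c_i_B - np.asarray(c_i_C, dtype=float)) * a


@dataclass
class SoluteSolution:
    """Steady SA / atRA:SA fields with flux decomposition."""

    grid: Grid
    c2: np.ndarray           # free albumin (mol m^-3)
    c3: np.ndarray           # atRA:SA complex (mol m^-3)
    r3_S: np.ndarray         # scleral consumption magnitude (mol m^-3 s^-1)
    J_adv: dict = field(default_factory=dict)   # {2: arr, 3: arr} mol m^-2 s^-1
    J_diff: dict = field(default_factory=dict)
    picard_iterations: int = 0

    @property
    def c_total(self) -> np.ndarray:
        """Osmotically active albumin pool c2 + c3."""
        return self.c2 + self.c3

    def mean(self, species: int, region: str = "S") -> float:
        """Thickness-weighted average over 'C', 'S' or 'CS'."""
        c = {2: self.c2, 3: self.c3}[species]
        k = self.grid.i_interface
        sl = {"C": slice(0, k + 1), "S": slice(k, None),
              "CS": slice(None)}[region]
        x = self.grid.x[sl]
        return float(np.trapezoid(c[sl], x) / (x[-1] - x[0]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_m": self.grid.x,
            "c2_mM": self.c2,
            "c3_nM": self.c3 * 1e6,
            "J_adv_2": self.J_adv[2], "J_diff_2": self.J_diff[2],
            "J_adv_3": self.J_adv[3], "J_diff_3": self.J_diff[3],
            "r3_S_mM_per_s": self.r3_S,
        })


# ---------------------------------------------------------------------------
# assembly helpers
# ---------------------------------------------------------------------------

def _face_fields(params: ParameterSet, grid: Grid, fluid: FluidSolution,
                 D_C: float, D_S: float):
    """Velocity and diffusivity at the n-1 interior faces."""
    x = grid.x
    k = grid.i_interface
    xf = 0.5 * (x[:-1] + x[1:])
    in_cho = xf < grid.L_C
    uf = np.where(in_cho,
                  np.interp(xf, x[: k + 1], fluid.u[: k + 1]),
                  fluid.u_sclera)
    Df = np.where(in_cho, D_C, D_S)
    return uf, Df


def _transport_band(grid: Grid, uf, Df, u_out: float) -> np.ndarray:
    """Tridiagonal flux-divergence operator in solve_banded (1,1) layout.

    Face flux F_j = uf*(c_j + c_{j+1})/2 - Df*(c_{j+1} - c_j)/h_j
    contributes +F_j to cell j and -F_j to cell j+1; no-flux left
    boundary, pure advective outflow u_out*c at the right boundary.
    """
    n = grid.n
    h = grid.h
    ab = np.zeros((3, n))
    adv = 0.5 * uf
    dif = Df / h
    ab[1, :-1] += adv + dif         # dF_j/dc_j into cell j
    ab[0, 1:] = adv - dif           # dF_j/dc_{j+1} into cell j
    ab[1, 1:] += -(adv - dif)       # -F_j into cell j+1
    ab[2, :-1] = -(adv + dif)
    ab[1, -1] += u_out
    return ab


def _solve_linear(ab_base: np.ndarray, lin_coeff: np.ndarray,
                  rhs_src: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve (transport + lin_coeff*w on the diagonal) c = rhs_src*w."""
    ab = ab_base.copy()
    ab[1] += lin_coeff * w
    return la.solve_banded((1, 1), ab, rhs_src * w)


def _layer_weights(grid: Grid):
    """Per-cell volume lying in the choroid / sclera (interface cell is
    split at x = L_C)."""
    n = grid.n
    k = grid.i_interface
    h = grid.h
    w = grid.cell_widths()
    wcho = np.zeros(n)
    wscl = np.zeros(n)
    wcho[:k] = w[:k]
    wcho[k] = h[k - 1] / 2
    wscl[k] = h[k] / 2
    wscl[k + 1:] = w[k + 1:]
    return wcho, wscl, w


def solve_solute(params: ParameterSet, grid: Grid, fluid: FluidSolution,
                 tol: float = 1e-10, max_iter: int = 300,
                 warm_start: "SoluteSolution | None" = None,
                 strict: bool = True) -> SoluteSolution:
    """Solve the coupled SA / atRA:SA steady transport on a fluid field.

    The complex (species 3) equation is closed in itself; it is solved
    first by Picard iteration on the induction factor, then free SA
    (species 2) follows from one linear solve with the complex-dependent
    sources. ``warm_start`` (a previous solution on the same grid) seeds
    the Picard iteration, which the outer fluid-solute coupling exploits.
    Raises :class:`SolverError` on non-convergence or negative
    concentrations beyond round-off.
    """
    x = grid.x
    n = x.size
    k = grid.i_interface
    a = np.zeros(n)
    a[: k + 1] = capillary_density(x[: k + 1], params)
    wcho, wscl, w = _layer_weights(grid)
    fcho = wcho / w     # fraction of each cell in the choroid
    fscl = wscl / w

    # --- species 3: atRA:SA ------------------------------------------
    uf3, Df3 = _face_fields(params, grid, fluid, params.D3_C, params.D3_S)
    ab3 = _transport_band(grid, uf3, Df3, fluid.u_sclera)
    beta_a = params.beta * a * fcho
    source3 = (params.k_prod * a + params.beta * a * params.c3_B) * fcho

    if warm_start is not None and warm_start.c3.shape == (n,):
        c3 = warm_start.c3.copy()
        lam = params.k_CYP_deg * induction_factor(c3, params)
    else:
        c3 = np.zeros(n)
        lam = np.zeros(n)                  # effective sink rate (1/s)
    history = []
    converged = False
    relax = 0.5
    for it in range(max_iter):
        c3_new = _solve_linear(ab3, beta_a + lam * fscl, source3, w)
        if not np.all(np.isfinite(c3_new)):
            raise SolverError("atRA:SA solve produced non-finite values")
        scale = max(np.max(np.abs(c3_new)), 1e-300)
        res = float(np.max(np.abs(c3_new - c3)) / scale)
        history.append(res)
        c3 = c3_new
        lam_target = params.k_CYP_deg * induction_factor(
            np.maximum(c3, 0.0), params)
        lam = relax * lam_target + (1 - relax) * lam
        if res <= tol:
            converged = True
            break
        if it > 40 and history[-1] > 0.9 * history[-10]:
            relax = 0.25   # stalling: damp harder
    if not converged:
        raise SolverError("Picard iteration on the degradation sink did "
                          f"not converge; residual history: {history[-5:]}")

    scale3 = max(np.max(np.abs(c3)), 1e-300)
    if strict and np.min(c3) < -1e-12 * scale3:
        raise SolverError(f"negative atRA:SA concentration: {np.min(c3)}")
    c3 = np.maximum(c3, 0.0)
    r3_S = params.k_CYP_deg * induction_factor(c3, params) * c3 * (fscl > 0)

    # --- species 2: free SA ------------------------------------------
    uf2, Df2 = _face_fields(params, grid, fluid, params.D2_C, params.D2_S)
    ab2 = _transport_band(grid, uf2, Df2, fluid.u_sclera)
    source2 = ((-params.k_prod * a + params.beta * a * params.c2_B) * fcho
               + r3_S * fscl)
    c2 = _solve_linear(ab2, params.beta * a * fcho, source2, w)
    if not np.all(np.isfinite(c2)):
        raise SolverError("SA solve produced non-finite values")
    scale2 = max(np.max(np.abs(c2)), 1e-300)
    if strict and np.min(c2) < -1e-12 * scale2:
        raise SolverError(f"negative SA concentration: {np.min(c2)}")
    c2 = np.maximum(c2, 0.0)

    # --- nodal flux decomposition ------------------------------------
    def _edge_grad(cv, i0, i1, i2):
        # derivative at x[i0] of the quadratic through three nodes
        x0, x1, x2_ = x[i0], x[i1], x[i2]
        return (cv[i0] * (2 * x0 - x1 - x2_) / ((x0 - x1) * (x0 - x2_))
                + cv[i1] * (x0 - x2_) / ((x1 - x0) * (x1 - x2_))
                + cv[i2] * (x0 - x1) / ((x2_ - x0) * (x2_ - x1)))

    J_adv, J_diff = {}, {}
    for sp_i, c, DC, DS in ((2, c2, params.D2_C, params.D2_S),
                            (3, c3, params.D3_C, params.D3_S)):
        J_adv[sp_i] = fluid.u * c
        grad = np.gradient(c, x)
        # second-order one-sided gradients at the boundaries, and a
        # choroid-side one-sided gradient at the interface (layer kink)
        grad[0] = _edge_grad(c, 0, 1, 2)
        grad[-1] = _edge_grad(c, n - 1, n - 2, n - 3)
        grad[k] = _edge_grad(c, k, k - 1, k - 2)
        D_nodal = np.where(np.arange(n) <= k, DC, DS)
        J_diff[sp_i] = -D_nodal * grad

    return SoluteSolution(grid=grid, c2=c2, c3=c3, r3_S=r3_S,
                          J_adv=J_adv, J_diff=J_diff,
                          picard_iterations=it + 1)
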