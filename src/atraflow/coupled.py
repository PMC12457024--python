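"""Fixed-point coupling of the fluid and solute solvers.

The albumin pool (c2 + c3) feeds back on the fluid problem through the
Starling osmotic term, so the two solvers are alternated until the IOP
and the concentration profiles stop changing. The coupling starts from a
zero osmotic gradient (tissue pool equal to blood), which gives a
physically sensible first IOP, and is a strong contraction at reference
parameters (a handful of sweeps).

``summarize`` computes every scalar observable reported for the model:
IOP, outflow partition, mean concentrations, and the integrated
synthesis / leakage / consumption rates (trapezoidal quadrature on the
solution grid).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .fluid import (FluidSolution, SolverError, partition_outflow,
                    solve_fluid)
from .grid import Grid, make_grid
from .params import MMHG_PA, ParameterSet, capillary_density
from .solute import SoluteSolution, solve_solute

__all__ = ["SummaryOutputs", "SteadyStateResult", "solve_steady_state",
           "summarize"]

MOLM3_TO_NM = 1e6   # 1 mol/m^3 = 1 mM = 1e6 nM


@dataclass
class SummaryOutputs:
    """Scalar observables of a converged steady state."""

    species: str
    condition: str
    IOP_mmHg: float
    Q_u: float                       # unconventional outflow (m^3/s)
    Qu_over_Qprod: float             # fraction
    u_S: float                       # scleral outflow velocity (m/s)
    u_CC: float                      # integral of q_C over choroid (m/s)
    uveovortex_fraction: float       # share of drainage via choroidal vessels
    drainage_ratio: float            # choriocapillaris / sclera drainage
    c2S_over_c2B: float              # scleral SA relative to blood
    mean_c2_CS: float                # mol/m^3
    mean_c3_S_nM: float
    mean_c3_CS_nM: float
    mean_c3_CS_mM: float             # same quantity on the mM scale
    c3_orbit_nM: float               # complex at the outer scleral surface
    SA_leak_rate: float              # mol/s, blood -> tissue
    atRA_synthesis_rate: float       # mol/s
    atRA_blood_leak_rate: float      # mol/s (negative = back into blood)
    atRA_scleral_consumption_rate: float   # mol/s
    scleral_consumption_fraction: float
    max_r3_S: float                  # peak scleral consumption (mol/m^3/s)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SteadyStateResult:
    fluid: FluidSolution
    solute: SoluteSolution
    summary: SummaryOutputs
    outer_iterations: int


def summarize(fluid: FluidSolution, solute: SoluteSolution,
              params: ParameterSet) -> SummaryOutputs:
    grid = fluid.grid
    k = grid.i_interface
    xc = grid.x[: k + 1]
    xs = grid.x[k:]
    a = capillary_density(xc, params)

    part = partition_outflow(fluid, params)

    c2S = float(np.trapezoid(solute.c2[k:], xs) / params.L_S)
    c2CS = float(np.trapezoid(solute.c2, grid.x) / params.L_total)
    c3S = solute.mean(3, "S")
    c3CS = solute.mean(3, "CS")

    synth = params.A_S * float(np.trapezoid(params.k_prod * a, xc))
    leak3 = params.A_S * float(np.trapezoid(
        params.beta * a * (params.c3_B - solute.c3[: k + 1]), xc))
    leak2 = params.A_S * float(np.trapezoid(
        params.beta * a * (params.c2_B - solute.c2[: k + 1]), xc))
    consumption = params.A_S * float(np.trapezoid(solute.r3_S[k:], xs))

    # atRA supplied to the tissue: synthesis always; transmural leakage
    # only when it is a net influx (feeding); back-leakage is a loss.
    supply = synth + max(leak3, 0.0)
    cons_frac = consumption / supply if supply > 0 else np.nan

    return SummaryOutputs(
        species=params.species,
        condition=params.condition,
        IOP_mmHg=fluid.iop / MMHG_PA,
        Q_u=fluid.Q_u,
        Qu_over_Qprod=fluid.Q_u / params.Q_prod,
        u_S=fluid.u_sclera,
        u_CC=fluid.uCC,
        uveovortex_fraction=part["uveovortex_fraction"],
        drainage_ratio=part["drainage_ratio"],
        c2S_over_c2B=c2S / params.c2_B,
        mean_c2_CS=c2CS,
        mean_c3_S_nM=c3S * MOLM3_TO_NM,
        mean_c3_CS_nM=c3CS * MOLM3_TO_NM,
        mean_c3_CS_mM=c3CS,
        c3_orbit_nM=float(solute.c3[-1]) * MOLM3_TO_NM,
        SA_leak_rate=leak2,
        atRA_synthesis_rate=synth,
        atRA_blood_leak_rate=leak3,
        atRA_scleral_consumption_rate=consumption,
        scleral_consumption_fraction=cons_frac,
        max_r3_S=float(np.max(solute.r3_S)),
    )


def solve_steady_state(params: ParameterSet, grid: Grid | None = None,
                       tol_iop_mmHg: float = 1e-6, tol_c: float = 1e-8,
                       max_outer: int = 50) -> SteadyStateResult:
    """Alternate fluid and solute solves to the coupled steady state.

    Converged when successive IOP iterates differ by < ``tol_iop_mmHg``
    and the albumin-pool profile by < ``tol_c`` (relative, max norm).
    Deterministic for fixed inputs and grid.
    """
    params = params.validate()
    if grid is None:
        grid = make_grid(params)
    # far from reference parameters the undamped osmotic feedback can
    # overshoot into an unphysical basin; retry with increasing damping
    attempts = ((1.0, max_outer, True), (0.25, 6 * max_outer, False),
                (0.05, 40 * max_outer, False))
    for i, (relax0, iters, adapt) in enumerate(attempts):
        try:
            return _iterate(params, grid, tol_iop_mmHg, tol_c, iters,
                            relax0=relax0, adapt=adapt)
        except SolverError:
            if i == len(attempts) - 1:
                raise


def _iterate(params: ParameterSet, grid: Grid, tol_iop_mmHg: float,
             tol_c: float, max_outer: int, relax0: float,
             adapt: bool = True) -> SteadyStateResult:
    c_tot = np.full(grid.n, params.c_SA_blood_total)
    iop_prev = np.inf
    history = []
    relax = relax0
    solute = None
    for it in range(1, max_outer + 1):
        fluid = solve_fluid(params, grid, c_total=c_tot)
        # positivity is enforced on the converged state below; transient
        # iterates far from reference parameters may briefly undershoot
        solute = solve_solute(params, grid, fluid, warm_start=solute,
                              strict=False)
        c_new = relax * solute.c_total + (1 - relax) * c_tot
        d_iop = abs(fluid.iop - iop_prev) / MMHG_PA
        d_c = float(np.max(np.abs(c_new - c_tot))
                    / max(np.max(np.abs(c_new)), 1e-300))
        history.append((fluid.iop / MMHG_PA, d_c))
        iop_prev = fluid.iop
        c_tot = np.maximum(c_new, 0.0)
        # damp the osmotic feedback if the residual stops contracting
        if adapt and it >= 2 and d_c > 0.7 * history[-2][1]:
            relax = max(0.5 * relax, 0.1)
        if d_iop < tol_iop_mmHg and d_c < tol_c:
            solute = solve_solute(params, grid, fluid, warm_start=solute,
                                  strict=True)
            return SteadyStateResult(
                fluid=fluid, solute=solute,
                summary=summarize(fluid, solute, params),
                outer_iterations=it)
    raise SolverError("fluid-solute coupling did not converge in "
                      f"{max_outer} iterations; (IOP, dC) history: "
                      f"{history[-6:]}")
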