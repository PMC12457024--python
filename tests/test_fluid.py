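"""Fluid solver tests, including two independent analytic oracles:

* the no-filtration closed form, where the scleral pressure drop and the
  Goldmann balance reduce IOP to a one-line formula; and
* the sharp-step capillary distribution, for which the pressure is
  piecewise analytic (cosh/sinh in the capillary region, affine
  elsewhere) and the full problem reduces to a 7x7 linear system.
"""

import math

import numpy as np
import pytest

from atraflow import (goldmann_unconventional_flow, make_grid,
                      partition_outflow, solve_fluid, solve_steady_state,
                      starling_source)
from atraflow.params import MMHG_PA, ULMIN_M3S


def closed_form_iop_no_filtration(p):
    """IOP when Lp_star = u_RPE = 0: uniform scleral flux Q_u/A_S."""
    R = p.mu * p.L_S / (p.K_S * p.A_S)
    return ((p.dP_SCS + p.p_orbit + R * p.Q_prod + R * p.C_fac * p.EVP)
            / (1.0 + R * p.C_fac))


def sharp_step_solution(p):
    """Piecewise-analytic pressure for an indicator capillary density.

    With a(x) = 1/alpha on [0, alpha*L_C] and zero elsewhere (tissue
    albumin equal to blood, so no osmotic term), the choroidal pressure
    is IOP + dP_blood + A*cosh(kx) + B*sinh(kx) in the capillary region
    and affine outside; returns (IOP, callable p(x)).
    """
    x1, LC, L = p.alpha * p.L_C, p.L_C, p.L_total
    kap = math.sqrt(p.mu * p.Lp_star / (p.K_C * p.alpha))
    ch, sh = math.cosh(kap * x1), math.sinh(kap * x1)
    # unknowns [A, B, a2, b2, aS, bS, IOP]
    M = np.zeros((7, 7))
    b = np.zeros(7)
    M[0, 1] = kap
    b[0] = -p.mu * p.u_RPE / p.K_C
    M[1] = [ch, sh, -1.0, -x1, 0, 0, 1.0]
    b[1] = -p.dP_blood
    M[2] = [kap * sh, kap * ch, 0, -1.0, 0, 0, 0]
    M[3] = [0, 0, 1.0, LC, -1.0, -LC, 0]
    M[4] = [0, 0, 0, -p.K_C / p.mu, 0, p.K_S / p.mu,
            -p.C_fac / p.A_S]
    b[4] = -(p.Q_prod + p.C_fac * p.EVP) / p.A_S
    M[5] = [0, 0, 0, 0, 1.0, L, 0]
    b[5] = p.p_orbit
    M[6] = [0, 0, 1.0, LC, 0, 0, -1.0]
    b[6] = -p.dP_SCS
    A, B, a2, b2, aS, bS, iop = np.linalg.solve(M, b)

    def pressure(x):
        x = np.asarray(x, dtype=float)
        return np.where(
            x <= x1, iop + p.dP_blood + A * np.cosh(kap * x)
            + B * np.sinh(kap * x),
            np.where(x <= LC, a2 + b2 * x, aS + bS * x))

    return float(iop), pressure


class TestGoldmann:
    def test_zero_conventional_gradient(self, human_params):
        p = human_params
        assert goldmann_unconventional_flow(p.EVP, p) == pytest.approx(
            p.Q_prod)

    def test_human_reference_magnitude(self, human_params):
        # 2.53 - 0.26*(14.9 - 7.1) ul/min
        q = goldmann_unconventional_flow(14.9 * MMHG_PA, human_params)
        assert q == pytest.approx(0.502 * ULMIN_M3S, rel=0.01)
        assert q / human_params.Q_prod == pytest.approx(0.199, rel=0.01)


class TestStarling:
    def test_equilibrium_gives_zero(self, human_params):
        p = human_params
        iop = 15 * MMHG_PA
        q = starling_source(0.0, iop + p.dP_blood, p.c_SA_blood_total,
                            p, iop)
        assert q == 0.0

    def test_vanishes_at_interface(self, human_params):
        p = human_params
        iop = 15 * MMHG_PA
        q0 = starling_source(0.0, iop, 0.0, p, iop)
        qL = starling_source(p.L_C, iop, 0.0, p, iop)
        assert abs(qL) < 1e-10 * abs(q0)

    def test_hydrostatic_only_plateau(self, mouse_params):
        """With tissue albumin equal to blood, the capillary-region source
        plateau is ~(1/alpha)*Lp_star*(dP_blood + dP_SCS): the choroidal
        pressure sits close to IOP - dP_SCS, so the Starling bracket is
        the two pressure offsets (to within the smoothing of the step
        and the small choroidal pressure drop)."""
        p = mouse_params
        grid = make_grid(p)
        sol = solve_fluid(p, grid)   # c_total = blood -> no osmosis
        expected = p.Lp_star / p.alpha * (p.dP_blood + p.dP_SCS)
        assert sol.q_C[0] == pytest.approx(expected, rel=0.05)


class TestSolveFluid:
    def test_matches_no_filtration_closed_form(self, human_params):
        p = human_params.replace(Lp_star=0.0, u_RPE=0.0)
        sol = solve_fluid(p, make_grid(p))
        assert sol.iop == pytest.approx(closed_form_iop_no_filtration(p),
                                        rel=1e-8)

    def test_boundary_and_interface_conditions(self, human_result,
                                               human_params):
        sol, p = human_result.fluid, human_params
        g = sol.grid
        k = g.i_interface
        assert sol.p[k] == pytest.approx(sol.iop - p.dP_SCS, rel=1e-10)
        assert sol.p[-1] == pytest.approx(p.p_orbit, rel=1e-10)
        # velocity jump at the SCS equals Qu/A_S
        assert sol.u[k + 1] - sol.u[k] == pytest.approx(
            sol.Q_u / p.A_S, rel=1e-10)

    def test_scleral_pressure_is_affine(self, human_result):
        sol = human_result.fluid
        k = sol.grid.i_interface
        xs, ps = sol.grid.x[k:], sol.p[k:]
        slope = (ps[-1] - ps[0]) / (xs[-1] - xs[0])
        fit = ps[0] + slope * (xs - xs[0])
        assert np.max(np.abs(ps - fit)) < 1e-6 * abs(ps[0] - ps[-1])

    def test_global_mass_balance(self, all_results):
        for name, res in all_results.items():
            sol = res.fluid
            p = res.summary
            A_S = {"mouse": 3.2e-5, "feeding": 3.2e-5,
                   "human": 1.49e-3}[name]
            lhs = A_S * (sol.u_sclera - sol.uCC)
            rhs = A_S * sol.u[0] + sol.Q_u
            assert lhs == pytest.approx(rhs, rel=1e-3)

    def test_mouse_velocity_positive_everywhere(self, mouse_result):
        assert np.all(mouse_result.fluid.u > 0)

    def test_human_outer_choroid_velocity_negative(self, human_result):
        sol = human_result.fluid
        k = sol.grid.i_interface
        assert sol.u[k] < 0          # just inside the interface

    def test_grid_refinement_stability(self, human_params):
        iops = []
        for n in (400, 800):
            sol = solve_fluid(human_params, make_grid(human_params, n, n))
            iops.append(sol.iop / MMHG_PA)
        assert abs(iops[1] - iops[0]) < 0.01


class TestSharpStepOracle:
    def test_numerical_matches_piecewise_analytic(self, human_params):
        p = human_params
        iop_ana, p_ana = sharp_step_solution(p)
        x1 = p.alpha * p.L_C

        def indicator(xs):
            return np.where(xs <= x1, 1.0 / p.alpha, 0.0)

        errs = []
        for n in (200, 800):
            grid = make_grid(p, n, n)
            sol = solve_fluid(p, grid, density=indicator)
            errs.append(abs(sol.iop - iop_ana))
            assert np.max(np.abs(sol.p - p_ana(grid.x))) < 5e-3 * abs(
                iop_ana - p.p_orbit)
        assert errs[1] < errs[0]            # converging under refinement
        assert errs[1] < 0.05 * MMHG_PA

    def test_smoothed_step_approaches_sharp_limit(self, human_params):
        """As Gamma grows the smoothed-step solution approaches the
        sharp-step analytic one."""
        iop_ana, _ = sharp_step_solution(human_params)
        errs = []
        for gamma in (100.0, 400.0, 1600.0):
            p = human_params.replace(Gamma=gamma)
            sol = solve_fluid(p, make_grid(p, 600, 200))
            errs.append(abs(sol.iop - iop_ana))
        assert errs[2] < errs[0]
        assert errs[2] < 0.03 * MMHG_PA


class TestPartition:
    def test_human_uveovortex_dominates(self, human_result, human_params):
        part = partition_outflow(human_result.fluid, human_params)
        assert part["uveovortex_fraction"] > 0.8
        assert part["uveovortex_fraction"] + \
            part["uveoscleral_fraction"] == pytest.approx(1.0, abs=1e-12)

    def test_no_filtration_means_no_uveovortex(self, mouse_params):
        p = mouse_params.replace(Lp_star=0.0)
        sol = solve_fluid(p, make_grid(p))
        part = partition_outflow(sol, p)
        assert part["uveovortex_fraction"] == 0.0

    def test_increasing_permeability_lowers_iop_and_scleral_flow(
            self, human_params):
        """Higher capillary hydraulic permeability opens the uveovortex
        route: IOP and trans-scleral outflow both drop."""
        grid_n = 100
        base = solve_steady_state(
            human_params, grid=make_grid(human_params, grid_n, grid_n))
        up = human_params.replace(Lp_star=2 * human_params.Lp_star)
        more = solve_steady_state(up, grid=make_grid(up, grid_n, grid_n))
        assert more.summary.IOP_mmHg < base.summary.IOP_mmHg
        assert more.summary.u_S < base.summary.u_S
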