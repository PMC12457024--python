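"""Extended Fourier Amplitude Sensitivity Test (eFAST).

Variance-based global sensitivity analysis: every parameter traverses its
range along a space-filling search curve driven by an integer frequency;
the parameter of interest gets the highest interference-free frequency
and its *total* sensitivity index is estimated as one minus the share of
output variance found at the low (complementary) frequencies, which
captures main effects and all interactions involving the parameter.
Random phase shifts give independent resampling curves whose spread
yields a standard error. An optional inert dummy parameter estimates the
index noise floor.

Directional effects ("does increasing the parameter raise or lower the
output, on average?") are reported from the sign of the Spearman rank
correlation over the pooled samples.

Two reference analyses mirror the model's use of the method: a
fluid/albumin set {K_S, Lp_star, beta, u_RPE, dP_blood, dP_SCS} with
outputs IOP, uCC, uS, <c2>_CS, and an atRA set adding
{k_prod, k_CYP_deg, Ind_C50, c3_B} with outputs <c3>_S and the orbital
atRA:SA concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coupled import solve_steady_state
from .grid import make_grid
from .params import MMHG_PA, ParameterSet

__all__ = ["SensitivityDesign", "SensitivityResult", "efast_frequencies",
           "efast_sample", "efast_total_index", "reference_design"]

DUMMY = "_dummy"


@dataclass
class SensitivityDesign:
    """Sampling plan for one eFAST analysis.

    ``parameters`` maps name -> (low, high) absolute bounds. ``N`` is the
    number of samples per search curve, ``M`` the interference factor
    (harmonics attributed to each parameter), ``N_r`` the number of
    random-phase resampling curves. The Nyquist-type condition
    N >= 4*M*omega_max + 1 is enforced by the frequency assignment.
    """

    parameters: dict
    outputs: list
    M: int = 4
    N: int = 65
    N_r: int = 5
    seed: int = 0
    include_dummy: bool = True

    def __post_init__(self):
        for name, (lo, hi) in self.parameters.items():
            if not lo < hi:
                raise ValueError(f"range of {name!r} must satisfy low < high")
        if self.N < 4 * self.M + 1:
            raise ValueError("too few samples per curve for the requested "
                             f"interference factor: N={self.N}, M={self.M}")

    @property
    def names(self) -> list:
        n = list(self.parameters)
        if self.include_dummy:
            n.append(DUMMY)
        return n

    @property
    def bounds(self) -> np.ndarray:
        b = [self.parameters[n] for n in self.parameters]
        if self.include_dummy:
            b.append((0.0, 1.0))
        return np.asarray(b, dtype=float)


@dataclass
class SensitivityResult:
    """Total-order indices with resampling spread and effect directions."""

    table: pd.DataFrame     # parameter, output, S_T, stderr, direction
    design: SensitivityDesign = None
    n_failed: int = 0

    def total_index(self, parameter: str, output: str) -> float:
        m = self.table[(self.table.parameter == parameter)
                       & (self.table.output == output)]
        if m.empty:
            raise KeyError((parameter, output))
        return float(m.S_T.iloc[0])

    def noise_floor(self, output: str) -> float:
        """Dummy-parameter index: indices below this are indistinguishable
        from estimation noise."""
        return self.total_index(DUMMY, output)

    def to_dataframe(self) -> pd.DataFrame:
        return self.table.copy()


def efast_frequencies(D: int, N: int, M: int) -> tuple[int, np.ndarray]:
    """Frequency of interest and complementary frequencies for D factors.

    The driven parameter gets omega_max = (N-1)//(4M) so that its M
    harmonics stay well below the folding frequency; the remaining D-1
    parameters share frequencies in [1, omega_max/(2M)] (spread evenly if
    possible, cycled otherwise), keeping their harmonics out of the
    driven parameter's band.
    """
    omega_max = (N - 1) // (4 * M)
    if omega_max < 2:
        raise ValueError(f"N={N} too small for M={M}: "
                         "raise N (need N >= 8*M + 1)")
    m = max(omega_max // (2 * M), 1)
    if D == 1:
        return omega_max, np.empty(0, dtype=int)
    if m >= D - 1:
        comp = np.floor(np.linspace(1, m, D - 1)).astype(int)
    else:
        comp = np.arange(D - 1) % m + 1
    return omega_max, comp


def efast_sample(design: SensitivityDesign) -> np.ndarray:
    """Search-curve samples, shape (D, N_r, N, D).

    Axis 0 indexes which parameter carries the high frequency; axis 3 is
    the parameter coordinate. Deterministic for a given design seed.
    """
    names = design.names
    D = len(names)
    N, M, N_r = design.N, design.M, design.N_r
    omega_max, comp = efast_frequencies(D, N, M)
    rng = np.random.default_rng(design.seed)
    bounds = design.bounds
    s = (2.0 * np.pi / N) * np.arange(N)

    X = np.empty((D, N_r, N, D))
    for i in range(D):
        omega = np.empty(D)
        omega[i] = omega_max
        omega[np.arange(D) != i] = comp
        for r in range(N_r):
            phi = rng.uniform(0.0, 2.0 * np.pi, size=D)
            g = 0.5 + np.arcsin(np.sin(np.outer(s, omega) + phi)) / np.pi
            X[i, r] = bounds[:, 0] + (bounds[:, 1] - bounds[:, 0]) * g
    return X


def _total_index_curve(y: np.ndarray, N: int, M: int, omega: int) -> float:
    """1 - (variance below omega/2) / (total variance) for one curve."""
    f = np.fft.rfft(y - np.mean(y))
    Sp = np.abs(f[1:]) ** 2
    V = Sp.sum()
    if V <= 0:
        return 0.0
    cutoff = max(omega // 2, 1)
    Dc = Sp[:cutoff].sum()
    return float(1.0 - Dc / V)


def efast_total_index(model, design: SensitivityDesign,
                      max_failure_fraction: float = 0.05
                      ) -> SensitivityResult:
    """Run ``model`` over the eFAST design and estimate total indices.

    ``model`` maps a parameter dict (design names excluding the dummy) to
    a dict of outputs. Failed evaluations (exceptions/non-finite) are
    imputed from the nearest successful sample on the same curve; more
    than ``max_failure_fraction`` failures aborts.
    """
    names = design.names
    D = len(names)
    N, M, N_r = design.N, design.M, design.N_r
    omega_max, _ = efast_frequencies(D, N, M)
    X = efast_sample(design)

    n_failed = 0
    n_total = D * N_r * N
    Y = np.full((D, N_r, N, len(design.outputs)), np.nan)
    for i in range(D):
        for r in range(N_r):
            for j in range(N):
                point = {n: X[i, r, j, d] for d, n in enumerate(names)
                         if n != DUMMY}
                try:
                    out = model(point)
                    row = [out[o] for o in design.outputs]
                    if not np.all(np.isfinite(row)):
                        raise FloatingPointError("non-finite output")
                    Y[i, r, j] = row
                except Exception:
                    n_failed += 1
                    if n_failed > max_failure_fraction * n_total:
                        raise RuntimeError(
                            f"more than {100*max_failure_fraction:.0f}% of "
                            "model evaluations failed")
            # impute failures from the nearest successful neighbour
            for o in range(len(design.outputs)):
                col = Y[i, r, :, o]
                bad = ~np.isfinite(col)
                if bad.any():
                    good = np.flatnonzero(~bad)
                    if good.size == 0:
                        raise RuntimeError("an entire search curve failed")
                    idx = good[np.argmin(
                        np.abs(np.flatnonzero(bad)[:, None] - good), axis=1)]
                    col[bad] = col[idx]

    rows = []
    for o, oname in enumerate(design.outputs):
        # direction from pooled rank correlation
        for i, pname in enumerate(names):
            ST = [_total_index_curve(Y[i, r, :, o], N, M, omega_max)
                  for r in range(N_r)]
            xs = X[:, :, :, i].ravel()
            ys = Y[:, :, :, o].ravel()
            rho = stats.spearmanr(xs, ys).statistic if np.ptp(ys) > 0 else 0.0
            direction = ("+" if rho > 0.1 else
                         "-" if rho < -0.1 else "indeterminate")
            rows.append({
                "parameter": pname, "output": oname,
                "S_T": float(np.mean(ST)),
                "stderr": float(np.std(ST, ddof=1) / np.sqrt(N_r))
                if N_r > 1 else np.nan,
                "direction": direction,
            })
    return SensitivityResult(table=pd.DataFrame(rows), design=design,
                             n_failed=n_failed)


# ---------------------------------------------------------------------------
# reference analyses on the transport model
# ---------------------------------------------------------------------------

_REL_HALF = ("K_S", "u_RPE", "Ind_C50", "c3_B")      # [0.5, 1.5] x ref
_REL_THIRD = ("Lp_star", "beta", "k_prod", "k_CYP_deg")  # [1/3, 3] x ref


def _ranges(params: ParameterSet, names) -> dict:
    r = {}
    for n in names:
        if n == "dP_blood":
            r[n] = (3 * MMHG_PA, 7 * MMHG_PA)
        elif n == "dP_SCS":
            r[n] = (0.0, 2 * MMHG_PA)
        elif n in _REL_HALF:
            v = getattr(params, n)
            r[n] = (0.5 * v, 1.5 * v)
        elif n in _REL_THIRD:
            v = getattr(params, n)
            r[n] = (v / 3.0, 3.0 * v)
        else:
            raise ValueError(f"no sensitivity range defined for {n!r}")
    return r


def reference_design(params: ParameterSet, analysis: str = "fluid",
                     M: int = 4, N: int = 65, N_r: int = 5, seed: int = 0,
                     include_dummy: bool = True, grid_n: int = 80):
    """Build the (design, model) pair for one of the two standard analyses.

    ``analysis='fluid'`` varies the six fluid/albumin parameters with
    outputs IOP (mmHg), uCC, uS and <c2>_CS; ``analysis='atra'`` adds the
    four atRA parameters with outputs <c3>_S and c3 at the orbit (nM).
    """
    if analysis == "fluid":
        names = ["K_S", "Lp_star", "beta", "u_RPE", "dP_blood", "dP_SCS"]
        outputs = ["IOP", "uCC", "uS", "c2_CS"]
    elif analysis == "atra":
        names = ["K_S", "Lp_star", "beta", "u_RPE", "dP_blood", "dP_SCS",
                 "k_prod", "k_CYP_deg", "Ind_C50", "c3_B"]
        outputs = ["c3_S", "c3_orbit"]
    else:
        raise ValueError("analysis must be 'fluid' or 'atra'")

    design = SensitivityDesign(parameters=_ranges(params, names),
                               outputs=outputs, M=M, N=N, N_r=N_r,
                               seed=seed, include_dummy=include_dummy)

    def model(point: dict) -> dict:
        trial = params.replace(**point)
        res = solve_steady_state(trial,
                                 grid=make_grid(trial, grid_n, grid_n),
                                 tol_iop_mmHg=1e-5, tol_c=1e-7)
        s = res.summary
        return {"IOP": s.IOP_mmHg, "uCC": s.u_CC, "uS": s.u_S,
                "c2_CS": s.mean_c2_CS, "c3_S": s.mean_c3_S_nM,
                "c3_orbit": s.c3_orbit_nM}

    return design, model
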