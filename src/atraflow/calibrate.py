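"""Fitting of the extremely uncertain transport parameters.

Four parameters cannot be measured directly and are set by matching model
outputs to well-characterized observables: the capillary hydraulic
permeability Lp_star and the solute exchange rate beta (against IOP, the
unconventional-outflow fraction and the scleral albumin ratio), and the
atRA synthesis and degradation rate constants k_prod and k_CYP_deg
(against the mean tissue atRA:SA concentration, for the mouse under both
control and feeding conditions — the feeding case pins k_CYP_deg because
vascular leakage dwarfs synthesis there, the control case then pins
k_prod).

The atRA pair rides one-way on the fluid/albumin solution (trace
concentrations), so the fit is two-staged by default. The objective is a
weighted sum of squared relative deviations over log-transformed
parameters (positive rates spanning orders of magnitude), minimized with
a bounded Nelder-Mead simplex — derivative-free, hence robust to the
iteration noise of the inner solvers, and bit-reproducible from a fixed
starting point.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import optimize

from .coupled import solve_steady_state
from .grid import make_grid
from .params import ParameterSet

__all__ = ["CalibrationTargets", "CalibrationResult",
           "fit_uncertain_parameters"]

FLUID_STAGE = ("Lp_star", "beta")
ATRA_STAGE = ("k_prod", "k_CYP_deg")
FREE_PARAMETERS = FLUID_STAGE + ATRA_STAGE


@dataclass
class CalibrationTargets:
    """Observables the fit must reproduce.

    Concentration targets are in mol/m^3 (== mM); ``c3CS_feeding`` needs
    ``feeding_c3_B``, the blood atRA:SA concentration of the feeding
    scenario. Any target may be omitted (None) if not fitted against.
    """

    IOP_mmHg: float | None = None
    Qu_fraction: float | None = None
    c2S_ratio: float | None = None
    c3CS_control: float | None = None
    c3CS_feeding: float | None = None
    feeding_c3_B: float | None = None
    weights: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("IOP_mmHg", "Qu_fraction", "c2S_ratio",
                     "c3CS_control", "c3CS_feeding"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"target {name} must be positive")
        if self.c3CS_feeding is not None and self.feeding_c3_B is None:
            raise ValueError("c3CS_feeding requires feeding_c3_B")

    def weight(self, name: str) -> float:
        return float(self.weights.get(name, 1.0))

    def to_file(self, path):
        path = pathlib.Path(path)
        d = dataclasses.asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_file(cls, path):
        path = pathlib.Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**d)


@dataclass
class CalibrationResult:
    fitted: dict                 # parameter -> value (SI)
    residuals: dict              # target -> relative residual
    objective: float
    n_evaluations: int
    converged: bool
    termination: str
    stages: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_targets(targets: CalibrationTargets, stage: str) -> dict:
    if stage == "fluid":
        pairs = {"IOP_mmHg": targets.IOP_mmHg,
                 "Qu_fraction": targets.Qu_fraction,
                 "c2S_ratio": targets.c2S_ratio}
    else:
        pairs = {"c3CS_control": targets.c3CS_control,
                 "c3CS_feeding": targets.c3CS_feeding}
    return {k: v for k, v in pairs.items() if v is not None}


def _model_outputs(params: ParameterSet, wanted: dict, grid_n: int,
                   feeding_c3_B: float | None) -> dict:
    """Forward-solve and extract the requested observables."""
    out = {}
    need_control = any(k != "c3CS_feeding" for k in wanted)
    if need_control:
        res = solve_steady_state(params, grid=make_grid(params, grid_n, grid_n),
                                 tol_iop_mmHg=1e-7, tol_c=1e-9)
        s = res.summary
        out.update({"IOP_mmHg": s.IOP_mmHg, "Qu_fraction": s.Qu_over_Qprod,
                    "c2S_ratio": s.c2S_over_c2B,
                    "c3CS_control": s.mean_c3_CS_mM})
    if "c3CS_feeding" in wanted:
        pf = params.replace(c3_B=feeding_c3_B, condition="feeding")
        res = solve_steady_state(pf, grid=make_grid(pf, grid_n, grid_n),
                                 tol_iop_mmHg=1e-7, tol_c=1e-9)
        out["c3CS_feeding"] = res.summary.mean_c3_CS_mM
    return {k: out[k] for k in wanted}


def fit_uncertain_parameters(params: ParameterSet,
                             targets: CalibrationTargets,
                             free: tuple[str, ...] = FREE_PARAMETERS,
                             bounds_factor: float = 100.0,
                             grid_n: int = 120,
                             xatol: float = 1e-6,
                             maxiter: int = 400) -> CalibrationResult:
    """Fit the free parameters so model outputs match ``targets``.

    ``free`` is any subset of {Lp_star, beta, k_prod, k_CYP_deg}; an
    empty subset returns the unmodified parameters with their residuals.
    Each parameter is searched in log10 space within
    [value/bounds_factor, value*bounds_factor] around its starting value.
    """
    unknown = set(free) - set(FREE_PARAMETERS)
    if unknown:
        raise ValueError(f"not calibratable: {sorted(unknown)}")

    work = params
    stage_reports = []
    n_eval_total = 0
    converged = True
    termination = "no free parameters"

    for stage, stage_params in (("fluid", FLUID_STAGE), ("atra", ATRA_STAGE)):
        names = [p for p in free if p in stage_params]
        wanted = _stage_targets(targets, stage)
        if not names:
            continue
        if len(wanted) < len(names):
            raise ValueError(
                f"stage {stage!r}: {len(names)} free parameters but only "
                f"{len(wanted)} targets supplied")
        x0 = np.log10([getattr(work, p) for p in names])
        lb = x0 - np.log10(bounds_factor)
        ub = x0 + np.log10(bounds_factor)
        n_eval = 0

        def objective(xlog, _names=names, _wanted=wanted):
            nonlocal n_eval
            n_eval += 1
            trial = work.replace(**{p: 10.0 ** v
                                    for p, v in zip(_names, xlog)})
            try:
                model = _model_outputs(trial, _wanted, grid_n,
                                       targets.feeding_c3_B)
            except Exception:
                return 1e6
            return sum(targets.weight(k)
                       * ((model[k] - t) / t) ** 2
                       for k, t in _wanted.items())

        f0 = objective(x0)
        n_eval -= 1  # probe not counted twice by minimize
        if not np.isfinite(f0) or f0 >= 1e6:
            raise RuntimeError(f"objective not finite at the initial point "
                               f"of stage {stage!r}")
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            bounds=list(zip(lb, ub)),
            options={"xatol": xatol, "fatol": 1e-14, "maxiter": maxiter,
                     "maxfev": 3 * maxiter})
        work = work.replace(**{p: 10.0 ** v for p, v in zip(names, res.x)})
        n_eval_total += n_eval
        converged = converged and bool(res.success)
        termination = res.message
        stage_reports.append({"stage": stage, "parameters": names,
                              "objective": float(res.fun),
                              "iterations": int(res.nit),
                              "success": bool(res.success)})

    # final residuals with a fresh forward solve
    all_wanted = {**_stage_targets(targets, "fluid"),
                  **_stage_targets(targets, "atra")}
    residuals = {}
    objective_value = 0.0
    if all_wanted:
        model = _model_outputs(work, all_wanted, grid_n,
                               targets.feeding_c3_B)
        for k, t in all_wanted.items():
            residuals[k] = (model[k] - t) / t
            objective_value += targets.weight(k) * residuals[k] ** 2

    return CalibrationResult(
        fitted={p: getattr(work, p) for p in free},
        residuals=residuals,
        objective=objective_value,
        n_evaluations=n_eval_total,
        converged=converged,
        termination=str(termination),
        stages=stage_reports)
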