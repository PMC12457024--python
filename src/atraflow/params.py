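"""Model parameters for choroid/sclera fluid and atRA transport.

All quantities are held internally in strict SI units (Pa, m, s, mol m^-3;
note 1 mM == 1 mol m^-3). Literature-style units (mmHg, ul/min, uM) appear
only in parameter files flagged ``units: table`` and are converted on load.

Three presets ship with the package: ``mouse``/``human`` under ``control``
(no retinoic-acid feeding) and ``mouse`` under ``feeding``. The feeding
preset differs from mouse control only in the blood atRA:SA concentration
``c3_B``, set from the measured serum plateau 90 min after oral dosing.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "ParameterError",
    "MMHG_PA",
    "ULMIN_M3S",
    "load_parameters",
    "available_presets",
    "capillary_density",
]

#: 1 mmHg in Pa
MMHG_PA = 133.322
#: 1 microlitre/minute in m^3/s
ULMIN_M3S = 1.0e-9 / 60.0

#: uncertainty category of each physical parameter
CATEGORIES = {
    "well_known": (
        "L_C", "L_S", "A_S", "C_fac", "Q_prod", "EVP", "mu", "p_orbit",
        "R_gas", "T_abs", "D2_C", "D3_C", "D2_S", "D3_S",
        "c_SA_blood_total", "c3_B", "sigma",
    ),
    "somewhat_known": (
        "K_C", "K_S", "dP_blood", "dP_SCS", "alpha", "u_RPE",
        "Ind_max", "Ind_C50", "f_u_inc", "Gamma", "Ka",
    ),
    "extremely_uncertain": ("beta", "Lp_star", "k_prod", "k_CYP_deg"),
}

# conversion factor file-unit -> SI, applied when a file declares table units
_TABLE_UNIT_TO_SI = {
    "L_C": 1e-6,            # um -> m
    "L_S": 1e-6,
    "p_orbit": MMHG_PA,     # mmHg -> Pa
    "dP_blood": MMHG_PA,
    "dP_SCS": MMHG_PA,
    "EVP": MMHG_PA,
    "Q_prod": ULMIN_M3S,    # ul/min -> m^3/s
    "C_fac": ULMIN_M3S / MMHG_PA,  # ul/min/mmHg -> m^3 s^-1 Pa^-1
    # concentrations in mM are numerically identical to mol m^-3
}


class ParameterError(ValueError):
    """Raised for missing, non-physical or unknown parameters."""


@dataclass
class ParameterSet:
    """Full physical description of one simulated case, in SI units.

    Geometry
    --------
    L_C, L_S : choroid / sclera thickness (m)
    alpha    : choriocapillaris fraction of the choroidal thickness
    Gamma    : sharpness of the smoothed capillary-density step (>> 1)
    A_S      : area of the choroid-sclera interface (m^2)

    Fluid
    -----
    mu       : extravascular fluid viscosity (Pa s)
    u_RPE    : RPE pumping velocity (m/s, directed outward)
    p_orbit  : orbital tissue pressure (Pa)
    dP_blood : choroidal blood pressure offset above IOP (Pa)
    dP_SCS   : suprachoroidal-space pressure offset below IOP (Pa)
    EVP      : episcleral venous pressure (Pa)
    Q_prod   : aqueous humour production (m^3/s)
    C_fac    : conventional outflow facility (m^3 s^-1 Pa^-1)
    Lp_star  : modified choriocapillary hydraulic permeability (s^-1 Pa^-1)
    K_C, K_S : Darcy permeabilities of choroid / sclera (m^2)

    Solutes (species 2 = serum albumin, species 3 = atRA:SA complex)
    ----------------------------------------------------------------
    D2_C, D3_C, D2_S, D3_S : diffusivities per layer (m^2/s)
    beta     : transmural SA/atRA:SA exchange rate (s^-1)
    c_SA_blood_total : total blood albumin c2_B + c3_B (mol m^-3)
    c3_B     : blood atRA:SA concentration (mol m^-3)
    sigma    : capillary reflection coefficient of the albumin pool
    k_prod   : choroidal atRA synthesis rate (mol m^-3 s^-1)
    k_CYP_deg: scleral CYP26 degradation rate constant (s^-1)
    Ind_max  : maximum fold induction of CYP26
    Ind_C50  : half-induction atRA concentration (mol m^-3)
    f_u_inc  : fraction unbound in the induction incubation
    Ka       : atRA-albumin equilibrium association constant (M^-1)
    """

    L_C: float
    L_S: float
    alpha: float
    Gamma: float
    R_gas: float
    T_abs: float
    mu: float
    u_RPE: float
    p_orbit: float
    dP_blood: float
    dP_SCS: float
    EVP: float
    Q_prod: float
    C_fac: float
    Lp_star: float
    K_S: float
    K_C: float
    D2_S: float
    D3_S: float
    D2_C: float
    D3_C: float
    beta: float
    c_SA_blood_total: float
    c3_B: float
    sigma: float
    k_prod: float
    k_CYP_deg: float
    Ind_max: float
    Ind_C50: float
    f_u_inc: float
    A_S: float
    Ka: float
    species: str = "mouse"
    condition: str = "control"

    # -- derived --------------------------------------------------------
    @property
    def c2_B(self) -> float:
        """Blood concentration of free albumin (mol m^-3)."""
        return self.c_SA_blood_total - self.c3_B

    @property
    def L_total(self) -> float:
        return self.L_C + self.L_S

    @property
    def p_B_offset(self) -> float:
        """Alias for dP_blood; blood pressure is IOP + this offset."""
        return self.dP_blood

    def category(self, name: str) -> str:
        for cat, names in CATEGORIES.items():
            if name in names:
                return cat
        raise ParameterError(f"unknown parameter {name!r}")

    # -- validation -----------------------------------------------------
    _POSITIVE = (
        "L_C", "L_S", "Gamma", "R_gas", "T_abs", "mu", "Q_prod", "C_fac",
        "K_S", "K_C", "D2_S", "D3_S", "D2_C", "D3_C",
        "c_SA_blood_total", "Ind_max", "Ind_C50", "A_S",
    )
    # rates that may legitimately vanish (degenerate / limiting cases)
    _NONNEGATIVE = ("u_RPE", "p_orbit", "dP_blood", "dP_SCS", "EVP",
                    "c3_B", "Ka", "Lp_star", "beta", "k_prod", "k_CYP_deg")

    def validate(self) -> "ParameterSet":
        for name in self._POSITIVE:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ParameterError(f"parameter {name!r} must be a positive "
                                     f"finite number, got {v!r}")
        for name in self._NONNEGATIVE:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise ParameterError(f"parameter {name!r} must be nonnegative, "
                                     f"got {v!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ParameterError(f"sigma must lie in [0, 1], got {self.sigma}")
        if not 0.0 < self.f_u_inc <= 1.0:
            raise ParameterError(f"f_u_inc must lie in (0, 1], got {self.f_u_inc}")
        if self.Gamma < 10.0:
            raise ParameterError("Gamma must be >> 1 (at least 10); "
                                 f"got {self.Gamma}")
        if self.c3_B > self.c_SA_blood_total:
            raise ParameterError("c3_B exceeds the total blood albumin "
                                 "c_SA_blood_total")
        if self.species not in ("mouse", "human"):
            raise ParameterError(f"unknown species {self.species!r}")
        return self

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs).validate()

    def to_file(self, path: str | pathlib.Path) -> None:
        """Write the parameter set (SI units) as YAML or JSON by extension."""
        path = pathlib.Path(path)
        payload = {"units": "SI", **self.to_dict()}
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        data = dict(data)
        units = data.pop("units", "SI")
        field_names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - field_names
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        missing = {f.name for f in dataclasses.fields(cls)
                   if f.default is dataclasses.MISSING} - set(data)
        if missing:
            raise ParameterError(f"missing parameter(s): {sorted(missing)}")
        if units == "table":
            for name, fac in _TABLE_UNIT_TO_SI.items():
                if name in data:
                    data[name] = float(data[name]) * fac
        elif units != "SI":
            raise ParameterError(f"unknown unit system {units!r}")
        numeric = {k: (float(v) if k not in ("species", "condition") else v)
                   for k, v in data.items()}
        return cls(**numeric).validate()

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "ParameterSet":
        path = pathlib.Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError(f"parameter file {path} is not a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_PRESET_FILES = {
    ("mouse", "control"): "mouse_control.yaml",
    ("mouse", "feeding"): "mouse_feeding.yaml",
    ("human", "control"): "human_control.yaml",
}


def available_presets() -> list[tuple[str, str]]:
    return sorted(_PRESET_FILES)


def load_parameters(source: str | pathlib.Path | None = None,
                    species: str = "mouse",
                    condition: str = "control") -> ParameterSet:
    """Load a validated :class:`ParameterSet`.

    Parameters
    ----------
    source
        Path to a YAML/JSON parameter file. If omitted, the shipped preset
        for ``(species, condition)`` is used; the three presets are the
        simulated reference cases (mouse control, mouse feeding,
        human control).
    """
    if source is not None:
        return ParameterSet.from_file(source)
    key = (species, condition)
    if key not in _PRESET_FILES:
        raise ParameterError(
            f"no preset for species={species!r}, condition={condition!r}; "
            f"available: {available_presets()}")
    ref = resources.files("atraflow.presets").joinpath(_PRESET_FILES[key])
    data = yaml.safe_load(ref.read_text())
    return ParameterSet.from_dict(data)


# ---------------------------------------------------------------------------
# capillary density
# ---------------------------------------------------------------------------

def capillary_density(x, params: ParameterSet):
    """Normalized filtering-capillary density a(x) across the choroid.

    a(x) = (1/alpha) * [1 - 1/(1 + exp(-Gamma*(x/L_C - alpha)))]

    A smoothed step of height 1/alpha over the choriocapillaris
    [0, alpha*L_C], decaying to zero in the outer choroid; normalized so
    that its integral over the choroid is ~L_C. Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-15) or np.any(x > params.L_C * (1 + 1e-12)):
        raise ValueError("position outside the choroid [0, L_C]")
    z = params.Gamma * (x / params.L_C - params.alpha)
    # stable logistic: 1 - 1/(1+e^-z) == 1/(1+e^z)
    a = (1.0 / params.alpha) / (1.0 + np.exp(np.clip(z, -700, 700)))
    return a if a.ndim else float(a)
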