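"""1-D mesh over the choroid + sclera domain [0, L_C + L_S].

The choroid-sclera interface x = L_C is always an exact node. Choroid
nodes are graded so that the narrow transition band of the smoothed
capillary-density step near x = alpha*L_C (width ~ 2*ln(9)*L_C/Gamma,
where the step falls from 90% to 10% of its plateau) is resolved by at
least 10 nodes regardless of the total node count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet

__all__ = ["Grid", "make_grid"]


@dataclass(frozen=True)
class Grid:
    x: np.ndarray            # node positions (m), strictly increasing
    i_interface: int         # index of the node at x = L_C
    L_C: float
    L_S: float

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if np.any(np.diff(x) <= 0):
            raise ValueError("grid nodes must be strictly increasing")
        for target in (0.0, self.L_C, self.L_C + self.L_S):
            if not np.any(np.isclose(x, target, rtol=0, atol=1e-12 * self.L_S)):
                raise ValueError(f"required node at x={target} missing")
        if not math.isclose(x[self.i_interface], self.L_C,
                            rel_tol=0, abs_tol=1e-12 * self.L_S):
            raise ValueError("i_interface does not point at x = L_C")
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def h(self) -> np.ndarray:
        """Node spacings, length n-1."""
        return np.diff(self.x)

    @property
    def x_choroid(self) -> np.ndarray:
        return self.x[: self.i_interface + 1]

    @property
    def x_sclera(self) -> np.ndarray:
        return self.x[self.i_interface:]

    def cell_widths(self) -> np.ndarray:
        """Finite-volume cell widths (half-cells at boundaries)."""
        h = self.h
        w = np.empty(self.n)
        w[0] = h[0] / 2
        w[-1] = h[-1] / 2
        w[1:-1] = (h[:-1] + h[1:]) / 2
        return w


def _graded_choroid(params: ParameterSet, n: int) -> np.ndarray:
    """Choroid nodes clustered around the capillary-density transition."""
    L_C, alpha, Gamma = params.L_C, params.alpha, params.Gamma
    half = math.log(9.0) * L_C / Gamma          # 90%->10% half-width
    lo = max(0.0, alpha * L_C - 3 * half)
    hi = min(L_C, alpha * L_C + 3 * half)
    # allocate ~30% of nodes to the transition band; the floor of 32
    # guarantees >=10 nodes across the central 90%-10% fall
    n_band = max(32, int(0.3 * n))
    n_rest = max(4, n - n_band)
    len_lo, len_hi = lo, L_C - hi
    n_lo = max(2, int(round(n_rest * len_lo / (len_lo + len_hi))))
    n_hi = max(2, n_rest - n_lo)
    seg = [np.linspace(0.0, lo, n_lo, endpoint=False)] if lo > 0 else []
    seg.append(np.linspace(lo, hi, n_band, endpoint=False))
    seg.append(np.linspace(hi, L_C, n_hi + 1))
    x = np.concatenate(seg)
    return np.unique(x)


def make_grid(params: ParameterSet, n_choroid: int = 400,
              n_sclera: int = 400) -> Grid:
    """Build the default two-layer mesh for a parameter set.

    ``n_choroid``/``n_sclera`` are approximate node counts per layer;
    the interface node is shared.
    """
    if n_choroid < 16 or n_sclera < 8:
        raise ValueError("grid too coarse: need >=16 choroid and >=8 "
                         "sclera nodes")
    xc = _graded_choroid(params, n_choroid)
    xs = np.linspace(params.L_C, params.L_C + params.L_S, n_sclera + 1)
    x = np.concatenate([xc, xs[1:]])
    i_if = xc.size - 1
    return Grid(x=x, i_interface=i_if, L_C=params.L_C, L_S=params.L_S)
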