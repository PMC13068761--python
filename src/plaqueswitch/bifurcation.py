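"""Branch scans and critical parameter values for the reduced submodel.

The reduced system has a transcritical bifurcation: the extinction and
coexistence branches exchange stability where the physicality margin
rho_c - Pi_c/k(param) crosses zero.  This module evaluates both branches
along 1-D parameter grids, refines the exchange point by bisection, and
computes the closed-form critical values that the scans visualise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .reduced_model import ReducedParams, solve_k, steady_states

__all__ = [
    "BifurcationBranch",
    "scan",
    "extinction_threshold_rho",
    "critical_delta_c",
    "argmax_S2_delta_c",
]

SCANNABLE = ("rho_c", "Pi_c", "delta_c")


@dataclass
class BifurcationBranch:
    """Steady-state branches along a parameter grid.

    Cell counts are normalised by the SMC carrying capacity C_0.
    """

    param: str
    grid: np.ndarray
    table: pd.DataFrame           # one row per grid point, both branches
    exchange_points: list[float]  # refined stability-exchange locations

    def to_dataframe(self) -> pd.DataFrame:
        return self.table


def _margin(rp: ReducedParams) -> float:
    """Physicality margin of the coexistence branch: rho_c - Pi_c/k."""
    return rp.rho_c - rp.Pi_c / solve_k(rp)


def scan(rp: ReducedParams, param: str, grid) -> BifurcationBranch:
    """Evaluate both steady-state branches along a grid of one parameter.

    The grid must be strictly increasing and inside the validated region.
    Exchange-of-stability points interior to the grid are refined by
    bisection on the physicality margin to 1e-8.
    """
    if param not in SCANNABLE:
        raise ValueError(f"param must be one of {SCANNABLE}, got {param!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")

    rows = []
    margins = np.empty(len(grid))
    for i, val in enumerate(grid):
        rpi = replace(rp, **{param: float(val)})
        trivial, nontrivial = steady_states(rpi)
        margins[i] = rpi.rho_c - rpi.Pi_c / nontrivial.k
        rows.append({
            param: val,
            "C2_over_C0": nontrivial.C_star / rpi.C_0,
            "S2_over_C0": nontrivial.S_star / rpi.C_0,
            "Abar_c2": nontrivial.Abar_c_star,
            "k": nontrivial.k,
            "nontrivial_physical": nontrivial.physical,
            "nontrivial_stability": nontrivial.stability,
            "Abar_c1": trivial.Abar_c_star,
            "trivial_stability": trivial.stability,
        })
    table = pd.DataFrame(rows)

    exchange = []
    sign = np.sign(margins)
    for i in np.nonzero(np.diff(sign) != 0)[0]:
        x = brentq(lambda v: _margin(replace(rp, **{param: v})),
                   grid[i], grid[i + 1], xtol=1e-8)
        exchange.append(float(x))
    return BifurcationBranch(param=param, grid=grid, table=table,
                             exchange_points=exchange)


def extinction_threshold_rho(rp: ReducedParams) -> float:
    """Critical SMC proliferation rate Pi_c / k below which SMCs die out.

    Independent of rho_c itself (k does not involve rho_c).  Bounded between
    beta_c (no switching) and beta_c + delta_c (saturated switching).
    """
    return rp.Pi_c / solve_k(rp)


def critical_delta_c(rp: ReducedParams, cross_check: bool = True) -> float:
    """Forward switching rate at which the coexistence branch loses positivity.

    At the exchange, C2* = 0 forces k = Pi_c / rho_c; inverting the
    lipid-balance relation gives the closed form

        delta_c* = (rho_c - beta_c) (alpha_c^n + k^n) / k^n.

    With ``cross_check`` the value is verified against a bisection on the
    physicality margin as a function of delta_c.
    """
    k = rp.Pi_c / rp.rho_c
    if rp.rho_c <= rp.beta_c:
        return 0.0
    dc = (rp.rho_c - rp.beta_c) * (rp.alpha_c ** rp.n + k ** rp.n) / k ** rp.n
    if cross_check:
        lo, hi = dc * 0.5, dc * 2.0
        dc_num = brentq(lambda d: _margin(replace(rp, delta_c=d)), lo, hi,
                        xtol=1e-10 * dc)
        if abs(dc_num - dc) > 1e-6 * dc:
            raise RuntimeError(
                f"analytic ({dc}) and bisection ({dc_num}) critical delta_c disagree")
    return dc


def _S2(rp: ReducedParams, delta_c: float) -> float:
    rpi = replace(rp, delta_c=delta_c)
    k = solve_k(rpi)
    C2 = rpi.C_0 * (1.0 - rpi.Pi_c / (k * rpi.rho_c))
    return C2 * (rpi.Pi_c / k - rpi.beta_c) / (rpi.beta_s - rpi.rho_s)


def argmax_S2_delta_c(rp: ReducedParams, xatol: float = 1e-3) -> float:
    """Forward switching rate that maximises the coexistence SDM population.

    S2* rises with delta_c while switching supplies SDMs, then falls as
    switching depletes the SMC source; the maximiser lies strictly inside
    (0, critical delta_c) and is located by bounded scalar minimisation.
    """
    upper = critical_delta_c(rp, cross_check=False)
    res = minimize_scalar(lambda d: -_S2(rp, d), bounds=(1e-6, upper),
                          method="bounded", options={"xatol": xatol})
    if not res.success:
        raise RuntimeError(f"search for the S2-maximising delta_c failed: {res}")
    return float(res.x)
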