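"""Time integration, steady states and scenario experiments for the full model.

The seeding protocol mirrors plaque initiation: the system starts from the
all-zero state, modLDL influx recruits MDMs, and at scaled time ``t_c`` a
tiny SMC population carrying only endogenous lipid is injected
(``C`` and ``A_c`` both jump by ``C_init``).  The integration is restarted
exactly at the jump, never interpolated across it.

Steady states are found by long integration followed by a Newton polish of
the right-hand side; the polished root must agree with the trajectory
endpoint, which keeps the solver on the attracting branch reached by the
seeding protocol rather than on an arbitrary root.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import full_model
from .full_model import IDX, STATE_VARS, rhs
from .parameters import DimensionlessParams, validate

__all__ = [
    "Trajectory",
    "PathologyReport",
    "SteadyStateError",
    "run",
    "steady_state",
    "pathology_report",
    "scenario_sweep",
    "smc_derived_fraction",
]

#: Default integration horizon (scaled time; ~3.4 physical years at the
#: baseline time scale).  Chosen so baseline metrics drift < 0.1% over the
#: final 10 units.
DEFAULT_T_END = 60.0

#: Reference MDM apoptosis rate (1/hour) used to map scaled time back to
#: physical hours when no dimensional set is supplied.
DEFAULT_BETA_M = 0.002


class SteadyStateError(RuntimeError):
    """Raised when no steady state can be located (e.g. unbounded growth)."""


@dataclass
class Trajectory:
    """A solved trajectory of the full system."""

    t: np.ndarray          # scaled time, strictly increasing except at the seed
    y: np.ndarray          # states, shape (len(t), 10), STATE_VARS order
    t_c: float             # seeding time (nan if no seed applied)
    params: DimensionlessParams

    def __getitem__(self, var: str) -> np.ndarray:
        return self.y[:, IDX[var]]

    def time_hours(self, beta_m: float = DEFAULT_BETA_M) -> np.ndarray:
        """Physical time in hours (scaled time divided by the MDM apoptosis rate)."""
        return self.t / beta_m

    def final_state(self) -> np.ndarray:
        return self.y[-1].copy()

    def to_dataframe(self, beta_m: float = DEFAULT_BETA_M) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_VARS))
        df.insert(0, "t_hours", self.t / beta_m)
        df.insert(0, "t", self.t)
        df["smc_derived_fraction"] = smc_derived_fraction(self)
        return df


@dataclass(frozen=True)
class PathologyReport:
    """Summary pathology metrics of a single plaque state.

    The three headline indicators of a vulnerable plaque are a large
    macrophage burden (M + S, inflammation), a small cap SMC population
    (thin fibrous cap) and a large necrotic lipid mass (necrotic core).
    """

    macrophages: float         # M + S
    smc_count: float           # C
    sdm_count: float           # S
    mdm_count: float           # M
    necrotic_lipid: float      # N
    total_lipid: float         # L + A_c + A_s + A_m + A_p + N
    lipid_proportions: dict    # share of total lipid per compartment
    avg_load_mdm: float        # A_m / M (0 if M = 0)
    avg_load_smc: float
    avg_load_sdm: float
    smc_derived_fraction: float  # (C + S) / (C + S + M)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        props = d.pop("lipid_proportions")
        d.update({f"lipid_prop_{k}": v for k, v in props.items()})
        return d


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def pathology_report(state: np.ndarray) -> PathologyReport:
    L, H, C, A_c, S, A_s, M, A_m, A_p, N = state
    total = L + A_c + A_s + A_m + A_p + N
    props = {v: _ratio(state[IDX[v]], total) for v in full_model.LIPID_VARS}
    return PathologyReport(
        macrophages=M + S,
        smc_count=C, sdm_count=S, mdm_count=M,
        necrotic_lipid=N,
        total_lipid=total,
        lipid_proportions=props,
        avg_load_mdm=_ratio(A_m, M),
        avg_load_smc=_ratio(A_c, C),
        avg_load_sdm=_ratio(A_s, S),
        smc_derived_fraction=_ratio(C + S, C + S + M),
    )


def _check_params(p: DimensionlessParams) -> None:
    bad = validate(p)
    if bad:
        raise ValueError("invalid parameters: " + "; ".join(bad))


def _integrate(p, y0, t_span, rtol, atol, method, t_eval=None):
    sol = solve_ivp(lambda t, y: rhs(y, p), t_span, y0, method=method,
                    rtol=rtol, atol=atol, dense_output=False, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1]:.4g}, state={sol.y[:, -1]}: "
            f"{sol.message}")
    return sol


def run(p: DimensionlessParams, t_end: float = DEFAULT_T_END, *,
        rtol: float = 1e-9, atol: float = 1e-12, method: str = "LSODA",
        points_per_unit: int = 20, validate_params: bool = True) -> Trajectory:
    """Integrate the seeded two-phase protocol from the zero state.

    Phase one runs the MDM-only dynamics on [0, t_c]; at t_c the SMC seed
    (C_init cells with endogenous lipid only) is added to C and A_c and the
    solver restarted.  With ``C_init = 0`` the seed is skipped and the SMC,
    SDM blocks remain identically zero.
    """
    if validate_params:
        _check_params(p)
    seed = p.C_init > 0.0
    if seed and not (0.0 <= p.t_c < t_end):
        raise ValueError(f"need 0 <= t_c < t_end, got t_c={p.t_c}, t_end={t_end}")

    y0 = np.zeros(len(STATE_VARS))
    ts, ys = [], []
    t0 = 0.0
    if seed and p.t_c > 0.0:
        t_eval = np.linspace(0.0, p.t_c, max(int(points_per_unit * p.t_c), 2))
        sol = _integrate(p, y0, (0.0, p.t_c), rtol, atol, method, t_eval)
        ts.append(sol.t)
        ys.append(sol.y.T)
        y0 = sol.y[:, -1].copy()
        t0 = p.t_c
    if seed:
        y0[IDX["C"]] += p.C_init
        y0[IDX["A_c"]] += p.C_init
    t_eval = np.linspace(t0, t_end, max(int(points_per_unit * (t_end - t0)), 2))
    sol = _integrate(p, y0, (t0, t_end), rtol, atol, method, t_eval)
    y_seg = sol.y.T.copy()
    y_seg[0] = y0  # restart is exact, not interpolated across the jump
    ts.append(sol.t)
    ys.append(y_seg)

    t = np.concatenate(ts)
    y = np.vstack(ys)
    if y.min() < -1e-9:
        warnings.warn(
            f"trajectory undershoots zero by {-y.min():.3g}", RuntimeWarning)
    Cmax = y[:, IDX["C"]].max()
    if Cmax > p.C_0 * (1 + 1e-9):
        warnings.warn(
            f"SMC count exceeded its carrying capacity (max C = {Cmax:.4g} "
            f"> C_0 = {p.C_0:.4g})", RuntimeWarning)
    return Trajectory(t=t, y=y, t_c=p.t_c if seed else float("nan"), params=p)


def steady_state(p: DimensionlessParams, *, t_end: float = DEFAULT_T_END,
                 t_max: float = 480.0,
                 rtol: float = 1e-9, atol: float = 1e-12,
                 method: str = "LSODA", validate_params: bool = True,
                 slope_tol: float = 3e-5, resid_tol: float = 1e-10
                 ) -> np.ndarray:
    """Steady state reached by the seeding protocol.

    Integrates to ``t_end`` and keeps extending (up to ``t_max``) until the
    relative slope ||rhs||/||state|| falls below ``slope_tol``, then
    polishes with a damped Newton (hybrid) root solve on the right-hand
    side.  Fails loudly rather than returning a drifting or spurious state.
    """
    if validate_params:
        _check_params(p)
    seeded_sdm_source = p.C_init > 0.0 and p.delta_c > 0.0
    if p.beta_s <= p.rho_s and seeded_sdm_source:
        raise SteadyStateError(
            "no steady state: beta_s <= rho_s with a nonzero SDM source "
            "drives unbounded SDM growth")

    traj = run(p, t_end, rtol=rtol, atol=atol, method=method,
               validate_params=False, points_per_unit=4)
    y_end = traj.final_state()
    t = t_end

    def _slope(y):
        return np.linalg.norm(rhs(y, p)) / max(np.linalg.norm(y), 1.0)

    while _slope(y_end) > slope_tol and t < t_max:
        t_next = min(2.0 * t, t_max)  # double the horizon each extension
        sol = _integrate(p, y_end, (t, t_next), rtol, atol, method)
        y_end = sol.y[:, -1].copy()
        t = t_next
    slope = _slope(y_end)
    if slope > slope_tol:
        raise SteadyStateError(
            f"trajectory still evolving at t={t:.4g} (relative slope {slope:.3g})")

    sol = root(lambda y: rhs(y, p), y_end, method="hybr", tol=1e-13)
    y_ss = sol.x
    resid = np.max(np.abs(rhs(y_ss, p)))
    if not sol.success or resid > resid_tol:
        raise SteadyStateError(
            f"root polish failed (residual {resid:.3g}) from t={t_end} endpoint")
    if y_ss.min() < -1e-9:
        raise SteadyStateError(f"polished steady state is negative: {y_ss}")
    denom = np.maximum(np.abs(y_end), 1e-8)
    if np.max(np.abs(y_ss - y_end) / denom) > 1e-3:
        raise SteadyStateError(
            "root polish jumped away from the integrated endpoint; "
            "increase t_end")
    return np.clip(y_ss, 0.0, None)


def smc_derived_fraction(traj: Trajectory) -> np.ndarray:
    """Fraction of plaque cells of SMC origin, (C+S)/(C+S+M), 0 where empty."""
    C, S, M = traj["C"], traj["S"], traj["M"]
    denom = C + S + M
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, (C + S) / np.where(denom > 0, denom, 1.0), 0.0)
    return frac


#: Metrics reported by scenario_sweep, as functions of a PathologyReport.
SWEEP_METRICS = ("smc_count", "sdm_count", "mdm_count", "macrophages",
                 "necrotic_lipid", "total_lipid")


def scenario_sweep(p: DimensionlessParams, param_name: str, values,
                   metrics=SWEEP_METRICS, **steady_kw) -> pd.DataFrame:
    """Steady-state metrics and percentage changes along a 1-D parameter sweep.

    One steady solve per value; percentage changes are relative to the
    steady state at the *unmodified* baseline ``p``.  Per-point failures are
    recorded in an ``error`` column and the sweep continues.
    """
    base_report = pathology_report(steady_state(p, **steady_kw)).to_dict()
    rows = []
    for value in np.atleast_1d(values):
        row = {param_name: float(value), "error": ""}
        try:
            ss = steady_state(replace(p, **{param_name: float(value)}), **steady_kw)
            rep = pathology_report(ss).to_dict()
            for m in metrics:
                row[m] = rep[m]
                base = base_report[m]
                row[f"pct_change_{m}"] = (
                    100.0 * (rep[m] - base) / base if base != 0 else np.nan)
        except (SteadyStateError, ValueError, RuntimeError) as exc:
            row["error"] = str(exc)
            for m in metrics:
                row[m] = np.nan
                row[f"pct_change_{m}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
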