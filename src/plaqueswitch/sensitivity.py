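"""Global sensitivity of full-model steady states: LHS sampling plus PRCC.

Parameters are varied independently and uniformly within +/- a fraction of
their baseline values using Latin hypercube sampling (one sample per
equal-probability stratum per dimension).  Samples that violate the
boundedness constraint rho_s < beta_s are excluded after sampling, not
resampled.  For each retained sample the full model is run to steady state
and partial rank correlation coefficients (PRCCs) are computed between each
parameter and each steady-state output: rank-transform every column, then
correlate the residuals of the two rank-regressions on all remaining
parameters.  PRCC measures monotone influence while controlling for the
other inputs; values near +/-1 indicate strong monotone effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata

from .parameters import DimensionlessParams, baseline_dimensionless
from .simulate import SteadyStateError, steady_state

__all__ = [
    "DEFAULT_VARIED",
    "DEFAULT_OUTPUTS",
    "SensitivityDesign",
    "PRCCResult",
    "lhs_sample",
    "prcc",
    "run_sensitivity",
]

#: Parameters varied by default: every kinetic dimensionless parameter.
#: Excluded as structural: the MDM apoptosis rate (the time scale, ==1),
#: the seeding protocol constants t_c and C_init, the Hill exponent n, and
#: the recruitment weights tau_m, tau_s.
DEFAULT_VARIED = (
    "rho_c", "C_0", "beta_c", "delta_c", "alpha_c", "delta_s", "alpha_s",
    "sigma_L", "sigma_H", "Phi_m", "Phi_s", "Phi_c", "Theta_m", "Theta_s",
    "eta_m", "eta_s", "eta_c", "zeta_m", "zeta_s", "nu", "rho_s", "beta_s",
    "Gamma", "rho_m", "gamma",
)

#: Steady-state outputs: cell counts, intracellular lipids, dead-cell lipids.
DEFAULT_OUTPUTS = ("M", "C", "S", "A_m", "A_c", "A_s", "A_p", "N")

_OUTPUT_IDX = {"L": 0, "H": 1, "C": 2, "A_c": 3, "S": 4, "A_s": 5,
               "M": 6, "A_m": 7, "A_p": 8, "N": 9}


@dataclass(frozen=True)
class SensitivityDesign:
    """Specification of an LHS-PRCC experiment."""

    names: tuple[str, ...] = DEFAULT_VARIED
    frac: float = 0.2          # half-width of the uniform range, as a fraction
    n_samples: int = 1000
    seed: int = 0
    outputs: tuple[str, ...] = DEFAULT_OUTPUTS

    def __post_init__(self):
        if self.frac < 0 or self.frac >= 1:
            raise ValueError(f"frac must lie in [0, 1), got {self.frac!r}")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass
class PRCCResult:
    """PRCC matrix (parameters x outputs) plus run bookkeeping."""

    prcc: pd.DataFrame
    n_retained: int            # samples surviving the constraint
    n_converged: int           # samples with a converged steady state
    seed: int
    failures: list[str] = field(default_factory=list)


def lhs_sample(design: SensitivityDesign,
               baseline: DimensionlessParams | None = None) -> pd.DataFrame:
    """Latin hypercube sample of the design's parameter box.

    Marginals are uniform on [(1-frac)*baseline, (1+frac)*baseline].  Rows
    with rho_s >= beta_s (unbounded SDM growth) are dropped after sampling.
    """
    p0 = baseline if baseline is not None else baseline_dimensionless()
    base = np.array([getattr(p0, name) for name in design.names])
    sampler = qmc.LatinHypercube(d=len(design.names), seed=design.seed)
    unit = sampler.random(design.n_samples)
    lo, hi = base * (1 - design.frac), base * (1 + design.frac)
    X = pd.DataFrame(lo + unit * (hi - lo), columns=list(design.names))

    rho = X["rho_s"] if "rho_s" in design.names else p0.rho_s
    beta = X["beta_s"] if "beta_s" in design.names else p0.beta_s
    keep = np.asarray(rho < beta)
    if keep.ndim == 0:
        keep = np.full(len(X), bool(keep))
    return X[keep].reset_index(drop=True)


def _rank_residuals(R: np.ndarray) -> np.ndarray:
    """Residuals of each rank column regressed on all the others.

    R has z-scored rank columns; returns a matrix of the same shape where
    column j holds the residual of column j on the remaining columns (with
    intercept).  Used for both the parameter and the output side of PRCC.
    """
    n, d = R.shape
    out = np.empty_like(R)
    ones = np.ones((n, 1))
    for j in range(d):
        others = np.hstack([ones, np.delete(R, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, R[:, j], rcond=None)
        out[:, j] = R[:, j] - others @ coef
    return out


def prcc(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """Partial rank correlation of each column of X with each column of Y.

    For parameter x_j and output y: rank-transform all columns of X and y,
    regress both rank(x_j) and rank(y) on the ranks of the other
    parameters, and Pearson-correlate the residuals.

    Raises on singular (collinear or constant) parameter columns.
    """
    if len(X) != len(Y):
        raise ValueError("X and Y must have the same number of rows")
    Xv = X.to_numpy(dtype=float)
    n, d = Xv.shape
    if n <= d + 2:
        raise ValueError(f"too few samples ({n}) for {d} parameters")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant parameter columns: {const}")

    RX = np.apply_along_axis(rankdata, 0, Xv)
    RX = (RX - RX.mean(axis=0)) / RX.std(axis=0)
    cond = np.linalg.cond(np.corrcoef(RX, rowvar=False))
    if cond > 1e10:
        raise ValueError("parameter rank matrix is numerically singular; "
                         "check for collinear columns")
    res_X = _rank_residuals(RX)

    ones = np.ones((n, 1))
    out = np.empty((d, Y.shape[1]))
    for jy, col in enumerate(Y.columns):
        ry = rankdata(Y[col].to_numpy(dtype=float))
        ry = (ry - ry.mean()) / (ry.std() if ry.std() > 0 else 1.0)
        for jx in range(d):
            others = np.hstack([ones, np.delete(RX, jx, axis=1)])
            coef, *_ = np.linalg.lstsq(others, ry, rcond=None)
            res_y = ry - others @ coef
            num = res_X[:, jx] @ res_y
            den = np.linalg.norm(res_X[:, jx]) * np.linalg.norm(res_y)
            out[jx, jy] = num / den if den > 0 else 0.0
    return pd.DataFrame(out, index=list(X.columns), columns=list(Y.columns))


def run_sensitivity(baseline: DimensionlessParams | None = None,
                    design: SensitivityDesign | None = None,
                    **steady_kw) -> PRCCResult:
    """Full LHS-PRCC experiment on the model's steady states.

    Samples the design, runs each retained sample's seeding protocol to
    steady state, and computes the PRCC matrix.  Non-converging samples are
    dropped with a logged reason; more than 10% failures triggers a warning.
    """
    import warnings

    p0 = baseline if baseline is not None else baseline_dimensionless()
    design = design if design is not None else SensitivityDesign()
    X = lhs_sample(design, p0)

    rows, ok, failures = [], [], []
    for i in range(len(X)):
        pi = replace(p0, **{k: float(X.iloc[i][k]) for k in design.names})
        try:
            ss = steady_state(pi, validate_params=False, **steady_kw)
        except (SteadyStateError, RuntimeError, ValueError) as exc:
            failures.append(f"sample {i}: {exc}")
            continue
        rows.append([ss[_OUTPUT_IDX[v]] for v in design.outputs])
        ok.append(i)

    if len(failures) > 0.1 * len(X):
        warnings.warn(
            f"{len(failures)}/{len(X)} steady-state solves failed; "
            "PRCCs computed on the converged subset", RuntimeWarning)
    Y = pd.DataFrame(rows, columns=list(design.outputs))
    result = prcc(X.iloc[ok].reset_index(drop=True), Y)
    return PRCCResult(prcc=result, n_retained=len(X), n_converged=len(ok),
                      seed=design.seed, failures=failures)
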