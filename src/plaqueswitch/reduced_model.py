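"""Three-equation submodel of SMC phenotype switching.

With SDM-to-SMC reversion disabled (delta_s = 0) and SMC lipid uptake fixed
at a constant rate Pi_c, the (C, A_c, S) block decouples from the rest of
the plaque system.  Working with the average SMC lipid load Abar_c = A_c / C
instead of the total gives an autonomous 3-D system with exactly two steady
states:

* an extinction state (C*, Abar_c*, S*) = (0, 1 + Pi_c/rho_c, 0), and
* a coexistence state C* = C_0 (1 - Pi_c/(k rho_c)), Abar_c* = 1 + k,
  S* = C* (Pi_c/k - beta_c) / (beta_s - rho_s),

where k > 0, the average ingested SMC lipid at steady state, is the unique
positive root of

    (beta_c + delta_c) k^{n+1} - Pi_c k^n + alpha_c^n beta_c k
        - alpha_c^n Pi_c = 0,

equivalently of Pi_c / k = beta_c + delta_c k^n / (alpha_c^n + k^n).  The
coexistence state is physical (positive) iff rho_c > Pi_c / k, and the two
branches exchange stability exactly at that threshold: SMCs persist only if
proliferation outpaces the combined loss to apoptosis and switching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import DimensionlessParams

__all__ = [
    "ReducedParams",
    "ReducedSteadyState",
    "solve_k",
    "steady_states",
    "jacobian",
    "classify",
    "rhs_reduced",
]


@dataclass(frozen=True)
class ReducedParams:
    """Parameters of the reduced switching submodel (all dimensionless).

    Defaults are the baseline values of the full model; ``Pi_c`` is the
    constant SMC lipid-uptake rate that replaces the modLDL/efferocytosis
    terms and has no baseline in the full set (the analysis in this package
    follows the reference choice Pi_c = 3).
    """

    Pi_c: float = 3.0
    rho_c: float = 8.0
    C_0: float = 0.002 * 750 / 5.4
    beta_c: float = 0.2
    delta_c: float = 3.0
    alpha_c: float = 2.0
    beta_s: float = 5.3
    rho_s: float = 5.0
    n: float = 4.0

    @classmethod
    def from_full(cls, p: DimensionlessParams, Pi_c: float) -> "ReducedParams":
        return cls(Pi_c=Pi_c, rho_c=p.rho_c, C_0=p.C_0, beta_c=p.beta_c,
                   delta_c=p.delta_c, alpha_c=p.alpha_c, beta_s=p.beta_s,
                   rho_s=p.rho_s, n=p.n)

    def validate(self) -> list[str]:
        v = []
        if self.Pi_c <= 0:
            v.append("Pi_c must be strictly positive")
        if self.beta_s <= self.rho_s:
            v.append("beta_s > rho_s required for a bounded SDM population")
        for name in ("rho_c", "C_0", "beta_c", "alpha_c"):
            if getattr(self, name) <= 0:
                v.append(f"{name} must be strictly positive")
        if self.delta_c < 0 or self.rho_s < 0:
            v.append("delta_c and rho_s must be non-negative")
        if self.n < 1:
            v.append("n >= 1 required")
        return v


@dataclass(frozen=True)
class ReducedSteadyState:
    """A steady state of the reduced system with its local stability."""

    C_star: float
    Abar_c_star: float
    S_star: float
    eigenvalues: tuple[complex, complex, complex]
    stability: str            # "stable node" | "stable" | "saddle" | "unstable"
    physical: bool
    k: float | None = None    # average ingested lipid, coexistence branch only

    @property
    def stable(self) -> bool:
        return self.stability.startswith("stable")


def solve_k(rp: ReducedParams) -> float:
    """Unique positive root k of the steady-state lipid-balance equation.

    Solves Pi_c/k = beta_c + delta_c k^n/(alpha_c^n + k^n) by bisection:
    the right side is non-decreasing in k and Pi_c/k strictly decreasing,
    so the root is unique.  It always satisfies
    Pi_c/k in (beta_c, beta_c + delta_c].
    """
    bad = rp.validate()
    # beta_s/rho_s do not enter k; tolerate their violation here.
    bad = [b for b in bad if "beta_s" not in b]
    if bad:
        raise ValueError("; ".join(bad))
    if rp.delta_c == 0.0:
        return rp.Pi_c / rp.beta_c

    def g(k: float) -> float:
        x = (k / rp.alpha_c) ** rp.n
        return rp.beta_c + rp.delta_c * x / (1.0 + x) - rp.Pi_c / k

    # Bracket: g < 0 for small k, g > 0 for k > Pi_c/beta_c.
    lo = min(rp.Pi_c / (rp.beta_c + rp.delta_c), rp.alpha_c) * 0.5
    while g(lo) >= 0.0:
        lo *= 0.5
    hi = rp.Pi_c / rp.beta_c * 1.0000001
    while g(hi) <= 0.0:
        hi *= 2.0
    k = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)

    # Polish on the polynomial form and check its residual.
    poly = _k_poly(rp, k)
    dpoly = _k_poly_deriv(rp, k)
    if dpoly != 0.0:
        k -= poly / dpoly
    scale = abs(rp.Pi_c) * max(k, rp.alpha_c) ** rp.n + 1.0
    if abs(_k_poly(rp, k)) > 1e-12 * scale:
        raise RuntimeError(f"k root residual too large at k={k!r}")
    return k


def _k_poly(rp: ReducedParams, k: float) -> float:
    n = rp.n
    return ((rp.beta_c + rp.delta_c) * k ** (n + 1) - rp.Pi_c * k ** n
            + rp.alpha_c ** n * rp.beta_c * k - rp.alpha_c ** n * rp.Pi_c)


def _k_poly_deriv(rp: ReducedParams, k: float) -> float:
    n = rp.n
    return ((n + 1) * (rp.beta_c + rp.delta_c) * k ** n
            - n * rp.Pi_c * k ** (n - 1) + rp.alpha_c ** n * rp.beta_c)


def _classify_eigs(eigs: np.ndarray) -> str:
    re = np.real(eigs)
    if np.all(re < 0):
        if np.allclose(np.imag(eigs), 0.0):
            return "stable node"
        return "stable"
    if np.any(re < 0) and np.any(re > 0):
        return "saddle"
    return "unstable"


def steady_states(rp: ReducedParams
                  ) -> tuple[ReducedSteadyState, ReducedSteadyState]:
    """Both steady states of the reduced system, with stability labels.

    Returns ``(trivial, nontrivial)``.  The coexistence branch is always
    evaluated; its ``physical`` flag records whether it is positive
    (rho_c > Pi_c/k).
    """
    bad = rp.validate()
    if bad:
        raise ValueError("; ".join(bad))

    # Extinction branch.
    triv_state = (0.0, 1.0 + rp.Pi_c / rp.rho_c, 0.0)
    J1 = jacobian(rp, triv_state)
    eig1_num = np.sort_complex(np.linalg.eigvals(J1))
    eig1_closed = np.sort_complex(np.array([
        _lambda1_trivial(rp), -rp.rho_c, rp.rho_s - rp.beta_s], dtype=complex))
    if np.max(np.abs(eig1_num - eig1_closed)) > 1e-8 * (1 + np.max(np.abs(eig1_closed))):
        raise RuntimeError("numerical and closed-form trivial eigenvalues disagree")
    trivial = ReducedSteadyState(
        C_star=0.0, Abar_c_star=triv_state[1], S_star=0.0,
        eigenvalues=tuple(eig1_closed),
        stability=_classify_eigs(eig1_closed),
        physical=True)

    # Coexistence branch.
    k = solve_k(rp)
    C2 = rp.C_0 * (1.0 - rp.Pi_c / (k * rp.rho_c))
    S2 = C2 * (rp.Pi_c / k - rp.beta_c) / (rp.beta_s - rp.rho_s)
    physical = rp.rho_c > rp.Pi_c / k
    J2 = jacobian(rp, (C2, 1.0 + k, S2))
    eig2 = np.sort_complex(np.linalg.eigvals(J2))
    nontrivial = ReducedSteadyState(
        C_star=C2, Abar_c_star=1.0 + k, S_star=S2,
        eigenvalues=tuple(eig2),
        stability=_classify_eigs(eig2) if physical else "unstable",
        physical=physical, k=k)
    return trivial, nontrivial


def _lambda1_trivial(rp: ReducedParams) -> float:
    """Closed-form leading eigenvalue at the extinction state."""
    x = (rp.Pi_c / rp.rho_c / rp.alpha_c) ** rp.n
    return rp.rho_c - rp.beta_c - rp.delta_c * x / (1.0 + x)


def jacobian(rp: ReducedParams, state) -> np.ndarray:
    """Jacobian of the averaged-form reduced system at (C, Abar_c, S).

    The third column is (0, 0, rho_s - beta_s): the SDM count feeds back on
    nothing, so one eigenvalue is always the net SDM growth rate.
    """
    C, Abar, _S = state
    x = Abar - 1.0
    an = rp.alpha_c ** rp.n
    xn = x ** rp.n if x > 0 else 0.0
    h = xn / (an + xn)
    dh = (rp.n * an * x ** (rp.n - 1.0) / (an + xn) ** 2) if x > 0 else 0.0
    return np.array([
        [rp.rho_c * (1.0 - 2.0 * C / rp.C_0) - rp.beta_c - rp.delta_c * h,
         -rp.delta_c * C * dh,
         0.0],
        [rp.rho_c / rp.C_0 * x,
         rp.rho_c * (C / rp.C_0 - 1.0),
         0.0],
        [rp.delta_c * h,
         rp.delta_c * C * dh,
         rp.rho_s - rp.beta_s],
    ])


def classify(rp: ReducedParams
             ) -> dict[str, ReducedSteadyState]:
    """Stability report for both branches.

    Also asserts the exchange-of-stability logic: the coexistence branch is
    physical exactly when the extinction state's leading eigenvalue is
    positive (i.e. the extinction state is a saddle).
    """
    trivial, nontrivial = steady_states(rp)
    lam1 = _lambda1_trivial(rp)
    if nontrivial.physical != (lam1 > 0) and abs(lam1) > 1e-12:
        warnings.warn(
            "exchange-of-stability bookkeeping violated: "
            f"physical={nontrivial.physical} but lambda1={lam1}", RuntimeWarning)
    return {"trivial": trivial, "nontrivial": nontrivial}


def rhs_reduced(rp: ReducedParams, state, form: str = "average") -> np.ndarray:
    """Time derivative of the reduced system.

    ``form='average'`` uses (C, Abar_c, S) — finite as C -> 0 and the form
    used for steady-state analysis; ``form='total'`` uses (C, A_c, S).  The
    two coincide along trajectories with C > 0 under Abar_c = A_c / C.
    """
    an = rp.alpha_c ** rp.n
    if form == "average":
        C, Abar, S = state
        x = max(Abar - 1.0, 0.0)
        xn = x ** rp.n
        h = xn / (an + xn) if x > 0 else 0.0
        growth = rp.rho_c * (1.0 - C / rp.C_0)
        return np.array([
            growth * C - rp.beta_c * C - rp.delta_c * C * h,
            rp.Pi_c - growth * x,
            rp.delta_c * C * h - (rp.beta_s - rp.rho_s) * S,
        ])
    if form == "total":
        C, A_c, S = state
        x = max(A_c / C - 1.0, 0.0) if C > 0 else 0.0
        xn = x ** rp.n
        h = xn / (an + xn) if x > 0 else 0.0
        growth_c = rp.rho_c * (1.0 - C / rp.C_0) * C
        return np.array([
            growth_c - rp.beta_c * C - rp.delta_c * C * h,
            rp.Pi_c * C + growth_c - rp.beta_c * A_c - rp.delta_c * A_c * h,
            rp.delta_c * C * h - (rp.beta_s - rp.rho_s) * S,
        ])
    raise ValueError(f"form must be 'average' or 'total', got {form!r}")
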