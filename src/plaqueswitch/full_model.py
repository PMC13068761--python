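"""Right-hand side of the full dimensionless plaque system.

Ten state variables: modLDL lipid L, HDL acceptance capacity H, SMC count C
and total SMC lipid A_c, SDM count S and total SDM lipid A_s, MDM count M
and total MDM lipid A_m, apoptotic lipid A_p and necrotic lipid N.  All are
dimensionless; cell counts are scaled so the maximal MDM recruitment rate
sustains a unit population, lipids so one unit is the endogenous lipid of
that population, and time so the MDM apoptosis rate is 1.

Phenotype switching between SMCs and SDMs is driven by the average *ingested*
lipid per cell (average load minus the endogenous unit) through Hill
functions: heavily loaded SMCs switch forward to macrophage-like SDMs,
lightly loaded SDMs revert.  Empty-population convention: every per-capita
ratio and switching term is 0 when the relevant population is 0, which is
the limit of the printed forms and what the zero-seeded protocol requires.
The ingested-lipid argument is clamped at 0 from below so transient
numerical undershoot of the endogenous floor cannot generate spurious
switching (with even Hill exponents a negative argument would be
indistinguishable from a positive one).
"""

from __future__ import annotations

import numpy as np

from .parameters import DimensionlessParams

__all__ = [
    "STATE_VARS",
    "IDX",
    "recruitment",
    "switch_fwd",
    "switch_bwd",
    "rhs",
    "lipid_ledger",
]

STATE_VARS = ("L", "H", "C", "A_c", "S", "A_s", "M", "A_m", "A_p", "N")
IDX = {name: i for i, name in enumerate(STATE_VARS)}

#: Components of the total-lipid pool (everything except cells and HDL).
LIPID_VARS = ("L", "A_c", "A_s", "A_m", "A_p", "N")


def _hill(x: float, half: float, n: float) -> float:
    """x^n / (half^n + x^n), with the x=0 limit handled explicitly."""
    if x <= 0.0:
        return 0.0
    r = (x / half) ** n
    return r / (1.0 + r)


def recruitment(L: float, M: float, S: float, A_m: float, A_s: float,
                p: DimensionlessParams) -> float:
    """Dimensionless MDM recruitment rate, a saturating function in [0, 1).

    The stimulus is the total pro-inflammatory lipid: modLDL plus the
    ingested (above-endogenous) lipid of the MDM and SDM pools, weighted by
    tau_m and tau_s.  Half-maximal recruitment at stimulus = Gamma.  The
    stimulus is clamped at 0 from below.
    """
    stim = L + p.tau_m * (A_m - M) + p.tau_s * (A_s - S)
    if stim <= 0.0:
        return 0.0
    return stim / (p.Gamma + stim)


def switch_fwd(C: float, A_c: float, p: DimensionlessParams) -> float:
    """SMC -> SDM switching rate (cells per scaled time).

    delta_c * C * h(x) with x = max(A_c/C - 1, 0) and h a Hill function with
    half-saturation alpha_c; 0 when C = 0.
    """
    if C <= 0.0:
        return 0.0
    return p.delta_c * C * _hill(A_c / C - 1.0, p.alpha_c, p.n)


def switch_bwd(S: float, A_s: float, p: DimensionlessParams) -> float:
    """SDM -> SMC reversion rate (cells per scaled time).

    delta_s * S * (1 - h(y)) with y = max(A_s/S - 1, 0): reversion is
    maximal for lipid-free SDMs and shuts off as they load; 0 when S = 0.
    """
    if S <= 0.0:
        return 0.0
    return p.delta_s * S * (1.0 - _hill(A_s / S - 1.0, p.alpha_s, p.n))


def rhs(y, p: DimensionlessParams, guard_offload: bool = False) -> np.ndarray:
    """Time derivative of the full dimensionless state.

    Parameters
    ----------
    y : array-like, shape (10,)
        State in :data:`STATE_VARS` order; expected non-negative.
    p : DimensionlessParams
    guard_offload : bool
        If True, clamp the HDL offload terms so they cannot draw the MDM or
        SDM lipid pools below their endogenous floors (A_m >= M, A_s >= S).
        Off by default: the unguarded form is the model as stated, the guard
        only documents its known edge case.
    """
    L, H, C, A_c, S, A_s, M, A_m, A_p, N = y

    f = recruitment(L, M, S, A_m, A_s, p)
    fwd = switch_fwd(C, A_c, p)                   # cell flux SMC -> SDM
    fwd_lipid = fwd * (A_c / C) if C > 0.0 else 0.0
    bwd = switch_bwd(S, A_s, p)                   # cell flux SDM -> SMC
    bwd_lipid = bwd * (A_s / S) if S > 0.0 else 0.0

    offload_m = p.zeta_m * H * M
    offload_s = p.zeta_s * H * S
    if guard_offload:
        offload_m = min(offload_m, max(A_m - M, 0.0))
        offload_s = min(offload_s, max(A_s - S, 0.0))

    growth_c = p.rho_c * (1.0 - C / p.C_0) * C    # logistic SMC proliferation

    dL = p.sigma_L - (p.eta_m * M + p.eta_s * S + p.eta_c * C) * L
    dH = p.sigma_H - (p.zeta_m * M + p.zeta_s * S) * H
    dC = growth_c - p.beta_c * C - fwd + bwd
    dA_c = (p.eta_c * L * C + p.Phi_c * A_p * C + growth_c
            - p.beta_c * A_c - fwd_lipid + bwd_lipid)
    dS = fwd + (p.rho_s - p.beta_s) * S - bwd
    dA_s = ((p.eta_s * L + p.Phi_s * A_p + p.Theta_s * N + p.rho_s) * S
            - offload_s - p.beta_s * A_s + fwd_lipid - bwd_lipid)
    dM = f + (p.rho_m - 1.0 - p.gamma) * M
    dA_m = (f + (p.eta_m * L + p.Phi_m * A_p + p.Theta_m * N + p.rho_m) * M
            - offload_m - (1.0 + p.gamma) * A_m)
    dA_p = (A_m + p.beta_s * A_s + p.beta_c * A_c
            - (p.Phi_m * M + p.Phi_s * S + p.Phi_c * C) * A_p - p.nu * A_p)
    dN = p.nu * A_p - (p.Theta_m * M + p.Theta_s * S) * N

    return np.array([dL, dH, dC, dA_c, dS, dA_s, dM, dA_m, dA_p, dN])


def lipid_ledger(y, p: DimensionlessParams) -> tuple[float, float]:
    """Book-keeping totals for the lipid pool L + A_c + A_s + A_m + A_p + N.

    Apoptosis, efferocytosis, necrosis and switching only move lipid between
    compartments, so the time derivative of the total equals influx - efflux
    with

    * influx: the modLDL source, plus endogenous lipid synthesised for newly
      recruited MDMs and for proliferating SMCs, SDMs and MDMs;
    * efflux: offload to HDL from MDMs and SDMs, plus lipid carried out by
      emigrating MDMs.

    Returns ``(influx, efflux)``; their difference matches
    ``sum(rhs(y, p)[lipid components])`` to machine precision.
    """
    L, H, C, A_c, S, A_s, M, A_m, A_p, N = y
    f = recruitment(L, M, S, A_m, A_s, p)
    influx = (p.sigma_L + f
              + p.rho_c * (1.0 - C / p.C_0) * C
              + p.rho_s * S + p.rho_m * M)
    efflux = p.zeta_m * H * M + p.zeta_s * H * S + p.gamma * A_m
    return influx, efflux
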