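"""Dimensional and dimensionless parameter sets for the plaque model.

The model is parameterised twice: once in physical units (rates per hour,
lipid masses in grams) and once in the dimensionless form actually
integrated, obtained by scaling time with the MDM apoptosis rate ``beta_m``,
cell counts with ``alpha_m / beta_m`` (the maximal MDM recruitment rate over
the apoptosis rate) and lipid masses with ``a_0 * alpha_m / beta_m`` (the
endogenous lipid of that reference cell pool).  After scaling, the MDM
apoptosis rate is identically 1 and is not stored.

Derived entries of the dimensional set (e.g. the SDM proliferation rate is
0.625 times the SMC rate) are stored both as resolved numbers and as the
declared ratios in :data:`DERIVED_RATIOS`, so that a sweep of a parent
parameter can optionally be propagated to its dependants.  By default sweeps
vary one number at a time and do not propagate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields, replace
from typing import Iterable

import yaml

__all__ = [
    "DimensionalParams",
    "DimensionlessParams",
    "DERIVED_RATIOS",
    "baseline_dimensional",
    "baseline_dimensionless",
    "nondimensionalise",
    "validate",
    "validate_dimensional",
    "apply_ratios",
    "load_config",
    "save_config",
    "parse_overrides",
]

#: Endogenous lipid mass per cell (g); several defaults are ratios of it.
_A0 = 26.6e-12


@dataclass(frozen=True)
class DimensionalParams:
    """Physical parameters of the plaque model.

    Defaults are the baseline estimates (rates per hour, masses in grams,
    volumes in microlitres).  Derived entries (ratios of other parameters)
    are stored resolved.
    """

    alpha_m: float = 5.4          # MDM maximum recruitment rate, cells/hour
    kappa_m: float = 5e-8         # lipid stimulus for half-maximal recruitment, g
    rho_m: float = 0.0005         # MDM proliferation rate, 1/hour
    beta_m: float = 0.002         # MDM apoptosis rate, 1/hour
    gamma: float = 0.0015         # MDM emigration rate, 1/hour
    a_0: float = _A0              # endogenous lipid per cell, g/cell
    rho_c: float = 0.016          # SMC proliferation rate, 1/hour
    C_max: float = 750.0          # SMC carrying capacity, cells
    beta_c: float = 0.0004        # SMC apoptosis rate, 1/hour
    delta_c: float = 0.006        # max SMC->SDM switching rate, 1/hour
    alpha_c: float = 2 * _A0      # SMC lipid load for half-maximal switch, g/cell
    rho_s: float = 0.625 * 0.016  # SDM proliferation rate, 1/hour
    beta_s: float = 1.06 * 0.625 * 0.016  # SDM apoptosis rate, 1/hour
    delta_s: float = 0.006        # max SDM->SMC switching rate, 1/hour
    alpha_s: float = 0.5 * _A0    # SDM lipid load for half-maximal switch, g/cell
    Lambda: float = 5e-4          # serum entry rate, uL/hour
    sigma_L: float = 8e-7         # LDL lipid per unit serum volume, g/uL
    sigma_H: float = 5e-7         # HDL lipid capacity per unit serum volume, g/uL
    H_0: float = 5e-17            # lipid capacity of one HDL particle, g/particle
    eta_m: float = 1e-6           # modLDL consumption by MDMs, 1/(cell.hour)
    eta_c: float = 0.4e-6         # modLDL consumption by SMCs, 1/(cell.hour)
    eta_s: float = 0.75e-6        # modLDL consumption by SDMs, 1/(cell.hour)
    xi_m: float = 1e-23           # MDM lipid offload to HDL, g/(cell.particle.hour)
    xi_s: float = 0.25e-23        # SDM lipid offload to HDL, g/(cell.particle.hour)
    phi_m: float = 1e-5           # apoptotic lipid consumption by MDMs, 1/(cell.hour)
    phi_c: float = 0.2e-5         # apoptotic lipid consumption by SMCs, 1/(cell.hour)
    phi_s: float = 0.25e-5        # apoptotic lipid consumption by SDMs, 1/(cell.hour)
    theta_m: float = 3.6e-6       # necrotic lipid consumption by MDMs, 1/(cell.hour)
    theta_s: float = 0.25 * 3.6e-6  # necrotic lipid consumption by SDMs, 1/(cell.hour)
    nu: float = 0.05              # secondary necrosis rate, 1/hour
    t_c: float = 850.0            # time of SMC entry into plaque, hours
    C_init: float = 1.35          # SMC population seeded at t_c, cells
    tau_m: float = 1.0            # MDM lipid weighting in recruitment stimulus
    tau_s: float = 1.0            # SDM lipid weighting in recruitment stimulus
    n: float = 4.0                # Hill coefficient of the switching functions


#: Declared ratio definitions behind the derived baseline entries:
#: field -> (parent field, multiplier).
DERIVED_RATIOS: dict[str, tuple[str, float]] = {
    "rho_s": ("rho_c", 0.625),
    "beta_s": ("rho_s", 1.06),
    "delta_s": ("delta_c", 1.0),
    "alpha_c": ("a_0", 2.0),
    "alpha_s": ("a_0", 0.5),
    "eta_c": ("eta_m", 0.4),
    "eta_s": ("eta_m", 0.75),
    "xi_s": ("xi_m", 0.25),
    "phi_c": ("phi_m", 0.2),
    "phi_s": ("phi_m", 0.25),
    "theta_s": ("theta_m", 0.25),
}


def apply_ratios(p: DimensionalParams,
                 only: Iterable[str] | None = None) -> DimensionalParams:
    """Recompute derived entries from their parents via :data:`DERIVED_RATIOS`.

    ``only`` restricts propagation to the named derived fields.  Ratios are
    resolved in declaration order, so chained definitions (SDM apoptosis from
    SDM proliferation from SMC proliferation) cascade.
    """
    selected = set(DERIVED_RATIOS) if only is None else set(only)
    for name, (parent, factor) in DERIVED_RATIOS.items():
        if name in selected:
            p = replace(p, **{name: factor * getattr(p, parent)})
    return p


@dataclass(frozen=True)
class DimensionlessParams:
    """Scaled parameters driving the dimensionless system.

    The MDM apoptosis rate is the time unit and is identically 1 (not a
    field).  Defaults are the baseline set, i.e. the exact image of
    :func:`baseline_dimensional` under :func:`nondimensionalise`.
    """

    rho_c: float = 8.0
    C_0: float = 0.002 * 750 / 5.4
    beta_c: float = 0.2
    delta_c: float = 3.0
    alpha_c: float = 2.0
    delta_s: float = 3.0
    alpha_s: float = 0.5
    sigma_L: float = 5e-4 * 8e-7 / (_A0 * 5.4)
    sigma_H: float = 5e-4 * 5e-7 / (_A0 * 5.4)
    Phi_m: float = 1e-5 * 5.4 / 0.002**2
    Phi_s: float = 0.25e-5 * 5.4 / 0.002**2
    Phi_c: float = 0.2e-5 * 5.4 / 0.002**2
    Theta_m: float = 3.6e-6 * 5.4 / 0.002**2
    Theta_s: float = 0.9e-6 * 5.4 / 0.002**2
    eta_m: float = 1e-6 * 5.4 / 0.002**2
    eta_s: float = 0.75e-6 * 5.4 / 0.002**2
    eta_c: float = 0.4e-6 * 5.4 / 0.002**2
    zeta_m: float = 5.4 * 1e-23 / (5e-17 * 0.002**2)
    zeta_s: float = 5.4 * 0.25e-23 / (5e-17 * 0.002**2)
    nu: float = 25.0
    rho_s: float = 5.0
    beta_s: float = 1.06 * 5.0
    Gamma: float = 5e-8 * 0.002 / (_A0 * 5.4)
    rho_m: float = 0.25
    gamma: float = 0.75
    t_c: float = 1.7
    C_init: float = 5e-4
    tau_m: float = 1.0
    tau_s: float = 1.0
    n: float = 4.0


def baseline_dimensional() -> DimensionalParams:
    """Baseline physical parameter set (the model's reference estimates)."""
    return DimensionalParams()


def nondimensionalise(p: DimensionalParams) -> DimensionlessParams:
    """Map a dimensional parameter set to the scaled set.

    Raises
    ------
    ZeroDivisionError
        if any scaling denominator (``beta_m``, ``alpha_m``, ``a_0``,
        ``H_0``) is zero, which signals an invalid dimensional set.
    """
    for name in ("beta_m", "alpha_m", "a_0", "H_0"):
        if getattr(p, name) == 0:
            raise ZeroDivisionError(
                f"cannot nondimensionalise: {name} = 0 appears in a scaling denominator"
            )
    bm = p.beta_m
    lipid_scale = p.a_0 * p.alpha_m  # lipid mass of the reference cell pool
    return DimensionlessParams(
        rho_c=p.rho_c / bm,
        C_0=bm * p.C_max / p.alpha_m,
        beta_c=p.beta_c / bm,
        delta_c=p.delta_c / bm,
        alpha_c=p.alpha_c / p.a_0,
        delta_s=p.delta_s / bm,
        alpha_s=p.alpha_s / p.a_0,
        sigma_L=p.Lambda * p.sigma_L / lipid_scale,
        sigma_H=p.Lambda * p.sigma_H / lipid_scale,
        Phi_m=p.phi_m * p.alpha_m / bm**2,
        Phi_s=p.phi_s * p.alpha_m / bm**2,
        Phi_c=p.phi_c * p.alpha_m / bm**2,
        Theta_m=p.theta_m * p.alpha_m / bm**2,
        Theta_s=p.theta_s * p.alpha_m / bm**2,
        eta_m=p.eta_m * p.alpha_m / bm**2,
        eta_s=p.eta_s * p.alpha_m / bm**2,
        eta_c=p.eta_c * p.alpha_m / bm**2,
        zeta_m=p.xi_m * p.alpha_m / (p.H_0 * bm**2),
        zeta_s=p.xi_s * p.alpha_m / (p.H_0 * bm**2),
        nu=p.nu / bm,
        rho_s=p.rho_s / bm,
        beta_s=p.beta_s / bm,
        Gamma=p.kappa_m * bm / lipid_scale,
        rho_m=p.rho_m / bm,
        gamma=p.gamma / bm,
        t_c=bm * p.t_c,
        C_init=bm * p.C_init / p.alpha_m,
        tau_m=p.tau_m,
        tau_s=p.tau_s,
        n=p.n,
    )


def baseline_dimensionless() -> DimensionlessParams:
    """Baseline dimensionless set (image of the baseline physical set)."""
    return nondimensionalise(baseline_dimensional())


def validate(p: DimensionlessParams) -> list[str]:
    """Check the biological constraints of a dimensionless set.

    Returns a list of human-readable violations; empty iff the set is valid.
    """
    v: list[str] = []
    for f in fields(p):
        if getattr(p, f.name) < 0:
            v.append(f"{f.name} must be non-negative (got {getattr(p, f.name)!r})")
    if p.n < 1:
        v.append(f"n >= 1 required for the switching Hill functions (got {p.n!r})")
    if p.beta_s <= p.rho_s:
        v.append(
            "beta_s > rho_s required: a net SDM death rate keeps the SDM "
            f"population bounded (got beta_s={p.beta_s!r}, rho_s={p.rho_s!r})"
        )
    if p.alpha_c <= p.alpha_s:
        v.append(
            "alpha_c > alpha_s required: the forward switch saturates at a "
            f"higher lipid load than the reverse (got alpha_c={p.alpha_c!r}, "
            f"alpha_s={p.alpha_s!r})"
        )
    if p.zeta_m <= p.zeta_s:
        v.append(
            "zeta_m > zeta_s required: SDMs offload lipid to HDL less "
            f"efficiently than MDMs (got zeta_m={p.zeta_m!r}, zeta_s={p.zeta_s!r})"
        )
    if p.Gamma <= 0:
        v.append("Gamma must be strictly positive (recruitment half-saturation)")
    return v


_DIM_MAY_BE_ZERO = {"delta_s", "xi_s", "tau_m", "tau_s", "C_init"}


def validate_dimensional(p: DimensionalParams) -> list[str]:
    """Check positivity and ordering constraints of a dimensional set."""
    v: list[str] = []
    for f in fields(p):
        val = getattr(p, f.name)
        if f.name in _DIM_MAY_BE_ZERO:
            if val < 0:
                v.append(f"{f.name} must be >= 0 (got {val!r})")
        elif val <= 0:
            v.append(f"{f.name} must be strictly positive (got {val!r})")
    if p.n < 1:
        v.append(f"n >= 1 required (got {p.n!r})")
    if p.xi_m <= p.xi_s:
        v.append("xi_m > xi_s required (MDMs offload lipid faster than SDMs)")
    if p.alpha_c <= p.alpha_s:
        v.append("alpha_c > alpha_s required (forward switch half-saturation higher)")
    for slow, fast in (("eta_s", "eta_m"), ("phi_s", "phi_m"), ("theta_s", "theta_m")):
        if getattr(p, slow) >= getattr(p, fast):
            v.append(f"{slow} < {fast} required (SDM uptake rates below MDM rates)")
    return v


# ---------------------------------------------------------------------------
# Config file round-trip (flat YAML mapping, keys = field names).

def save_config(p: DimensionalParams | DimensionlessParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(p), fh, sort_keys=False)


def load_config(path, cls=DimensionlessParams):
    """Load a flat YAML mapping into a parameter dataclass.

    Unknown keys are rejected; missing keys fall back to defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown parameter keys in {path}: {sorted(unknown)}")
    return cls(**{k: float(v) for k, v in data.items()})


def parse_overrides(pairs: Iterable[str]) -> dict[str, float]:
    """Parse ``NAME=VALUE`` override strings into a dict of floats."""
    out: dict[str, float] = {}
    for pair in pairs:
        name, sep, value = pair.partition("=")
        if not sep or not name:
            raise ValueError(f"override must have the form NAME=VALUE, got {pair!r}")
        out[name.strip()] = float(value)
    return out
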