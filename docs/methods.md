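# Methods

## Model structure and assumptions

The plaque is modelled as a well-mixed compartment. Ten dimensionless state
variables evolve under mass-action and saturating kinetics: modLDL lipid
`L`, HDL acceptance capacity `H`, cell counts `C` (SMCs), `S` (SDMs), `M`
(MDMs), total lipid loads `A_c`, `A_s`, `A_m` of those populations, and the
apoptotic (`A_p`) and necrotic (`N`) lipid pools. Each live cell carries at
least one unit of endogenous lipid (the scaled mass `a_0`); everything a
cell holds above that is ingested lipid, and it is the *average ingested
lipid per cell* that drives phenotype switching through Hill functions with
exponent `n` (default 4) and half-saturation loads `alpha_c` (forward,
SMC→SDM) and `alpha_s` (reverse). The reverse switch is maximal for
lipid-free SDMs and shuts off as they load.

Key structural assumptions, in the package's own terms:

* MDM recruitment is a saturating function of a weighted lipid stimulus
  `L + tau_m(A_m − M) + tau_s(A_s − S)` with half-maximum `Gamma`; SMCs
  enter once, as a seed, not continuously.
* SMCs proliferate logistically with carrying capacity `C_0` (growth-factor
  and space limitation near the endothelium); SDMs and MDMs proliferate
  linearly, so SDMs are bounded only if apoptosis outpaces proliferation
  (`beta_s > rho_s`), which validation enforces.
* SDMs neither emigrate nor offload lipid efficiently (`zeta_s < zeta_m`);
  their only exit is death, which routes their lipid into the apoptotic
  pool and onward (via secondary necrosis at rate `nu`) into the necrotic
  core.
* All dead-cell lipid is pooled: consumers do not distinguish the origin of
  apoptotic lipid.

Time is scaled by the MDM apoptosis rate (0.002/hour), so one scaled time
unit is 500 hours; cell counts by the maximal recruitment rate over that
apoptosis rate; lipid masses by the endogenous lipid of that reference
population. The dimensional table is retained for unit-facing work, and
derived entries (e.g. the SDM proliferation rate as 0.625 of the SMC rate)
are stored both resolved and as declared ratios; parameter sweeps vary one
number at a time and do not propagate ratios unless explicitly reapplied.

## Numerical choices

* **Integration.** `scipy.integrate.solve_ivp` with LSODA (the system mixes
  rates from ~0.2 to 25, mildly stiff near equilibrium), rtol 1e-9,
  atol 1e-12. The SMC seed at `t_c` is applied as an exact restart — the
  state jump (`C` and `A_c` each gain `C_init`) is never interpolated
  across.
* **Empty populations.** Per-capita ratios and switching terms are defined
  as 0 when the relevant population is 0 (the limit of the printed forms);
  the ingested-lipid argument `A/pop − 1` is clamped at 0 from below so a
  transient numerical undershoot of the endogenous floor cannot generate
  switching (an even Hill exponent would otherwise map negative loads onto
  positive rates). The recruitment stimulus is likewise clamped at 0.
* **Known edge case.** The HDL offload terms are not limited by available
  ingested lipid; an optional `guard_offload` mode clamps them so lipid
  pools cannot be driven below their endogenous floors. It is off by
  default — the unguarded form is the model as stated. The carrying
  capacity `C <= C_0` is monitored with a warning, not enforced by
  projection.
* **Steady states.** Long integration (default horizon 60 scaled units,
  ~3.4 years, chosen so baseline metrics drift < 0.1% over the final 10
  units; extended adaptively up to 480 for slowly converging parameter
  sets) until the relative slope ‖rhs‖/‖state‖ < 3e-5, then a hybrid-Newton
  polish to residual ‖rhs‖ < 1e-10. The polished root must agree with the
  integrated endpoint, which pins the solver to the branch selected by the
  seeding protocol. The slope gate is deliberately coarse — the polish, not
  the integration, delivers the final accuracy — and the solver fails
  loudly (never silently returns a drifting state), including the
  structurally unbounded case `beta_s <= rho_s` with an SDM source.
* **Reduced-model root.** The steady ingested load `k` is found by Brent
  bisection on `beta_c + delta_c k^n/(alpha_c^n + k^n) − Pi_c/k`
  (increasing minus decreasing ⇒ unique positive root) rather than by
  enumerating polynomial roots, then Newton-polished on the degree-(n+1)
  polynomial with a machine-scale residual check. For `n = 1` the quadratic
  closed form is used as an independent cross-check in tests.
* **Stability.** Jacobians are coded symbolically from the model equations;
  at the extinction state the closed-form eigenvalues
  {ρ_c − β_c − δ_c h(Π_c/ρ_c), −ρ_c, ρ_s − β_s} are compared against the
  numerical spectrum (disagreement beyond 1e-8 is an error). Branch scans
  refine exchange-of-stability points by bisection on the physicality
  margin ρ_c − Π_c/k to 1e-8; saturated-uptake limits are evaluated at
  Π_c = 1e6 and compared to their analytic limits at 1e-3 relative.
* **Critical switching rates.** The loss-of-positivity point solves
  `delta_c* = (rho_c − beta_c)(alpha_c^n + k^n)/k^n` at `k = Pi_c/rho_c`,
  cross-checked by bisection; the SDM-maximising `delta_c` uses bounded
  scalar minimisation with an interior-peak (unimodality) check in tests.
  With the reference uptake Π_c = 3 these give 6318.7 and 221.6; both are
  reported at full precision rather than rounded to ~6350 / ~220.

## Sensitivity screen

Latin hypercube sampling (`scipy.stats.qmc.LatinHypercube`, seeded) places
one sample per equal-probability stratum per dimension; marginals are
uniform on ±20% of baseline (the conventional choice when only a variation
fraction is specified). All kinetic dimensionless parameters are varied
(25 of them); the time scale (≡1), the seeding constants `t_c`, `C_init`,
the Hill exponent `n` and the stimulus weights `tau_m`, `tau_s` are treated
as structural and held fixed. Samples with `rho_s >= beta_s` are excluded
after sampling rather than resampled — they correspond to structurally
unbounded SDM growth (with the reference ranges about 37% of rows). PRCC
uses the standard construction: rank-transform every column, regress each
parameter's and each output's ranks on the ranks of all remaining
parameters, and Pearson-correlate the residuals. A brute-force partial
correlation of ranks serves as the test oracle. No p-values are attached;
the screen is a ranking tool, not an inference procedure.

At baseline the screen shows the MDM emigration and proliferation rates
(`gamma`, `rho_m`) dominating the MDM count, the SDM proliferation and
apoptosis rates (`rho_s`, `beta_s`) dominating the SDM count (and, through
the SDM death route, the dead-cell lipid pools), and — among the switching
parameters — the forward half-saturation load `alpha_c` with the strongest
hold on intracellular lipids. The SMC count is additionally (and
structurally) controlled by its carrying capacity `C_0`.

## What the default scenarios do and do not show

The package's experiments are *in silico* contrasts on one calibrated
parameter set: MDM-only vs seeded plaques, switching disabled (`delta_c=0`)
vs baseline, and one-at-a-time sweeps. They characterise the model, not any
particular patient or mouse: real plaques have spatial structure, lipid-load
distributions within cell populations (here collapsed to averages), and
parameter uncertainty that the ±20% screen only brackets. Passing tests
show the implementation reproduces the model's stated mathematics and its
qualitative biology (SDM dominance, necrotic-core growth under switching),
not that the model is predictive.

## Known limitations

* The averaged-load formulation means switching responds to the population
  mean; heterogeneous loads would switch a subset of cells first.
* With `rho_s >= beta_s` the SDM population grows without bound by
  construction; the package refuses these parameters rather than adding an
  ad hoc logistic cap.
* The dimensional system is exposed only through the scaling map (states
  and time rescaled around the dimensionless core), not as a second
  independent right-hand side.
* Steady-state uniqueness is not proven; the solver reports the attractor
  reached by the seeding protocol, which is the scientifically relevant
  branch here.
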