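# Methods

This note documents the model equations as implemented, the numerical
choices, the synthetic-data generators, and the design decisions that
were genuinely open. Units are strict SI internally (Pa, m, s,
mol m⁻³; note 1 mM ≡ 1 mol m⁻³); literature-style units (mmHg, µl min⁻¹,
mM, µm) appear only in parameter files marked `units: table` and are
converted at the I/O boundary (1 mmHg = 133.322 Pa,
1 µl min⁻¹ = 1.6667×10⁻¹¹ m³ s⁻¹).

## Model and assumptions

The domain is a 1-D "slice" through the posterior eye wall exterior to
the retinal pigment epithelium (RPE): choroid on `[0, L_C]`, sclera on
`[L_C, L_C+L_S]`, with the suprachoroidal space (SCS) treated as the
interface surface (no volume, no separate concentration). The model is
steady: myopigenic signalling evolves over days while protein transport
across the sclera equilibrates in hours. Antero-posterior and azimuthal
variation, intracellular carriers (CRABP2), signalling interior to the
RPE, and transient feeding dynamics are all outside scope.

**Fluid.** Both layers are rigid porous media (Darcy). The sclera has no
sources (`p″ = 0`, pressure exactly affine); the choroid exchanges fluid
with the choriocapillaris by Starling filtration with a single lumped
capillary pool at pressure `IOP + ΔP_blood`. The capillary surface
density is the smoothed step `a(x)` of sharpness Γ (default 100) and
plateau `1/α`, normalized so `∫a dx ≈ L_C`. A single effective osmotic
species is used — the albumin pool `c₂+c₃` with reflection coefficient
σ = 1 — because albumin dominates the transmural oncotic difference and
both transported species are albumin. Boundary conditions: imposed RPE
pumping velocity at `x = 0`; pressure continuity and a velocity jump
`Q_u/A_S` at the interface (unconventional outflow entering via the
SCS); orbital pressure at the outer scleral surface. The Goldmann
balance `Q_u = Q_prod − C(IOP − EVP)` and the SCS anchor
`p(L_C) = IOP − ΔP_SCS` close the system and *determine* IOP.

**Solutes.** Free albumin and the atRA:SA complex obey steady
advection–diffusion–reaction per layer. In the choroid, synthesis
converts SA to complex at `k_prod·a(x)` (the binding equilibrium
eliminates free atRA exactly, since `r₁ = 0` at steady state and atRA is
untransportable unless carried), and both species exchange with blood at
`β(c_B − c)a(x)`. In the sclera the complex is consumed at
`k_CYPdeg·Ind(c₃)·c₃` with the saturating induction factor
`Ind = Ind_max(c₃/f_u)/(Ind_C50 + c₃/f_u)`, returning free SA.
Boundaries: zero total flux at the (solute-tight) RPE; concentration and
total-flux continuity at the interface — the SCS inflow is aqueous
humour and carries no albumin, so the advective jump is offset by a
diffusive-flux jump; zero gradient at the orbital surface (well-mixed
orbit).

## Numerics

* **Pressure.** Second-order central finite differences on a nonuniform
  grid; second-order one-sided stencils for the RPE flux condition and
  the interface flux matching. Because the problem is linear in
  `(p, IOP)` for a frozen albumin field, one augmented sparse system
  (field unknowns + the IOP scalar, with the SCS anchor as the extra
  row) is solved directly — no shooting. Velocities are reconstructed
  conservatively (`u = u_RPE + ∫q_C`), so the global mass balance closes
  to round-off by construction.
* **Solutes.** A conservative finite-volume scheme on the same grid with
  central face interpolation (face Péclet numbers are ≲0.05 at reference
  parameters, and the scheme remains stable well beyond Pe ~ 10 thanks
  to the diffusive face coupling); tridiagonal systems are solved with a
  banded LU. The interface cell is split at `x = L_C` so synthesis and
  exchange act only on its choroidal half and degradation only on its
  scleral half; total solute flux continuity across the velocity jump is
  automatic. The nonlinear induction sink is resolved by Picard
  iteration on the induction factor with under-relaxation 0.5 (dropping
  to 0.25 if the contraction stalls), to a relative tolerance of 1e-10.
* **Coupling.** Fluid and solute solves alternate, with `c₂+c₃` fed back
  into the Starling osmotic term, until IOP changes by <1e-6 mmHg and
  the pool profile by <1e-8 (relative). The first iterate uses a zero
  osmotic gradient (tissue pool = blood). The osmotic term is a
  first-order effect (~9 mmHg at reference concentrations), so the
  update is adaptively under-relaxed when the residual stops
  contracting, and two progressively damped restarts (relaxation 0.25,
  then 0.05) guard against overshoot into unphysical basins at extreme
  parameter combinations (needed only far from reference values, e.g.
  at sensitivity-range corners). Positivity of concentrations is
  enforced on the converged state; transient iterates may undershoot.
* **Grid.** Default 400 nodes per layer. Choroid nodes are graded so at
  least 10 nodes (typically ≳30) span the 90 %–10 % fall of the
  capillary step (width `2 ln 9 · L_C/Γ`), with the band resolution
  scaling with Γ. The interface is always an exact node. IOP is
  grid-converged to <0.001 mmHg at the default resolution and converges
  at second order (error ratio ≈ 4 per halving of h, verified in the
  tests). Quadratures (means, integrated rates) are trapezoidal on the
  solution grid, consistent with the second-order discretization.
* **Verification oracles.** (i) With `Lp* = u_RPE = 0` the pressure
  problem has a one-line closed-form IOP, matched to 1e-8 relative.
  (ii) With a sharp indicator capillary distribution the pressure is
  piecewise analytic (cosh/sinh in the capillary band, affine
  elsewhere); the solver with the smoothed step converges to this
  solution as Γ → ∞. (iii) With the induction factor saturated the
  scleral complex equation has constant coefficients and an exact
  exponential solution, matched to 0.5 %. (iv) The eFAST estimator is
  validated against the analytic Ishigami totals.

## Parameters

Three presets ship with the package (mouse control, mouse feeding,
human control); mouse feeding differs from mouse control **only** in the
blood atRA:SA concentration `c3_B` (1.25×10⁻⁶ vs 1.167×10⁻² mol m⁻³ —
the measured control serum level vs the 90-min post-feeding mean).
Parameters fall into three confidence tiers; the lowest tier
(`Lp*`, `β`, `k_prod`, `k_CYPdeg`) is fit, not measured. The interface
area `A_S` (3.2×10⁻⁵ m² mouse, 1.49×10⁻³ m² human) was fixed by
requiring the velocity balance `u_S = u_RPE + Q_u/A_S + u_CC` and the
synthesis rate `A_S·k_prod·L_C` to be mutually consistent with the
reference outputs; both checks close to <1 %. The association constant
defaults to `Ka = 2.3×10⁶ M⁻¹` with the literature range
(3.3×10⁵–2.3×10⁶) retained for the unbound-fraction bound check; `Ka`
affects only the diagnostic unbound fraction, not transport, because
the complex is the transported species.

## Calibration

The objective is a weighted sum of squared *relative* deviations
(targets span five orders of magnitude), over log₁₀-transformed
parameters (positive rates, bounds a factor 100 either side of the
start), minimized with bounded Nelder–Mead (derivative-free: the forward
model contains iterative inner solvers whose truncation noise corrupts
finite-difference gradients; from a fixed start the result is
bit-reproducible). Fitting is two-staged, exploiting the one-way
dependence of trace atRA on the fluid/albumin solution: (1) `(Lp*, β)`
against IOP, `Q_u/Q_prod` and the scleral albumin ratio; (2)
`(k_prod, k_CYPdeg)` against mean-tissue atRA:SA. A single control-case
atRA target cannot identify two rate constants, so stage 2 uses the
control *and* feeding values as a pair: under feeding, vascular leakage
dwarfs synthesis, pinning `k_CYPdeg`; the control target then pins
`k_prod`. Parameter-recovery experiments (noiseless synthetic targets,
3×-perturbed starts) recover all four parameters to <0.1 %. Human
`k_prod` and `k_CYPdeg` are shipped as given reference values (they
derive from cross-species scaling arguments that this package does not
re-derive).

## Sensitivity analysis (eFAST)

Each parameter traverses its range along a search curve
`x(s) = lo + (hi−lo)·[½ + arcsin(sin(ωs + φ))/π]`; the parameter of
interest carries `ω_max = ⌊(N−1)/(4M)⌋` (so its M harmonics respect the
Nyquist condition `N ≥ 4Mω+1`), the complement shares frequencies
`≤ ω_max/2M`. The total index is one minus the spectral power below
`ω_max/2` over the total power, averaged over `N_r` random-phase curves;
the spread gives a standard error, and an inert dummy parameter
estimates the noise floor that any reported ranking must exceed. Effect
directions use the Spearman rank correlation over pooled samples with an
|ρ| > 0.1 threshold. Defaults M = 4, N = 65, N_r = 5 (the benchmark
tests use N = 1025, where the Ishigami totals are reproduced within
0.05). Two standard analyses are wired to the transport model: the
fluid/albumin set {K_S, Lp*, β, u_RPE, ΔP_blood, ΔP_SCS} for outputs
(IOP, u_CC, u_S, ⟨c₂⟩_CS), and the atRA set adding
{k_prod, k_CYPdeg, Ind_C50, c3_B} for (⟨c₃⟩_S, orbital c₃). Ranges:
±50 % for K_S, u_RPE, Ind_C50, c3_B; ΔP_blood ∈ [3, 7] mmHg;
ΔP_SCS ∈ [0, 2] mmHg; ×[1/3, 3] for the four fitted rates. Failed
forward solves (at most a few per thousand, at range corners) are
imputed from the nearest successful sample on the same curve, with a 5 %
failure budget before aborting. Only *rankings* relative to the dummy
floor are treated as reproducible, not bar heights.

## Synthetic data

The serum generator emulates mouse serum atRA measurements: a control
cohort drawn from a positive-truncated normal (mean 1.25, SD
0.54 pmol ml⁻¹) and a fed cohort on a rise-to-plateau curve with
multiplicative log-normal noise (default CV 20 %). The rise is
Hill-shaped, anchored exactly at the measured 30-min (4.1 nmol ml⁻¹) and
90-min (11.67 nmol ml⁻¹) levels with a 12 nmol ml⁻¹ plateau; a single
saturating exponential was rejected because no time constant passes
through the 30-min point while sitting on the plateau by 90–120 min.
The generator reproduces cohort-level means and the four-orders-of-
magnitude control-vs-fed contrast, but not per-animal longitudinal
correlation or assay-specific error structure (some real cohorts have
n = 1–2); passing tests therefore validate the pipeline's statistical
plumbing, not biological variance components. `serum_to_model_input`
averages a time window and converts to mol m⁻³
(1 pmol ml⁻¹ = 10⁻⁶ mol m⁻³), which is how measured serum levels become
the blood boundary concentration `c3_B`. Target generation for
calibration runs the forward model at known parameters and optionally
perturbs each observable log-normally — the basis of the
parameter-recovery tests.

## Problem sizes used in the shipped tests and scripts

Production solves use 400 nodes per layer (IOP grid-converged to
<0.001 mmHg). Calibration and recovery experiments use 100–120 nodes per
layer and sensitivity sweeps 60–80, where IOP differs from the converged
value by <0.03 mmHg — an order of magnitude below every tolerance
asserted on those results. The acceptance script runs the three
reference cases at the production resolution.

## Known limitations

* The mean-field single-pool capillary bed (one `p_B`, one `c_B`) and
  the 1-D slice geometry suppress regional variation; outputs are
  "average location" values.
* The SCS is a surface: no suprachoroidal volume, pressure dynamics or
  separate concentration.
* CYP26 enzyme abundance is slaved to the local complex concentration
  (steady induced level); no explicit enzyme state, transport or
  induction kinetics.
* No human-feeding scenario is defined (no preset and no calibration
  targets exist for it).
* The reported reference outputs depend on fitted rate constants known
  to three significant figures; quantities that amplify small IOP
  differences (notably `Q_u/Q_prod`, with a ~10 %-per-mmHg slope) are
  reproducible only to a few percent even though IOP itself is
  reproduced to ~0.6 %.
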