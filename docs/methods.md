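# Methods

This note documents the models behind natzkit: the governing equations and
their assumptions, the parameters that matter and their defaults, the
numerical scheme, what the synthetic-data generators do and do not emulate,
and the design choices made where the problem left the design open.

## Reaction-transport model

### Governing equations

The sediment column is one-dimensional, steady state, with depth *z* in cm
below the sediment–water interface, positive downward. Solutes (O₂, NO₃⁻,
NH₄⁺, Mn²⁺, DIC; state in μM) obey

    0 = d/dz( φ Dₛ dC/dz ) − d( φ u C )/dz + Σᵣ νᵣ Rᵣ ,

solids (TOC in wt% dry sediment, MnO₂ in μmol g⁻¹ dry sediment)

    0 = d/dz( (1−φ) ρ D_b dS/dz ) − d( (1−φ) ρ w S )/dz + Σᵣ νᵣ Rᵣ ,

with all reaction terms in μmol per cm³ of bulk sediment per year.
Assumptions built into this form:

- **Steady state.** Burial at ~2 cm/ky against a 3-m column means the
  profiles integrate ~10⁵ years of history; transient forcing is out of
  scope.
- **Porosity** follows exponential compaction,
  φ(z) = φ_∞ + (φ₀ − φ_∞)·e^(−z/λ) (defaults 0.85 → 0.75, λ = 50 cm).
- **Porewater advection** velocity *u* is set equal to the solid burial
  velocity *w* (constant-compaction simplification). At w = 2×10⁻³ cm yr⁻¹
  advection is ~10⁴ times weaker than diffusion over the column, so the
  error of this closure is negligible at gravity-core scale.
- **Tortuosity** via the Boudreau relation Dₛ = D₀/(1 − 2 ln φ), the de
  facto standard for muds. Free-solution diffusivities default to values
  near 0–2 °C seawater (O₂ 365, NO₃⁻ 318, NH₄⁺ 330, Mn²⁺ 106, DIC 186
  cm² yr⁻¹), overridable per species.
- **Bioturbation** is a constant solid-phase mixing coefficient
  D_b = 0.1 cm² yr⁻¹ in the upper z_bio = 10 cm and zero below — the
  mixed-layer depth typical of pelagic sediment. Solute irrigation is not
  modeled.

### Reaction network

Organic matter (modeled as carbon with a fixed organic N:C ratio
r_NC = 16/106) decays at first order, k_TOC (default 1.2×10⁻⁴ yr⁻¹,
refractory deep-sea material), partitioned over terminal oxidants by a
Monod/hyperbolic-inhibition cascade; secondary redox reactions are
bimolecular:

| rate | expression | basis |
|---|---|---|
| R1 aerobic degradation | k_TOC·C_TOC·[O₂]/(K_O₂+[O₂]) | mol C |
| R2 denitrification | k_TOC·C_TOC·f(NO₃)·inh(O₂) | mol C |
| R3 MnO₂ reduction | k_TOC·C_TOC·f(MnO₂)·inh(O₂)·inh(NO₃) | mol C |
| R4 nitrification | k_nit·[O₂]·[NH₄⁺] | mol NH₄⁺ |
| R5 Mn²⁺ oxidation | k_mnox·[O₂]·[Mn²⁺] | mol Mn²⁺ |
| R6 anammox | k_amx·[NH₄⁺]·[NO₃⁻]·inh(O₂) | mol NH₄⁺ |

Half-saturation/inhibition constants default to K_O₂ = 20 μM, K_NO₃ =
10 μM, K_MnO₂ = 40 μmol g⁻¹, K_in,O₂ = K_in,NO₃ = 10 μM; bimolecular
constants k_nit = k_mnox = 0.5 μM⁻¹ yr⁻¹. Every constant is configuration-
exposed so alternative calibrations can be dropped in verbatim.

**Anammox oxidant.** Porewater nitrite is typically undetectable in these
systems, so the transport model uses the electron-balanced overall reaction
5 NH₄⁺ + 3 NO₃⁻ → 4 N₂ + 9 H₂O + 2 H⁺ with nitrite as an implicit
intermediate supplied by nitrate reducers; the canonical
NH₄⁺ + NO₂⁻ → N₂ + 2 H₂O form is retained for thermodynamics. Both are
available from `anammox_stoichiometry`.

**k_amx = 0.01 μM⁻¹ yr⁻¹ (10⁴ M⁻¹ yr⁻¹).** This sits at the low end of
published diagenetic anammox constants and places the reaction in the
kinetically controlled regime, where the NO₃⁻/NH₄⁺ overlap width carries
information about the rate constant. At much larger k the overlap is
diffusion-limited and the profiles become insensitive to k_amx — the
constant is then statistically unidentifiable from concentration data at
any realistic noise level, which would defeat the package's
parameter-recovery tests.

The stoichiometry matrix carries implicit N₂ and organic-N rows; nitrogen
and manganese conservation of every reaction column is asserted at network
construction.

### Boundary conditions

Any species can take a fixed concentration, fixed flux, or zero gradient at
either edge (solids: flux only at the top). The reference configuration
uses bottom-water values at the interface (O₂ 300, NO₃⁻ 15, NH₄⁺ 0, Mn²⁺ 0,
DIC 2200 μM), deposition fluxes for the solids (TOC 2.8, MnO₂ 0.03
μmol cm⁻² yr⁻¹), a fixed deep ammonium source (80 μM at 3 m, standing in
for deeper ammonification), and zero gradient elsewhere.

### Discretization and solver

Uniform finite-volume grid; cell residuals are face-flux imbalances plus
integrated sources, in μmol cm⁻² yr⁻¹. Numerical choices, each of which
was forced by a measurable failure of the simpler alternative:

- **Central face values** for advection (the burial Péclet and per-cell
  decay numbers are ≪ 1, so this is stable). First-order upwinding leaves
  an O(Δz) error that shifts the entire redox structure by several cm per
  grid doubling.
- **Upwind only at mixing-discontinuity faces.** At the base of the
  bioturbated layer the solid profile is kinked (flux continuity forces
  S′ → 0 on the mixed side), so the upstream cell value is the
  second-order-accurate face value there and the centered mean is not.
  The face at the discontinuity itself carries no mixing flux.
- **Quadratic one-sided gradients** at fixed-concentration boundaries
  (through the boundary value and two nearest cell centers); the half-cell
  two-point gradient is only first-order accurate in the boundary flux.
- **Grid alignment.** The default core grid uses 1-cm cells so that the
  10-cm mixed-layer base coincides with a cell face; otherwise the
  realized mixing depth wobbles by O(Δz) with resolution.

With these choices the scheme is second-order: it reproduces linear and
parabolic closed forms to machine precision, a cubic-solution oracle with
error ratios of 4 per grid doubling, and a piecewise-exponential closed
form across the mixed-layer discontinuity (error < 5×10⁻⁴ relative at
1-cm cells, quartering on refinement).

The nonlinear system is solved by damped Newton iteration (numerical
banded Jacobian by column coloring, bandwidth = number of species; step
halving on residual increase) with pseudo-transient continuation as
fallback (diagonal mass term, geometric time-step growth, re-entering
plain Newton when contractive). Convergence is a scaled residual norm —
per-species flux imbalance relative to the dominant face-flux magnitude —
below 10⁻¹⁰. Negative concentrations are clipped to zero between
iterations; a clip exceeding 10⁻⁶ (native units) at convergence is an
error, smaller clips are logged. The reference core converges in ~15
iterations (< 0.5 s at 300 cells).

`mass_balance_report` verifies the steady-state contract on every solution:
per-species boundary-flux difference equals the depth-integrated net
reaction (closure ~10⁻¹³ relative on the reference core), and total N
(boundary fluxes + organic-N release vs. N₂ production) balances.

## Energetics

ΔG°r at 25 °C/1 bar is the stoichiometric sum over a packaged formation-
energy table (ΔG°f, ΔH°f for NH₄⁺, NO₂⁻, NO₃⁻, dissolved N₂, H₂O, H⁺ from
standard seawater-geochemistry compilations). Temperature correction uses
the integrated van 't Hoff relation with constant reaction enthalpy;
pressure enters only through an optional user-supplied ΔV°r (default 0) —
a deliberate simplification of full Helgeson-style equations of state,
adequate over the ~0–25 °C, 1–300 bar range of interest where the T and P
corrections are small against ΔG°r ≈ −350 kJ mol⁻¹.

In-situ ΔGr = ΔG°r + RT ln Q, activities from μM concentrations via the
Davies equation at I = 0.7 mol kg⁻¹ (seawater) by default; a unit-activity
mode exists for oracle tests. Dissolved N₂ is not usually measured and
defaults to 500 μM (air-saturated deep seawater scale); H⁺ activity
defaults to pH 7.7. Concentrations at or below zero are floored at
10⁻³ μM (configurable) before entering Q. ΔGr is reported per mol NH₄⁺;
the per-mol-N variant is the per-NH₄⁺ value × 5/8 for the nitrate-coupled
reaction.

Power supply is P(z) = R₆(z)·|ΔGr(z)| (J cm⁻³ yr⁻¹; ÷3.154×10⁷ for
W cm⁻³), computed for modeled and, where supplied, measured
concentrations. Cell-specific rate divides the bulk rate by cell density
(cells g⁻¹ converted via ρ_dry(1−φ), ρ_dry = 2.5 g cm⁻³); proton pumping
converts with n_H = 4 protons per NH₄⁺ — the unique round number consistent
with both ends of the 10⁻³–10⁻¹ fmol cell⁻¹ d⁻¹ ↔ ~28–2,800 H⁺ s⁻¹
correspondence — exposed as configuration.

## Profile analysis

Quality gates: ≥ 6 data points and nitrate reaching depletion
(min NO₃⁻ < 2 μM). The 2-μM threshold for "depleted"/"detectable" is a
package convention near typical porewater detection limits, configurable
per species. NATZ boundaries are interpolated threshold crossings: NO₃⁻
scanning downward, NH₄⁺ scanning upward from the bottom of the profile
(the crossing nearest the zone). The interval is the ordered pair of the
two depths; zero thickness is legitimate.

Diffusive fluxes use a least-squares gradient over the 3 samples nearest
the zone edge on the stated side (3 is the minimum leaving a regression
residual; configurable), J = −φ Dₛ dC/dz, positive downward. Ammonium
efflux is classified by detection — any NH₄⁺ above threshold at or above
the zone top — rather than by an upper-zone gradient, because compiled
literature profiles are usually too sparse for a reliable gradient; the
inclusive boundary makes a zone whose detectable ammonium reaches the
seafloor count as efflux. Sites with no samples at or above the zone top
are reported indeterminate.

## Replication index

Windows default to 5 kb every 100 bp. Window coverages are
log₂-transformed, sorted descending, the top and bottom 5 % discarded
(robustness to mapping artifacts), and regressed against rank fraction.
The rank-fraction axis stays relative to the *untrimmed* sorted set;
rescaling the trimmed set to [0, 1] would shrink every slope by
(1 − 2·trim) and bias iRep low by a factor 2^(0.1·|slope|). No GC
correction is applied. iRep is reported raw; the two-copy interpretation
(fraction = iRep − 1) is a separate function so other replication models
can be substituted.

## Synthetic-data generators

All randomness flows through one `numpy` Generator per call, seeded
explicitly; identical seeds give identical outputs. Every generator
returns its truth object, and recovery tests compare against emitted
truth only.

- **Cores** are forward-model runs sampled at cruise-style depths (5-cm
  spacing over the upper 50 cm, 25-cm below) with independent Gaussian
  noise (default σ = 1 μM, clipped at zero). The default core develops an
  oxic zone depleted near 0.7 m, nitrate depletion near 1.4 m, Mn²⁺
  accumulation below the oxic zone, and a deep ammonium source — the
  qualitative structure of pelagic ridge-flank cores.
- **Abundance profiles** are log₁₀-scale Gaussian bumps (width 30 cm)
  centered in the NATZ: background 10² cells g⁻¹ (a qPCR detection-floor
  scale), peak 10⁶ — a four-order increase — with multiplicative lognormal
  noise of 0.1 log₁₀ units. The width resolves the peak at 25-cm sample
  spacing; the noise level keeps the realized max/min ratio within half a
  decade of the generating ratio.
- **Site collections** use piecewise-linear NO₃⁻/NH₄⁺ templates with
  log-uniform depletion depths over 1.3–460 cm (the observed global NATZ
  depth range) rather than full forward-model runs, for speed; efflux
  sites carry a detectable ammonium tail above the zone, no-efflux sites
  are clamped below the detection threshold there so the generating label
  is exact. A configurable fraction of sites gets only 5 points to
  exercise the quality gate.
- **Coverage tracks** draw per-base expected depth log-linear from origin
  (position 0) bidirectionally to the terminus (mid-genome), cut into
  contiguous scaffolds and windowed. Poisson noise is applied per base —
  the counting noise of independent read sampling, which overlapping 5-kb
  windows then average. Drawing independent Poisson noise per *window*
  would be wrong by the window/step ratio (~50×) and swamps the trend at
  realistic depths.
- **k_amx recovery** re-solves the forward model inside a bounded 1-D
  search over log₁₀ k_amx against the summed NO₃⁻ + NH₄⁺ misfit. The
  recovery study samples every 5 cm: at cruise-style 25-cm spacing in the
  zone, the Fisher information at σ = 2 μM bounds the achievable precision
  near a factor of two, so sparse-grid recovery to 25 % is not possible
  for any rate constant.

**What passing tests do not show.** The generators emulate the *structure*
of real data, not its full error budget: no systematic offsets between
cores, no porosity/temperature measurement error, no compositionality or
copy-number bias in abundance proxies, no mapping bias or GC structure in
coverage. Recovery results therefore demonstrate correctness of the
estimators under their stated noise models, not field accuracy on cruise
data.

## Known limitations

- No transient simulation; no S/CH₄/Fe chemistry, pH/alkalinity
  speciation, or bioirrigation; microbial biomass is not coupled into the
  reaction-transport model.
- Thermodynamics use a fixed constants table and van 't Hoff scaling, not
  a full speciation engine; pressure effects require a user ΔV°r.
- The rate-law forms and constants are standard diagenetic closures, not a
  site-specific calibration; `fit_k_amx` is the only built-in calibration
  and sweeps a single constant.
- iRep here implements the coverage-sorting slope estimate with symmetric
  trimming only — no GC correction or fragment-filtering heuristics — and
  its value cannot be converted to a growth rate: it is a snapshot of the
  replicating fraction with no time dimension.
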