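# Methods

This note documents the models, numerical choices and limitations of
`lagcomp` at the level a user needs to interpret its output.

## Compartment transport

The liquid phase is a network of `Nc = Nax·Nr·Nθ` well-mixed compartments
obtained by binning a structured cylindrical grid along its coordinate
planes. Divisions must divide the grid counts evenly: compartment
interfaces then coincide with grid planes, no cell straddles two
compartments, and interfaces are geometrically smooth (rugged interfaces
are known to overestimate aggregated fluxes).

Two matrices (kg/s) carry the inter-compartment exchange:

* **Convective** Φc: each interface grid-face contributes its unsigned
  mass flux to the entry of its actual flow direction, so φc,ij ≠ φc,ji
  in general. For a discretely divergence-free input field, each
  compartment's inflow equals its outflow (rows of Φc sum to zero).
* **Turbulent** Φt: per face `ρ·A_face·√(2k_t/3)` — interface area times
  the isotropic RMS velocity fluctuation — credited equally in both
  directions. Φt is accumulated once per unordered compartment pair and
  mirrored, so its symmetry is exact in floating point, not just to
  round-off.

Diagonals hold minus the total outflow, which makes every column of
Φ = Φc + Φt sum to zero identically; the transport operator
`(Φ·Cs)/M` therefore conserves total substrate to machine precision.
Everything is on a mass basis (constant broth density ρ = 1000 kg/m³
folded in): compartment size is broth mass M_i = ρV_i, and the residence
time is τ_i = M_i/|φ_ii| with the *combined* outflow in the denominator.
Destination probabilities for parcel jumps are likewise drawn from the
combined matrix, and destination tables are ordered by ascending
compartment index so that stochastic runs are reproducible bit-for-bit.

## Synthetic flow fields

The compartmentizer consumes cell volumes, signed face fluxes and face
turbulent kinetic energy. The bundled generator produces these on a
uniform cylindrical grid from a *discrete streamfunction evaluated on
grid nodes*: the flux through a face is a difference of nodal values, so
the signed flux sum around every cell telescopes to zero exactly — mass
closure by construction, not by iterative correction. A sine envelope
pins the streamfunction to zero on the boundary (zero wall-normal flow);
Gaussian bumps add circulation loops. The default topology is two
counter-rotating loops per Rushton impeller (four for the default
two-impeller tank), each with strength taken from the impeller pumping
capacity `Q = Fl·N·D³` with Fl = 0.75. Azimuthal transport, when the
grid has more than one θ-sector, is a θ-uniform solid-body swirl and
hence individually divergence-free.

Turbulent kinetic energy is a positive background plus Gaussian peaks at
each impeller plane near the blade-tip radius, scaled from the squared
tip speed (defaults: peak 1.2 % and background 0.012 % of v_tip²,
giving k ≈ 0.5 m²/s² at the impellers of the default tank). These
magnitudes are configuration knobs chosen to give a plausible
convective-to-turbulent flux ratio; the generator claims the right
*structure* (loops, peaks, exact closure), not hydrodynamic fidelity to
any particular vessel. Consequences for testing: properties that depend
on exact conservation, Markov transport, or Euler–Lagrange consistency
transfer to real flux matrices unchanged, while absolute mixing times and
gradient magnitudes do not — with the default field the 54 m³ tank at
layout A26R6T1 mixes in ≈ 137 s (CoM criterion), a plausible but not
calibrated value.

## Parcel jumps

Within a step Δt a parcel escapes compartment *i* with probability
`P_jump = 1 − e^(−Δt/τ_i)` (ideal mixing ⇒ exponential residence) and,
conditional on jumping, selects the first destination whose cumulative
probability covers the jump quantifier `Q = (P_jump − ψ)/P_jump`, which
is uniform on (0, 1]; a single uniform deviate ψ per parcel per step
serves both decisions. At most one jump per parcel per step is allowed.
This discretization biases residence times *long* by roughly Δt/2 and
shifts the stationary occupation of the discrete chain away from the
mass-proportional law by O(Δt/τ); both effects vanish as Δt → 0 and are
asserted in the test suite. The mitigation is the step cap Δt_max, not
multi-jump chaining. Parcels carry no sub-compartment position and no
inertia (micron-scale cells, negligible Stokes number).

## Kinetics

Units: Cs in mol per kg broth, qs in mol/gdw/s internally (constructors
accept mmol/gdw/h), pools in µmol per g biomass with rates per second.
Rate laws evaluate at `max(Cs, 0)`; the ODE state itself is never
clipped, preserving the integrator's error estimate near washout where
Cs ~ Ks ~ µmol/kg.

* **Black-box**: Monod uptake with fixed biomass, either as a
  homogeneous Eulerian field (`Rs,i = Cx·qs(Cs,i)`) or localized to
  parcels (`Rs,i = Σ_p qs,p·Cx,p / M_i`). At matched total biomass the
  two coincide as Np → ∞.
* **Structured**: metabolic pools follow `dX/dt = S·r − µX`; enzymatic
  pools follow zero-order synthesis, first-order turnover and growth
  dilution. Uptake is transporter-proportional Monod,
  `qs = k11·XE11·Cs/(Ks+Cs)`, so uptake capacity adapts on the enzyme's
  expression timescale — the qualitative difference from black-box
  kinetics in a fluctuating environment.

The shipped `DemoPoolModel` is a synthetic eight-pool stand-in (fast
glycolytic pool, amino acids feeding a Michaelis–Menten product
synthesis, biosynthetic precursors driving growth, storage, and four
enzymes including the transporter). Its constants are set to realistic
orders of magnitude for a slow-growing glucose-limited fungal process:
pool turnover from ~30 s (glycolytic) to hours (storage, enzymes), and
µ ≈ 0.01–0.03 h⁻¹ at chemostat conditions. The cellular energy state is
an algebraic factor on growth rather than an explicit ATP pool, removing
the stiffest timescale. All drains are proportional to their own pool, so
trajectories from non-negative states stay non-negative. The model's job
is to exercise the coupling machinery — its parameters are config, not
biology; a literature model plugs in through the same contract
(`npool`, pool classes, `uptake`, `reaction_rates`, `growth_rate`,
`pool_rhs`, stoichiometry).

Protocol closures: **chemostat** fixes Cx and the transporter pool and
feeds at a constant rate (steady state when uptake balances feed; for a
single mixed compartment the steady substrate level inverts in closed
form to `Cs* = Ks·α/(1−α)`, α = F_molar/(Cx·qs,max) — the package's main
analytic oracle). **Fed-batch** grows per-parcel biomass at the parcel's
own µ under an imposed feed profile, sampled and held every 30 s, at
fixed liquid volume; tank biomass is reported as ΣCx,p/(ρV_T).

## Time integration

One embedded Bogacki–Shampine 3(2) Runge–Kutta pair advances the joint
state (Nc liquid concentrations, Np·Npool pools, per-parcel biomass in
fed-batch, plus two quadrature states for cumulative feed and uptake).
Error control: RMS of the component-wise error against
`abs_tol + rel_tol·|y|` (defaults 1e-9 and 1e-3), accept at ≤ 1, step
factor `0.9·err^(−1/3)` clipped to [0.2, 5], capped at Δt_max. Parcels
jump once per *accepted* step over that step's actual size; rejected
steps consume no random numbers, so the stochastic stream is independent
of the rejection history and runs are deterministic given (seed, config,
model). Because jumps change the right-hand side, the first-same-as-last
property of the pair is not exploited — the derivative is re-evaluated
after each accepted step. The Lagrangian reaction source is piecewise
constant in the parcel *assignments* between jump passes but fully
continuous in the concentrations, which the error estimator sees. No
special event handling is applied at jump discontinuities; the adaptive
controller keeps steps small enough in practice.

The cumulative feed/uptake quadrature states close the global substrate
balance `(ΔCs stock) = feed − uptake` to round-off (< 1e-12 relative in
the shipped runs); this audit is reported with every reactive run.

Two numerical cautions are documented rather than hidden: (i) with an
explicit pair, step caps well above the kinetic relaxation time put the
solver at its stability boundary and the steady state wobbles at the
tolerance level — the chemostat oracle runs use Δt_max ≤ 1 s for the
~0.6 s Monod relaxation; (ii) mixing runs default to Δt_max = 0.01 s,
reactive runs to 0.03 s.

## Mixing and lifeline analysis

The probe mixing time is the *last* exit of the normalized probe signal
from [0.95, 1.05] (linearly interpolated at the crossing); the volumetric
mixing time is the first sustained drop of the coefficient of mixing
(volume-weighted coefficient of variation) below 0.0283. A parcel-based
CoM uses `Cp,i = Np,i/V_i` in place of the tracer. Counting statistics
floor the parcel CoM at ≈ √((Nc−1)/Np) for mass-proportional occupation,
so small populations never reach the threshold — the result is flagged,
not an error. When tracer and parcel curves are compared, the package
uses the curve-level relative L2 error over the pre-threshold window
(‖CoM_p − CoM_t‖₂/‖CoM_t‖₂): a pointwise-relative metric would be
dominated by the statistical floor just above the threshold and would
not converge for any finite Np.

Lifelines sample each tracked parcel's uptake saturation qs/qs,max on a
uniform grid (default 0.06 s) via cubic-Hermite dense output inside each
accepted step, using the parcel assignment in force during that step.
Classification: Excess above 0.95, Starvation below 0.05, Limitation
between (strict inequalities; the boundary value is Limitation). Two
filters precede statistics: a centered moving average spanning 0.36 s
(7 samples at the default rate; shrinking windows at the edges) and a
fuzzy threshold band of ±0.01 implemented as hysteresis — entering
Excess requires crossing 0.96, leaving it 0.94, mirrored for Starvation.
Hysteresis was chosen over dead-band averaging because it is stateful,
cheap, and provably visit-removing: a filtered Excess visit requires a
raw sample above the threshold, so filtering never invents visits. Visit
durations are keyed by transition pattern (previous regime + regime +
next regime); visits truncated by the series ends are discarded. Regime
fractions are time-in-regime percentages over windows (default 1800 s)
with the across-window spread reported as ±2 SD. Population
heterogeneity is summarized as across-parcel histograms and standard
deviations of selected pools at a chosen time.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline at
desk-scale sizes chosen to make every stochastic assertion comfortably
significant: the 52×12×1 synthetic grid with layouts A26R6T1 (156
compartments) and A13R3T1; 10⁴ parcels for the escape-time law
(Δt = τ/100), 10⁵ for destination frequencies and stationarity, 10²–10⁵
for mixing equivalence; 160–400 s of flow time for mixing and gradient
runs with time averages over the second half; 20–400 parcels for the
structured and audit runs. Statistical gates use fixed seeds and
standard tests (Kolmogorov–Smirnov, chi-square, total variation against
a brute-force stationary eigenvector at 3× the multinomial standard
error). The finite-Np bias comparison averages over a three-seed set
because single-seed gaps at adjacent Np overlap.

## Known limitations

No gas phase, oxygen, CO₂, pH or heat; single substrate (glucose);
Newtonian single-phase broth at constant density; fixed liquid volume
even in fed-batch; no parcel division or death; geometric
compartmentalization only (though externally generated flux matrices
load from text files); the synthetic flow field is structurally, not
hydrodynamically, realistic; and the demonstration pool model is a
framework exerciser, not a validated strain model.
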