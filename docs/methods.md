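# Methods

## The model

The package treats dynamical systems whose trajectories are (i) infinitely
numerous, (ii) individually fractal with critical fractal dimension 2, and
(iii) locally irreversible. Elementary displacements along such paths are
dX± = υ± dt + ζ √(2𝒟) |dt|^{1/2} with ⟨ζ⟩ = 0, ⟨ζ²⟩ = 1; the two-valued
velocity pair (υ₊, υ₋) combines into the complex field 𝒱 = V − iU, and the
covariant derivative d̂/dt = ∂/∂t + 𝒱·∇ − i𝒟Δ turns Newton's equation
m d̂𝒱/dt = −∇φ into a Schrödinger equation for ψ = √P e^{iθ} with
V = 2𝒟∇θ. The macroquantum constant 𝒟 (length²/time) is a property of the
system, not a universal constant; the action constant is S₀ = 2m𝒟 and the
generalized Compton relation is λ_C = 2𝒟/c. The engine is unit-agnostic: a
run declares consistent units and 𝒟, m are never defaulted. Internally the
equation is used multiplied through by 2m,

    i S₀ ∂ψ/∂t = −(S₀²/2m) Δψ + φ ψ + 2mβ|ψ|² ψ,

so that with S₀ = ℏ every reported energy equals the textbook value (the
"ℏ-reduction" checks are literal), and the barotropic-fluid pressure term
appears as the Ginzburg–Landau nonlinearity β = c_s²/2ρ₀ ≥ 0.

## Discretization and numerical choices

**Grids.** Uniform grids in 1–3 dimensions. `box` boundaries are Dirichlet
walls at 0 and the extent with n interior nodes ((n+1)·spacing = extent,
so the box eigenvalues 2m𝒟²π²k²/a² are exact in the continuum limit);
`periodic` wraps the stencil with n·spacing = extent.

**Stationary states.** Second-order central Laplacian; dense tridiagonal
eigensolve in 1D, shift-inverted sparse Lanczos in 2D/3D (shift just below
min φ). The discrete Hamiltonian is symmetric by construction. Eigenvalue
errors fall by ≈ 4× per grid doubling (verified); grids of 1200–1500 nodes
put the first few levels of the benchmark problems below 1e-4 relative.

**Time evolution.** Implicit-midpoint (Crank–Nicolson), one sparse LU
factorization reused across steps; unconditionally stable and unitary for
the linear flow, norm drift < 1e-10 per 10³ steps. The nonlinear β term is
an exact local phase rotation applied for dt/2 before and after each linear
step (Strang splitting), so real β conserves the norm exactly. A warning is
issued when dt exceeds spacing²/(2𝒟) (accuracy, not stability).

**Quantum potentials.** Q = −2m𝒟² Δ√P/√P and the log form
−m𝒟²(ΔlnP + ½(∇lnP)²) are evaluated with the grid Laplacian; densities are
floored at 1e-12 of their maximum and cells whose finite-difference stencil
touches a floored cell are masked (NaN) — the continuum formulas are
singular on the zero set of P, and those "walls" are physical boundaries,
not numerical artifacts. For bulk densities observed through a finite
window (the dopant model), the Laplacian extrapolates linearly past the
edge instead of assuming Dirichlet walls; otherwise a uniform density would
show spurious wall spikes.

**Phase reconstruction (hydro/diffusive → wave).** θ is integrated along a
spanning tree from the origin with trapezoid edge integrals; every
elementary plaquette circulation of V/2𝒟 is checked (default tolerance
1e-6 rad) and a violation raises a representation error — only potential
flows admit a single-valued wave function. Velocities *extracted* from a
wave field by central differences carry O(dx²) circulation, so round-trip
tests on coarse grids pass a correspondingly looser loop tolerance. The
diffusive reconstruction ψ = P^{(1−i)/2} e^{iθ₊} is computed by
decomposing θ₊ = θ + ln√P analytically and integrating only the smooth
velocity V = υ₊ − 𝒟∇lnP, so nodes do not contaminate the phase. (P, υ₊)
cannot carry the sign of ψ across a zero — both are even around a simple
node — so for essentially-real reconstructions in 1D the C¹-continuity
convention (sign alternates at each interior zero, detected as ≥ 5 e-fold
dips of lnP) is applied. Without a convention the first excited state
would be reconstructed with aligned lobes.

**Hydrodynamic evolution.** `evolve_hydro` integrates continuity + Euler
with the quantum force by a Lagrangian quantum-trajectory scheme (1D):
markers carry (x, V, lnP) through dx/dt = V, dV/dt = −∂(φ+Q)/∂x/m,
dlnP/dt = −∂V/∂x, with spatial derivatives from sliding local quadratic
least squares (window 7 of 33 markers spanning the region within 9 e-folds
of the density maximum). The choice is deliberate: Eulerian
finite-difference integration of the Madelung equations is linearly
unstable in the density tails — relative perturbations of lnP amplify at a
rate ∝ 𝒟·k·|∇lnP|, which for a Gaussian tail exceeds any practical
dissipation over a trap period — whereas the Lagrangian form with
least-squares derivatives is exact for Gaussian states (all fields
polynomial) and filters sub-window noise by construction. Marker crossing
(a caustic, where the potential-flow description genuinely fails) raises a
diagnostic error. The measured density L² error against the wave evolution
is ≈ 6e-5 over one full trap period. Limitations: 1D, single-domain
(nodeless) densities, and the region more than `depth_cap` e-folds below
the density maximum (default 9, i.e. P < 1.2e-4·max) is truncated —
acceptable because it carries ≈ 1e-4 of the L² norm. `quantum_sign=-1`
integrates the same equations with the diffusion potential −Q.

**Fokker–Planck evolution.** RK4 with central differences; the diffusion
term is written div(𝒟∇P) with the same divergence stencil as the drift
flux, so the equilibrium identity div(Pυ₊) = 𝒟ΔP with υ₊ = 𝒟∇P/P holds
exactly on the grid. The backward equation is only ever integrated in
paired mode with υ₋ slaved to υ₊ − 2𝒟∇lnP on the current density, because
it cannot found a classical process on its own. Gibbs entropy −∫P lnP dV
is checked for monotone increase only: for free Gaussian diffusion it grows
logarithmically, not linearly, in time.

**Residual diagnostics.** The two-fluid and geodesic equation residuals use
central differences in space and midpoint differencing in time along the
actual Crank–Nicolson evolution (the backward step obtained by conjugation).
They are reported relative to the largest constituent term, with the
denominator floored at m·v_rms²/L so that exact free solutions (all terms
zero) report a machine-level number instead of 0/0. Node regions are
excluded from the norms (default mask 1e-5 of max density; the residuals
converge at second order, and 1200-point grids put the coherent-state
two-fluid residuals below 1e-3).

**Node and peak counting.** The global phase is removed and a state whose
profile cannot be made real within 1e-6 of its amplitude is rejected; values
below 1e-6 of the maximum are treated as zero. Peaks require prominence
≥ 0.1 of the global maximum (1D: prominence-filtered search with the edges
padded; 2D/3D: connected components of the super-level set containing a
local maximum).

## Scale laws

The first-order scale ODE dL/dln ε = a + bL is related to the fractal
length L = L₀(1 + (λ/ε)^τ) by a = τL₀, b = −τ (checked by an ODE-residual
property test). The scale-oscillator law is implemented on its interior
branch (ε < λ₁ < λ₀); resolutions inside the forbidden band raise a typed
error rather than returning complex values — the wall is a hard domain
boundary. One point of record: at ε = 10⁻⁶λ₀ with λ₁ = λ₀/10 the ratio of
the oscillator law to the scale-invariant asymptote is exactly
√(1 − 1/36) ≈ 0.986, i.e. a 1.4% deviation; the tests assert this exact
value and the monotone approach to 1, reaching 1% agreement only some eight
decades below λ₀. The cell-wall profile is piecewise: inner plateau 1+τ₀,
the diverging oscillator slope 1 + τ₀u/√(u²−u₁²) up to the wall, constant
outside; the plateau radius is a configuration choice (default λ₁/20).

**Log-periodic fitting** is two-stage because the likelihood is multimodal
in ω: on a grid of candidate frequencies (default 200 points on [1, 15])
the remaining parameters are profiled linearly in the
(ln a, ν, b·cos, b·sin) parametrization of ln L — exact to first order in
b — and the best grid point seeds a full nonlinear least-squares refinement
of the exact model, which reduces noiseless series to machine-level
residuals. Significance of the ω peak: the residuals of the pure power-law
fit are permuted (200 shuffles by default, seeded) and the relative
sum-of-squares gain of the best oscillatory fit is compared with its
permutation distribution. Fits require ≥ 8 samples spanning ≥ 1 decade.

## Synthetic data

The generators produce Gaussian densities (normalized on the grid), smooth
random potentials (low-pass-filtered white noise, seeded), log-periodic
event series with multiplicative log-normal noise (defaults ν = 0.5,
b = 0.3, ω = 6, 1% noise, 50 samples per series — the regime in which the
fitter's recovery is asserted), solid-body vortex velocity fields (the
canonical non-potential flow that the wave reconstruction must reject) and
Gaussian-dip dopant densities. They emulate the *mathematical* structure of
the inputs — smoothness, positivity, known ground truth — not the
messiness of real measurements: no outliers, no irregular sampling, no
correlated noise, no model misspecification. Passing tests therefore show
that the algorithms recover what they are designed to recover under their
stated assumptions, not that real chronologies or flow data satisfy those
assumptions. A single seed threads every stochastic component through
deterministic substreams.

## Study conditions and problem sizes

Benchmarks run with 𝒟 = 1/2, m = 1 (S₀ = 1) unless a formula's printed
values dictate otherwise. The worked-example constants are the printed
laboratory/observational numbers: σ_a = 87 m/s², L = 0.071 m, T_L = 39 ms
and a₀ = 4.5 (DNS) vs 6.2 (experiment) for the R_λ = 690 von Kármán flow;
p = 0.155 = 1/6.5, 4 defects/8 charges and d_CuO = 3.9 Å for the cuprate;
0.5 Å and 30 m as the biological extreme scales. The K41 ensemble uses 30
paths × 4000 steps (1.2×10⁵ samples) with lags spanning two decades;
log-periodic recovery uses 20 independent seeded series; Madelung and
diffusion-reversal equivalences use 512–640-node grids with 4000–4500 RK4
steps. These sizes make every check converge comfortably within its stated
tolerance while keeping the full suite around half a minute.

## Known limitations

* Hydrodynamic evolution is 1D and restricted to nodeless potential flows;
  2D/3D transforms and potentials are supported, but not 2D/3D hydro time
  integration.
* The flower model's "tension" force is a constant-magnitude transverse
  acceleration integrated to quadratic curves, and the petal count k is an
  input; the azimuthal quantization mechanism itself is not modelled, nor
  is the gravity/tension opening sequence.
* The duplication transition path is the normalized interpolation
  cos(πs/2)ψ₀ + sin(πs/2)ψ₁ — illustrative, since only its endpoints are
  stationary; the testable content is endpoint stationarity, intermediate
  transience and the 1 → 2 peak jump.
* Only the β|ψ|² nonlinearity is implemented; no magnetic/vector-potential
  terms, no spin, and no Navier–Stokes solver (the turbulence layer
  implements the correction terms and path statistics, not a CFD code).
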