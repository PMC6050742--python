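# Methods

## Model

A single osteon is modelled as a hollow cylinder `a ≤ r ≤ b` of `n`
homogeneous, perfectly bonded, transversely isotropic Biot-poroelastic
lamellae (symmetry axis `z`), with solid and fluid phases compressible and
fluid flow restricted to the radial direction of the lacunar–canalicular
network. The central Haversian canal is not a distinct fluid domain; its
wall is the drained inner boundary. Loading is a prescribed harmonic axial
strain `ε_z(t) = ε_z0 e^{iωt}` applied through rigid impermeable platens,
so every field is a complex amplitude times `e^{iωt}` and the problem is a
two-point boundary-value problem in `r`.

Constitutive law (drained skeleton + pore pressure):

    σ_rr = M₁₁ ε_rr + M₁₂ ε_θθ + M₁₃ ε_zz − α p
    σ_θθ = M₁₂ ε_rr + M₁₁ ε_θθ + M₁₃ ε_zz − α p

with the drained plane stiffness, `D = E_z − E_z ν_r − 2 E_r ν_z²`:

    M₁₁ = E_r (E_z − E_r ν_z²) / ((1+ν_r) D)
    M₁₂ = E_r (E_z ν_r + E_r ν_z²) / ((1+ν_r) D)
    M₁₃ = E_r E_z ν_z / D

The sign of the `E_r ν_z²` term in `M₁₂` is fixed by requiring the
isotropic limit to collapse to the Lamé constants (`M₁₂ → λ`); the
minus-sign variant sometimes seen in print fails that check.

Fluid mass balance with Biot modulus `N` and effective stress coefficients
`α` (in-plane), `α′` (axial) closes the system. Radial equilibrium and
mass balance reduce, per lamella, to

    M₁₁ d/dr (du/dr + u/r) − α dp/dr = 0
    iω [α (du/dr + u/r) + α′ ε_z0 + p/N] = (k_i/μ)(p'' + p'/r)

whose pressure solution is `p_i(r) = P_i + A_i I₀(C_i r) + B_i K₀(C_i r)`
with `C_i = sqrt(iωμ(M₁₁ + Nα²)/(k_i N M₁₁))` on the principal branch
(`Re C ≥ 0`, `arg C = π/4` exactly, since the radicand is purely
imaginary) and particular term
`P_i = −N M₁₁ (α c_i + α′ ε_z0)/(M₁₁ + N α²)`. The displacement
amplitude integrates to

    u_i(r) = (r/2) Q_i + (α/(C_i M₁₁)) [A_i I₁(C_i r) − B_i K₁(C_i r)] + s_i/r,
    Q_i = α P_i / M₁₁ + c_i,

and in the radial stress the Bessel-order-zero contributions cancel,
leaving

    σ_i(r) = (M₁₁+M₁₂) Q_i/2 − (M₁₁−M₁₂)(α/(C_i M₁₁ r))[A_i I₁ − B_i K₁]
             − (M₁₁−M₁₂) s_i/r² + M₁₃ ε_z0 − α P_i.

## Boundary conditions and closure

Per lamella there are four constants `(A_i, B_i, c_i, s_i)`. The hydraulic
conditions are drained surfaces `p(a) = p(b) = 0` (the cement line and the
canal wall are treated as fully permeable) and continuity of `p` and of
the Darcy flux `k ∂p/∂r` at every interface. The mechanical conditions
are continuity of `u_r` and `σ_rr` at every interface. That yields
`4n − 2` equations; the remaining two are the mechanical closure at the
lateral surfaces. This package uses **traction-free** surfaces,
`σ_rr(a) = σ_rr(b) = 0`, the standard hollow-cylinder osteon convention;
a confined alternative (`u_r = 0` at both surfaces) can be selected via
`assemble_system(..., closure="confined")` for sensitivity studies. The
choice affects the mean stress state but not the structure of the pressure
profile.

The hydraulic and mechanical blocks are coupled through `c_i` (the
particular pressure term contains it), so the equations cannot be solved
sequentially; all `4n` unknowns are assembled into one dense complex
system (unknown order `A₁, B₁, …, A_n, B_n, c₁…c_n, s₁…s_n`) and solved at
once.

## Numerical choices

* **Equilibration and conditioning.** At physiological parameters
  `|C r| ≈ 0.03–0.1`, where `I₀ ≈ 1` and the Bessel basis is nearly
  degenerate with the constant particular term; the coefficient matrix is
  therefore intrinsically ill-conditioned (verified in 60-digit
  arithmetic) even though the *fields* are perfectly well determined —
  near-null coefficient directions leave every sampled field value
  essentially unchanged. The solver applies two-sided diagonal
  equilibration, LU with partial pivoting, and judges the solve by its row
  residual (gate: 1e-8 relative) plus a-posteriori diagnostics: boundary
  pressure magnitude and the worst interface jump of `p`, `u`,
  `k ∂p/∂r` and `σ_rr`, all reported in `SolverReport`. Measured values
  for the benchmark cases are 1e-13…1e-10 relative to the field maxima.
* **Overflow guard.** `I₀` grows like `e^{|Cr|}`; when
  `max |C_i| b > 30` (high frequency / very low permeability), each
  lamella's `(A_i, B_i)` columns are rescaled by `1/I₀(C_i r_i⁺)` and
  `1/K₀(C_i r_i⁻)` and the scaling is undone after the solve.
* **Sampling.** Profiles default to 200 points per lamella including both
  endpoints, so each interface radius appears twice with its owning layer
  recorded; continuity is directly assertable from the samples. The
  seepage amplitude uses the analytic derivative
  `dp/dr = C_i [A_i I₁(C_i r) − B_i K₁(C_i r)]`, never numerical
  differentiation.
* **Degenerate inputs.** `n = 1` is supported and serves as the
  closed-form single-layer reference; `ε_z0 = 0` yields the exact zero
  solution; `a = 0` is rejected (the `1/r` terms are singular on the
  axis).
* **Peak time.** The instant of peak pressure is found by scanning the
  phase at 1° resolution over one period and refining with a bounded
  scalar minimizer; the peak of `max_r |Re(p₀ e^{iωt})|` repeats every
  half period, and the scan is insensitive to which of the two is chosen.

## Finite-difference verification

An independent path discretizes the coupled `(u, p)` amplitude equations
directly: second-order central differences in each lamella, second-order
one-sided stencils for the interface rows (continuity of `p`, `u`,
`k ∂p/∂r`, `σ_rr`) and the boundary rows (`p = 0`, `σ_rr = 0`), and one
sparse complex solve. It shares no code or special functions with the
analytic path. Internally the equations are nondimensionalized (radius by
`b`, displacement by `b ε_z0`, pressure by `M₁₁ ε_z0`) so the sparse
matrix is well scaled. Convergence is second order (observed order
2.00 ± 0.01 against the single-layer closed form); at 2000 nodes the
layered cases agree with the analytic solution to relative L2 ≈ 3e-8 in
pressure.

## Study conditions and presets

The reference configuration is a 50–150 μm osteon of six equal-width
lamellae with cortical-bone constants: `E_r = 15.9 GPa`, `E_z = 20.3 GPa`,
`ν_r = 0.328`, `ν_z = 0.25`, `α = 0.132`, `α′ = 0.092`, `N = 38 GPa`,
`μ = 1e-3 Pa·s`. Lacunar–canalicular permeability is of order `1e-18 m²`
(a conservative value within the experimentally reported `1e-25…1e-17 m²`
span); the preset distributions are a linear outward increase
(`case1`: 0.5…1.5 ×1e-18 m²), a symmetric fast-centre profile (`case2`),
its reverse (`case3`), and a uniform reference. Strain amplitudes span the
physiological 0.04–0.3 % (presets 0.0004, 0.00092, 0.0015, 0.003, with
0.00092 the benchmark) and angular frequencies 1–21 rad/s (presets 1, 5,
10, 21). The frequency unit deserves a caveat: gait frequencies are often
quoted in Hz, and the configuration layer accepts either `frequency_hz`
(converted by `ω = 2πf`) or `omega_rad_s`; the presets use ω in rad/s.
Intermediate sweep values are representative choices within the stated
ranges, not measurements.

These presets are idealized study conditions, not bone: real osteons have
irregular lamellar widths, anisotropic and spatially continuous
permeability, vascular and collagen–apatite porosity, and non-harmonic
loading. Passing tests on these conditions demonstrates the correctness of
the boundary-value solution and its implementation, not predictive
accuracy for tissue.

## Limitations

Only the lacunar–canalicular porosity is modelled; vascular and
collagen–apatite porosities are neglected. Flow is radial only; axial and
circumferential seepage, transient (non-harmonic) response, temperature
effects, nonlinear poroelasticity and interfacial debonding are out of
scope. The mechanical closure at the lateral surfaces is a modelling
choice (traction-free here) that published osteon studies rarely state
explicitly; it is isolated behind the `closure` argument precisely so the
sensitivity can be checked.
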