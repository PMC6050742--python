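# osteonflow

Loading-induced interstitial fluid flow in a single osteon, solved in
closed form for an arbitrary per-lamella permeability distribution.

An osteon — the basic structural unit of cortical bone — is a hollow
cylinder of concentric mineralized lamellae around a central Haversian
canal. Daily cyclic loading (walking, running) pressurizes the interstitial
fluid in the lacunar–canalicular pore network and drives a radial seepage
flow that osteocytes are believed to sense, triggering bone remodelling.
Because the lacunar–canalicular permeability differs from lamella to
lamella, the spatial *distribution* of permeability — not just its
magnitude — shapes the flow stimulus. `osteonflow` quantifies this.

## Model

The osteon is idealized as a hollow, axisymmetric, transversely isotropic
Biot-poroelastic cylinder of `n` perfectly bonded lamellae spanning
`a ≤ r ≤ b`, each with its own intrinsic permeability `k_i`, loaded by a
harmonic axial strain `ε_z(t) = ε_z0 e^{iωt}` between rigid impermeable
platens. All fields reduce to complex radial amplitudes. The pressure
amplitude in lamella *i* satisfies a modified-Bessel equation and is

    p_i(r) = P_i + A_i I₀(C_i r) + B_i K₀(C_i r),
    C_i² = iωμ (M₁₁ + Nα²) / (k_i N M₁₁),

where `M₁₁` is the drained plane stiffness, `N` Biot's modulus, `α, α′`
the Biot effective stress coefficients, `μ` the pore-fluid viscosity, and
`P_i` a constant particular term. The radial displacement integrates to a
matching closed form with two further constants `c_i, s_i` per lamella.
The `4n` constants are fixed by drained surfaces (`p(a) = p(b) = 0`),
continuity of pressure, Darcy flux `k ∂p/∂r`, displacement and radial
stress at the interfaces, and traction-free lateral surfaces
(`σ_rr(a) = σ_rr(b) = 0`); the resulting complex linear system is solved
by LU with partial pivoting after diagonal equilibration. The seepage
velocity follows from Darcy's law, `q_r = −(k/μ) ∂p/∂r`, evaluated
analytically.

An independent frequency-domain finite-difference discretization of the
coupled displacement–pressure equations (second-order stencils, interface
continuity rows, no Bessel functions) verifies the analytic path.

## Worked example

```python
import numpy as np
from osteonflow import Loading, run_case

profile = run_case("case1", Loading(eps_z0=0.00092, omega=21.0))
print(f"peak |p| = {np.abs(profile.p0).max():.2f} Pa")
print(f"|p| at inner wall: {abs(profile.p0[0]):.3e} Pa")
```

prints

```
peak |p| = 686.45 Pa
|p| at inner wall: 4.734e-10 Pa
```

i.e. under a 0.092 % axial strain at ω = 21 rad/s the pore pressure in the
linearly graded permeability case peaks at about 0.69 kPa inside the wall
(at r ≈ 85 μm, shifted toward the low-permeability side), and vanishes at
the drained surfaces as the boundary conditions require. `run_case`
accepts `"case1"` (permeability increasing outward), `"case2"`
(fast centre), `"case3"` (fast surfaces) and `"uniform"`; arbitrary
geometries and materials go through `solve_profile` or a TOML config.

The same functionality is available from a shell:

```
osteonflow run --config case1.toml --out-dir out/       # profile CSV
osteonflow sweep --out-dir out/                         # strain × frequency table
osteonflow verify --config case1.toml --out-dir out/    # finite-difference cross-check
osteonflow cases --out-dir out/                         # all permeability presets
```

The `examples/` directory holds short narrative scripts: the pressure
profile, the strain/frequency sweep, seepage velocity across cases, and
the finite-difference verification.

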