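# Methods

## Constitutive model

The flesh volume (skin, fat and muscle homogenised into one isotropic
solid) is an uncoupled Neo-Hookean material,

    Ψ(F) = C₁ (Ī₁ − 3) + ½ K (ln J)²,

with `Ī₁ = J^(−2/3) tr(FᵀF)`, `J = det F`, both coefficients in MPa and a
consistent mm / N / MPa unit system throughout. `K` penalises volume
change; it is slaved to the stiffness coefficient as `K = k_ratio · C₁`
with `k_ratio = 1000` by default, so a single parameter controls the
material. The effective Poisson ratio stored on `Material` (default 0.5)
is bookkeeping used only in the modulus conversions `C₁ = E/(4(1+ν))` and
`E = 4(1+ν)C₁`; compressibility is actually governed by `K`.

The Cauchy stress and the spatial elasticity tensor are the analytic
derivatives of Ψ (isochoric part from the deviatoric push-forward,
volumetric part from `U(J) = ½K(ln J)²`); both are finite-difference
verified in the test suite to 1e-5/1e-4 relative. Everything is
homogeneous of degree one in (C₁, K), which is the property the
calibration relies on.

## Forward model

* **Elements.** 4- or 10-node tetrahedra with the standard displacement
  formulation; quadratic elements are the default. Near-incompressibility
  is handled by the high `K/C₁` ratio with second-order elements rather
  than a mixed three-field formulation; possible volumetric locking is
  monitored through `max_volume_change` (largest per-element deviation of
  the volume ratio from 1), with < 1% at `k_ratio = 1000` as the
  acceptance guideline. Per-element volume change is the
  quadrature-weighted mean of J over the element — exactly the element's
  relative volume change; per-point extremes would be a stricter, different
  quantity.
* **Quadrature.** The symmetric 4-point degree-2 rule; with affine
  (sub-parametric) element geometry this integrates the homogeneous-stress
  patch test exactly, which the suite asserts.
* **Assembly.** Total-Lagrangian, vectorised over all elements
  (`einsum` contractions, COO scatter). The internal force is the exact
  gradient of the stored energy (finite-difference checked); the spatial
  tangent `c_ijkl + δ_ik σ_jl` keeps Newton quadratic.
* **Boundary conditions.** The bone node set is fully fixed. Probe load
  transmission is either
  * `penalty` — frictionless node-to-rigid-plane contact against the flat
    rectangular probe face. Gap = signed distance along the face normal;
    force `k_pen · g(pen)` along the normal only. The auto-penalty
    `k_pen = penalty_scale · C₁ · h_char` (default scale 100, `h_char`
    the mean-element edge length) makes the full problem — contact
    included — exactly homogeneous in (C₁, K), so reaction forces are
    exactly linear in C₁ at fixed `k_ratio`; or
  * `prescribed_patch` — skin nodes initially under the footprint
    translate with the probe; simpler, exactly material-linear, used for
    property tests.
* **Contact regularisation.** Two deliberate smoothings keep the
  semi-smooth Newton iteration stable: the penalty force-gap law is
  quadratically blended over a depth `0.02 h_char` (C¹ at grazing
  contact), and the rectangular footprint indicator is tapered with a
  smoothstep over 10% of each half-length, with the taper gradient
  included in the (then nonsymmetric) contact tangent. Without either,
  nodes flipping across the active-set or footprint boundary cause
  residual 2-cycles. The associated force error is at the contact
  -discretisation level and is exercised by the regression tests.
* **Solution.** Displacement-driven increments (default 100, i.e. 0.01 of
  the total advance each; studies and tests use 6–10). Each increment is
  equilibrated by Newton iteration with sparse LU (`MMD_ATA` ordering), a
  backtracking line search enforcing monotone residual decrease, an
  update cap of half an element length, relative residual tolerance 1e-6,
  and step halving down to 1/64 of an increment on failure. A
  non-convergent increment yields a flagged partial result, never a bogus
  curve.
* **Outputs.** Reaction force is the component of the total probe force
  along the displacement axis (the resultant-vs-component choice is a
  convention; the axial component is used and is switchable in
  post-processing since nodal contact forces are stored). Surface fields:
  nodally averaged von Mises stress restricted to the skin set, and
  contact pressure = nodal contact force magnitude over tributary area of
  the deformed skin triangles.

## Calibration

`fit_slope_zero_intercept` computes `Σ dᵢFᵢ / Σ dᵢ²`. `crop_align` maps
the simulated curve into the experimental window: drop samples below the
experimental preload force, re-zero displacement at the first retained
sample, drop samples beyond the experimental displacement span. The
simulated fit also uses a zero intercept — after re-zeroing, the origin is
physically meaningful — but a free-intercept variant is available
(`sim_zero_intercept=False`). Each forward run simulates 1.5× the
experimental displacement span (configurable) so the cropped curve always
covers the window.

The update `C₁ ← C₁ · s_exp / s_sim` converges in one step for an exactly
linear forward model, and is a numerically verified contraction when the
local elasticity of `s_sim` w.r.t. `C₁` lies in (0, 2). Convergence is
`|s_sim/s_exp − 1| < tol`, default 2.5%; exhausting `max_iter` (20)
returns a non-converged state rather than raising.

The Brent baseline roots `s_sim(C₁) − s_exp` on a bracket (default
`[c1_init/20, 20·c1_init]`); every forward evaluation counts as one
iteration so counts are directly comparable, and the same slope criterion
decides convergence of the final state. Reference iteration counts for the
Brent baseline depend on unreported optimiser settings, so counts are
compared only as an inequality (ratio ≤ Brent), which holds on every
surrogate problem in the suite.

## Synthetic data

The phantom is an annular cylinder of flesh (default outer radius 33 mm,
bone radius 12 mm, length 40–80 mm) around a rigid bone: the 21 mm default
flesh thickness matches an adult upper-leg indentation site, so probe
advances of 10–30% of thickness are exercisable. Meshing is a structured
cylindrical hex grid split into six tets per hex (Freudenthal, conforming
by translation invariance), optionally elevated to quadratic with straight
mid-edges; node sets are the inner (bone) and outer (skin) surfaces.
Explicit `(n_r, n_theta, n_z)` divisions support refinement families that
hold the contact-facing surface resolution fixed.

The surrogate forward model `F(d) = C₁ · a · (d + b d²)` (geometry scale
`a = 300` mm, stiffening `b = 0.05`/mm) mimics the FE model's exact C₁
linearity and the mild progressive stiffening of indentation curves; its
defaults put peak forces near 10 N at 6 mm for C₁ = 0.005 MPa, the scale
of freehand records. `synth_experiment` applies a preload crop (default
0.14 N — a realistic already-in-contact starting force), re-zeroes
displacement and adds i.i.d. Gaussian force noise (displacement is treated
as exact; motion-capture noise is not modelled). Real measurement-noise
magnitudes are unreported, so the noise default is a placeholder settable
per run.

What the phantom does *not* emulate: real cross-sections are not circular,
flesh is layered and prestrained by gravity, probes rotate slightly, and
tissue is viscoelastic. Passing tests therefore demonstrate correctness of
the numerics and of the calibration logic, not anatomical fidelity.

## Study protocols and problem sizes

The sensitivity and convergence protocols run one indentation per
configuration on the phantom: 50 × 10 mm probe face at the outer surface,
4.5 mm advance (21% of flesh thickness, mid experimental range), 8
increments, C₁ = 0.005 MPa. The sensitivity sweep (ratios 100 / 1000 /
10000 on a (3, 19, 4)-division quadratic mesh, ~2300 elements) reproduces
the expected trends: largest volume change strictly decreasing
(≈1.6% → 0.20% → 0.05%) and reaction force non-decreasing. The
convergence family refines radially only (1, 2, 4 layers at fixed 19 × 4
surface divisions) so the contact discretisation is bitwise identical
across meshes; refinement then isolates structural stiffness and the
coarser meshes are stiffer (≈4.33 → 3.55 → 3.50 N), approaching the limit
from above. When circumferential resolution is refined instead, contact
footprint sampling changes simultaneously and can mask that trend — which
is why the protocol pins the surface mesh. Reference convergence tables
of this kind sometimes print "average percent difference" columns whose
averaging convention is ambiguous (not reproducible from their own force
columns); the implemented metric is the explicit rule above — mean of
`|F_i − F_j|/F_i` over the two next-finer meshes — and no externally
printed metric value is asserted.

Runtime is recorded in reports but never asserted (hardware-dependent).

## Known limitations

* Node-to-plane penalty contact only: no friction, no deformable-
  deformable contact, no large sliding reprojection; the probe is a flat
  rectangle (physical transducer footprints are curved).
* Displacement elements can still lock at very coarse radial resolution
  and high `K/C₁`; the volume-change monitor is the guardrail.
* Quasi-static only; no viscoelasticity, anisotropy, layering, gravity
  prestrain, or real anatomy (CT segmentation and surface remeshing are
  out of scope).
* Deep indentation (≳25% of flesh thickness on coarse meshes) can reach
  element inversion; the solver then reports an honest partial result.
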