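# Methods

## The model

`fibermech` predicts the uniaxial tensile stress–strain response of a
randomly oriented electrospun nanofibrous membrane from three measurable
inputs: the tensile law of its single fibers, the fiber diameter statistics,
and the membrane's porosity. The membrane is idealized as layers of
straight, continuous, non-interacting fibers, uniformly oriented in the
plane; loading is quasi-static, so rate effects and relaxation are outside
the model.

**Single-fiber law.** A fiber's axial stress is the empirical logarithmic
law σ(ε) = a − b·ln(ε + c), with a (MPa), b (MPa, negative for
strain-hardening fibers, stored exactly as fitted) and c (> 0,
dimensionless). For every published SF/PCL fit the raw law is negative at
ε = 0 (e.g. ≈ −3.14 MPa for pure silk fibroin), which is unphysical, so
evaluation clamps negative values to zero by default; the raw law stays
inspectable via `clamp=False` and is what R² is computed against, since the
published fits were evidently unclamped. Stress units are taken as MPa
throughout (the natural scale for electrospun polymer fibers; the original
fits do not state units for a and b).

**Kinematics.** A unit circle of fibers through a common intersection maps
affinely to an ellipse: the diagonal stretch (λx, λy) with λy = 1 + ε. This
affine completion is the unique linear in-plane deformation consistent with
the standard reorientation formula θ′ = arctan[λy sinθ / (λx cosθ)]; it
also fixes the deformed half-length r′ = r0·√(λx²cos²θ + λy²sin²θ) and the
fiber axial strain ε_f = r′/r0 − 1, neither of which the reorientation
formula alone determines. Two conventions map the membrane's shrinkage
coefficient v (> 0) to λx:

* `literal-eq2` (default): λx = v — v is a constant transverse scale
  factor, the form in which the reorientation formula is usually printed.
  Its quirk: at ε = 0 the configuration is already transversely contracted,
  but since the clamped law carries no stress at ε_f ≤ 0 the predicted
  membrane stress at zero strain is still exactly zero.
* `strain-ratio`: λx = 1 + v·ε — v read as a strain ratio. Note that with
  v > 0 this is transverse *expansion*; physically shrinking mats would
  need the signed ratio, but the v > 0 contract is kept so both conventions
  share one parameter. The identity deformation (λx = λy = 1) is realized
  by this convention at ε = 0, which the closed-form and identity tests use.

The fiber projection strain (change of a fiber's axial projection) is
measured against the reference projection r0·sinθ by default, under which
it equals the membrane strain ε identically — the consistency property that
motivates the affine map. Dividing instead by the deformed projection
r′·sinθ′ (available via `denominator="deformed"`) yields ε/(1+ε); both
forms are kept because the relation appears in the literature in the second
form, which is inconsistent at θ = π/2. Neither is silently corrected.

**Orientation average and unit cell.** A fiber contributes the axial force
f_y = (π/4) d² σ̄_f sinθ′; the mean over a uniform orientation distribution
is f̄_y = (2/π)∫₀^{π/2} f_y(θ) dθ. The total over the unit cell is
F_y = n·f̄_y with n = 2V(1−p)/(r0 π D²), D the harmonic mean diameter —
the count that conserves solid volume: n·(π/4)D²·2r0 = V(1−p) exactly.
The cell is a slab of cross-section A and thickness 2r0 (V = A·2r0), the
only convention under which every counted fiber crosses the mid-plane and
the all-fiber sum is a cross-section force, so σ_membrane = F_y/A with no
crossing correction. How the cell volume maps to the plotted stress is not
standardized in the source literature; this slab convention is an explicit
modeling assumption of this package.

**Which diameter enters the aggregate.** The (1 + d/D)/2 correction is
defined for a *tested* fiber of diameter d; a membrane prediction has no
single d. The model evaluates the force at d = D (correction factor 1),
which keeps the force sum and the porosity-based count mutually consistent.
The expected correction over the sample, (1 + d̄/D)/2, is available via
`diameter_correction="expected"`. The discrete simulator deliberately uses
the literal per-fiber reading instead (each fiber's own d in both d² and
the correction), so the difference between the two choices is measured by
the test suite rather than hidden: for lognormal diameter dispersion the
per-fiber reading is systematically stiffer.

## Numerical choices

* **Quadrature.** Gauss–Legendre on the loaded angular interval. With the
  clamp active the law is positive only where ε_f exceeds the zero-stress
  crossing exp(a/b) − c; ε_f(θ) is monotone (its derivative has the sign of
  λy² − λx²), so the boundary angle is a single root found by bisection and
  the integral is restricted to the loaded interval. Because c is small
  (~10⁻⁴ for real fits) the integrand varies on that scale near the
  boundary, so each segment uses composite panels geometrically halved
  toward both endpoints (down to 2⁻⁴⁰ of the span); order 64 per panel by
  default. Every integral is re-evaluated at doubled order and rejected
  (explicit `QuadratureError`, never silent) if the two disagree beyond
  ~10⁻⁷ relative. Without the clamp the domain is split at the compression
  kink ε_f = 0 instead.
* **Compression.** Fibers with ε_f ≤ 0 carry zero force — a buckling
  assumption implicit in modeling only the tensile response.
* **Fitting.** Trust-region-reflective least squares with analytic
  Jacobian, c bounded below by 10⁻⁸ (c → 0 makes the Jacobian singular),
  tight tolerances (10⁻¹⁵), and a data-driven default start: a₀ = max
  stress, b₀ = −(stress span)/ln[(ε_max + c₀)/(ε_min + c₀)] with c₀ = 10⁻³.
  (The log of the *offset-shifted strain ratio* is used rather than the raw
  strain span, so the default is well-defined for spans below 1.)
  Degenerate inputs (< 4 distinct strains, constant stress) and
  non-convergence raise `FitError`; the fit never returns silent garbage.
* **Root finding.** Clamp-boundary angles via `brentq` at machine
  tolerance.

## Synthetic data

No raw single-fiber or membrane test data is publicly deposited for the
SF/PCL system, so the generators make every stage testable:

* **Single-fiber curves**: the clamped law plus i.i.d. Gaussian noise
  (default scale 0.1 MPa, a realistic nano-tensile noise floor) on a
  uniform strain grid, emulating one fiber's test record.
* **Diameters**: lognormal (positive support, right skew — the shape SEM
  diameter histograms of electrospun mats show), at the 60–100 nm scale of
  the published SF/PCL blends. Only summary diameters are published, not a
  distribution, so lognormal is this package's choice.
* **Networks**: orientations i.i.d. uniform on [0, π/2] (the model's own
  layup assumption — no orientation measurement exists to verify it),
  diameters lognormal, all bit-reproducible from explicit integer seeds.

What the synthetic data does *not* emulate: fiber waviness/crimp, thickness
non-uniformity, inter-fiber bonding, unloaded fibers, and fracture. Passing
tests therefore validate the mathematics of the model and its
implementation, not the model's fidelity to real mats — real membranes are
expected to sit somewhat below the prediction precisely because of those
omitted features.

## Default study conditions

Where the model needs conditions that are not published quantities, the
package fixes them once: porosity p = 0.85 (typical electrospun mat),
fiber half-length r0 = 5 µm, unit-cell cross-section A = 1 µm², shrinkage
v = 0.9 under `literal-eq2` (mild transverse contraction). The published
blend inputs (five (a, b, c) fits and the diameter summaries) ship in
`fibermech.data`.

## Verification strategy and problem sizes

The headline check is oracle equivalence: the analytic quadrature against
the discrete 10⁵-fiber Monte-Carlo sum, within 3 standard errors, on 20
random (spec, strain) draws spanning all five blends, with matched (d = D)
network diameters so the comparison isolates the orientation integral and
kinematics chain. Supporting checks: the exact closed-form limit
f̄_y = (2/π)(π/4)D²σ₀ for a constant unclamped law under identity
deformation (∫sinθ dθ = 1); parameter recovery (noiseless round trips to
10⁻⁶ relative, 100 noisy replicates within 2% on a); the machine-precision
tangent identity of the reorientation map on 10⁴ random states; solid-volume
conservation to 10⁻¹² relative; the power-mean ordering of diameter
statistics; and qualitative shape (monotone rising curves on [0, 0.5]
strain, stress decreasing in porosity). `scripts/acceptance.py` recomputes
all of these from a fresh seed.

## Known limitations

* The clamp boundary makes the predicted curve C⁰ but not C¹ at the strain
  where the first fibers load; a real mat's toe region is governed by crimp
  straightening, which the model omits entirely.
* The `literal-eq2` convention pre-contracts the network at ε = 0; the
  alternative convention is provided, but no measurement in the source
  material determines which (or a strain-dependent v) is correct.
* Predictions are as good as the porosity and shrinkage inputs; neither is
  estimated by this package.
* Post-peak softening and fracture are out of scope; predicted curves rise
  monotonically by construction for hardening (b < 0) fiber laws.
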