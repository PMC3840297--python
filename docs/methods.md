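# Methods

## Scope and approach

The package realizes the idealized receptive-field families of scale-space
theory — affine Gaussian derivatives over space, color-opponent variants,
non-causal and time-causal spatio-temporal kernels, and the nonlinear
complex-cell energies built on them — as sampled kernels plus the filtering,
warping, and rendering machinery needed to test their defining properties.
The defining properties are mathematical identities (semigroup, covariance,
non-enhancement, invariance), so validation is not against data but against
the identities themselves: each is turned into a measurement with an explicit
tolerance, run by `rfkit.verify` and by the test suite.

## Kernel discretization

Kernels are exact point samples of the analytic functions.  Derivatives come
from the Hermite-type recursion `∂ᵢ(P·g) = (∂ᵢP − P·(Σ⁻¹x)ᵢ)·g` on a
polynomial prefactor `P`, so arbitrary partial/directional derivative kernels
up to order 4 are sampled without finite differencing.  Zero-order kernels
are renormalized to unit discrete mass.  Derivative kernels are
moment-corrected to exact zero sum by default: the raw sampled sum of an
even-order derivative is an aliasing residual that by Poisson summation
grows to ~10⁻³ at s = 0.5 px², far above the 10⁻⁶ bookkeeping tolerance,
while the correction (a constant shift) is harmless at the scales involved.
The default truncation radius is `ceil((4+m)·√λ₁)` samples, giving < 10⁻⁴
mass loss up to order 4; smaller grids produce a warning and a flagged
kernel.  Degenerate Σ (λ₂ = 0) is allowed only in the diffusion parameters,
never for sampled kernels.

Convolution runs in the spatial domain for kernels up to 31² and through an
FFT on a boundary-padded copy above that; both routes agree to ~10⁻¹⁴ and are
cross-checked in the tests.  Boundary policies: reflect (default), zero,
periodic.

## Resolution choices for continuum identities

Several verified properties are identities of the *continuous* kernel
families.  Certifying them numerically requires resolving the kernels, so
the discretization error does not masquerade as a violation of the property:

* **Semigroup / cascade** is measured at grid spacing h = 0.5 px.  At unit
  spacing, sampled Gaussians at s = 0.5 px² (σ = 0.71 px) violate the
  semigroup at the 3·10⁻² level purely through spectral aliasing — a
  sampling artifact, not a failure of the family (the discrete-analogue
  Gaussian that removes it is deliberately out of scope).  At h = 0.5 all
  scale pairs from {0.5, 1, 2} pass below 10⁻⁸.
* **Diffusion–convolution equivalence** integrates the explicit second-order
  scheme on a 64² grid with h = 0.25 px (domain ±8 = 8σ at s = 1).  The
  measured deviation from the sampled Gaussian is 0.23 % relative L2; the
  scheme converges at second order (1.0 % at h = 0.5), but at h = 1 the
  impulse excites the entire spectrum and the semi-discrete limit sits 22 %
  from the Gaussian.
* **The φ identities** use dt = 5·10⁻³ for the τ-semigroup (rel. L1 ≈ 10⁻³)
  and dt = 5·10⁻⁴ with second-order edge differences for
  `∂ₜφ = ½∂ₜₜφ|_τ` (≈ 7·10⁻⁵ of max |∂ₜφ|).  φ's unit mass is integrated on
  a log-spaced grid out to 10⁷τ², because the t^{−3/2} tail carries mass
  `erfc(τ/√(2T))` ≈ 11 % beyond 50τ² — a horizon of a few τ² can never
  certify the mass to 10⁻³.

## Temporal filtering

The first-order integrator ODE `∂ₜL_k = (L_{k−1} − L_k)/μ_k` is discretized
with backward Euler, which is unconditionally stable, positivity-preserving,
and a convex combination of past state and current input (hence exactly
non-creating for 1D extrema).  A forward-Euler option exists for
cross-checks.  At dt = μ_min/20 the impulse response of the recursive filter
matches the composed truncated-exponential kernel to 1.6 % relative L1,
halving as dt halves (both are first-order-accurate routes to the same
continuum kernel).  The streaming interface (`IntegratorCascade.step`)
retains only the K-level state vector — no temporal buffer.

State initialization is zero by default; the `init="first"` option preloads
the state with the first frame, as if it had been held for all past time.
The extrema-non-creation measurement uses the warm start, because the
property concerns the filter in steady operation: a zero initial state
injects a step transient at t = 0 that does not belong to the signal and can
add one spurious extremum at the first level.

Units: for the time-causal φ family the temporal scale parameter τ has
dimension √time (it enters as τ²/2t), whereas for the Gaussian family τ is a
variance with dimension time².  The parameter documentation keeps the two
conventions explicit; silently mixing them is the easiest way to produce
nonsense kernels.  φ has no finite mean; its "temporal delay" is reported as
the mode τ²/3 by convention.

Transformed temporal derivatives `∂ₜ′ = t^κ∂ₜ` (κ ∈ [0,1], default 1/2 as
used in the model-cell illustrations) are applied numerically — central
differences weighted by t^κ, pinned to 0 at t ≤ 0.  Note that as a
*convolution kernel* `∂ₜ′ⁿ h(t; τ)` does not integrate to zero for κ > 0
(∫t^κ h′ dt = −κ∫t^{κ−1}h dt), so the steady-state response of such a kernel
to a static stimulus is small but not exactly zero; exact cancellation holds
for plain ∂ₜ (κ = 0) and for applying ∂ₜ′ to the smoothed *response*, which
commutes only when κ = 0.

## Spatio-temporal derivative algebra

Kernels of the Gaussian family are sums of terms
`c · (D^α g)(x − vt; Σ) · T^{(n)}(t)`.  Spatial derivatives act on the
spatial factor in the co-moving frame; the velocity-adapted derivative
`∂ₜ̄ = vᵀ∇ₓ + ∂ₜ` differentiates the temporal factor alone (the transport
parts cancel), while plain ∂ₜ expands by the product rule into
−v-weighted spatial terms plus a temporal term.  This keeps every derivative
kernel an exact analytic sample.  The 3×3 space-time covariance is
constructed as `G_v diag(Σ, τ) G_vᵀ`, which reproduces the factorized kernel
form exactly.  Temporal delay defaults to δ = 3.5√τ for the non-causal
family, leaving < 10⁻³ of its mass at t < 0.

## Synthetic fixtures and what passing means

All verification inputs are generated analytically: seeded Gaussian noise
band-limited by a hard radial cutoff (0.12–0.15 cycles/px), gratings whose
motion is an exact per-frame phase shift (no resampling error in the ground
truth), impulses, step edges, and rendered log-brightness scenes with smooth
positive albedo/illumination maps.  Band-limitation matters: the covariance
measurements are interpolation-limited (bilinear or cubic warps), and the
non-enhancement measurement differentiates a finite scale step, so both
assume the fixtures carry no energy near Nyquist.  Passing therefore
certifies the kernel algebra and its discretization on smooth inputs; it
does not bound the behavior on aliased or noise-dominated real imagery, nor
does it validate the models against physiological recordings — these are
idealized cells, not fits.

Measured margins at the default conditions: affine covariance ≤ 0.4 % rel.
L2 for 20 random maps with condition number ≤ 3 on 128² fixtures (tolerance
5 %); Galilean covariance ≤ 0.5 % on 64³ stacks for |v| ≤ 1 px/frame; the
velocity-adapted temporal derivative of a matched drifting grating is ~10⁻⁹
of the response scale (tolerance 10⁻³).

## Design choices where the design was open

* Directional derivatives are by convention aligned with Σ's
  eigendirections; misaligned φ is permitted but flags the kernel.
* The DoG is defined as `(g(s+Δs) − g(s))/Δs` compared against `½∇²g(s)`;
  the forward difference gives the clean O(Δs) convergence the tests assert
  (error ratio ≈ 0.52–0.58 per halving).
* The opponent transform is applied to sensor RGB as given, with no gamma
  handling; the photometry module handles log-scale questions, where a
  sensor gamma `I^γ` simply scales the whole log image (vignetting included)
  by γ.
* The quadrature constant C defaults to 2/3 (ripple-minimizing); e/4 is
  available.  The source literature rounds e/4 to 0.670 although e/4 =
  0.6796 to four digits; we document rather than correct the inconsistency.
* The divisive-normalization weight function over ensemble geometry is a
  user-supplied callable in effect — the ensemble takes explicit weights
  with a uniform default — since no principled form is established.
* Foveal tiling uses sunflower layouts per octave: each octave's fields fill
  the disk where that size is admissible under σ_min(e) = σ₀(1 + e/e₀), with
  a fixed count per octave, so spacing scales with √s automatically.  σ₀ and
  e₀ default to 1 px and 20 px and are configurable; only the linear law
  itself is prescribed.
* Time-causal temporal family defaults: the integrator cascade for streaming
  use (`rf respond`), the Gaussian family where delayed, symmetric temporal
  profiles are wanted.

## Known limitations

* **One qualitative claim fails quantitatively.**  The lagged/non-lagged
  lobe-dominance characterization (first temporal lobe dominant for n = 1,
  second for n = 2) holds for the integrator cascade at κ = ½, and for the
  φ kernel at n = 1, but for `∂ₜ′∂ₜ′φ` at κ = ½ the *first* lobe peak is the
  larger one (1.59 : 1; the zeros sit at t = (9 ± √33)/24 · τ², confirmed
  symbolically).  φ satisfies both assertions at κ = 1 and the cascade at
  κ = ½, but no single κ satisfies both families.  The verification suite
  reports all four assertions at the default κ = ½ and the φ/n = 2 one
  fails; we report the measurement rather than tune κ per family.
* Sampled (not discrete-analogue) kernels: below s ≈ 1 px², pixel-rate
  processing inherits the aliasing quantified above.
* The hemisphere illumination integral is not computed — illumination enters
  as a supplied positive map; specularities, focal blur, and spherical
  camera geometry are not modelled.
* No scale selection or feature detection is built on the kernels, and no
  fitting of the nonlinear models to cell recordings is provided.
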