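# Methods

## Model and solver

The package evolves a degraded image `f` under the biased anisotropic
diffusion equation

    du/dt = div( α w(|∇u|) ∇u ) + α β (f − u),    w(s) = 1/(1 + s²/λ²),

starting from `u⁰ = f`. The equation is the gradient flow of the discrete
energy `Σ_pixels [ αβ(u−f)² + w|∇u|² + λ²(w − ln w) ]·Δx²`; for fixed `u`
the integrand is minimised pointwise in `w ∈ (0,1]` by the stated
edge-stopping function, which the test suite verifies numerically against
randomly perturbed weight fields.

A dimensionless form of the equation exists (rescaling time by `αβ` and
space by `β`), but it degenerates at `β = 0`, which is a meaningful and
useful limit (pure anisotropic diffusion). The solver therefore integrates
the dimensional equation at unit grid spacing and reports
`τ = α·β·n·Δt` in traces purely as a derived coordinate (with `τ := n`
when `β = 0`).

### Discretisation

All first derivatives are second-order centered differences
`(h[i+1] − h[i−1])/(2Δx)`. The image gradient uses replicate (edge-value)
padding — the discrete zero-normal-derivative condition. The divergence of
the flux `w∇u` applies the same centered difference to the flux components
with **zero ghost flux**: since replicate padding of `u` makes the ghost
gradient across each face vanish, the consistent ghost value for the
normal flux component is zero. (Replicating the flux value instead pushes
flux through the border and, measurably, lets iterates of a [0,1] image
escape the interval near the frame edge; the zero-ghost form keeps the
update a convex combination of neighbour values everywhere.)

The composition of two centered first differences is the wide `D0∘D0`
stencil coupling pixels two apart. Its von-Neumann growth factor in the
linear limit (`w ≡ 1`, `β = 0`) is `g = 1 − αΔt(sin²k_x + sin²k_y)/Δx²`,
so the scheme is stable iff `α·Δt/Δx² ≤ 1`; the worst mode
(`k_x = k_y = π/2`, a period-4 cosine) is neutrally stable at `α = 1` and
grows by `|1 − 2α|` per step beyond it. The acceptance suite constructs
that mode with the half-pixel phase that makes its replicate-padded
extension exact and measures growth factors of 1.000 at `α = 1.0` and
≈1.1 at `α = 1.05`. `SolverConfig` warns rather than errors above the
bound so the unstable regime can be probed deliberately. The known
odd–even decoupling of the wide stencil is accepted as part of the method.

Time stepping is explicit Euler with `Δt = Δx = 1`. For `α ≤ 1` (hence
`w·α ≤ 1`) and `αβΔt ≤ 1` the interior update is a convex combination of
the five coupled values and the anchor `f`, so iterates of a [0,1] input
remain in [0,1]; the solver never clips its iterates (clipping would mask
an instability), and the test suite checks the bound empirically over 10⁴
steps at 256².

### The contrast scale λ

`λ = 0.9 · mean(|∇u|)` over all pixels, with the per-pixel Euclidean norm
of the two-component gradient (the L1 combination `|∂x|+|∂y|` was rejected
for anisotropy). By default the estimate is taken **once from the input
image and frozen** (`lambda_mode="auto_fixed_from_input"`). This is a
deliberate choice with a visible consequence: if λ is re-estimated from
the current iterate each step (`"auto_per_step"`, also provided), it
shrinks as the image smooths, diffusion becomes ever more conservative,
and pure diffusion never over-smooths — which makes the fidelity term
redundant (the PSNR-optimal β is then always the smallest value tried, at
every noise level). With λ frozen, small-β runs over-smooth past an
interior PSNR maximum while large-β runs plateau, the optimal β is
interior, and it moves toward smaller values as the noise level rises —
the behaviour the fidelity term exists to produce. A constant image gives
a zero raw estimate; λ is floored at 1e−12 and the weight degenerates to
`w ≡ 1` there, keeping constant images exact fixed points.

### Choosing β

`best_beta_sweep` runs an independent solve per β (no state shared) and
tabulates, for each, the final PSNR at the step horizon, the maximum PSNR
over the trace, and the step of that maximum. Two selectors are exposed:
`best_beta` (argmax of the trace maximum) and `best_beta_final` (argmax of
the final reconstruction's PSNR — the operational choice when the run
length is fixed up front, and the one used in the acceptance checks,
since a practitioner keeps the image the run ends on). Ties break toward
the smaller β (less smoothing bias). β carries units of inverse area;
`rescale_beta(β, L)` maps a value tuned at the 512-pixel reference frame
to another resolution as `β·512/L`.

Stopping is a fixed step budget, optionally shortened by a patience rule
on the reference PSNR when a reference is supplied; both are recorded in
the trace.

## Quality metrics

PSNR is the standard `20·log₁₀(max(ref)/RMSE)` in dB, `+∞` (documented
sentinel) at zero error so traces on clean inputs do not abort. SSIM
follows the Wang et al. reference implementation — 11×11 Gaussian window,
σ = 1.5, K₁ = 0.01, K₂ = 0.03, weighted (population) covariances — via
scikit-image, cross-checked in the tests against an independently coded
windowed double loop. The dynamic range defaults to `max(ref)` to mirror
the PSNR peak convention; pass 1.0 to score [0,1] images against the unit
range. `difference_map` is the signed per-pixel `(u − ref)/max(ref)`
diagnostic.

## Synthetic data

No real detector frames ship with the package; all tests run on two
generated phantoms.

* **Cartoon phantom** (`make_cartoon_phantom`): a tilted gradient
  background, one broad smooth blob, and sharp-edged disks and rectangles,
  max-normalised to 1 — flat regions, ramps and step edges in controlled
  proportions (edge pixels with `|∇f| > 0.2` are ~1% of the frame at
  L=256). It stands in for a generic grayscale test image in the
  Gaussian-noise experiments.
* **Fiber-diffraction phantom** (`make_fiber_pattern`): a sum of radial
  elements — each a ring of Gaussian radial profile, windowed to a hard
  angular arc (half-width π gives a full ring) — over a uniform
  background, zeroed inside a central beamstop and max-normalised. With
  `pi_symmetric` every arc is paired with its antipode and the field is
  symmetrised to be bit-exactly invariant under 180° rotation on an odd
  grid, emulating the arc symmetry of oriented-fiber scattering. The
  default spec (one full ring, a strong meridional arc pair, a weaker
  equatorial pair, background 0.03, beamstop at 5% of the frame) is a
  collagen-like geometry.

Noise models: additive i.i.d. Gaussian noise of stated mean/variance in
squared [0,1]-intensity units, clipped to [0,1] by default; and Poisson
counting noise with expected counts `ν = f₀·max_counts`, re-normalised by
the observed maximum count (mirroring the per-image rescaling used when
comparing exposures of very different integration times; an option divides
by `max_counts` instead to keep the scale linear for statistical tests).
The study conditions are Gaussian variances 0.01/0.05/0.10 and Poisson
maxima of ~10³ counts (noisy) against either the noiseless phantom or a
~6×10⁴-count exposure (clean). All generators are pure functions of their
arguments including the seed.

What the phantoms do **not** emulate: physical diffraction (structure
factors, Lorentz–polarisation, detector point spread), natural-image
texture (the cartoon phantom is piecewise smooth, so fine-texture loss is
not penalised), dead pixels, or detector gaps. Passing tests therefore
demonstrate the solver's contracts and the direction and rough magnitude
of denoising gains in these regimes, not performance figures transferable
to any particular instrument. On the fiber phantom at 10³ counts, ~80% of
the initial squared error sits in the bright arc pixels, which compresses
achievable PSNR gains (≈+0.2–0.5 dB) while SSIM gains are large
(≈0.973 → 0.989) — the characteristic counting-noise signature.

## Problem sizes and numerical choices

The shipped checks use 256² frames for the Gaussian sweeps (1200 steps,
β grid 0.02–0.8), 255² for the Poisson sweeps (800 steps, β grid
0.02–0.8), 10⁴ steps for the bound-preservation check, and 512²/2000 steps
for the end-to-end CLI pipeline — sizes chosen so the full suite documents
the method's behaviour at realistic detector scales while remaining quick
to run routinely. Oracle-equivalence checks run on 5×5–9×9 seeded
instances at 1e−12 (1e−9 for SSIM). Images are row-major, (row, col) =
(y, x), row 0 at top; integer rasters quantise with round-half-up after
clipping; float NPY round-trips bit-exactly.

## Known limitations

* Explicit Euler only: the step bound makes long diffusion horizons cost
  linearly many sweeps; no semi-implicit or multigrid path.
* Scalar edge-stopping weight only (no tensor/anisotropic-matrix
  diffusion, no non-local means).
* The wide stencil's odd–even decoupling can leave a faint checkerboard
  component in very long β=0 runs.
* SSIM on weak (far-from-full-range) references depends strongly on the
  dynamic-range convention; comparisons across publications require care.
* Grayscale 2D only.
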