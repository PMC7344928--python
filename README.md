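# diffdenoise

Edge-preserving denoising for 2D X-ray diffraction patterns and other
counting-detector images, built on biased anisotropic diffusion.

Frames from counting detectors (imaging plates, CCDs, hybrid photon
counters) carry Poisson shot noise: at ~10³ counts per pixel the relative
noise in the weak diffuse scatter is large, and it contaminates every
downstream step — background subtraction, peak fitting, texture analysis.
Plain Gaussian smoothing removes the noise but also blurs the Bragg rings
and arcs that carry the signal. This package implements a classical remedy:
diffusion whose local strength collapses at image edges, plus a fidelity
term that stops the smoothing from drifting away from the data.

## The model

The degraded image `f : D → [0,1]` is evolved as `u(t)` under

```
∂u/∂t = ∇·( α w(|∇u|) ∇u ) + α β (f − u),      u(0) = f,
w(s)  = 1 / (1 + s²/λ²)
```

* `α` — diffusion scale; with the explicit scheme below it doubles as the
  time step and is bounded by stability (`α ≤ 1` at unit spacing).
* `β` — fidelity weight. `β = 0` is pure anisotropic diffusion (eventually
  over-smooths); large `β` pins `u` to the noisy input. The optimum is the
  method's one free parameter, and it scales with resolution as
  `β → β·512/L` (see `rescale_beta`).
* `λ` — contrast scale separating noise gradients (`w ≈ 1`, smoothed) from
  edge gradients (`w ≈ 0`, preserved). Estimated from the input image as
  `λ = 0.9·mean|∇f|` and frozen for the run (per-step re-estimation is
  available as an option).

The PDE is the gradient flow of the energy
`∬ αβ(u−f)² + w|∇u|² + λ²(w − ln w) dx`, in which the stated `w` is the
pointwise-optimal edge-stopping function.

Discretisation: second-order centered differences applied twice (the wide
`D0∘D0` stencil), replicate padding for the image gradient and zero ghost
flux at the border (no flux leaves the frame), explicit Euler in time with
`Δx = Δt = 1`. The scheme is monotone for `α ≤ 1`, so iterates of a [0,1]
image stay in [0,1] without clipping.

Quality is tracked with standard PSNR (`20·log₁₀(peak/RMSE)`, peak taken
from the reference) and SSIM (11×11 Gaussian window, σ = 1.5, K₁ = 0.01,
K₂ = 0.03).

## Worked example

```python
import diffdenoise as dd

# clean pi-symmetric fiber pattern and its ~1000-count Poisson exposure
f0 = dd.make_fiber_pattern(dd.default_fiber_spec(255))
f = dd.add_poisson_noise(f0, max_counts=1000, seed=0)

den = dd.DiffusionDenoiser(alpha=0.1, beta=0.4, n_steps=800)
u = den.fit_transform(f)

print(f"PSNR: {dd.psnr(f, f0):.2f} dB -> {dd.psnr(u, f0):.2f} dB")
print(f"SSIM: {dd.ssim(f, f0):.3f} -> {dd.ssim(u, f0):.3f}")
print(f"lambda (frozen from input): {den.lambda_fixed_:.4f}")
```

prints

```
PSNR: 37.54 dB -> 37.73 dB
SSIM: 0.973 -> 0.990
lambda (frozen from input): 0.0135
```

— the counting-noise signature: the structural similarity of the pattern
recovers strongly while the peak error, dominated by the bright arcs the
fidelity term correctly leaves alone, moves only marginally. The
`DiffusionDenoiser` is a scikit-learn transformer (`get_params`, `clone`,
pipelines over image stacks all work); the same functionality is available
functionally via `dd.solve(f, dd.SolverConfig(...), reference=f0)`, which
also returns a per-iteration trace (step, τ = αβ·n·Δt, λ, PSNR, SSIM) that
exports to CSV.

The command line mirrors the library:

```sh
diffdenoise simulate --phantom fiber --size 512 --noise poisson:1000 --seed 3 --out sim
diffdenoise denoise --input sim_noisy.npy --output out.npy --beta 0.06 --steps 2000 --normalization none
diffdenoise metrics out.npy sim_clean.npy
diffdenoise sweep --input sim_noisy.npy --reference sim_clean.npy --betas 0:0.5:0.02 --out sweep.csv
```

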