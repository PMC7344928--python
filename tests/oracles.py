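"""Independent brute-force oracles.

Every function here is a deliberately slow, per-pixel double-loop (or scalar)
re-implementation of an operation in diffdenoise, written against the
mathematical definitions and kept free of any code from the package's
vectorised paths.  Tests compare the fast implementations against these.
"""

import math

import numpy as np


def _at(a, i, j):
    """Replicate (edge-value) padding lookup."""
    H, W = a.shape
    return a[min(max(i, 0), H - 1), min(max(j, 0), W - 1)]


def grad_oracle(u, dx=1.0):
    """Centered gradient, loop form: returns (d/drow, d/dcol)."""
    H, W = u.shape
    gr = np.zeros((H, W))
    gc = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            gr[i, j] = (_at(u, i + 1, j) - _at(u, i - 1, j)) / (2 * dx)
            gc[i, j] = (_at(u, i, j + 1) - _at(u, i, j - 1)) / (2 * dx)
    return gr, gc


def div_oracle(fr, fc, dx=1.0):
    """Centered divergence of a two-component field, loop form (replicate)."""
    H, W = fr.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            out[i, j] = (_at(fr, i + 1, j) - _at(fr, i - 1, j)) / (2 * dx) + (
                _at(fc, i, j + 1) - _at(fc, i, j - 1)
            ) / (2 * dx)
    return out


def _at0(a, i, j):
    """Zero-ghost lookup (no-flux boundary for flux components)."""
    H, W = a.shape
    if i < 0 or i >= H or j < 0 or j >= W:
        return 0.0
    return a[i, j]


def div_noflux_oracle(fr, fc, dx=1.0):
    """Centered flux divergence with zero ghost flux, loop form."""
    H, W = fr.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            out[i, j] = (_at0(fr, i + 1, j) - _at0(fr, i - 1, j)) / (2 * dx) + (
                _at0(fc, i, j + 1) - _at0(fc, i, j - 1)
            ) / (2 * dx)
    return out


def lambda_oracle(u, coeff=0.9, floor=1e-12, dx=1.0):
    gr, gc = grad_oracle(u, dx)
    total = 0.0
    for i in range(u.shape[0]):
        for j in range(u.shape[1]):
            total += math.hypot(gr[i, j], gc[i, j])
    return max(floor, coeff * total / u.size)


def step_oracle(u, f, alpha, beta, dt, dx, lam):
    """One explicit Euler update of the biased anisotropic diffusion scheme."""
    gr, gc = grad_oracle(u, dx)
    w = 1.0 / (1.0 + (gr**2 + gc**2) / lam**2)
    div = div_noflux_oracle(w * gr, w * gc, dx)
    out = np.zeros_like(u)
    H, W = u.shape
    for i in range(H):
        for j in range(W):
            out[i, j] = (
                u[i, j]
                + alpha * dt * div[i, j]
                + alpha * beta * dt * (f[i, j] - u[i, j])
            )
    return out


def energy_oracle(u, f, w, alpha, beta, dx, lam):
    """Scalar double-loop summation of the discrete energy."""
    gr, gc = grad_oracle(u, dx)
    total = 0.0
    H, W = u.shape
    for i in range(H):
        for j in range(W):
            g2 = gr[i, j] ** 2 + gc[i, j] ** 2
            total += (
                alpha * beta * (u[i, j] - f[i, j]) ** 2
                + w[i, j] * g2
                + lam**2 * (w[i, j] - math.log(w[i, j]))
            )
    return total * dx**2


def psnr_oracle(u, ref):
    H, W = u.shape
    sq = 0.0
    for i in range(H):
        for j in range(W):
            sq += (u[i, j] - ref[i, j]) ** 2
    mse = sq / (H * W)
    if mse == 0:
        return math.inf
    return 20.0 * math.log10(ref.max() / math.sqrt(mse))


def _gaussian_kernel(size=11, sigma=1.5):
    r = size // 2
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    k = np.exp(-(x**2 + y**2) / (2 * sigma**2))
    return k / k.sum()


def ssim_oracle(u, ref, dynamic_range, size=11, sigma=1.5, K1=0.01, K2=0.03):
    """Windowed-loop mean SSIM: Gaussian-weighted moments over every fully
    interior window position, population (weighted) covariances."""
    k = _gaussian_kernel(size, sigma)
    r = size // 2
    C1 = (K1 * dynamic_range) ** 2
    C2 = (K2 * dynamic_range) ** 2
    H, W = u.shape
    vals = []
    for i in range(r, H - r):
        for j in range(r, W - r):
            wu = u[i - r : i + r + 1, j - r : j + r + 1]
            wr = ref[i - r : i + r + 1, j - r : j + r + 1]
            mu_u = (k * wu).sum()
            mu_r = (k * wr).sum()
            var_u = (k * wu * wu).sum() - mu_u**2
            var_r = (k * wr * wr).sum() - mu_r**2
            cov = (k * wu * wr).sum() - mu_u * mu_r
            s = ((2 * mu_u * mu_r + C1) * (2 * cov + C2)) / (
                (mu_u**2 + mu_r**2 + C1) * (var_u + var_r + C2)
            )
            vals.append(s)
    return float(np.mean(vals))


def linear_smooth_oracle(u, alpha, dt, dx, n):
    """n applications of the wide-stencil linear smoother (w forced to 1,
    beta = 0), loop form."""
    for _ in range(n):
        gr, gc = grad_oracle(u, dx)
        u = u + alpha * dt * div_noflux_oracle(gr, gc, dx)
    return u
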