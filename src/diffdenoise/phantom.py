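"""Synthetic test images and the two noise models of counting-detector work.

Two phantoms are provided:

* a *cartoon* phantom — flat regions, smooth ramps and sharp-edged shapes
  over a gradient background, standing in for a generic grayscale test
  image in Gaussian-noise experiments;
* a *fiber-diffraction* phantom — radially Gaussian rings and angularly
  windowed partial arcs about a beam centre, with a central beamstop,
  emulating the geometry of a 2D X-ray pattern from an oriented fibrous
  specimen (e.g. collagen): oriented scattering appears as pi-symmetric
  arc pairs rather than full 2*pi rings.

Noise injectors: additive zero-mean Gaussian noise of a stated variance
(clipped to [0,1]), and Poisson counting noise where the clean image sets
the expected counts per pixel up to a ``max_counts`` scale — the study
conditions being ~10^3 counts for a noisy exposure against ~6x10^4 for a
long clean one.  All generators are pure functions of their arguments
including the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import validate_field
from .exceptions import InvalidInputError, ParameterError

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "default_fiber_spec",
    "make_cartoon_phantom",
    "make_fiber_pattern",
    "add_gaussian_noise",
    "add_poisson_noise",
]


@dataclass
class PhantomSpec:
    """Geometry of a synthetic fiber-diffraction pattern.

    The pattern is a sum of radial elements; element ``k`` is a ring of
    radius ``ring_radii[k]`` pixels with Gaussian radial profile of sigma
    ``ring_widths[k]``, restricted to the angular window
    ``|theta - arc_centers[k]| <= arc_half_widths[k]`` (a half-width of pi
    gives the full ring) and scaled by ``amplitudes[k]``.  With
    ``pi_symmetric`` every arc is paired with its mirror at theta + pi and
    the field is exactly invariant under 180-degree rotation on an odd grid.
    """

    size: int = 255
    ring_radii: "list[float]" = field(default_factory=list)
    ring_widths: "list[float]" = field(default_factory=list)
    arc_centers: "list[float]" = field(default_factory=list)
    arc_half_widths: "list[float]" = field(default_factory=list)
    amplitudes: "list[float]" = field(default_factory=list)
    background_level: float = 0.0
    beamstop_radius: float = 0.0
    pi_symmetric: bool = True

    def validate(self) -> None:
        n = len(self.ring_radii)
        for name in ("ring_widths", "arc_centers", "arc_half_widths", "amplitudes"):
            if len(getattr(self, name)) != n:
                raise ParameterError(
                    f"PhantomSpec: {name} must have the same length as ring_radii"
                )
        if self.size < 16:
            raise ParameterError("PhantomSpec: size must be >= 16")
        if any(r >= self.size / 2 for r in self.ring_radii):
            raise ParameterError("PhantomSpec: ring radii must be < size/2")
        if any(w <= 0 for w in self.ring_widths):
            raise ParameterError("PhantomSpec: ring widths must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ParameterError("PhantomSpec: amplitudes must be non-negative")
        if not 0 <= self.background_level < 1:
            raise ParameterError("PhantomSpec: background_level must be in [0, 1)")
        if self.beamstop_radius < 0:
            raise ParameterError("PhantomSpec: beamstop_radius must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "PhantomSpec":
        return cls(**json.loads(s))


def default_fiber_spec(L: int = 255) -> PhantomSpec:
    """Collagen-like fiber pattern: one full ring, a strong meridional arc
    pair and a weaker equatorial pair, with background and beamstop."""
    return PhantomSpec(
        size=L,
        ring_radii=[0.32 * L, 0.18 * L, 0.26 * L],
        ring_widths=[0.012 * L, 0.010 * L, 0.009 * L],
        arc_centers=[0.0, math.pi / 2, 0.0],
        arc_half_widths=[math.pi, 0.35, 0.55],
        amplitudes=[0.45, 1.0, 0.7],
        background_level=0.03,
        beamstop_radius=0.05 * L,
        pi_symmetric=True,
    )


@dataclass
class NoiseSpec:
    """Noise model descriptor for configuration files and the CLI.

    ``kind`` is "gaussian" (additive, ``mean``/``variance`` in squared [0,1]
    intensity units, clipped unless ``clip`` is off) or "poisson"
    (``max_counts`` expected counts at unit intensity).
    """

    kind: str = "poisson"
    mean: float = 0.0
    variance: float = 0.05
    max_counts: int = 1000
    seed: int = 0
    clip: bool = True

    def validate(self) -> None:
        if self.kind not in ("gaussian", "poisson"):
            raise ParameterError(f"unknown noise kind {self.kind!r}")
        if self.variance < 0:
            raise ParameterError("variance must be non-negative")
        if self.max_counts < 1:
            raise ParameterError("max_counts must be >= 1")

    def apply(self, f0: np.ndarray) -> np.ndarray:
        self.validate()
        if self.kind == "gaussian":
            return add_gaussian_noise(f0, self.mean, self.variance, self.seed, self.clip)
        return add_poisson_noise(f0, self.max_counts, self.seed)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NoiseSpec":
        return cls(**json.loads(s))


def make_cartoon_phantom(L: int, seed: int) -> np.ndarray:
    """Piecewise-smooth [0,1] test image: gradient background, a smooth blob,
    and sharp-edged disks and rectangles; deterministic for (L, seed)."""
    if L < 64:
        raise ParameterError(f"cartoon phantom needs L >= 64, got {L}")
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:L, 0:L].astype(np.float64) / (L - 1)

    img = 0.15 + 0.30 * (0.6 * x + 0.4 * y)  # tilted background ramp

    # one broad smooth blob (tests behaviour on smooth ramps)
    cx, cy = rng.uniform(0.25, 0.75, size=2)
    s = rng.uniform(0.15, 0.25)
    img += 0.25 * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * s**2))

    # sharp-edged disks: assigned, not added, to create step edges
    for _ in range(4):
        dcx, dcy = rng.uniform(0.1, 0.9, size=2)
        r = rng.uniform(0.05, 0.14)
        level = rng.uniform(0.25, 0.95)
        img[(x - dcx) ** 2 + (y - dcy) ** 2 < r**2] = level

    # sharp-edged rectangles
    for _ in range(2):
        x0, y0 = rng.uniform(0.05, 0.7, size=2)
        wdt, hgt = rng.uniform(0.1, 0.25, size=2)
        level = rng.uniform(0.2, 0.9)
        img[(x >= x0) & (x < x0 + wdt) & (y >= y0) & (y < y0 + hgt)] = level

    img = np.clip(img, 0.0, None)
    img /= img.max()
    return img


def _rot180(a: np.ndarray) -> np.ndarray:
    return a[::-1, ::-1]


def make_fiber_pattern(spec: PhantomSpec) -> np.ndarray:
    """Render the fiber-diffraction phantom described by ``spec``.

    Rings have Gaussian radial profiles; arcs are hard angular windows
    around their centre angle (and, when pi-symmetric, its antipode).  The
    beamstop zeroes the centre; the result is max-normalised to 1.
    """
    spec.validate()
    L = spec.size
    c = (L - 1) / 2.0
    y, x = np.mgrid[0:L, 0:L].astype(np.float64)
    dy, dx_ = y - c, x - c
    r = np.hypot(dy, dx_)
    theta = np.arctan2(dy, dx_)

    img = np.full((L, L), float(spec.background_level))
    for r0, wdt, th0, hw, amp in zip(
        spec.ring_radii,
        spec.ring_widths,
        spec.arc_centers,
        spec.arc_half_widths,
        spec.amplitudes,
    ):
        radial = amp * np.exp(-((r - r0) ** 2) / (2.0 * wdt**2))
        if hw >= math.pi:
            window = True
        else:
            d = np.abs((theta - th0 + math.pi) % (2 * math.pi) - math.pi)
            if spec.pi_symmetric:
                d = np.minimum(d, math.pi - d)  # distance to {th0, th0 + pi}
            window = d <= hw
        img += np.where(window, radial, 0.0)

    if spec.beamstop_radius > 0:
        img[r < spec.beamstop_radius] = 0.0

    if spec.pi_symmetric and L % 2 == 1:
        # enforce bit-exact 180-degree rotation invariance on the odd grid
        img = 0.5 * (img + _rot180(img))

    peak = img.max()
    if peak <= 0:
        raise ParameterError("phantom is identically zero; nothing to normalise")
    return img / peak


def add_gaussian_noise(
    f0,
    mean: float = 0.0,
    variance: float = 0.05,
    seed: int = 0,
    clip: bool = True,
) -> np.ndarray:
    """Add i.i.d. Gaussian noise of the given mean and variance per pixel."""
    f0 = validate_field(f0, "f0")
    if variance < 0:
        raise ParameterError("variance must be non-negative")
    rng = np.random.default_rng(seed)
    out = f0 + rng.normal(mean, math.sqrt(variance), size=f0.shape)
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def add_poisson_noise(
    f0,
    max_counts: int = 1000,
    seed: int = 0,
    preserve_scale: bool = False,
) -> np.ndarray:
    """Poisson counting noise: counts n ~ Poisson(f0 * max_counts).

    By default the counts are re-normalised by their observed maximum
    (mirroring the per-image rescaling used when comparing exposures of very
    different integration times); ``preserve_scale`` divides by
    ``max_counts`` instead, keeping the intensity scale linear in f0.
    """
    f0 = validate_field(f0, "f0")
    if np.any(f0 < 0):
        raise InvalidInputError("poisson noise requires non-negative intensities")
    if max_counts < 1:
        raise ParameterError("max_counts must be >= 1")
    rng = np.random.default_rng(seed)
    n = rng.poisson(f0 * max_counts).astype(np.float64)
    if preserve_scale:
        return n / max_counts
    peak = n.max()
    if peak == 0:
        return np.zeros_like(f0)
    return n / peak
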