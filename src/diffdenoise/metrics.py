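"""Image-quality figures of merit: PSNR, SSIM, and the signed difference map.

PSNR here is the standard peak signal-to-noise ratio

    PSNR = 20 * log10( max(ref) / RMSE ),   RMSE = sqrt(mean (u - ref)^2)

in decibels, with the peak taken from the noiseless reference (pass
``dynamic_range=1.0`` explicitly to score [0,1] images against the unit
peak instead).  SSIM follows the Wang et al. reference implementation:
mean local structural similarity over an 11x11 Gaussian window with
sigma = 1.5, K1 = 0.01, K2 = 0.03 and weighted (population) covariances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity as _sk_ssim

from .core import validate_field, _check_same_shape
from .exceptions import InvalidInputError, ParameterError, ShapeError

__all__ = ["MetricReport", "psnr", "ssim", "difference_map", "report"]

#: SSIM window parameters of the reference implementation
SSIM_WIN_SIZE = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03


@dataclass
class MetricReport:
    """PSNR/SSIM/MSE summary of one image pair."""

    psnr_db: float
    ssim: float
    mse: float
    peak: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "psnr_db": self.psnr_db,
                "ssim": self.ssim,
                "mse": self.mse,
                "peak": self.peak,
            }
        )


def psnr(u, ref) -> float:
    """Peak signal-to-noise ratio of u against the reference, in dB.

    Returns ``math.inf`` (a documented sentinel, not an error) when the
    images are identical, so metric traces on clean inputs do not abort.
    """
    u = validate_field(u, "u")
    ref = validate_field(ref, "ref")
    _check_same_shape(u, ref, "psnr")
    peak = float(ref.max())
    if peak <= 0:
        raise InvalidInputError("psnr: reference has non-positive peak")
    mse = float(np.mean((u - ref) ** 2))
    if mse == 0.0:
        return math.inf
    return 20.0 * math.log10(peak / math.sqrt(mse))


def ssim(u, ref, dynamic_range: "float | None" = None) -> float:
    """Mean structural similarity with the reference-implementation defaults.

    ``dynamic_range`` defaults to ``max(ref)`` to mirror the PSNR peak
    convention; pass 1.0 to treat inputs as full-range [0,1] images.
    """
    u = validate_field(u, "u")
    ref = validate_field(ref, "ref")
    _check_same_shape(u, ref, "ssim")
    if dynamic_range is None:
        dynamic_range = float(ref.max())
    if dynamic_range <= 0:
        raise ParameterError("dynamic_range must be positive")
    if min(u.shape) < SSIM_WIN_SIZE:
        raise ShapeError(
            f"ssim: image {u.shape} smaller than the {SSIM_WIN_SIZE}x"
            f"{SSIM_WIN_SIZE} window"
        )
    return float(
        _sk_ssim(
            ref,
            u,
            data_range=dynamic_range,
            gaussian_weights=True,
            sigma=SSIM_SIGMA,
            win_size=SSIM_WIN_SIZE,
            use_sample_covariance=False,
            K1=SSIM_K1,
            K2=SSIM_K2,
        )
    )


def difference_map(u, ref) -> np.ndarray:
    """Signed per-pixel difference ratio (u - ref) / max(ref)."""
    u = validate_field(u, "u")
    ref = validate_field(ref, "ref")
    _check_same_shape(u, ref, "difference_map")
    peak = float(ref.max())
    if peak <= 0:
        raise InvalidInputError("difference_map: reference has non-positive peak")
    return (u - ref) / peak


def report(u, ref, dynamic_range: "float | None" = None) -> MetricReport:
    """Full :class:`MetricReport` for an image pair."""
    u = validate_field(u, "u")
    ref = validate_field(ref, "ref")
    _check_same_shape(u, ref, "report")
    return MetricReport(
        psnr_db=psnr(u, ref),
        ssim=ssim(u, ref, dynamic_range),
        mse=float(np.mean((u - ref) ** 2)),
        peak=float(ref.max()),
    )
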