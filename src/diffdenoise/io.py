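"""Raster I/O and run configuration.

Grayscale rasters are exchanged as 8/16-bit PNG or TIFF, or as lossless
float NPY.  Orientation is fixed throughout the package: row-major arrays,
row 0 at the top, (row, col) = (y, x) — diffraction frames are frequently
transposed between tools, so the convention is part of the contract.

Integer formats are quantised with round-half-up after clipping to [0, 1];
``npy_float`` round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .core import SolverConfig, validate_field
from .exceptions import FormatError, ParameterError
from .phantom import NoiseSpec, PhantomSpec

__all__ = ["FORMATS", "read_image", "write_image", "RunConfig"]

FORMATS = ("png8", "png16", "tiff8", "tiff16", "npy_float")

_SUFFIX_DEFAULT = {
    ".png": "png8",
    ".tif": "tiff16",
    ".tiff": "tiff16",
    ".npy": "npy_float",
}


def _infer_format(path: Path, fmt: "str | None") -> str:
    if fmt is not None:
        if fmt not in FORMATS:
            raise FormatError(f"unknown format {fmt!r}; expected one of {FORMATS}")
        return fmt
    try:
        return _SUFFIX_DEFAULT[path.suffix.lower()]
    except KeyError:
        raise FormatError(
            f"cannot infer format from suffix {path.suffix!r}; pass fmt explicitly"
        ) from None


def read_image(path, normalization: str = "by_bit_depth", flatten: bool = False) -> np.ndarray:
    """Read a grayscale raster as a float64 field.

    normalization:
      * ``by_bit_depth`` — divide integer data by 255 (8-bit) or 65535 (16-bit);
      * ``by_max``       — divide by the image maximum (the per-image rescaling
        used when comparing detector exposures of different integration times);
      * ``none``         — raw values.

    Multi-channel images are rejected unless ``flatten`` is set, in which
    case channels are averaged.
    """
    path = Path(path)
    if normalization not in ("by_bit_depth", "by_max", "none"):
        raise ParameterError(f"unknown normalization {normalization!r}")

    if path.suffix.lower() == ".npy":
        arr = np.load(path)
        if not np.issubdtype(arr.dtype, np.floating):
            raise FormatError(f"npy raster must be float, got {arr.dtype}")
        bit_scale = None
    else:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
        if arr.dtype == np.uint8:
            bit_scale = 255.0
        elif arr.dtype in (np.uint16, np.int32):  # PIL yields I;16 as int32
            bit_scale = 65535.0
        else:
            raise FormatError(f"unsupported raster dtype {arr.dtype}")

    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        if not flatten:
            raise FormatError(
                f"{path.name} is multi-channel ({arr.shape[2]} channels); "
                "pass flatten=True to average channels"
            )
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected a 2-D raster, got shape {arr.shape}")

    if normalization == "by_bit_depth":
        if bit_scale is None:
            raise FormatError("by_bit_depth normalization is undefined for float NPY")
        arr = arr / bit_scale
    elif normalization == "by_max":
        peak = arr.max()
        if peak > 0:
            arr = arr / peak
    return arr


def _quantize(field_arr: np.ndarray, maxval: int) -> np.ndarray:
    # round-half-up after clipping; out-of-range values saturate
    return np.floor(np.clip(field_arr, 0.0, 1.0) * maxval + 0.5).astype(
        np.uint8 if maxval == 255 else np.uint16
    )


def write_image(field_arr, path, fmt: "str | None" = None) -> None:
    """Write a float field to disk; format inferred from the suffix unless given."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "npy_float":
        np.save(path, np.asarray(field_arr, dtype=np.float64))
        return
    field_arr = validate_field(field_arr, "image")
    if fmt in ("png8", "tiff8"):
        q = _quantize(field_arr, 255)
    else:
        q = _quantize(field_arr, 65535)
    if fmt.startswith("png"):
        Image.fromarray(q).save(path, format="PNG")
    else:
        tifffile.imwrite(path, q)


@dataclass
class RunConfig:
    """Flat JSON-serialisable description of one denoising run."""

    solver: SolverConfig = field(default_factory=SolverConfig)
    noise: "NoiseSpec | None" = None
    phantom: "PhantomSpec | None" = None
    input_path: "str | None" = None
    output_path: "str | None" = None
    reference_path: "str | None" = None
    normalization: str = "by_bit_depth"
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = {
            "solver": asdict(self.solver),
            "noise": None if self.noise is None else asdict(self.noise),
            "phantom": None if self.phantom is None else asdict(self.phantom),
            "input_path": self.input_path,
            "output_path": self.output_path,
            "reference_path": self.reference_path,
            "normalization": self.normalization,
            "log_level": self.log_level,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        d = json.loads(s)
        known = {
            "solver",
            "noise",
            "phantom",
            "input_path",
            "output_path",
            "reference_path",
            "normalization",
            "log_level",
        }
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown RunConfig keys: {sorted(unknown)}")
        solver = SolverConfig(**d.get("solver", {}))
        noise = None if d.get("noise") is None else NoiseSpec(**d["noise"])
        phantom = None if d.get("phantom") is None else PhantomSpec(**d["phantom"])
        return cls(
            solver=solver,
            noise=noise,
            phantom=phantom,
            input_path=d.get("input_path"),
            output_path=d.get("output_path"),
            reference_path=d.get("reference_path"),
            normalization=d.get("normalization", "by_bit_depth"),
            log_level=d.get("log_level", "INFO"),
        )
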