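"""Scikit-learn style wrapper around the diffusion solver.

:class:`DiffusionDenoiser` presents the solver as a transformer: hyper-
parameters in ``__init__`` (untouched by fit), ``get_params``/``set_params``
via ``BaseEstimator``, validation and fitted attributes (trailing
underscore) in :meth:`fit`, and denoising in :meth:`transform`.  Input may
be a single image ``(H, W)`` or a stack ``(n_images, H, W)``; the output
matches the input layout, so the estimator composes with sklearn
pipelines and parameter searches over image stacks.

``fit`` is cheap: for ``lambda_mode="auto_fixed_from_input"`` it freezes
the contrast scale from the (first) fitted image; otherwise it only
validates.  The denoiser is input-conditioned rather than trained, which
is the usual situation for filter-like transformers.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import core
from .core import SolverConfig, SolveTrace
from .exceptions import ShapeError

__all__ = ["DiffusionDenoiser", "denoise_image"]


class DiffusionDenoiser(TransformerMixin, BaseEstimator):
    """Biased anisotropic diffusion denoiser with a transformer interface.

    Parameters mirror :class:`~diffdenoise.core.SolverConfig`; see that class
    for the numerical contract.

    Attributes
    ----------
    lambda_fixed_ : float or None
        Contrast scale frozen from the fitted image when
        ``lambda_mode="auto_fixed_from_input"``, else None.
    n_images_in_ : int
        Number of images seen by fit.
    image_shape_ : tuple of int
        (H, W) of the fitted images.
    traces_ : list of SolveTrace
        Traces of the most recent :meth:`transform` call, one per image.

    Examples
    --------
    >>> from diffdenoise.phantom import make_cartoon_phantom, add_gaussian_noise
    >>> f0 = make_cartoon_phantom(128, seed=0)
    >>> f = add_gaussian_noise(f0, variance=0.05, seed=1)
    >>> den = DiffusionDenoiser(alpha=0.1, beta=0.3, n_steps=200)
    >>> u = den.fit_transform(f)
    >>> u.shape
    (128, 128)
    """

    def __init__(
        self,
        alpha: float = 0.1,
        beta: float = 0.06,
        dt: float = 1.0,
        dx: float = 1.0,
        lambda_mode: "str | float" = "auto_fixed_from_input",
        lambda_coeff: float = 0.9,
        lambda_floor: float = 1e-12,
        n_steps: int = 500,
        record_every: int = 10,
        patience: "int | None" = None,
    ):
        self.alpha = alpha
        self.beta = beta
        self.dt = dt
        self.dx = dx
        self.lambda_mode = lambda_mode
        self.lambda_coeff = lambda_coeff
        self.lambda_floor = lambda_floor
        self.n_steps = n_steps
        self.record_every = record_every
        self.patience = patience

    # -- helpers ----------------------------------------------------------
    def _as_stack(self, X) -> "tuple[np.ndarray, bool]":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            return X[None, ...], True
        if X.ndim == 3:
            return X, False
        raise ShapeError(
            f"expected an image (H, W) or a stack (n, H, W), got ndim={X.ndim}"
        )

    def _config(self, track_ssim: bool = False) -> SolverConfig:
        lambda_mode = self.lambda_mode
        if lambda_mode == "auto_fixed_from_input" and getattr(
            self, "lambda_fixed_", None
        ) is not None:
            lambda_mode = self.lambda_fixed_
        return SolverConfig(
            alpha=self.alpha,
            beta=self.beta,
            dt=self.dt,
            dx=self.dx,
            lambda_mode=lambda_mode,
            lambda_coeff=self.lambda_coeff,
            lambda_floor=self.lambda_floor,
            n_steps=self.n_steps,
            record_every=self.record_every,
            track_ssim=track_ssim,
            patience=self.patience,
        )

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y=None):
        """Validate parameters and, if requested, freeze lambda from X."""
        stack, _ = self._as_stack(X)
        for img in stack:
            core.validate_field(img, "X")
        self._config()  # parameter validation via SolverConfig
        self.n_images_in_ = stack.shape[0]
        self.image_shape_ = stack.shape[1:]
        if self.lambda_mode == "auto_fixed_from_input":
            self.lambda_fixed_ = core.estimate_lambda(
                stack[0], self.lambda_coeff, self.lambda_floor, self.dx
            )
        else:
            self.lambda_fixed_ = None
        return self

    def transform(self, X, reference=None) -> np.ndarray:
        """Denoise each image; traces are kept in ``traces_``.

        ``reference`` (same layout as X) enables PSNR tracking in the traces.
        """
        if not hasattr(self, "image_shape_"):
            raise AttributeError("DiffusionDenoiser is not fitted; call fit first")
        stack, single = self._as_stack(X)
        refs = None
        if reference is not None:
            refs, _ = self._as_stack(reference)
            if refs.shape != stack.shape:
                raise ShapeError("reference layout must match X")
        cfg = self._config(track_ssim=reference is not None)
        outs: "list[np.ndarray]" = []
        traces: "list[SolveTrace]" = []
        for i, img in enumerate(stack):
            u, trace = core.solve(
                img, cfg, reference=None if refs is None else refs[i]
            )
            outs.append(u)
            traces.append(trace)
        self.traces_ = traces
        out = np.stack(outs)
        return out[0] if single else out

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform(X, **kwargs)


def denoise_image(
    f,
    reference=None,
    **params,
) -> "tuple[np.ndarray, SolveTrace]":
    """One-call functional façade: denoise a single image.

    Keyword arguments are :class:`DiffusionDenoiser` parameters.  Returns
    the denoised image and its solve trace.
    """
    den = DiffusionDenoiser(**params)
    u = den.fit(f).transform(f, reference=reference)
    return u, den.traces_[0]
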