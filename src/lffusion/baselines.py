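"""Richardson-Lucy deconvolution baseline for both modalities.

The RL iteration is the classic multiplicative maximum-likelihood update for
Poisson-like data,

    x_{k+1} = x_k * A^T( m / (A x_k) ) / A^T(1),

where ``A`` is the linear forward projector of the chosen modality and
``A^T`` its exact adjoint (matched transpose, built from the same operators).
Iterates stay non-negative and the Csiszar I-divergence between the
measurement and its reprojection is non-increasing.
"""

from __future__ import annotations

import numpy as np

from .forward import (
    FLFMViewStack,
    LightField4D,
    Volume3D,
    backproject_flfm,
    backproject_lfm,
    project_flfm,
    project_lfm,
)
from .optics import FLFMPSF, LFMPSF, InvalidConfigError

__all__ = ["rl_deconvolve", "i_divergence"]

_EPS = 1e-12


def i_divergence(measured: np.ndarray, reprojected: np.ndarray) -> float:
    """Csiszar I-divergence D(m || r) = sum m log(m/r) - m + r (>= 0)."""
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reprojected, dtype=float)
    pos = m > 0
    div = float(np.sum(r) - np.sum(m))
    div += float(np.sum(m[pos] * np.log(m[pos] / np.maximum(r[pos], _EPS))))
    return div


def rl_deconvolve(
    measurement,
    psf,
    n_iter: int,
    modality: str,
    init: np.ndarray | None = None,
    lenslet_stride: int = 1,
    volume_hw: tuple[int, int] | None = None,
) -> Volume3D:
    """Richardson-Lucy 3D deconvolution.

    ``modality`` is ``"lfm"`` (measurement: :class:`LightField4D` or its raw
    4D array) or ``"flfm"`` (measurement: :class:`FLFMViewStack`).  The volume
    is initialized uniform (or with ``init``) and updated multiplicatively for
    ``n_iter`` iterations.
    """
    if n_iter < 1:
        raise InvalidConfigError("n_iter must be >= 1")
    modality = modality.lower()
    if modality == "lfm":
        if not isinstance(psf, LFMPSF):
            raise InvalidConfigError("LFM deconvolution needs an LFMPSF")
        if psf.data.sum() <= 0:
            raise InvalidConfigError("PSF is identically zero")
        lf = measurement if isinstance(measurement, LightField4D) else LightField4D(measurement)
        if np.any(lf.data < 0):
            raise InvalidConfigError("measurement must be non-negative")
        n_z = psf.data.shape[0]
        if lenslet_stride > 1:
            hw = volume_hw or (
                lf.data.shape[2] * lenslet_stride,
                lf.data.shape[3] * lenslet_stride,
            )
        else:
            hw = (lf.data.shape[2], lf.data.shape[3])
        shape = (n_z, hw[0], hw[1])

        def fwd(x: Volume3D) -> np.ndarray:
            return project_lfm(x, psf, lenslet_stride=lenslet_stride).data

        def adj(y: np.ndarray) -> np.ndarray:
            return backproject_lfm(
                LightField4D(y), psf, lenslet_stride=lenslet_stride, volume_hw=hw
            ).data

        meas = lf.data
    elif modality == "flfm":
        if not isinstance(psf, FLFMPSF):
            raise InvalidConfigError("FLFM deconvolution needs an FLFMPSF")
        if not isinstance(measurement, FLFMViewStack):
            raise InvalidConfigError("FLFM measurement must be an FLFMViewStack")
        if np.any(measurement.data < 0):
            raise InvalidConfigError("measurement must be non-negative")
        n_z = psf.n_depths
        shape = (n_z, measurement.data.shape[1], measurement.data.shape[2])
        meta = measurement

        def fwd(x: Volume3D) -> np.ndarray:
            views, _ = project_flfm(x, psf, return_sensor=False)
            return views.data

        def adj(y: np.ndarray) -> np.ndarray:
            stack = FLFMViewStack(
                data=y,
                view_offsets=meta.view_offsets,
                view_centers_px=meta.view_centers_px,
            )
            return backproject_flfm(stack, psf).data

        meas = measurement.data
    else:
        raise InvalidConfigError(f"unknown modality {modality!r}")

    x = np.full(shape, max(float(meas.mean()), _EPS)) if init is None else init.copy()
    norm = adj(np.ones_like(meas))
    norm = np.maximum(norm, _EPS)
    for _ in range(n_iter):
        reproj = fwd(Volume3D(x))
        ratio = meas / np.maximum(reproj, _EPS)
        x = x * adj(ratio) / norm
        x = np.maximum(x, 0.0)
    return Volume3D(x)
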