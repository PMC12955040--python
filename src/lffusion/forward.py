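"""Project 3D volumes to LFM and FLFM sensor data.

The LFM projector convolves each depth slice of the volume with that depth's
per-view kernel and accumulates over depth, producing a 4D light field
``L(u, v, w, h)``; ``(u, v)`` index sensor pixels under a lenslet (views) and
``(w, h)`` the lenslet-scale spatial grid.  ``u`` is the angular coordinate
conjugate to the second spatial axis ``h``, ``v`` the one conjugate to ``w``.

The FLFM projector works in the frequency domain: each depth slice's spectrum
is multiplied by the depth's complex weight and frequency response, a per-view
phase ramp applies the depth-proportional parallax shift of that view, and the
sum over depths is transformed back.  Every factor is Hermitian-symmetric, so
the imaginary residue of the result is at rounding level and is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .optics import FLFMPSF, LFMPSF, InvalidConfigError

__all__ = [
    "Volume3D",
    "LightField4D",
    "FLFMViewStack",
    "project_lfm",
    "backproject_lfm",
    "project_flfm",
    "backproject_flfm",
    "lfm_views",
    "lfm_views_to_4d",
    "flfm_views",
]


@dataclass
class Volume3D:
    """Non-negative intensity volume, axis order (z, y, x), voxel size in um."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidConfigError("volume must be 3D (z, y, x)")
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("volume contains non-finite values")
        if np.any(self.data < 0):
            raise InvalidConfigError("volume intensities must be non-negative")

    @property
    def n_z(self) -> int:
        return self.data.shape[0]


@dataclass
class LightField4D:
    """4D light field L(u, v, w, h); angular axes (u, v), spatial axes (w, h)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InvalidConfigError("light field must be 4D (u, v, w, h)")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]


@dataclass
class FLFMViewStack:
    """Seven FLFM sub-aperture views in 2-3-2 row order, plus view metadata."""

    data: np.ndarray  # (n_views, y, x)
    view_offsets: np.ndarray  # (n_views, 2) in pitch units, (row, col)
    view_centers_px: np.ndarray  # (n_views, 2) on the sensor canvas, (y, x)
    clipped_mass: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidConfigError("view stack must be (n_views, y, x)")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# LFM projection
# ---------------------------------------------------------------------------


def _lfm_kernel_ffts(psf: LFMPSF, fshape: tuple[int, int]) -> np.ndarray:
    """rfft2 of every (z, u, v) kernel at the padded shape, laid out
    (z, u, v, fy, fx) with the convention u = kernel column axis."""
    nz, ms, _, nn, _ = psf.data.shape
    # kernel for view (u, v): v indexes sensor-pixel rows, u sensor-pixel cols
    kernels = psf.data.transpose(0, 4, 3, 1, 2)  # (z, u, v, s_y, s_x)
    return sfft.rfft2(kernels, fshape, axes=(3, 4))


def project_lfm(
    vol: Volume3D, psf: LFMPSF, lenslet_stride: int = 1
) -> LightField4D:
    """Light field of a volume: per-depth, per-view 2D convolution.

    ``L[u, v] = sum_z vol[z] * K[z, u, v]`` with 'same'-size FFT convolution
    (zero padding, output cropped about the kernel centre).  With
    ``lenslet_stride = m > 1`` the convolution output is sampled every m-th
    pixel (cell-centred), so the spatial axes (w, h) are lenslet indices —
    the physical sampling of an MLA whose pitch spans m volume voxels.
    """
    if vol.n_z != psf.data.shape[0]:
        raise InvalidConfigError(
            f"volume depth {vol.n_z} does not match PSF depth {psf.data.shape[0]}"
        )
    nz, ms, _, nn, _ = psf.data.shape
    ny, nx = vol.data.shape[1:]
    fy, fx = ny + ms - 1, nx + ms - 1
    fshape = (sfft.next_fast_len(fy), sfft.next_fast_len(fx))
    fk = _lfm_kernel_ffts(psf, fshape)  # (z, u, v, fy, fx)
    fv = sfft.rfft2(vol.data, fshape, axes=(1, 2))  # (z, fy, fx)
    acc = np.einsum("zuvyx,zyx->uvyx", fk, fv, optimize=True)
    full = sfft.irfft2(acc, fshape, axes=(2, 3))[:, :, :fy, :fx]
    lo_y, lo_x = (ms - 1) // 2, (ms - 1) // 2
    same = full[:, :, lo_y : lo_y + ny, lo_x : lo_x + nx]
    if lenslet_stride > 1:
        p0 = (lenslet_stride - 1) // 2
        same = same[:, :, p0::lenslet_stride, p0::lenslet_stride]
    return LightField4D(np.maximum(same, 0.0))


def backproject_lfm(
    lf: LightField4D, psf: LFMPSF, lenslet_stride: int = 1,
    volume_hw: tuple[int, int] | None = None,
) -> Volume3D:
    """Adjoint of :func:`project_lfm` (matched-transpose correlation).

    For strided projection the light field is scattered back onto the
    volume grid (zeros between lenslet samples) before correlating;
    ``volume_hw`` gives the target lateral size (required when the stride
    does not divide it evenly; defaults to ``stride * (w, h)``).
    """
    nz, ms, _, nn, _ = psf.data.shape
    nu, nv, wy, wx = lf.data.shape
    if lenslet_stride > 1:
        ny, nx = volume_hw if volume_hw else (wy * lenslet_stride, wx * lenslet_stride)
        p0 = (lenslet_stride - 1) // 2
        data = np.zeros((nu, nv, ny, nx))
        data[:, :, p0::lenslet_stride, p0::lenslet_stride] = lf.data
    else:
        ny, nx = wy, wx
        data = lf.data
    fy, fx = ny + ms - 1, nx + ms - 1
    fshape = (sfft.next_fast_len(fy), sfft.next_fast_len(fx))
    fk = _lfm_kernel_ffts(psf, fshape)
    # pad the light field so correlation mirrors the 'same' crop of the forward
    lo = (ms - 1) // 2
    buf = np.zeros((nu, nv, fy, fx))
    buf[:, :, lo : lo + ny, lo : lo + nx] = data
    fl = sfft.rfft2(buf, fshape, axes=(2, 3))
    acc = np.einsum("zuvyx,uvyx->zyx", np.conj(fk), fl, optimize=True)
    out = sfft.irfft2(acc, fshape, axes=(1, 2))[:, :ny, :nx]
    return Volume3D(np.maximum(out, 0.0))


# ---------------------------------------------------------------------------
# FLFM projection
# ---------------------------------------------------------------------------


def _flfm_view_spectra(vol_fft: np.ndarray, psf: FLFMPSF) -> np.ndarray:
    """Per-view spectra: sum_z w_z * F{I_z} * R_z * phase-ramp(view, z)."""
    n = psf.response.shape[1]
    f = np.fft.fftfreq(n)
    fyy, fxx = np.meshgrid(f, f, indexing="ij")
    nviews = psf.view_offsets.shape[0]
    out = np.zeros((nviews, n, n), dtype=complex)
    for iz, z in enumerate(psf.depth_grid_um):
        term = psf.weights[iz, 0, 0] * vol_fft[iz] * psf.response[iz]
        for i in range(nviews):
            sy = float(z) * psf.disparity_px_per_um * psf.view_offsets[i, 0]
            sx = float(z) * psf.disparity_px_per_um * psf.view_offsets[i, 1]
            ramp = np.exp(-2j * np.pi * (fyy * sy + fxx * sx))
            out[i] += term * ramp
    return out


def project_flfm(
    vol: Volume3D, psf: FLFMPSF, return_sensor: bool = True
) -> tuple[FLFMViewStack, np.ndarray | None]:
    """FLFM sub-aperture views (and mosaic sensor image) of a volume.

    Each depth slice is zero-padded onto the PSF canvas; its spectrum is
    multiplied by ``w(z) * R(fx, fy, z)`` and, per view, by the phase ramp of
    that view's depth-proportional parallax shift.  The inverse transform is
    real to rounding (every factor is Hermitian-symmetric); negative values
    are clipped and the clipped mass recorded.
    """
    if vol.n_z != psf.n_depths:
        raise InvalidConfigError(
            f"volume depth {vol.n_z} does not match PSF depth {psf.n_depths}"
        )
    n = psf.response.shape[1]
    ny, nx = vol.data.shape[1:]
    if ny > n or nx > n:
        raise InvalidConfigError("volume lateral extent exceeds the PSF canvas")
    lo_y, lo_x = (n - ny) // 2, (n - nx) // 2
    canvas = np.zeros((vol.n_z, n, n))
    canvas[:, lo_y : lo_y + ny, lo_x : lo_x + nx] = vol.data
    vol_fft = np.fft.fft2(canvas, axes=(1, 2))
    spectra = _flfm_view_spectra(vol_fft, psf)
    imgs = np.fft.ifft2(spectra, axes=(1, 2))
    scale = np.max(np.abs(imgs)) or 1.0
    resid = float(np.max(np.abs(imgs.imag)) / scale)
    if resid > 1e-8:
        raise FloatingPointError(f"imaginary residue {resid:.2e} exceeds 1e-8")
    real = imgs.real
    clipped = float(-np.sum(real[real < 0]))
    real = np.maximum(real, 0.0)
    views = real[:, lo_y : lo_y + ny, lo_x : lo_x + nx]
    stack = FLFMViewStack(
        data=views,
        view_offsets=psf.view_offsets.copy(),
        view_centers_px=psf.view_centers_px.copy(),
        clipped_mass=clipped,
    )
    sensor = _assemble_sensor(stack) if return_sensor else None
    return stack, sensor


def backproject_flfm(views: FLFMViewStack, psf: FLFMPSF) -> Volume3D:
    """Adjoint of :func:`project_flfm` restricted to the view-stack output."""
    n = psf.response.shape[1]
    nviews, ny, nx = views.data.shape
    lo_y, lo_x = (n - ny) // 2, (n - nx) // 2
    canvas = np.zeros((nviews, n, n))
    canvas[:, lo_y : lo_y + ny, lo_x : lo_x + nx] = views.data
    vfft = np.fft.fft2(canvas, axes=(1, 2))
    f = np.fft.fftfreq(n)
    fyy, fxx = np.meshgrid(f, f, indexing="ij")
    out = np.zeros((psf.n_depths, n, n))
    for iz, z in enumerate(psf.depth_grid_um):
        term = np.conj(psf.weights[iz, 0, 0] * psf.response[iz])
        acc = np.zeros((n, n), dtype=complex)
        for i in range(nviews):
            sy = float(z) * psf.disparity_px_per_um * psf.view_offsets[i, 0]
            sx = float(z) * psf.disparity_px_per_um * psf.view_offsets[i, 1]
            ramp = np.exp(2j * np.pi * (fyy * sy + fxx * sx))
            acc += vfft[i] * ramp
        out[iz] = np.fft.ifft2(term * acc).real
    vol = out[:, lo_y : lo_y + ny, lo_x : lo_x + nx]
    return Volume3D(np.maximum(vol, 0.0))


def _assemble_sensor(stack: FLFMViewStack) -> np.ndarray:
    """Mosaic sensor image: each view pasted about its sensor-canvas centre."""
    nviews, ny, nx = stack.data.shape
    centers = np.asarray(stack.view_centers_px, dtype=float)
    span_y = int(np.ceil(np.max(np.abs(centers[:, 0])))) + ny // 2 + 1
    span_x = int(np.ceil(np.max(np.abs(centers[:, 1])))) + nx // 2 + 1
    h, w = 2 * span_y, 2 * span_x
    sensor = np.zeros((h, w))
    for i in range(nviews):
        cy = h // 2 + int(round(centers[i, 0]))
        cx = w // 2 + int(round(centers[i, 1]))
        y0, x0 = cy - ny // 2, cx - nx // 2
        sensor[y0 : y0 + ny, x0 : x0 + nx] += stack.data[i]
    return sensor


# ---------------------------------------------------------------------------
# view rearrangement
# ---------------------------------------------------------------------------


def lfm_views(lf: LightField4D) -> np.ndarray:
    """Channel stack (u*v, w, h) in row-major (u outer, v inner) order."""
    nu, nv, nw, nh = lf.data.shape
    return lf.data.reshape(nu * nv, nw, nh)


def lfm_views_to_4d(stack: np.ndarray, n_u: int) -> LightField4D:
    """Inverse of :func:`lfm_views`; bit-exact."""
    c, nw, nh = stack.shape
    if c % n_u:
        raise InvalidConfigError("channel count is not a multiple of n_u")
    return LightField4D(stack.reshape(n_u, c // n_u, nw, nh))


def flfm_views(sensor: np.ndarray, stack_meta: FLFMViewStack, crop: int) -> FLFMViewStack:
    """Crop seven equal windows from a sensor mosaic, 2-3-2 top-left to
    bottom-right order, using the view centres recorded in ``stack_meta``."""
    h, w = sensor.shape
    centers = np.asarray(stack_meta.view_centers_px, dtype=float)
    out = np.zeros((centers.shape[0], crop, crop))
    for i in range(centers.shape[0]):
        cy = h // 2 + int(round(centers[i, 0]))
        cx = w // 2 + int(round(centers[i, 1]))
        y0, x0 = cy - crop // 2, cx - crop // 2
        if y0 < 0 or x0 < 0 or y0 + crop > h or x0 + crop > w:
            raise InvalidConfigError(f"view {i} crop window falls outside the sensor")
        out[i] = sensor[y0 : y0 + crop, x0 : x0 + crop]
    return FLFMViewStack(
        data=out,
        view_offsets=stack_meta.view_offsets.copy(),
        view_centers_px=centers.copy(),
    )
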