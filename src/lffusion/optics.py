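"""Wave-optics primitives and PSF computation for LFM and FLFM.

Scalar diffraction model: the focal field of the objective is computed with a
Debye integral over the aperture half-angle, microlens arrays are thin phase
masks, and free-space propagation uses the band-limited angular-spectrum
method.  Two point-spread functions are produced:

* LFM: a 5D intensity tensor ``(z, s_y, s_x, u, v)`` — for every depth and
  every sub-lenslet source offset, the sensor response in the ``N_num x N_num``
  pixel window of the central lenslet.
* FLFM: a per-depth frequency-domain response plus a complex scalar weight
  ``w(z)`` per depth; the product ``w(z) * R(fx, fy, z)`` is the Hermitian
  optical transfer function of that depth, so projected images are real.

All lengths are micrometres unless a field name says otherwise; wavelengths
are tagged in nanometres.  Square grids have their origin on the sample with
index ``N // 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j0

__all__ = [
    "InvalidConfigError",
    "ConvergenceError",
    "OpticalConfig",
    "MLAConfig",
    "ApertureProfile",
    "ComplexField2D",
    "LFMPSF",
    "FLFMPSF",
    "ApertureOptState",
    "grid_coords",
    "debye_wavefront",
    "debye_radial",
    "aperture_profile",
    "apply_aperture",
    "mla_transmission",
    "angular_spectrum_propagate",
    "flfm_bandlimit",
    "aperture_objective",
    "aperture_gradient",
    "optimize_aperture",
    "compute_lfm_psf",
    "compute_flfm_psf",
    "lfm_reference_config",
    "flfm_reference_config",
    "lfm_desk_config",
    "flfm_desk_config",
]


class InvalidConfigError(ValueError):
    """Raised when an optical or MLA configuration violates its invariants."""


class ConvergenceError(RuntimeError):
    """Raised when aperture optimization cannot find a descent step."""

    def __init__(self, message: str, history: Sequence[float]):
        super().__init__(message)
        self.history = list(history)


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalConfig:
    """Objective / sampling parameters of one imaging arm.

    ``depth_grid_um`` is the uniform, strictly ascending list of source depths
    (axial positions relative to the native focal plane).  ``lateral_spacing_um``
    and ``lateral_extent_px`` define the square simulation grid at the plane
    where fields are evaluated (native image plane for LFM).
    """

    numerical_aperture: float
    magnification: float
    wavelength_nm: float
    refractive_index: float
    sensor_pixel_pitch_um: float
    depth_grid_um: np.ndarray
    lateral_spacing_um: float
    lateral_extent_px: int

    def __post_init__(self):
        z = np.asarray(self.depth_grid_um, dtype=float)
        object.__setattr__(self, "depth_grid_um", z)
        if not self.numerical_aperture < self.refractive_index:
            raise InvalidConfigError(
                f"NA ({self.numerical_aperture}) must be < refractive index "
                f"({self.refractive_index})"
            )
        if self.wavelength_nm <= 0:
            raise InvalidConfigError("wavelength must be positive")
        if z.ndim != 1 or z.size < 1:
            raise InvalidConfigError("depth grid must be a 1D list of depths")
        if z.size > 1:
            dz = np.diff(z)
            if np.any(dz <= 0):
                raise InvalidConfigError("depth grid must be strictly increasing")
            if not np.allclose(dz, dz[0], rtol=1e-8, atol=0.0):
                raise InvalidConfigError("depth grid must be uniformly spaced")
        if self.lateral_extent_px <= 0 or self.lateral_extent_px % 2:
            raise InvalidConfigError("lateral extent must be a positive even integer")
        if self.lateral_spacing_um <= 0:
            raise InvalidConfigError("lateral spacing must be positive")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    @property
    def n_depths(self) -> int:
        return int(self.depth_grid_um.size)

    @property
    def aperture_half_angle(self) -> float:
        return float(np.arcsin(self.numerical_aperture / self.refractive_index))


@dataclass(frozen=True)
class MLAConfig:
    """Microlens-array geometry; relay lenses only matter for the Fourier arm."""

    pitch_um: float
    focal_length_um: float
    pixels_per_lenslet: int
    f_number: float | None = None
    relay_f1_mm: float | None = None
    relay_f2_mm: float | None = None

    def __post_init__(self):
        for name in ("pitch_um", "focal_length_um"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.pixels_per_lenslet < 1 or self.pixels_per_lenslet % 2 == 0:
            raise InvalidConfigError(
                "pixels_per_lenslet must be odd so a central view exists"
            )

    @property
    def relay_magnification(self) -> float:
        if self.relay_f1_mm and self.relay_f2_mm:
            return self.relay_f2_mm / self.relay_f1_mm
        return 1.0


@dataclass
class ApertureProfile:
    """Sampled transmission of a (super-Gaussian) pupil mask, values in [0, 1]."""

    cutoff: float
    order: float
    transmission: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        self.transmission = np.asarray(self.transmission, dtype=float)
        if self.cutoff <= 0:
            raise InvalidConfigError("aperture cutoff must be positive")
        if np.any(self.transmission < -1e-12) or np.any(self.transmission > 1 + 1e-12):
            raise InvalidConfigError("transmission must lie in [0, 1]")


@dataclass
class ComplexField2D:
    """Complex scalar wavefront sampled on a uniform square (y, x) grid."""

    data: np.ndarray
    spacing_um: float
    wavelength_nm: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise InvalidConfigError("field grid must be square")
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("field contains non-finite values")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def energy(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))


@dataclass
class LFMPSF:
    """5D LFM intensity response ``(z, s_y, s_x, u, v)``.

    ``(s_y, s_x)`` index sub-lenslet source offsets covering one microlens
    pitch; ``(u, v)`` are sensor pixels under the central lenslet.  Each depth
    slice is normalized to unit sum so forward projection conserves flux per
    plane.
    """

    data: np.ndarray
    depth_grid_um: np.ndarray
    offset_spacing_um: float
    sensor_pixel_pitch_um: float

    def __post_init__(self):
        if self.data.ndim != 5:
            raise InvalidConfigError("LFM PSF must be 5D (z, s_y, s_x, u, v)")
        if np.any(self.data < 0):
            raise InvalidConfigError("LFM PSF entries must be non-negative")
        if self.data.shape[0] != len(self.depth_grid_um):
            raise InvalidConfigError("depth axis must match the depth grid")

    @property
    def n_views(self) -> int:
        return self.data.shape[3]


@dataclass
class FLFMPSF:
    """Per-depth FLFM frequency response with complex depth weights.

    ``response[z]`` is a complex 2D spectrum; the effective Hermitian transfer
    function of depth ``z`` is ``weights[z] * response[z]``, whose inverse DFT
    is the real, non-negative intensity PSF of that plane.  ``view_offsets``
    are the seven lenslet positions of the 2-3-2 layout in units of the MLA
    pitch, ``view_centers_px`` their sensor-pixel positions, and
    ``disparity_px_per_um`` the per-view lateral image shift per micrometre of
    depth (the parallax gain).
    """

    response: np.ndarray  # (n_z, N, N) complex
    weights: np.ndarray  # (n_z, 1, 1) complex
    depth_grid_um: np.ndarray
    view_offsets: np.ndarray  # (7, 2) in pitch units, (row, col)
    view_centers_px: np.ndarray  # (7, 2) float pixels, (y, x)
    disparity_px_per_um: float
    spacing_um: float

    def __post_init__(self):
        if self.weights.shape != (len(self.depth_grid_um), 1, 1):
            raise InvalidConfigError("weights must be shaped (n_z, 1, 1)")
        if self.response.shape[0] != len(self.depth_grid_um):
            raise InvalidConfigError("response depth axis must match depth grid")

    @property
    def n_depths(self) -> int:
        return int(len(self.depth_grid_um))

    def depth_psf(self, k: int) -> np.ndarray:
        """Real intensity PSF of depth plane ``k`` (inverse DFT of w*R)."""
        img = np.fft.ifft2(self.weights[k, 0, 0] * self.response[k])
        scale = np.max(np.abs(img)) or 1.0
        if np.max(np.abs(img.imag)) > 1e-8 * scale:
            raise InvalidConfigError("depth response is not Hermitian")
        return np.fft.fftshift(img.real)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def grid_coords(n: int, spacing: float) -> np.ndarray:
    """1D coordinates of a square grid with the origin at index ``n // 2``."""
    return (np.arange(n) - n // 2) * float(spacing)


def debye_radial(
    config: OpticalConfig,
    source_depth_um: float,
    radii_um: np.ndarray,
    apodization: Callable[[np.ndarray], np.ndarray] | None = None,
    n_nodes: int = 256,
) -> np.ndarray:
    """Debye scalar integral evaluated at object-space radii.

    Ub(r) = int_0^theta_max Uo(theta) J0(2 pi r sin(theta) / lambda)
            sin(theta) d(theta)

    with the defocus of the source depth folded into
    Uo(theta) = apod(theta) * exp(i k n z cos(theta)), k = 2 pi / lambda.
    Gauss-Legendre quadrature with ``n_nodes`` nodes over [0, theta_max].
    """
    if config.numerical_aperture >= config.refractive_index:
        raise InvalidConfigError("NA must be smaller than the immersion index")
    theta_max = config.aperture_half_angle
    if theta_max <= 0:
        return np.zeros_like(np.asarray(radii_um, dtype=float), dtype=complex)
    nodes, wts = leggauss(n_nodes)
    theta = 0.5 * theta_max * (nodes + 1.0)
    wts = 0.5 * theta_max * wts
    lam = config.wavelength_um
    k = 2.0 * np.pi / lam
    uo = np.exp(
        1j * k * config.refractive_index * source_depth_um * np.cos(theta)
    )
    if apodization is not None:
        uo = uo * apodization(theta)
    weights = wts * uo * np.sin(theta)
    r = np.asarray(radii_um, dtype=float)
    bessel = j0((2.0 * np.pi / lam) * np.outer(r.ravel(), np.sin(theta)))
    out = bessel @ weights
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("Debye quadrature produced non-finite values")
    return out.reshape(r.shape)


def debye_wavefront(
    config: OpticalConfig,
    source_depth_um: float,
    center_um: tuple[float, float] = (0.0, 0.0),
    apodization: Callable[[np.ndarray], np.ndarray] | None = None,
    n_nodes: int = 256,
) -> ComplexField2D:
    """Focal field of a point source at the given depth, on the config grid.

    The grid lives at the native image plane; lateral coordinates are referred
    back to object space through the magnification, so the returned pattern is
    the (magnified) Debye focal spot centred at ``center_um`` (image-plane
    micrometres).  The field is radially symmetric about that centre.
    """
    zmin = float(config.depth_grid_um.min())
    zmax = float(config.depth_grid_um.max())
    pad = max(abs(zmax - zmin), 1.0)
    if not (zmin - pad <= source_depth_um <= zmax + pad):
        raise InvalidConfigError("source depth far outside the configured range")
    n = config.lateral_extent_px
    c = grid_coords(n, config.lateral_spacing_um)
    yy, xx = np.meshgrid(c - center_um[0], c - center_um[1], indexing="ij")
    r_img = np.hypot(yy, xx)
    r_obj = r_img / config.magnification
    # evaluate on unique radii only; equal radii get bit-identical values
    uniq, inv = np.unique(np.round(r_obj, 12), return_inverse=True)
    vals = debye_radial(config, source_depth_um, uniq, apodization, n_nodes)
    data = vals[inv].reshape(r_obj.shape)
    return ComplexField2D(data, config.lateral_spacing_um, config.wavelength_nm)


def aperture_profile(rho_grid: np.ndarray, cutoff: float, order: float) -> ApertureProfile:
    """Super-Gaussian transmission ``exp(-(rho/cutoff)**(2*order))``.

    ``rho_grid`` is a normalized radial coordinate (any non-negative array);
    ``order >= 1`` sharpens the roll-off toward an ideal disk as it grows.
    """
    if cutoff <= 0:
        raise InvalidConfigError("cutoff must be positive")
    if order < 1:
        raise InvalidConfigError("order must be >= 1")
    rho = np.asarray(rho_grid, dtype=float)
    trans = np.exp(-((rho / cutoff) ** (2.0 * order)))
    return ApertureProfile(cutoff=cutoff, order=order, transmission=trans, rho=rho)


def apply_aperture(fld: ComplexField2D, profile: ApertureProfile) -> ComplexField2D:
    """Pointwise pupil clipping ``U * P``; contracts energy since P in [0,1]."""
    if fld.data.shape != profile.transmission.shape:
        raise ValueError(
            f"grid mismatch: field {fld.data.shape} vs profile "
            f"{profile.transmission.shape}"
        )
    return ComplexField2D(
        fld.data * profile.transmission, fld.spacing_um, fld.wavelength_nm
    )


def mla_transmission(
    mla: MLAConfig,
    spacing_um: float,
    extent_px: int,
    wavelength_nm: float,
) -> ComplexField2D:
    """Periodic thin-lens phase mask of the microlens array.

    Each tile carries ``exp(-i pi (x'^2 + y'^2) / (lambda f_ml))`` about its
    lenslet centre; one lenslet is centred on the grid origin.
    """
    d = mla.pitch_um
    if d < 2 * spacing_um:
        raise InvalidConfigError("MLA pitch undersampled: pitch < 2 grid samples")
    ratio = d / spacing_um
    if abs(ratio - round(ratio)) > 0.005 * ratio:
        raise InvalidConfigError(
            "grid spacing must divide the MLA pitch to within 0.5%"
        )
    c = grid_coords(extent_px, spacing_um)
    local = np.mod(c + d / 2.0, d) - d / 2.0
    yy, xx = np.meshgrid(local, local, indexing="ij")
    lam_um = wavelength_nm * 1e-3
    phase = -np.pi * (xx**2 + yy**2) / (lam_um * mla.focal_length_um)
    return ComplexField2D(np.exp(1j * phase), spacing_um, wavelength_nm)


def angular_spectrum_propagate(
    fld: ComplexField2D, distance_um: float, pad: bool = False
) -> ComplexField2D:
    """Band-limited angular-spectrum propagation over ``distance_um``.

    The transfer function is ``exp(i 2 pi / lambda * d * sqrt(1 - (lambda fx)^2
    - (lambda fy)^2))`` with evanescent components (negative radicand) zeroed.
    Without padding the operator is exactly unitary on the propagating band;
    ``pad=True`` zero-pads to twice the extent to suppress wrap-around (used
    inside PSF pipelines) and crops back.
    """
    lam = fld.wavelength_nm * 1e-3
    data = fld.data
    n0 = data.shape[0]
    if pad:
        n = 2 * n0
        buf = np.zeros((n, n), dtype=complex)
        lo = n0 // 2
        buf[lo : lo + n0, lo : lo + n0] = data
        data = buf
    n = data.shape[0]
    f = np.fft.fftfreq(n, d=fld.spacing_um)
    fy, fx = np.meshgrid(f, f, indexing="ij")
    arg = 1.0 - (lam * fx) ** 2 - (lam * fy) ** 2
    band = arg > 0.0
    kernel = np.zeros_like(arg, dtype=complex)
    kernel[band] = np.exp(
        1j * (2.0 * np.pi / lam) * distance_um * np.sqrt(arg[band])
    )
    out = np.fft.ifft2(np.fft.fft2(data) * kernel)
    if pad:
        lo = n0 // 2
        out = out[lo : lo + n0, lo : lo + n0]
    return ComplexField2D(out, fld.spacing_um, fld.wavelength_nm)


def _sinc_filter_response(n: int, spacing_um: float, cutoff: float) -> np.ndarray:
    """Ideal frequency response of the continuous ``sinc(2 rho / cutoff)``
    anti-aliasing kernel: unity inside the radial frequency ``1 / cutoff``,
    zero outside (DC gain 1).

    Built directly in the frequency domain: a truncated sampled spatial
    kernel would carry a band-edge boost and ringing that contradict the
    filter's suppression role.
    """
    f = np.fft.fftfreq(n, d=spacing_um)
    fy, fx = np.meshgrid(f, f, indexing="ij")
    return (np.hypot(fy, fx) <= 1.0 / cutoff).astype(float)


def flfm_bandlimit(fld: ComplexField2D, cutoff: float) -> ComplexField2D:
    """Anti-aliasing band-limit: suppress spatial frequencies beyond the
    radial cutoff ``1 / cutoff`` (the band of the sinc(2 rho / cutoff)
    kernel); exactly idempotent, DC gain 1."""
    if cutoff <= 0:
        raise InvalidConfigError("bandlimit cutoff must be positive")
    resp = _sinc_filter_response(fld.n, fld.spacing_um, cutoff)
    out = np.fft.ifft2(np.fft.fft2(fld.data) * resp)
    return ComplexField2D(out, fld.spacing_um, fld.wavelength_nm)


# ---------------------------------------------------------------------------
# aperture optimization
# ---------------------------------------------------------------------------


@dataclass
class ApertureOptState:
    """State of the gradient-descent refinement of the pupil transmission.

    The forward model is a single Fourier relation: the simulated PSF is
    ``|IDFT(U * P)|^2`` (orthonormal DFT) for the fixed base wavefront ``U``.
    The objective is ``J(P) = ||PSF_target - PSF_sim||_2^2 + lam1 * ||grad P||_1``
    with forward-difference gradients and subgradient 0 at ties.
    """

    profile: np.ndarray
    pupil_field: np.ndarray
    psf_target: np.ndarray
    eta: float = 1e-2
    lam1: float = 0.0
    j_history: list = field(default_factory=list)
    psf_sim: np.ndarray | None = None

    def __post_init__(self):
        if self.eta <= 0:
            raise InvalidConfigError("step size must be positive")
        if self.lam1 < 0:
            raise InvalidConfigError("regularization weight must be >= 0")


def _simulate_psf(pupil: np.ndarray, profile: np.ndarray) -> np.ndarray:
    amp = np.fft.ifft2(pupil * profile, norm="ortho")
    return np.abs(amp) ** 2


def _tv_l1(p: np.ndarray) -> float:
    return float(np.sum(np.abs(np.diff(p, axis=0))) + np.sum(np.abs(np.diff(p, axis=1))))


def _tv_l1_subgrad(p: np.ndarray) -> np.ndarray:
    g = np.zeros_like(p)
    dy = np.sign(np.diff(p, axis=0))
    dx = np.sign(np.diff(p, axis=1))
    g[1:, :] += dy
    g[:-1, :] -= dy
    g[:, 1:] += dx
    g[:, :-1] -= dx
    return g


def aperture_objective(state: ApertureOptState, profile: np.ndarray | None = None) -> float:
    p = state.profile if profile is None else profile
    sim = _simulate_psf(state.pupil_field, p)
    data = float(np.sum((state.psf_target - sim) ** 2))
    return data + state.lam1 * _tv_l1(p)


def aperture_gradient(state: ApertureOptState, profile: np.ndarray | None = None) -> np.ndarray:
    """Analytic gradient of J with respect to the (real) profile."""
    p = state.profile if profile is None else profile
    amp = np.fft.ifft2(state.pupil_field * p, norm="ortho")
    sim = np.abs(amp) ** 2
    resid = sim - state.psf_target
    back = np.fft.fft2(resid * amp, norm="ortho")
    grad = 4.0 * np.real(np.conj(state.pupil_field) * back)
    if state.lam1 > 0:
        grad = grad + state.lam1 * _tv_l1_subgrad(p)
    return grad


def optimize_aperture(state: ApertureOptState, n_iter: int) -> ApertureOptState:
    """Projected gradient descent on the pupil profile.

    Steps ``P <- clip(P - eta * grad J, 0, 1)`` are accepted only if J does not
    increase; otherwise the step is halved, up to 20 times, after which a
    ``ConvergenceError`` carrying the J history is raised.
    """
    p = state.profile.astype(float).copy()
    eta = state.eta
    hist = list(state.j_history)
    j_cur = aperture_objective(state, p)
    if not hist:
        hist.append(j_cur)
    for _ in range(n_iter):
        g = aperture_gradient(state, p)
        if np.max(np.abs(g)) == 0.0:
            hist.append(j_cur)
            continue
        step = eta
        for _half in range(21):
            cand = np.clip(p - step * g, 0.0, 1.0)
            j_new = aperture_objective(state, cand)
            if j_new <= j_cur:
                break
            step *= 0.5
        else:
            raise ConvergenceError("no descent step found after 20 halvings", hist)
        if j_new > j_cur:
            raise ConvergenceError("no descent step found after 20 halvings", hist)
        p, j_cur = cand, j_new
        hist.append(j_cur)
    return replace(
        state,
        profile=p,
        j_history=hist,
        psf_sim=_simulate_psf(state.pupil_field, p),
    )


# ---------------------------------------------------------------------------
# PSF computation
# ---------------------------------------------------------------------------


def _bin_sensor(intensity: np.ndarray, oversample: int) -> np.ndarray:
    n = intensity.shape[0]
    m = n // oversample
    return intensity[: m * oversample, : m * oversample].reshape(
        m, oversample, m, oversample
    ).sum(axis=(1, 3))


def compute_lfm_psf(
    config: OpticalConfig,
    mla: MLAConfig,
    n_offsets: int = 16,
    apodization: Callable[[np.ndarray], np.ndarray] | None = None,
    n_nodes: int = 256,
) -> LFMPSF:
    """Full 5D LFM PSF ``(n_z, n_offsets, n_offsets, N_num, N_num)``.

    For each depth and each of ``n_offsets x n_offsets`` cell-centred source
    offsets within one lenslet pitch, the chain is: Debye focal field (relay
    magnification folded into the image-plane grid) -> MLA phase mask ->
    angular-spectrum propagation over the lenslet focal length (zero-padded)
    -> squared magnitude binned into sensor pixels; the ``N_num x N_num``
    window of the central lenslet is recorded.

    Point symmetry PSF(x, y, z) = PSF(-x, -y, z) is exploited: only the first
    half of the ``s_y`` offsets is simulated, the other half is the mirror
    image with the (u, v) window flipped.  Each depth slice is normalized to
    unit sum.
    """
    if n_offsets % 2:
        raise InvalidConfigError("n_offsets must be even for mirror symmetry")
    d = mla.pitch_um
    spacing = config.lateral_spacing_um
    n_grid = config.lateral_extent_px
    nnum = mla.pixels_per_lenslet
    sensor_px = d / nnum
    oversample = sensor_px / spacing
    if abs(oversample - round(oversample)) > 5e-3 * oversample:
        raise InvalidConfigError(
            "grid spacing must divide the sensor pixel pitch (pitch / N_num)"
        )
    oversample = int(round(oversample))
    t_mask = mla_transmission(mla, spacing, n_grid, config.wavelength_nm).data

    c = grid_coords(n_grid, spacing)
    yy, xx = np.meshgrid(c, c, indexing="ij")
    offsets = (np.arange(n_offsets) + 0.5) / n_offsets * d - d / 2.0

    # sensor-pixel window of the central lenslet
    m_sens = n_grid // oversample
    center_pix = (n_grid // 2) // oversample
    lo = center_pix - nnum // 2
    hi = lo + nnum
    if lo < 0 or hi > m_sens:
        raise InvalidConfigError("grid too small for one full lenslet window")

    nz = config.n_depths
    psf = np.zeros((nz, n_offsets, n_offsets, nnum, nnum))
    r_max = float(np.hypot(np.abs(c).max() + d, np.abs(c).max() + d))
    r_table = np.linspace(0.0, r_max / config.magnification, 4 * n_grid)

    half = n_offsets // 2
    for iz, z in enumerate(config.depth_grid_um):
        ub_1d = debye_radial(config, float(z), r_table, apodization, n_nodes)
        for iy in range(half):
            for ix in range(n_offsets):
                r = np.hypot(yy - offsets[iy], xx - offsets[ix]) / config.magnification
                u = np.interp(r, r_table, ub_1d.real) + 1j * np.interp(
                    r, r_table, ub_1d.imag
                )
                fld = ComplexField2D(u * t_mask, spacing, config.wavelength_nm)
                out = angular_spectrum_propagate(fld, mla.focal_length_um, pad=True)
                intensity = np.abs(out.data) ** 2
                pix = _bin_sensor(intensity, oversample)
                psf[iz, iy, ix] = pix[lo:hi, lo:hi]
                # mirrored source offset: point-inverted response
                psf[iz, n_offsets - 1 - iy, n_offsets - 1 - ix] = pix[lo:hi, lo:hi][
                    ::-1, ::-1
                ]
        s = psf[iz].sum()
        if s > 0:
            psf[iz] /= s
    return LFMPSF(
        data=psf,
        depth_grid_um=config.depth_grid_um,
        offset_spacing_um=d / n_offsets,
        sensor_pixel_pitch_um=sensor_px,
    )


# 2-3-2 view layout: (row, col) offsets in units of the MLA pitch
_VIEW_OFFSETS_232 = np.array(
    [
        (-1.0, -0.5),
        (-1.0, 0.5),
        (0.0, -1.0),
        (0.0, 0.0),
        (0.0, 1.0),
        (1.0, -0.5),
        (1.0, 0.5),
    ]
)


def compute_flfm_psf(
    config: OpticalConfig,
    mla: MLAConfig,
    aperture: ApertureProfile | None = None,
    bandlimit_cutoff_um: float | None = None,
    apodization: Callable[[np.ndarray], np.ndarray] | None = None,
    n_nodes: int = 256,
    view_spacing_px: float | None = None,
) -> FLFMPSF:
    """Per-depth FLFM frequency response and complex depth weights.

    Chain per depth: Debye focal field -> pupil aperture clipping (the profile
    is resampled onto the normalized pupil radius of the field's DFT grid) ->
    sinc band-limit -> intensity PSF -> unit-sum normalization -> OTF.  The
    stored response is ``R = OTF / w`` with ``w(z)`` the unit-modulus phase of
    the on-axis complex amplitude, so ``w * R`` is exactly the Hermitian OTF
    while the weights themselves are genuinely complex away from focus.
    """
    n = config.lateral_extent_px
    spacing = config.lateral_spacing_um
    f_na = config.numerical_aperture / config.wavelength_um  # pupil radius, 1/um
    fgrid = np.fft.fftfreq(n, d=spacing)
    fyy, fxx = np.meshgrid(fgrid, fgrid, indexing="ij")
    rho_pupil = np.hypot(fyy, fxx) * config.magnification / f_na

    if aperture is None:
        profile = aperture_profile(rho_pupil, cutoff=1.0, order=8.0)
    else:
        profile = aperture_profile(rho_pupil, aperture.cutoff, aperture.order)

    cutoff = bandlimit_cutoff_um
    if cutoff is None:
        # pass the full NA-limited band of the sampled image plane
        cutoff = 2.0 * spacing

    nz = config.n_depths
    response = np.zeros((nz, n, n), dtype=complex)
    weights = np.zeros((nz, 1, 1), dtype=complex)
    for iz, z in enumerate(config.depth_grid_um):
        fld = debye_wavefront(config, float(z), apodization=apodization, n_nodes=n_nodes)
        spectrum = ComplexField2D(np.fft.fft2(fld.data), spacing, config.wavelength_nm)
        clipped = apply_aperture(spectrum, profile)
        img = ComplexField2D(np.fft.ifft2(clipped.data), spacing, config.wavelength_nm)
        img = flfm_bandlimit(img, cutoff)
        on_axis = img.data[n // 2, n // 2]
        if on_axis == 0:
            on_axis = 1.0 + 0.0j
        w = on_axis / abs(on_axis)
        psf_int = np.abs(img.data) ** 2
        s = psf_int.sum()
        if s > 0:
            psf_int = psf_int / s
        otf = np.fft.fft2(np.fft.ifftshift(psf_int))
        weights[iz, 0, 0] = w
        response[iz] = otf / w

    m_relay = mla.relay_magnification
    if view_spacing_px is None:
        view_spacing_px = mla.pitch_um * m_relay / config.sensor_pixel_pitch_um
    centers_px = _VIEW_OFFSETS_232 * float(view_spacing_px)
    # parallax: a view at pupil offset (pitch units) sees the object at angle
    # tan(theta) = pitch / f_obj, so a depth-z point shifts by z * tan(theta)
    # in object space, i.e. z * tan(theta) * M on the canvas grid
    f_obj_um = (mla.relay_f1_mm or 180.0) * 1000.0 / config.magnification
    tan_per_pitch = mla.pitch_um / f_obj_um
    disparity_px_per_um = (
        tan_per_pitch * config.magnification / config.lateral_spacing_um
    )
    return FLFMPSF(
        response=response,
        weights=weights,
        depth_grid_um=config.depth_grid_um,
        view_offsets=_VIEW_OFFSETS_232.copy(),
        view_centers_px=centers_px,
        disparity_px_per_um=disparity_px_per_um,
        spacing_um=spacing,
    )


# ---------------------------------------------------------------------------
# reference and desk presets
# ---------------------------------------------------------------------------


def lfm_reference_config() -> tuple[OpticalConfig, MLAConfig]:
    """Published LFM arm: 40x/0.8 water objective, 150 um MLA, 11 px views."""
    cfg = OpticalConfig(
        numerical_aperture=0.8,
        magnification=40.0,
        wavelength_nm=580.0,
        refractive_index=1.33,
        sensor_pixel_pitch_um=150.0 / 11.0,
        depth_grid_um=np.arange(-30.0, 31.0, 1.0),
        lateral_spacing_um=150.0 / 22.0,
        lateral_extent_px=64,
    )
    mla = MLAConfig(pitch_um=150.0, focal_length_um=3500.0, pixels_per_lenslet=11)
    return cfg, mla


def flfm_reference_config() -> tuple[OpticalConfig, MLAConfig]:
    """Published FLFM arm: 100x/1.4 oil objective, Fourier MLA d=3.25 mm."""
    cfg = OpticalConfig(
        numerical_aperture=1.4,
        magnification=100.0,
        wavelength_nm=510.0,
        refractive_index=1.515,
        sensor_pixel_pitch_um=6.5,
        depth_grid_um=np.arange(-30.0, 31.0, 1.0),
        lateral_spacing_um=0.1,
        lateral_extent_px=128,
    )
    mla = MLAConfig(
        pitch_um=3250.0,
        focal_length_um=120_000.0,
        pixels_per_lenslet=1,
        f_number=37.0,
        relay_f1_mm=180.0,
        relay_f2_mm=300.0,
    )
    return cfg, mla


def lfm_desk_config(
    n_depths: int = 21, n_views: int = 5, extent_px: int = 40
) -> tuple[OpticalConfig, MLAConfig]:
    """Small LFM preset for fast end-to-end runs on one CPU.

    A moderate-NA, low-magnification arm whose defocus range stays within the
    lenslet focal regime, so per-view kernels shift cleanly with depth inside
    the single-lenslet window.  The default 21-plane depth range makes the
    desk reconstruction problem underdetermined per modality, mirroring the
    regime of the full-scale geometry (many more depth planes than effective
    angular measurements).
    """
    half = (n_depths - 1) // 2
    pitch = 50.0
    cfg = OpticalConfig(
        numerical_aperture=0.4,
        magnification=10.0,
        wavelength_nm=580.0,
        refractive_index=1.33,
        sensor_pixel_pitch_um=pitch / n_views,
        depth_grid_um=np.arange(-half, half + 1, 1.0),
        lateral_spacing_um=pitch / (2 * n_views),
        lateral_extent_px=extent_px,
    )
    mla = MLAConfig(pitch_um=pitch, focal_length_um=1500.0, pixels_per_lenslet=n_views)
    return cfg, mla


def flfm_desk_config(
    n_depths: int = 21, extent_px: int = 96
) -> tuple[OpticalConfig, MLAConfig]:
    """Small FLFM preset matched to the desk LFM depth range.

    Canvas pixels coincide with sensor pixels (1 um); the Fourier MLA pitch
    subdivides the pupil so the per-view parallax is about 0.5 px per um of
    depth (keeping extreme-depth EPI slopes within the range the slope
    estimator resolves).  View centres are laid out with ``view_spacing_px``
    in :func:`compute_flfm_psf`.
    """
    half = (n_depths - 1) // 2
    cfg = OpticalConfig(
        numerical_aperture=0.45,
        magnification=6.0,
        wavelength_nm=510.0,
        refractive_index=1.33,
        sensor_pixel_pitch_um=1.0,
        depth_grid_um=np.arange(-half, half + 1, 1.0),
        lateral_spacing_um=1.0,
        lateral_extent_px=extent_px,
    )
    mla = MLAConfig(
        pitch_um=2000.0,
        focal_length_um=120_000.0,
        pixels_per_lenslet=1,
        f_number=37.0,
        relay_f1_mm=150.0,
        relay_f2_mm=150.0,
    )
    return cfg, mla
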