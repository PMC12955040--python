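"""Visual diagnostics: depth-coded maps, projections, spectra."""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps

from .optics import InvalidConfigError

__all__ = ["render_views"]


def _depth_colormap(vol: np.ndarray, cmap: str = "turbo") -> np.ndarray:
    """Hue encodes the depth of the brightest voxel along z; brightness
    encodes the maximum intensity itself."""
    n_z = vol.shape[0]
    arg = np.argmax(vol, axis=0)
    mx = np.max(vol, axis=0)
    peak = mx.max() or 1.0
    cm = colormaps[cmap]
    hues = cm(arg / max(n_z - 1, 1))[..., :3]
    return hues * (mx / peak)[..., None]


def render_views(vol: np.ndarray, mode: str, z_slice: int | None = None):
    """Render a volume for inspection.

    ``mode``:
      * ``depth_colormap`` — RGB image, hue = depth of argmax, value = MIP.
      * ``projections`` — dict of maximum-intensity projections on the
        X-Y, X-Z and Y-Z planes.
      * ``spectrum`` — log-magnitude centred 2D spectrum of one z-slice
        (the central slice unless ``z_slice`` is given).
    """
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3 or vol.size == 0:
        raise InvalidConfigError("expected a non-empty 3D volume")
    if mode == "depth_colormap":
        return _depth_colormap(vol)
    if mode == "projections":
        return {
            "xy": vol.max(axis=0),
            "xz": vol.max(axis=1),
            "yz": vol.max(axis=2),
        }
    if mode == "spectrum":
        k = vol.shape[0] // 2 if z_slice is None else z_slice
        spec = np.fft.fftshift(np.fft.fft2(vol[k]))
        return np.log1p(np.abs(spec))
    raise InvalidConfigError(f"unknown render mode {mode!r}")
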