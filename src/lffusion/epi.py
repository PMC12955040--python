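"""Epipolar plane image (EPI) stacks and a slope-analysis utility.

An EPI fixes one spatial axis of a light field and records intensity against
one angular and one spatial coordinate; scene depth appears as the slope of
the lines traced by points across views.  All constructions here are pure
axis permutations/reshapes and are bit-exact invertible.

Axis conventions (see :mod:`lffusion.forward`): the light field is
``L(u, v, w, h)`` with ``u`` conjugate to ``h`` and ``v`` conjugate to ``w``;
FLFM view stacks are 2-3-2 and contribute their central row (horizontal
parallax, paired with ``w`` = image x here) and central column (vertical
parallax, paired with ``h``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import FLFMViewStack, LightField4D
from .optics import InvalidConfigError

__all__ = [
    "EPIStack",
    "lfm_epi",
    "lfm_epi_inverse",
    "flfm_epi",
    "flfm_epi_inverse",
    "epi_dominant_slope",
]

_LAYOUTS = {"vw_u_h", "uh_v_w", "h_c_w", "w_c_h"}

# central row / central column view indices of the 2-3-2 layout
_CENTRAL_ROW = (2, 3, 4)
_CENTRAL_COL = (0, 3, 5)


@dataclass
class EPIStack:
    """Channel-stacked EPIs with a layout tag.

    Layouts: ``vw_u_h`` = (v*w, u, h) and ``uh_v_w`` = (u*h, v, w) for LFM;
    ``h_c_w`` = (h, c, w) and ``w_c_h`` = (w, c, h) for FLFM, where ``c``
    indexes the three collinear views of the central row/column.
    """

    data: np.ndarray
    layout: str
    meta: tuple = ()

    def __post_init__(self):
        if self.layout not in _LAYOUTS:
            raise InvalidConfigError(f"unknown EPI layout {self.layout!r}")
        if self.data.ndim != 3:
            raise InvalidConfigError("EPI stack must be 3D")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def lfm_epi(lf: LightField4D) -> tuple[EPIStack, EPIStack]:
    """LFM EPI stacks: u-h plane (v*w, u, h) and v-w plane (u*h, v, w).

    Channel order is v-major-then-w for the first stack and u-major-then-h
    for the second; both are lossless rearrangements.
    """
    nu, nv, nw, nh = lf.data.shape
    uh = lf.data.transpose(1, 2, 0, 3).reshape(nv * nw, nu, nh)
    vw = lf.data.transpose(0, 3, 1, 2).reshape(nu * nh, nv, nw)
    return (
        EPIStack(uh, "vw_u_h", meta=(nu, nv, nw, nh)),
        EPIStack(vw, "uh_v_w", meta=(nu, nv, nw, nh)),
    )


def lfm_epi_inverse(stack: EPIStack) -> LightField4D:
    """Recover the 4D light field from either LFM EPI stack, bit-exactly."""
    nu, nv, nw, nh = stack.meta
    if stack.layout == "vw_u_h":
        return LightField4D(
            stack.data.reshape(nv, nw, nu, nh).transpose(2, 0, 1, 3)
        )
    if stack.layout == "uh_v_w":
        return LightField4D(
            stack.data.reshape(nu, nh, nv, nw).transpose(0, 2, 3, 1)
        )
    raise InvalidConfigError(f"not an LFM EPI layout: {stack.layout!r}")


def flfm_epi(views: FLFMViewStack) -> tuple[EPIStack, EPIStack]:
    """FLFM EPI stacks from the 2-3-2 view layout.

    The central row (three collinear views with horizontal parallax) builds
    the c-w stack (h, c, w); the central column builds the c-h stack
    (w, c, h).  Both recover the selected views bit-exactly.
    """
    if views.n_views != 7:
        raise InvalidConfigError("FLFM EPIs require the 7-view 2-3-2 layout")
    row = views.data[list(_CENTRAL_ROW)]  # (c, y=h, x=w)
    col = views.data[list(_CENTRAL_COL)]
    cw = row.transpose(1, 0, 2)  # (h, c, w)
    ch = col.transpose(2, 0, 1)  # (w, c, h)
    shape = views.data.shape
    return EPIStack(cw, "h_c_w", meta=shape), EPIStack(ch, "w_c_h", meta=shape)


def flfm_epi_inverse(stack: EPIStack) -> np.ndarray:
    """Recover the three selected views (c, y, x) from an FLFM EPI stack."""
    if stack.layout == "h_c_w":
        return stack.data.transpose(1, 0, 2)
    if stack.layout == "w_c_h":
        return stack.data.transpose(1, 2, 0)
    raise InvalidConfigError(f"not an FLFM EPI layout: {stack.layout!r}")


def epi_dominant_slope(epi_slice: np.ndarray, n_refine: int = 2) -> float:
    """Dominant line slope of one EPI slice, in pixels per view step.

    The slice is (views, spatial).  A structure tensor accumulated over the
    slice gives the dominant orientation; the returned value is the spatial
    displacement per unit view index along the iso-intensity direction.
    Because finite differences along the view axis alias for steep lines,
    the estimate is refined ``n_refine`` times by shearing the slice with the
    current slope and re-estimating the residual orientation.
    Returns NaN (undefined-slope flag) for constant slices; orientation ties
    break toward slope 0.
    """
    epi = np.asarray(epi_slice, dtype=float)
    if epi.ndim != 2 or epi.shape[0] < 2:
        raise InvalidConfigError("EPI slice needs >= 2 view rows")
    total = _tensor_slope(epi)
    if not np.isfinite(total):
        return total
    for _ in range(n_refine):
        residual = _tensor_slope(_shear(epi, -total))
        if not np.isfinite(residual):
            break
        total += residual
    return float(total)


def _shear(epi: np.ndarray, slope: float) -> np.ndarray:
    """Shift row v by ``slope * (v - centre)`` pixels (linear interpolation)."""
    n_views, width = epi.shape
    xs = np.arange(width, dtype=float)
    centre = (n_views - 1) / 2.0
    out = np.empty_like(epi)
    for v in range(n_views):
        out[v] = np.interp(xs - slope * (v - centre), xs, epi[v])
    return out


def _tensor_slope(epi: np.ndarray) -> float:
    gv, gs = np.gradient(epi)
    jvv = float(np.sum(gv * gv))
    jss = float(np.sum(gs * gs))
    jvs = float(np.sum(gv * gs))
    trace = jvv + jss
    if trace < 1e-24 * max(1.0, float(np.max(np.abs(epi))) ** 2):
        return float("nan")
    tensor = np.array([[jvv, jvs], [jvs, jss]])
    evals, evecs = np.linalg.eigh(tensor)
    coherence = (evals[1] - evals[0]) / trace
    if coherence < 1e-12:  # isotropic: orientation tie, break toward 0
        return 0.0
    normal = evecs[:, 1]  # gradient direction, (view, spatial) components
    line = np.array([-normal[1], normal[0]])  # iso-intensity direction
    if abs(line[0]) < 1e-12:
        return float("inf")
    return float(line[1] / line[0])
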