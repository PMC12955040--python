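"""Synthetic ground-truth volumes and paired dual-modality samples.

Two phantom families emulate the structures the method targets:

* ``tubulin`` — sparse, smooth curvilinear filaments (random cubic-spline
  walks with a Gaussian cross-section), resembling sparsely labelled
  microtubule volumes.
* ``vessel`` — branching vascular trees (recursive bifurcation with radius
  tapering), resembling brain-vessel stacks.

``make_dataset`` turns phantoms into full samples: the ground truth volume,
its LFM light field, its FLFM view stack and all four EPI stacks, split into
train/test subsets by a seeded shuffle (default 8:2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .epi import EPIStack, flfm_epi, lfm_epi
from .forward import (
    FLFMViewStack,
    LightField4D,
    Volume3D,
    project_flfm,
    project_lfm,
)
from .optics import FLFMPSF, LFMPSF, InvalidConfigError

__all__ = [
    "PhantomConfig",
    "SamplePair",
    "VesselSegment",
    "make_tubulin_volume",
    "make_vessel_volume",
    "vessel_tree",
    "make_dataset",
    "tubulin_full_preset",
    "tubulin_desk_preset",
    "vessel_desk_preset",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and morphology of one phantom family.

    ``shape`` is (z, y, x) voxels; ``voxel_size_um`` is (z, y, x) micrometres.
    ``structure_radius_vox`` is the Gaussian cross-section sigma for tubulin
    filaments and the root tube radius for vessels.
    """

    shape: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float] = (1.0, 0.34, 0.34)
    kind: Literal["tubulin", "vessel"] = "tubulin"
    n_structures: int = 8
    structure_radius_vox: float = 1.0
    intensity_range: tuple[float, float] = (0.5, 1.0)
    seed: int = 0
    # tubulin morphology
    n_control_points: int = 5
    points_per_voxel: float = 3.0
    # vessel morphology
    branch_depth: int = 3
    taper: float = 0.7
    branch_angle_deg: float = 35.0
    segment_length_frac: float = 0.35

    def __post_init__(self):
        if any(s <= 0 for s in self.shape):
            raise InvalidConfigError("phantom shape must be positive")
        if self.structure_radius_vox < 0.5:
            raise InvalidConfigError("structure radius must be >= 0.5 voxel")
        if not 0 < self.taper < 1:
            raise InvalidConfigError("taper must lie in (0, 1)")


@dataclass
class SamplePair:
    """One dataset row: ground truth plus every derived modality."""

    ground_truth: Volume3D
    lfm: LightField4D
    flfm: FLFMViewStack
    epi_lfm_uh: EPIStack
    epi_lfm_vw: EPIStack
    epi_flfm_cw: EPIStack
    epi_flfm_ch: EPIStack
    sample_id: str
    seed: int


@dataclass(frozen=True)
class VesselSegment:
    start: np.ndarray  # (z, y, x) voxel coordinates
    end: np.ndarray
    radius_vox: float
    depth: int


def _splat_points(
    vol: np.ndarray, pts: np.ndarray, weights: np.ndarray
) -> None:
    """Accumulate point masses at rounded voxel positions (in-place)."""
    idx = np.round(pts).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(vol.shape)), axis=1)
    idx = idx[ok]
    np.add.at(vol, (idx[:, 0], idx[:, 1], idx[:, 2]), weights[ok])


def make_tubulin_volume(cfg: PhantomConfig) -> Volume3D:
    """Sparse filament phantom: smooth random 3D curves with Gaussian
    cross-section of ``structure_radius_vox``.  Deterministic in the seed."""
    if cfg.kind != "tubulin":
        raise InvalidConfigError("config kind must be 'tubulin'")
    rng = np.random.default_rng(cfg.seed)
    vol = np.zeros(cfg.shape, dtype=float)
    if cfg.n_structures == 0:
        return Volume3D(vol, cfg.voxel_size_um)
    shape = np.array(cfg.shape, dtype=float)
    for _ in range(cfg.n_structures):
        ctrl = rng.uniform(0.1, 0.9, size=(cfg.n_control_points, 3)) * shape
        t = np.linspace(0.0, 1.0, cfg.n_control_points)
        spline = CubicSpline(t, ctrl, axis=0)
        approx_len = float(np.sum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1)))
        n_pts = max(int(approx_len * cfg.points_per_voxel), 8)
        pts = spline(np.linspace(0.0, 1.0, n_pts))
        amp = rng.uniform(*cfg.intensity_range)
        _splat_points(vol, pts, np.full(n_pts, amp / cfg.points_per_voxel))
    vol = gaussian_filter(vol, sigma=cfg.structure_radius_vox)
    peak = vol.max()
    if peak > 0:
        vol /= peak
    return Volume3D(vol, cfg.voxel_size_um)


def vessel_tree(cfg: PhantomConfig) -> list[VesselSegment]:
    """Branch skeleton of the vessel phantom: recursive bifurcation with
    radius tapering ``taper`` per generation.  Deterministic in the seed."""
    rng = np.random.default_rng(cfg.seed)
    shape = np.array(cfg.shape, dtype=float)
    seg_len = cfg.segment_length_frac * float(min(shape[1], shape[2]))
    segments: list[VesselSegment] = []

    def grow(start: np.ndarray, direction: np.ndarray, radius: float, depth: int):
        end = start + direction * seg_len * (0.8 + 0.4 * rng.random())
        segments.append(VesselSegment(start.copy(), end.copy(), radius, depth))
        if depth >= cfg.branch_depth:
            return
        for _ in range(2):
            ang = np.deg2rad(cfg.branch_angle_deg) * (0.5 + rng.random())
            axis = rng.normal(size=3)
            axis -= axis @ direction * direction
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                axis = np.array([0.0, 1.0, 0.0])
                norm = 1.0
            axis /= norm
            child_dir = np.cos(ang) * direction + np.sin(ang) * axis
            child_dir /= np.linalg.norm(child_dir)
            grow(end, child_dir, radius * cfg.taper, depth + 1)

    for _ in range(max(cfg.n_structures, 1) if cfg.n_structures else 0):
        start = np.array(
            [
                rng.uniform(0.3, 0.7) * shape[0],
                rng.uniform(0.2, 0.8) * shape[1],
                rng.uniform(0.2, 0.8) * shape[2],
            ]
        )
        direction = rng.normal(size=3)
        direction[0] *= 0.3  # keep trees roughly in-plane
        direction /= np.linalg.norm(direction)
        grow(start, direction, cfg.structure_radius_vox, 0)
    return segments


def make_vessel_volume(cfg: PhantomConfig) -> Volume3D:
    """Branching-tree phantom rasterized as tapering tubes."""
    if cfg.kind != "vessel":
        raise InvalidConfigError("config kind must be 'vessel'")
    vol = np.zeros(cfg.shape, dtype=float)
    if cfg.n_structures == 0:
        return Volume3D(vol, cfg.voxel_size_um)
    rng = np.random.default_rng(cfg.seed + 1)
    for seg in vessel_tree(cfg):
        vec = seg.end - seg.start
        length = float(np.linalg.norm(vec))
        n_pts = max(int(length * 2.0), 2)
        pts = seg.start + np.linspace(0.0, 1.0, n_pts)[:, None] * vec
        amp = rng.uniform(*cfg.intensity_range)
        _stamp_tube(vol, pts, seg.radius_vox, amp)
    peak = vol.max()
    if peak > 0:
        vol /= peak
    return Volume3D(vol, cfg.voxel_size_um)


def _stamp_tube(vol: np.ndarray, pts: np.ndarray, radius: float, amp: float) -> None:
    """Stamp a Gaussian ball of sigma ``radius/2`` at each centre-line point,
    taking the running maximum so overlapping stamps form a solid tube."""
    sigma = max(radius / 2.0, 0.5)
    half = max(int(np.ceil(3 * sigma)), 1)
    ax = np.arange(-half, half + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    ball = amp * np.exp(-(zz**2 + yy**2 + xx**2) / (2.0 * sigma**2))
    shp = vol.shape
    for p in pts:
        c = np.round(p).astype(int)
        lo = c - half
        hi = c + half + 1
        s_lo = np.maximum(lo, 0)
        s_hi = np.minimum(hi, shp)
        if np.any(s_lo >= s_hi):
            continue
        b_lo = s_lo - lo
        b_hi = b_lo + (s_hi - s_lo)
        view = vol[s_lo[0] : s_hi[0], s_lo[1] : s_hi[1], s_lo[2] : s_hi[2]]
        np.maximum(
            view,
            ball[b_lo[0] : b_hi[0], b_lo[1] : b_hi[1], b_lo[2] : b_hi[2]],
            out=view,
        )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def make_sample(
    cfg: PhantomConfig,
    lfm_psf: LFMPSF,
    flfm_psf: FLFMPSF,
    sample_id: str,
    seed: int,
    lfm_stride: int = 1,
) -> SamplePair:
    """Generate one phantom and derive every modality from it.

    ``lfm_stride`` samples the LFM light field at lenslet pitch (every
    ``lfm_stride``-th voxel), the physical spatial sampling of the MLA.
    """
    scfg = replace(cfg, seed=seed)
    if cfg.kind == "tubulin":
        gt = make_tubulin_volume(scfg)
    else:
        gt = make_vessel_volume(scfg)
    lf = project_lfm(gt, lfm_psf, lenslet_stride=lfm_stride)
    views, _ = project_flfm(gt, flfm_psf, return_sensor=False)
    uh, vw = lfm_epi(lf)
    cw, ch = flfm_epi(views)
    return SamplePair(
        ground_truth=gt,
        lfm=lf,
        flfm=views,
        epi_lfm_uh=uh,
        epi_lfm_vw=vw,
        epi_flfm_cw=cw,
        epi_flfm_ch=ch,
        sample_id=sample_id,
        seed=seed,
    )


def make_dataset(
    n_samples: int,
    cfg: PhantomConfig,
    lfm_psf: LFMPSF,
    flfm_psf: FLFMPSF,
    split_ratio: float = 0.8,
    master_seed: int = 0,
    lfm_stride: int = 1,
) -> tuple[list[SamplePair], list[SamplePair]]:
    """Generate ``n_samples`` paired samples and split them train/test.

    Per-sample seeds are spawned from the master seed, so the full dataset
    (including the split membership) regenerates bit-exactly.
    """
    if n_samples < 2:
        raise InvalidConfigError("need at least 2 samples to split")
    if not 0.0 < split_ratio < 1.0:
        raise InvalidConfigError("split ratio must lie in (0, 1)")
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_samples)]
    samples = [
        make_sample(
            cfg, lfm_psf, flfm_psf, sample_id=f"sample_{i:04d}", seed=seeds[i],
            lfm_stride=lfm_stride,
        )
        for i in range(n_samples)
    ]
    order = np.random.default_rng(master_seed).permutation(n_samples)
    n_train = int(round(split_ratio * n_samples))
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def tubulin_full_preset(seed: int = 0) -> PhantomConfig:
    """Published tubulin geometry: 176 x 176 x 61 voxels at 0.34/0.34/1 um."""
    return PhantomConfig(
        shape=(61, 176, 176),
        voxel_size_um=(1.0, 0.34, 0.34),
        kind="tubulin",
        n_structures=12,
        structure_radius_vox=1.5,
        seed=seed,
    )


def tubulin_desk_preset(seed: int = 0, shape: tuple[int, int, int] = (21, 32, 32)) -> PhantomConfig:
    """Small filament preset for CPU-scale end-to-end runs."""
    return PhantomConfig(
        shape=shape,
        voxel_size_um=(1.0, 0.34, 0.34),
        kind="tubulin",
        n_structures=4,
        structure_radius_vox=1.0,
        n_control_points=4,
        seed=seed,
    )


def vessel_desk_preset(seed: int = 0, shape: tuple[int, int, int] = (21, 32, 32)) -> PhantomConfig:
    """Small branching-tree preset (scaled stand-in for vessel stacks)."""
    return PhantomConfig(
        shape=shape,
        voxel_size_um=(0.9, 0.087, 0.087),
        kind="vessel",
        n_structures=1,
        structure_radius_vox=1.6,
        branch_depth=2,
        seed=seed,
    )
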