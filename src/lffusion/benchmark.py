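"""Desk-scale end-to-end benchmark: modality-ablation study and baselines.

This module fixes the study conditions of the CPU-scale benchmark in one
place so tests, scripts and examples all run the identical protocol:

* desk optics presets for both arms (21 depths, 5x5 LFM views sampled at
  lenslet pitch — 4 voxels per lenslet — and 7 FLFM views),
* filament phantoms of shape (21, 32, 32), 22 training / 6 test volumes,
* one training recipe for every modality combination (Adam at 2e-3,
  batch 2, trained to plateau: up to 60 epochs with early stopping once
  the loss improves < 2% over 5-epoch windows),
* median test PSNR over three model seeds per combination,
* Richardson-Lucy baselines on both modalities (30 iterations, the LFM
  one solving the same lenslet-sampled strided problem).

The ablation mirrors the method's modality ladder: every single modality,
the within-arm and cross-arm dual combinations, and the full four-branch
fusion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import baselines, metrics, network, optics, phantom
from .epi import epi_dominant_slope, flfm_epi
from .forward import Volume3D, project_flfm

__all__ = [
    "ABLATION_VARIANTS",
    "AblationReport",
    "desk_psfs",
    "run_desk_ablation",
    "flfm_slope_depth_spearman",
]

ABLATION_VARIANTS: tuple[tuple[str, ...], ...] = (
    ("lfm",),
    ("flfm",),
    ("lfm_epi",),
    ("flfm_epi",),
    ("lfm", "lfm_epi"),
    ("flfm", "flfm_epi"),
    ("lfm", "flfm"),
    ("lfm", "flfm", "lfm_epi", "flfm_epi"),
)

SINGLE_VARIANTS = tuple(v for v in ABLATION_VARIANTS if len(v) == 1)
DUAL_VARIANTS = tuple(v for v in ABLATION_VARIANTS if len(v) == 2)
FULL_VARIANT = ("lfm", "flfm", "lfm_epi", "flfm_epi")


@dataclass
class AblationReport:
    """Median-over-seeds test metrics per modality combination."""

    psnr_by_variant: dict[str, float] = field(default_factory=dict)
    ssim_by_variant: dict[str, float] = field(default_factory=dict)
    per_seed_psnr: dict[str, list[float]] = field(default_factory=dict)
    rl_lfm_psnr: float = float("nan")
    rl_lfm_ssim: float = float("nan")
    rl_flfm_psnr: float = float("nan")
    rl_flfm_ssim: float = float("nan")

    @property
    def fused_psnr(self) -> float:
        return self.psnr_by_variant["+".join(FULL_VARIANT)]

    @property
    def best_dual_psnr(self) -> float:
        return max(self.psnr_by_variant["+".join(v)] for v in DUAL_VARIANTS)

    @property
    def best_single_psnr(self) -> float:
        return max(self.psnr_by_variant["+".join(v)] for v in SINGLE_VARIANTS)


LFM_LENSLET_STRIDE = 4  # volume voxels per lenslet pitch in the benchmark


def desk_psfs(n_offsets: int = LFM_LENSLET_STRIDE, view_spacing_px: float = 36.0):
    """Both desk-preset PSFs (LFM 5D tensor, FLFM frequency responses).

    ``n_offsets`` is the sub-lenslet offset count of the LFM tensor and
    equals the lenslet stride of the benchmark projector, so one lenslet
    pitch spans exactly that many volume voxels.
    """
    lcfg, lmla = optics.lfm_desk_config()
    lpsf = optics.compute_lfm_psf(lcfg, lmla, n_offsets=n_offsets)
    fcfg, fmla = optics.flfm_desk_config()
    fpsf = optics.compute_flfm_psf(fcfg, fmla, view_spacing_px=view_spacing_px)
    return lpsf, fpsf


def run_desk_ablation(
    master_seed: int = 0,
    n_samples: int = 28,
    n_train: int = 22,
    epochs: int = 60,
    n_seeds: int = 3,
    shape: tuple[int, int, int] = (21, 32, 32),
    rl_iterations: int = 30,
    variants: tuple[tuple[str, ...], ...] = ABLATION_VARIANTS,
    progress=None,
) -> AblationReport:
    """Full modality-ablation benchmark at desk scale.

    Generates one dataset from ``master_seed``, trains every modality
    combination with ``n_seeds`` model/optimizer seeds under the same recipe,
    and reports the median test PSNR/SSIM per combination plus the
    Richardson-Lucy baselines on the same test set.
    """
    lpsf, fpsf = desk_psfs()
    cfg = phantom.tubulin_desk_preset(shape=shape)
    train_set, test_set = phantom.make_dataset(
        n_samples, cfg, lpsf, fpsf, master_seed=master_seed,
        lfm_stride=LFM_LENSLET_STRIDE,
    )
    train_set = train_set[:n_train]

    ss = np.random.SeedSequence(master_seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_seeds)]

    report = AblationReport()
    # cascaded pretraining: single-modality runs are trained first and seed
    # the branches of every multi-branch model; the full four-branch model
    # additionally inherits the view branches and the cross-arm fusion stage
    # from the trained LFM+FLFM dual of the same seed (its pass-through
    # within-arm stages make it start at exactly the dual's function), so
    # fine-tuning builds on the best sub-model rather than competing with it.
    branch_bank: dict[tuple[str, int], list] = {}
    dual_bank: dict[int, network.FusionModel] = {}
    ordered = sorted(variants, key=len)
    for variant in ordered:
        key = "+".join(variant)
        psnrs, ssims = [], []
        for seed in run_seeds:
            spec = network.model_spec_for(
                train_set[0], unet_base=10, unified_channels=10, modalities=variant
            )
            model = network.FusionModel(spec, rng=seed)
            if len(variant) > 1:
                for m in variant:
                    state = branch_bank.get((m, seed))
                    if state is not None:
                        model.load_branch_state(m, state)
            if variant == FULL_VARIANT and seed in dual_bank:
                dual = dual_bank[seed]
                for m in ("lfm", "flfm"):
                    model.load_branch_state(m, dual.branch_state(m))
                for dst, src in zip(
                    model.fuse_final.parameters(), dual.fuse_final.parameters()
                ):
                    dst.data = src.data.copy()
            network.train(
                model,
                train_set,
                network.TrainConfig(
                    epochs=epochs, batch_size=2, learning_rate=2e-3, seed=seed,
                    early_stop_patience=5, early_stop_tol=0.02, keep_best=True,
                ),
            )
            if len(variant) == 1:
                branch_bank[(variant[0], seed)] = model.branch_state(variant[0])
            if variant == ("lfm", "flfm"):
                dual_bank[seed] = model
            rep = metrics.evaluate_suite(model.reconstruct, test_set, method=key)
            psnrs.append(rep.mean_psnr)
            ssims.append(rep.mean_ssim)
            if progress is not None:
                progress(key, seed, rep.mean_psnr)
        report.per_seed_psnr[key] = psnrs
        report.psnr_by_variant[key] = float(np.median(psnrs))
        report.ssim_by_variant[key] = float(np.median(ssims))

    hw = (shape[1], shape[2])
    rl_l = metrics.evaluate_suite(
        lambda s: baselines.rl_deconvolve(
            s.lfm, lpsf, rl_iterations, "lfm",
            lenslet_stride=LFM_LENSLET_STRIDE, volume_hw=hw,
        ).data,
        test_set,
        method="rl_lfm",
    )
    rl_f = metrics.evaluate_suite(
        lambda s: baselines.rl_deconvolve(s.flfm, fpsf, rl_iterations, "flfm").data,
        test_set,
        method="rl_flfm",
    )
    report.rl_lfm_psnr = rl_l.mean_psnr
    report.rl_lfm_ssim = rl_l.mean_ssim
    report.rl_flfm_psnr = rl_f.mean_psnr
    report.rl_flfm_ssim = rl_f.mean_ssim
    return report


def flfm_slope_depth_spearman(fpsf=None, lateral: int = 32) -> float:
    """Spearman correlation of |EPI slope| with |depth| for point sources
    projected through the desk FLFM arm (one source per depth plane)."""
    from scipy.stats import spearmanr

    if fpsf is None:
        _, fpsf = desk_psfs()
    nz = fpsf.n_depths
    slopes = []
    for iz in range(nz):
        vol = np.zeros((nz, lateral, lateral))
        vol[iz, lateral // 2, lateral // 2] = 1.0
        views, _ = project_flfm(Volume3D(vol), fpsf, return_sensor=False)
        cw, _ = flfm_epi(views)
        sl = cw.data[np.argmax(cw.data.sum(axis=(1, 2)))]
        slopes.append(epi_dominant_slope(sl))
    z = np.asarray(fpsf.depth_grid_um)
    return float(spearmanr(np.abs(slopes), np.abs(z)).statistic)
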