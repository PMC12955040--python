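"""Four-branch multimodal reconstruction network with hierarchical
result-level fusion and a multilevel supervision loss.

Each modality (LFM view stack, FLFM view stack, LFM EPIs, FLFM EPIs) passes
through its own adapter — bilinear resize to the ground-truth lateral size
followed by convolutions to a unified channel width — and its own 2D U-Net
that emits the volume with depth as output channels.  Fusion is a two-stage
cascade on reconstructed volumes: A = fuse(LFM, LFM_EPI), B = fuse(FLFM,
FLFM_EPI), final = fuse(A, B).  Every branch volume and the fused volume are
supervised against the ground truth with mean squared error; the total loss
is the plain sum of the five terms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Parameter, Tensor
from .nn.layers import Adam, ConvBlock, Module, UNet2D
from .optics import InvalidConfigError
from .phantom import SamplePair

__all__ = [
    "MODALITIES",
    "BranchSpec",
    "ModelSpec",
    "LossBreakdown",
    "TrainConfig",
    "Adapter",
    "FusionBlock",
    "FusionModel",
    "branch_inputs",
    "multilevel_loss",
    "train",
]

MODALITIES = ("lfm", "flfm", "lfm_epi", "flfm_epi")


@dataclass(frozen=True)
class BranchSpec:
    """Configuration of one modality branch."""

    modality: str
    in_channels: tuple[int, ...]  # one entry per sub-stack (EPIs have two)
    target_hw: tuple[int, int]
    unified_channels: int = 12
    unet_base: int = 12
    unet_depth: int = 2

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise InvalidConfigError(f"unknown modality {self.modality!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Geometry and capacity of the whole fusion model."""

    n_z: int
    target_hw: tuple[int, int]
    lfm_channels: int
    lfm_epi_channels: tuple[int, int]
    flfm_channels: int = 7
    flfm_epi_channels: tuple[int, int] | None = None
    unified_channels: int = 12
    unet_base: int = 12
    unet_depth: int = 2
    modalities: tuple[str, ...] = MODALITIES

    def branch_spec(self, modality: str) -> BranchSpec:
        chans = {
            "lfm": (self.lfm_channels,),
            "flfm": (self.flfm_channels,),
            "lfm_epi": tuple(self.lfm_epi_channels),
            "flfm_epi": tuple(self.flfm_epi_channels or self.lfm_epi_channels),
        }[modality]
        return BranchSpec(
            modality=modality,
            in_channels=chans,
            target_hw=self.target_hw,
            unified_channels=self.unified_channels,
            unet_base=self.unet_base,
            unet_depth=self.unet_depth,
        )


@dataclass
class LossBreakdown:
    """Per-branch supervision losses; ``total`` is their plain sum."""

    loss_lfm: float = 0.0
    loss_flfm: float = 0.0
    loss_lfm_epi: float = 0.0
    loss_flfm_epi: float = 0.0
    loss_fuse: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.loss_lfm
            + self.loss_flfm
            + self.loss_lfm_epi
            + self.loss_flfm_epi
            + self.loss_fuse
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "loss_lfm": self.loss_lfm,
            "loss_flfm": self.loss_flfm,
            "loss_lfm_epi": self.loss_lfm_epi,
            "loss_flfm_epi": self.loss_flfm_epi,
            "loss_fuse": self.loss_fuse,
            "total": self.total,
        }


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (the optimization recipe is this package's
    own; only the loss structure is fixed by the method)."""

    epochs: int = 20
    batch_size: int = 2
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    device: str = "cpu"
    checkpoint_every: int = 0  # epochs; 0 disables
    # train-to-plateau: stop once the mean loss of the last `patience` epochs
    # improves on the preceding window by less than `tol` (relative); 0 = off
    early_stop_patience: int = 0
    early_stop_tol: float = 0.02
    # restore the epoch state with the lowest mean training loss at the end
    keep_best: bool = False

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise InvalidConfigError("hyperparameters must be positive")


class Adapter(Module):
    """Resize each sub-stack to the target size, convolve to the unified
    channel width, and (for EPI branches) concatenate the sub-stacks."""

    def __init__(self, spec: BranchSpec, rng: np.random.Generator):
        self.spec = spec
        self.blocks = [
            ConvBlock(c, spec.unified_channels, rng) for c in spec.in_channels
        ]
        total = spec.unified_channels * len(spec.in_channels)
        self.merge = ConvBlock(total, spec.unified_channels, rng)

    def __call__(self, stacks: list[Tensor]) -> Tensor:
        if len(stacks) != len(self.blocks):
            raise InvalidConfigError(
                f"{self.spec.modality}: expected {len(self.blocks)} sub-stacks"
            )
        feats = []
        for blk, s in zip(self.blocks, stacks):
            if s.data.shape[1] != blk.w.data.shape[1]:
                raise InvalidConfigError(
                    f"{self.spec.modality}: channel mismatch "
                    f"{s.data.shape[1]} vs {blk.w.data.shape[1]}"
                )
            feats.append(blk(ag.bilinear_resize(s, self.spec.target_hw)))
        merged = feats[0] if len(feats) == 1 else ag.concat(feats)
        return self.merge(merged)


class FusionBlock(Module):
    """Result-level fusion of two volumes.

    The fused volume is a gated combination ``g_a * a + g_b * b`` (learnable
    per-depth-plane gates, initialized to the plain average) plus a
    convolutional correction whose output layer is zero-initialized.  With
    fresh weights the block therefore returns the branch average — a warm
    start that never degrades the cascade — and training can both re-weight
    the branches (per depth plane) and learn a cross-modal correction on top.
    """

    def __init__(
        self,
        n_z: int,
        rng: np.random.Generator,
        hidden: int | None = None,
        gate_init: tuple[float, float] = (0.5, 0.5),
    ):
        hidden = hidden or max(2 * n_z, 8)
        self.c1 = ConvBlock(2 * n_z, hidden, rng)
        self.c2 = ConvBlock(hidden, n_z, rng, act=False, zero_init=True)
        self.gate_a = Parameter(np.full((1, n_z, 1, 1), gate_init[0]))
        self.gate_b = Parameter(np.full((1, n_z, 1, 1), gate_init[1]))

    def __call__(self, a: Tensor, b: Tensor) -> Tensor:
        if a.data.shape != b.data.shape:
            raise InvalidConfigError(
                f"fusion shape mismatch: {a.data.shape} vs {b.data.shape}"
            )
        correction = self.c2(self.c1(ag.concat([a, b])))
        gated = ag.add(ag.mul(a, self.gate_a), ag.mul(b, self.gate_b))
        return ag.add(gated, correction)


class FusionModel(Module):
    """The full four-branch network (or any subset, for ablations)."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.spec = spec
        self.adapters: dict[str, Adapter] = {}
        self.unets: dict[str, UNet2D] = {}
        for m in spec.modalities:
            bs = spec.branch_spec(m)
            self.adapters[m] = Adapter(bs, rng)
            self.unets[m] = UNet2D(
                bs.unified_channels, spec.n_z, rng, base=bs.unet_base,
                depth=bs.unet_depth,
            )
        # Within-arm stages start as the view branch: the EPI branch supplies
        # parallax information through the learned gates and correction rather
        # than entering as an equal partner.
        self.fuse_a = (
            FusionBlock(spec.n_z, rng, gate_init=(1.0, 0.0))
            if {"lfm", "lfm_epi"} <= set(spec.modalities) else None
        )
        self.fuse_b = (
            FusionBlock(spec.n_z, rng, gate_init=(1.0, 0.0))
            if {"flfm", "flfm_epi"} <= set(spec.modalities) else None
        )
        has_left = bool({"lfm", "lfm_epi"} & set(spec.modalities))
        has_right = bool({"flfm", "flfm_epi"} & set(spec.modalities))
        self.fuse_final = FusionBlock(spec.n_z, rng) if (has_left and has_right) else None

    # Module.parameters only walks attributes; include the dict members
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for mod in list(self.adapters.values()) + list(self.unets.values()):
            params.extend(mod.parameters())
        for blk in (self.fuse_a, self.fuse_b, self.fuse_final):
            if blk is not None:
                params.extend(blk.parameters())
        return params

    def branch_forward(self, modality: str, stacks: list[Tensor]) -> Tensor:
        feats = self.adapters[modality](stacks)
        return self.unets[modality](feats)

    def branch_state(self, modality: str) -> list[np.ndarray]:
        """Weights of one branch (adapter + U-Net), for transfer/pretraining."""
        return [
            p.data.copy()
            for p in self.adapters[modality].parameters()
            + self.unets[modality].parameters()
        ]

    def load_branch_state(self, modality: str, arrays: list[np.ndarray]):
        params = (
            self.adapters[modality].parameters()
            + self.unets[modality].parameters()
        )
        if len(params) != len(arrays):
            raise InvalidConfigError("branch state length mismatch")
        for p, a in zip(params, arrays):
            p.data = a.copy().astype(p.data.dtype)

    def forward_batch(self, inputs: dict[str, list[np.ndarray]]) -> dict[str, Tensor]:
        """Run all configured branches and the fusion cascade.

        ``inputs[modality]`` is a list of batched arrays (N, C, H, W), one per
        sub-stack.  Returns every branch volume plus the final ``"fused"``
        volume, each (N, n_z, H, W).
        """
        outs: dict[str, Tensor] = {}
        for m in self.spec.modalities:
            if m not in inputs:
                raise InvalidConfigError(f"missing input for modality {m!r}")
            stacks = [Tensor(a, requires_grad=False) for a in inputs[m]]
            outs[m] = self.branch_forward(m, stacks)
        left = None
        if "lfm" in outs and "lfm_epi" in outs:
            left = self.fuse_a(outs["lfm"], outs["lfm_epi"])
        elif "lfm" in outs:
            left = outs["lfm"]
        elif "lfm_epi" in outs:
            left = outs["lfm_epi"]
        right = None
        if "flfm" in outs and "flfm_epi" in outs:
            right = self.fuse_b(outs["flfm"], outs["flfm_epi"])
        elif "flfm" in outs:
            right = outs["flfm"]
        elif "flfm_epi" in outs:
            right = outs["flfm_epi"]
        if left is not None and right is not None:
            outs["fused"] = self.fuse_final(left, right)
        else:
            outs["fused"] = left if left is not None else right
        return outs

    def forward_full(self, sample: SamplePair) -> dict[str, np.ndarray]:
        """Volumes for one sample (no gradient bookkeeping kept)."""
        inputs = {
            m: [a[None] for a in branch_inputs(sample)[m]]
            for m in self.spec.modalities
        }
        outs = self.forward_batch(inputs)
        return {k: v.data[0] for k, v in outs.items()}

    def reconstruct(self, sample: SamplePair) -> np.ndarray:
        """Final fused volume estimate (n_z, H, W)."""
        return self.forward_full(sample)["fused"]


def branch_inputs(sample: SamplePair) -> dict[str, list[np.ndarray]]:
    """Network-ready sub-stacks of one sample, keyed by modality."""
    return {
        "lfm": [sample.lfm.data.reshape(-1, *sample.lfm.data.shape[2:])],
        "flfm": [sample.flfm.data],
        "lfm_epi": [sample.epi_lfm_uh.data, sample.epi_lfm_vw.data],
        "flfm_epi": [sample.epi_flfm_cw.data, sample.epi_flfm_ch.data],
    }


def model_spec_for(sample: SamplePair, **overrides) -> ModelSpec:
    """Infer the model geometry from one sample."""
    gt = sample.ground_truth.data
    inp = branch_inputs(sample)
    return ModelSpec(
        n_z=gt.shape[0],
        target_hw=(gt.shape[1], gt.shape[2]),
        lfm_channels=inp["lfm"][0].shape[0],
        lfm_epi_channels=(inp["lfm_epi"][0].shape[0], inp["lfm_epi"][1].shape[0]),
        flfm_channels=inp["flfm"][0].shape[0],
        flfm_epi_channels=(inp["flfm_epi"][0].shape[0], inp["flfm_epi"][1].shape[0]),
        **overrides,
    )


def multilevel_loss(
    outputs: dict[str, Tensor], gt: np.ndarray
) -> tuple[Tensor, LossBreakdown]:
    """Mean-squared-error supervision of every branch volume and the fused
    volume; the scalar total is the sum of the individual terms."""
    gt = np.asarray(gt, dtype=float)
    terms: list[Tensor] = []
    values: dict[str, float] = {}
    for key in MODALITIES + ("fused",):
        if key not in outputs:
            continue
        out = outputs[key]
        target = gt
        if target.ndim == 3 and out.data.ndim == 4:
            target = np.broadcast_to(target[None], out.data.shape)
        if out.data.shape != target.shape:
            raise InvalidConfigError(
                f"{key}: output shape {out.data.shape} does not match gt {gt.shape}"
            )
        term = ag.mse(out, target)
        terms.append(term)
        values[key] = float(term.data)
    total = terms[0]
    for t in terms[1:]:
        total = ag.add(total, t)
    breakdown = LossBreakdown(
        loss_lfm=values.get("lfm", 0.0),
        loss_flfm=values.get("flfm", 0.0),
        loss_lfm_epi=values.get("lfm_epi", 0.0),
        loss_flfm_epi=values.get("flfm_epi", 0.0),
        loss_fuse=values.get("fused", 0.0),
    )
    return total, breakdown


def _batched_inputs(
    samples: list[SamplePair], modalities: tuple[str, ...]
) -> tuple[dict[str, list[np.ndarray]], np.ndarray]:
    per = [branch_inputs(s) for s in samples]
    inputs = {
        m: [
            np.stack([p[m][i] for p in per])
            for i in range(len(per[0][m]))
        ]
        for m in modalities
    }
    gt = np.stack([s.ground_truth.data for s in samples])
    return inputs, gt


def train(
    model: FusionModel,
    dataset: list[SamplePair],
    cfg: TrainConfig,
    out_dir: str | Path | None = None,
) -> list[LossBreakdown]:
    """Seeded mini-batch training loop minimizing the multilevel loss.

    Returns the per-epoch mean loss breakdown.  A NaN loss aborts the run and
    restores the last finite parameter state.  If ``out_dir`` is given, the
    loss history is written as CSV and checkpoints as ``.npz``.
    """
    if not dataset:
        raise InvalidConfigError("training set is empty")
    if cfg.optimizer.lower() != "adam":
        raise InvalidConfigError(f"unsupported optimizer {cfg.optimizer!r}")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[LossBreakdown] = []
    last_good = model.state_dict()
    best_loss, best_state = np.inf, None
    if cfg.keep_best:
        # the (possibly pretrained) initial state competes as a candidate
        init_losses = []
        for start in range(0, len(dataset), cfg.batch_size):
            batch = dataset[start : start + cfg.batch_size]
            inputs, gt = _batched_inputs(batch, model.spec.modalities)
            outs = model.forward_batch(inputs)
            _, bd = multilevel_loss(outs, gt)
            init_losses.append(bd.total)
        best_loss = float(np.mean(init_losses))
        best_state = last_good
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        sums = np.zeros(5)
        n_batches = 0
        aborted = False
        for start in range(0, len(dataset), cfg.batch_size):
            batch = [dataset[i] for i in order[start : start + cfg.batch_size]]
            inputs, gt = _batched_inputs(batch, model.spec.modalities)
            model.zero_grad()
            outs = model.forward_batch(inputs)
            total, bd = multilevel_loss(outs, gt)
            if not np.isfinite(total.data):
                model.load_state_dict(last_good)
                aborted = True
                break
            total.backward()
            opt.step()
            sums += np.array(
                [bd.loss_lfm, bd.loss_flfm, bd.loss_lfm_epi, bd.loss_flfm_epi, bd.loss_fuse]
            )
            n_batches += 1
        if n_batches:
            mean = sums / n_batches
            history.append(
                LossBreakdown(
                    loss_lfm=mean[0], loss_flfm=mean[1], loss_lfm_epi=mean[2],
                    loss_flfm_epi=mean[3], loss_fuse=mean[4],
                )
            )
            last_good = model.state_dict()
            if cfg.keep_best and history[-1].total < best_loss:
                best_loss = history[-1].total
                best_state = last_good
        if out_path is not None and cfg.checkpoint_every and (
            (epoch + 1) % cfg.checkpoint_every == 0
        ):
            np.savez(
                out_path / f"checkpoint_{epoch + 1:04d}.npz",
                *model.state_dict(),
            )
        if aborted:
            break
        p = cfg.early_stop_patience
        if p and len(history) >= 2 * p:
            recent = np.mean([h.total for h in history[-p:]])
            previous = np.mean([h.total for h in history[-2 * p : -p]])
            if recent > (1.0 - cfg.early_stop_tol) * previous:
                break
    if cfg.keep_best and best_state is not None:
        model.load_state_dict(best_state)
    if out_path is not None:
        with open(out_path / "history.csv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=[
                    "epoch", "loss_lfm", "loss_flfm", "loss_lfm_epi",
                    "loss_flfm_epi", "loss_fuse", "total",
                ],
            )
            writer.writeheader()
            for i, bd in enumerate(history):
                writer.writerow({"epoch": i, **bd.as_dict()})
    return history
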