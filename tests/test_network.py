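"""Four-branch fusion network: adapters, cascade, loss, training loop."""

import numpy as np
import pytest

from lffusion import network as N
from lffusion.nn import autograd as ag
from lffusion.nn.autograd import Tensor
from lffusion.optics import InvalidConfigError


@pytest.fixture(scope="module")
def spec(desk_sample):
    return N.model_spec_for(desk_sample, unet_base=6, unified_channels=6)


@pytest.fixture(scope="module")
def model(spec):
    return N.FusionModel(spec, rng=0)


class TestAdapter:
    def test_resize_is_identity_at_target_size(self, rng):
        bs = N.BranchSpec("flfm", (7,), (16, 16), unified_channels=4)
        adapter = N.Adapter(bs, rng)
        x = Tensor(rng.random((1, 7, 16, 16)), requires_grad=False)
        resized = ag.bilinear_resize(x, bs.target_hw)
        np.testing.assert_array_equal(resized.data, x.data)

    def test_output_channels_unified_for_all_modalities(self, model, desk_sample):
        inputs = N.branch_inputs(desk_sample)
        for m in N.MODALITIES:
            stacks = [Tensor(a[None], requires_grad=False) for a in inputs[m]]
            feats = model.adapters[m](stacks)
            assert feats.data.shape[1] == model.spec.unified_channels
            assert feats.data.shape[2:] == model.spec.target_hw

    def test_lfm_channels_for_published_view_count(self):
        # 11 x 11 views stack to 121 input channels
        spec = N.ModelSpec(
            n_z=61, target_hw=(32, 32), lfm_channels=121,
            lfm_epi_channels=(10, 10),
        )
        assert spec.branch_spec("lfm").in_channels == (121,)

    def test_channel_mismatch_rejected(self, model, rng):
        stacks = [Tensor(rng.random((1, 3, 8, 8)), requires_grad=False)]
        with pytest.raises(InvalidConfigError):
            model.adapters["flfm"](stacks)


class TestBranchAndFusion:
    def test_branch_outputs_ground_truth_shape(self, model, desk_sample):
        outs = model.forward_full(desk_sample)
        gt = desk_sample.ground_truth.data
        for key in N.MODALITIES + ("fused",):
            assert outs[key].shape == gt.shape

    def test_fresh_fusion_block_returns_branch_average(self, rng):
        blk = N.FusionBlock(4, rng)
        a = Tensor(rng.random((1, 4, 6, 6)), requires_grad=False)
        b = Tensor(rng.random((1, 4, 6, 6)), requires_grad=False)
        out = blk(a, b)
        np.testing.assert_allclose(out.data, 0.5 * (a.data + b.data), atol=1e-12)

    def test_fusion_gradient_reaches_both_inputs(self, rng):
        blk = N.FusionBlock(4, rng)
        blk.c2.w.data = rng.normal(0, 0.1, size=blk.c2.w.data.shape)
        a = Tensor(rng.random((1, 4, 6, 6)))
        b = Tensor(rng.random((1, 4, 6, 6)))
        loss = ag.mse(blk(a, b), rng.random((1, 4, 6, 6)))
        loss.backward()
        assert np.isfinite(a.grad).all() and np.linalg.norm(a.grad) > 0
        assert np.isfinite(b.grad).all() and np.linalg.norm(b.grad) > 0

    def test_fusion_shape_mismatch_rejected(self, rng):
        blk = N.FusionBlock(4, rng)
        with pytest.raises(InvalidConfigError):
            blk(
                Tensor(np.zeros((1, 4, 6, 6))),
                Tensor(np.zeros((1, 4, 5, 6))),
            )

    def test_forward_deterministic(self, model, desk_sample):
        a = model.forward_full(desk_sample)["fused"]
        b = model.forward_full(desk_sample)["fused"]
        np.testing.assert_array_equal(a, b)

    def test_zeroed_branch_input_still_finite(self, model, desk_sample):
        inputs = {
            m: [a[None] for a in N.branch_inputs(desk_sample)[m]]
            for m in model.spec.modalities
        }
        inputs["lfm"] = [np.zeros_like(inputs["lfm"][0])]
        outs = model.forward_batch(inputs)
        for t in outs.values():
            assert np.isfinite(t.data).all()

    def test_every_branch_receives_gradient(self, model, desk_sample):
        inputs = {
            m: [a[None] for a in N.branch_inputs(desk_sample)[m]]
            for m in model.spec.modalities
        }
        model.zero_grad()
        outs = model.forward_batch(inputs)
        total, _ = N.multilevel_loss(outs, desk_sample.ground_truth.data[None])
        total.backward()
        for m in model.spec.modalities:
            norms = [np.linalg.norm(p.grad) for p in model.unets[m].parameters()
                     if p.grad is not None]
            assert norms and max(norms) > 0


class TestMultilevelLoss:
    def _outputs(self, gt, offsets):
        return {k: Tensor(gt + dv) for k, dv in offsets.items()}

    def test_zero_when_all_outputs_equal_gt(self, rng):
        gt = rng.random((3, 8, 8))
        outs = self._outputs(gt, {k: 0.0 for k in N.MODALITIES + ("fused",)})
        total, bd = N.multilevel_loss(outs, gt)
        assert total.data == 0.0
        assert bd.total == 0.0

    def test_constant_offset_closed_form(self, rng):
        gt = rng.random((3, 8, 8))
        offsets = {k: 0.0 for k in N.MODALITIES}
        offsets["fused"] = 1.0
        total, bd = N.multilevel_loss(self._outputs(gt, offsets), gt)
        assert total.data == pytest.approx(1.0, abs=1e-6)
        assert bd.loss_fuse == pytest.approx(1.0, abs=1e-12)

    def test_total_is_sum_of_terms(self, rng):
        gt = rng.random((3, 8, 8))
        outs = {k: Tensor(rng.random((3, 8, 8))) for k in N.MODALITIES + ("fused",)}
        total, bd = N.multilevel_loss(outs, gt)
        terms = [
            bd.loss_lfm, bd.loss_flfm, bd.loss_lfm_epi, bd.loss_flfm_epi,
            bd.loss_fuse,
        ]
        assert all(t >= 0 for t in terms)
        assert bd.total == pytest.approx(sum(terms), abs=1e-10)
        assert total.data == pytest.approx(bd.total, rel=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        gt = rng.random((3, 8, 8))
        outs = {"fused": Tensor(rng.random((3, 8, 7)))}
        with pytest.raises(InvalidConfigError):
            N.multilevel_loss(outs, gt)


class TestTraining:
    def test_overfits_single_sample(self, desk_sample):
        spec = N.model_spec_for(desk_sample, unet_base=8, unified_channels=8)
        model = N.FusionModel(spec, rng=3)
        cfg = N.TrainConfig(epochs=200, batch_size=1, learning_rate=3e-3, seed=3)
        hist = N.train(model, [desk_sample], cfg)
        assert hist[-1].total <= hist[0].total / 10.0

    def test_same_seed_reproduces_first_epoch_loss(self, desk_sample):
        spec = N.model_spec_for(desk_sample, unet_base=4, unified_channels=4)
        losses = []
        for _ in range(2):
            model = N.FusionModel(spec, rng=11)
            hist = N.train(
                model, [desk_sample],
                N.TrainConfig(epochs=1, batch_size=1, learning_rate=1e-3, seed=11),
            )
            losses.append(hist[0].total)
        assert losses[0] == losses[1]

    def test_empty_dataset_rejected(self, spec):
        model = N.FusionModel(spec, rng=0)
        with pytest.raises(InvalidConfigError):
            N.train(model, [], N.TrainConfig(epochs=1))

    def test_history_written_to_csv(self, desk_sample, tmp_path):
        spec = N.model_spec_for(desk_sample, unet_base=4, unified_channels=4)
        model = N.FusionModel(spec, rng=0)
        N.train(
            model, [desk_sample],
            N.TrainConfig(epochs=2, batch_size=1, learning_rate=1e-3, seed=0,
                          checkpoint_every=1),
            out_dir=tmp_path,
        )
        assert (tmp_path / "history.csv").exists()
        assert (tmp_path / "checkpoint_0002.npz").exists()
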