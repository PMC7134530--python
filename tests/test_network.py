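"""Model assembly: multiview fusion, task heads, losses, ablation switches,
forward-pass contracts and multi-task gradient flow."""

import numpy as np
import pytest

import atriaseg as ag
from atriaseg.autodiff import Tensor
from atriaseg.network import TaskHead, variant_config


class TestFuseViews:
    def test_zero_complements_leave_axial_unchanged(self, rng):
        fa = rng.normal(size=(4, 2, 4, 4))
        z = np.zeros_like(fa)
        np.testing.assert_allclose(ag.fuse_views(fa, z, z).data, fa, atol=1e-7)

    def test_zero_axial_sums_transposed_complements(self, rng):
        v = rng.normal(size=(4, 2, 4, 4))
        fused = ag.fuse_views(np.zeros_like(v), v, np.zeros_like(v))
        expected = ag.transpose_to_axial(v, "sagittal")
        np.testing.assert_allclose(fused.data, expected, atol=1e-6)
        # same complement fed through both orthogonal views doubles nothing:
        # each view is transposed by its own permutation
        fused2 = ag.fuse_views(np.zeros_like(v), v, v)
        expected2 = expected + ag.transpose_to_axial(v, "coronal")
        np.testing.assert_allclose(fused2.data, expected2, atol=1e-6)

    def test_elementwise_definition_on_small_grid(self, rng):
        """Brute force on a 3^3 grid with one channel: fused voxel (z, y, x)
        must equal Fa[z,y,x] + Fs[x,z,y] + Fc[y,z,x]."""
        fa = rng.normal(size=(3, 1, 3, 3))
        fs = rng.normal(size=(3, 1, 3, 3))
        fc = rng.normal(size=(3, 1, 3, 3))
        fused = ag.fuse_views(fa, fs, fc).data
        for z in range(3):
            for y in range(3):
                for x in range(3):
                    expected = fa[z, 0, y, x] + fs[x, 0, z, y] + fc[y, 0, z, x]
                    assert fused[z, 0, y, x] == pytest.approx(expected, abs=1e-6)

    def test_incompatible_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            ag.fuse_views(rng.normal(size=(3, 1, 3, 3)),
                          rng.normal(size=(4, 1, 4, 4)),
                          rng.normal(size=(3, 1, 3, 3)))


class TestTaskHeads:
    @pytest.mark.parametrize("final_kernel", [3, 1])
    def test_zero_final_layer_gives_uniform_half(self, rng, final_kernel):
        head = TaskHead(4, final_kernel=final_kernel, rng=np.random.default_rng(0))
        head.set_mode("identity")
        head.final.weight.data = np.zeros_like(head.final.weight.data)
        head.final.bias.data = np.zeros_like(head.final.bias.data)
        out = head(Tensor(rng.normal(size=(2, 4, 8, 8))))
        np.testing.assert_allclose(out.data, 0.5, atol=1e-7)

    def test_output_contract_and_concat_width(self, rng):
        head = TaskHead(4, final_kernel=3, rng=np.random.default_rng(0))
        head.set_mode("eval")
        out = head(Tensor(rng.normal(size=(2, 4, 8, 8))))
        assert out.data.shape == (2, 1, 8, 8)
        assert 0.0 < out.data.min() and out.data.max() < 1.0
        # the two 16-kernel layers concatenate into a 32-channel final input
        assert head.final.weight.data.shape[1] == 32

    def test_one_by_one_final_layer_mixes_no_space(self, rng):
        """Impulse check: perturbing the concatenated features at one pixel
        must change the 1x1 final layer's output at that pixel only."""
        head = TaskHead(2, final_kernel=1, rng=np.random.default_rng(3))
        feats = rng.normal(size=(1, 32, 7, 7))
        base = head.final(Tensor(feats))
        bumped = feats.copy()
        bumped[0, :, 3, 4] += 1.0
        out = head.final(Tensor(bumped))
        diff = np.abs(out.data - base.data)[0, 0]
        assert diff[3, 4] > 0
        diff[3, 4] = 0
        assert np.all(diff == 0)


class TestForward:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        cfg = ag.MVTTConfig(cube_edge=16, base_channels=2, n_res_blocks=1)
        model = ag.MVTTNetwork(cfg, seed=0)
        model.set_mode("eval")
        return model

    def test_output_shapes_and_ranges(self, tiny_model, rng):
        vol = rng.normal(size=(16, 16, 16)).astype(np.float32)
        out = tiny_model.forward(vol)
        assert out.anatomy_volume().shape == (16, 16, 16)
        assert out.scar_volume().shape == (16, 16, 16)
        for arr in (out.anatomy_volume(), out.scar_volume()):
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_inference_is_deterministic(self, tiny_model, rng):
        vol = rng.normal(size=(16, 16, 16)).astype(np.float32)
        a = tiny_model.forward(vol)
        b = tiny_model.forward(vol)
        np.testing.assert_array_equal(a.anatomy_volume(), b.anatomy_volume())
        np.testing.assert_array_equal(a.scar_volume(), b.scar_volume())

    def test_noncubic_input_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((8, 16, 16), dtype=np.float32))

    def test_ablation_flags_shape_parameter_registry(self):
        def names(**kw):
            cfg = ag.MVTTConfig(cube_edge=16, base_channels=2, n_res_blocks=1, **kw)
            return set(ag.MVTTNetwork(cfg, seed=0).parameters())

        full = names()
        assert any(n.startswith("attention_net") for n in full)
        assert any(n.startswith("axial_net.clstm") for n in full)
        assert any(n.startswith("sagittal_net") for n in full)
        # removing attention removes exactly the mask-branch parameters
        no_at = names(use_attention=False)
        assert no_at == {n for n in full if not n.startswith("attention_net")}
        # single-view drops the orthogonal branches
        sv = names(use_multiview=False)
        assert not any(n.startswith(("sagittal_net", "coronal_net")) for n in sv)
        # single-task variants drop the other head (and attention for anatomy)
        assert not any(n.startswith("scar_head") for n in names(tasks="anatomy_only"))
        assert not any(n.startswith("anatomy_head") for n in names(tasks="scar_only"))
        # no ConvLSTM: recurrence replaced by a third encoder conv
        no_lstm = names(use_convlstm=False)
        assert not any(".clstm" in n for n in no_lstm)
        assert any(n.startswith("axial_net.enc3") for n in no_lstm)

    def test_kernel_size_switch_changes_kernels(self):
        cfg = ag.MVTTConfig(cube_edge=16, base_channels=2, kernel_size=5)
        model = ag.MVTTNetwork(cfg, seed=0)
        assert model.axial_net.enc1.conv.weight.data.shape[-2:] == (5, 5)

    def test_plain_conv_mode_disables_dilation(self):
        cfg = ag.MVTTConfig(cube_edge=16, base_channels=2, conv_mode="plain")
        model = ag.MVTTNetwork(cfg, seed=0)
        rates = [l.conv.dilation for l in model.sagittal_net.blocks[0].layers]
        assert rates == [1, 1, 1]
        hdc = ag.MVTTNetwork(ag.MVTTConfig(cube_edge=16, base_channels=2), seed=0)
        assert [l.conv.dilation for l in hdc.sagittal_net.blocks[0].layers] == [1, 2, 5]

    def test_variant_lookup(self):
        assert variant_config("MV").use_convlstm is False
        assert variant_config("SV+CLSTM").use_multiview is False
        assert variant_config("AFT").convlstm_activation == "tanh"
        with pytest.raises(KeyError):
            variant_config("nope")


class TestLosses:
    def test_dice_loss_perfect_prediction_is_zero(self, rng):
        g = (rng.uniform(size=(6, 6, 6)) > 0.5).astype(np.float32)
        assert float(ag.dice_loss(Tensor(g), g).data) == pytest.approx(0.0, abs=1e-6)

    def test_dice_loss_disjoint_supports_approach_one(self):
        m = np.zeros((8, 8, 8), dtype=np.float32)
        g = np.zeros_like(m)
        m[:4] = 1.0
        g[4:] = 1.0
        loss = float(ag.dice_loss(Tensor(m), g).data)
        assert loss > 0.99

    def test_dice_loss_uniform_half_against_half_cover(self):
        m = np.full((10, 10, 10), 0.5, dtype=np.float64)
        g = np.zeros_like(m)
        g[:5] = 1.0
        # 1 - (2*0.25N) / (0.5N + 0.5N) = 0.5, up to the eps smoothing
        assert float(ag.dice_loss(Tensor(m), g).data) == pytest.approx(0.5, abs=1e-3)

    def test_hybrid_loss_is_additive(self, rng):
        ml = Tensor(rng.uniform(size=(5, 5, 5)))
        mas = Tensor(rng.uniform(size=(5, 5, 5)))
        gl = (rng.uniform(size=(5, 5, 5)) > 0.4).astype(np.float32)
        gas = (rng.uniform(size=(5, 5, 5)) > 0.8).astype(np.float32)
        total = float(ag.hybrid_loss(ml, mas, gl, gas).data)
        parts = float(ag.dice_loss(ml, gl).data) + float(ag.dice_loss(mas, gas).data)
        assert total == pytest.approx(parts, abs=1e-6)

    def test_hybrid_loss_requires_both_tasks(self, rng):
        with pytest.raises(ValueError):
            ag.hybrid_loss(None, Tensor(rng.uniform(size=(3, 3, 3))),
                           np.zeros((3, 3, 3)), np.zeros((3, 3, 3)))

    def test_anatomy_perfect_scar_disjoint(self):
        gl = np.zeros((8, 8, 8), dtype=np.float32)
        gl[2:6] = 1.0
        mas = np.zeros_like(gl)
        gas = np.zeros_like(gl)
        mas[:2] = 1.0
        gas[6:] = 1.0
        loss = float(ag.hybrid_loss(Tensor(gl), Tensor(mas), gl, gas).data)
        assert loss == pytest.approx(1.0, abs=0.01)


class TestMultiTaskGradients:
    def test_shared_subnetworks_receive_gradients_from_both_tasks(self, rng):
        cfg = ag.MVTTConfig(cube_edge=12, base_channels=2, n_res_blocks=1)
        model = ag.MVTTNetwork(cfg, seed=1)
        model.set_mode("train")
        vol = rng.normal(size=(12, 12, 12)).astype(np.float32)
        gl = (rng.uniform(size=(12, 12, 12)) > 0.5).astype(np.float32)
        gas = (rng.uniform(size=(12, 12, 12)) > 0.9).astype(np.float32)
        shared_prefixes = ("axial_net", "sagittal_net", "coronal_net")

        def shared_grad_norms(loss_tensor):
            model.zero_grad()
            loss_tensor.backward()
            return {
                name: 0.0 if p.grad is None else float(np.abs(p.grad).sum())
                for name, p in model.parameters().items()
                if name.startswith(shared_prefixes) and p.data.ndim == 4
            }

        out = model.forward(vol)
        anat = shared_grad_norms(ag.dice_loss(out.anatomy_prob, gl))
        out = model.forward(vol)
        scar = shared_grad_norms(ag.dice_loss(out.scar_prob, gas))
        # every shared convolution kernel is driven by both loss terms
        assert all(v > 0 for v in anat.values())
        assert all(v > 0 for v in scar.values())

    def test_loss_invariant_to_spatial_permutation_with_1x1_kernels(self, rng):
        """Degeneracy check: with every convolution 1x1 the computation is
        pixelwise, so permuting the in-plane axes of input and targets
        consistently leaves the loss unchanged."""
        cfg = ag.MVTTConfig(cube_edge=8, base_channels=2, kernel_size=1,
                            n_res_blocks=1, dilation_cycle=(1, 1))
        model = ag.MVTTNetwork(cfg, seed=2)
        # the task heads keep their fixed 3x3 layers; zero the off-centre
        # taps so every convolution in the graph acts pixelwise
        for head in (model.anatomy_head, model.scar_head):
            for conv in (head.layer1.conv, head.layer2.conv, head.final):
                w = conv.weight.data
                if w.shape[-1] == 3:
                    mask = np.zeros_like(w)
                    mask[..., 1, 1] = 1.0
                    conv.weight.data = w * mask
        model.set_mode("train")
        vol = rng.normal(size=(8, 8, 8)).astype(np.float32)
        gl = (rng.uniform(size=(8, 8, 8)) > 0.5).astype(np.float32)
        gas = (rng.uniform(size=(8, 8, 8)) > 0.8).astype(np.float32)
        out = model.forward(vol)
        base = float(ag.hybrid_loss(out.anatomy_prob, out.scar_prob, gl, gas).data)
        py = rng.permutation(8)
        px = rng.permutation(8)
        vol_p = vol[:, py][:, :, px]
        out_p = model.forward(vol_p)
        perm = float(
            ag.hybrid_loss(
                out_p.anatomy_prob, out_p.scar_prob, gl[:, py][:, :, px],
                gas[:, py][:, :, px]
            ).data
        )
        assert perm == pytest.approx(base, rel=1e-4)


class TestAttentionMaskRange:
    def test_network_attention_masks_lie_strictly_inside_unit_interval(self, rng):
        from atriaseg.autodiff import Tensor

        cfg = ag.MVTTConfig(cube_edge=12, base_channels=3, n_res_blocks=1)
        model = ag.MVTTNetwork(cfg, seed=4)
        model.set_mode("eval")
        stack = Tensor(rng.normal(size=(12, 1, 12, 12)).astype(np.float32))
        mask = model.attention_net(stack)
        assert 0.0 < mask.data.min() and mask.data.max() < 1.0
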