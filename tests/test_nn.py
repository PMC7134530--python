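"""ConvLSTM cell, hybrid-dilated-convolution blocks and attention primitives."""

import numpy as np
import pytest

from atriaseg.autodiff import Tensor
from atriaseg.nn import (
    ConvLSTMParams,
    ConvLSTMState,
    HDCBlock,
    HDCBlockConfig,
    attention_modulate,
    convlstm_sequence,
    convlstm_step,
    sigmoid_mask,
)
from oracles import scalar_convlstm_oracle

_SCALAR_KEYS = [
    "wxf", "whf", "wcf", "bf", "wxi", "whi", "wci", "bi",
    "wxc", "whc", "bc", "wxo", "who", "wco", "bo",
]


def scalar_params(rng) -> tuple[ConvLSTMParams, dict]:
    """1x1-spatial, 1x1-kernel parameters shared with the scalar oracle."""
    vals = {k: float(rng.normal()) for k in _SCALAR_KEYS}
    p = ConvLSTMParams.init(1, 1, 1, (1, 1))
    for k, v in vals.items():
        getattr(p, k).data = np.full_like(getattr(p, k).data, v, dtype=np.float64)
    return p, vals


class TestConvLSTM:
    def test_zero_parameters_give_zero_state(self):
        p = ConvLSTMParams.init(2, 3, 3, (5, 5))
        for t in p.parameters().values():
            t.data = np.zeros_like(t.data)
        state = ConvLSTMState.zeros(3, (5, 5))
        out = convlstm_step(p, np.random.default_rng(0).normal(size=(1, 2, 5, 5)), state)
        # gates sit at 0.5 but the candidate passes ReLU(0) = 0
        np.testing.assert_allclose(out.c.data, 0.0, atol=1e-7)
        np.testing.assert_allclose(out.h.data, 0.0, atol=1e-7)

    def test_matches_scalar_oracle_over_random_parameters(self, rng):
        for _ in range(20):
            p, vals = scalar_params(rng)
            xs = [float(rng.normal()) for _ in range(10)]
            expected = scalar_convlstm_oracle(vals, xs)
            state = ConvLSTMState.zeros(1, (1, 1), dtype=np.float64)
            for x, (h_ref, c_ref) in zip(xs, expected):
                state = convlstm_step(
                    p, np.full((1, 1, 1, 1), x, dtype=np.float64), state
                )
                assert state.h.data.item() == pytest.approx(h_ref, abs=1e-6)
                assert state.c.data.item() == pytest.approx(c_ref, abs=1e-6)

    def test_saturated_closed_gates_suppress_memory(self, rng):
        p, _ = scalar_params(rng)
        p.bf.data = np.full_like(p.bf.data, -30.0)  # forget gate -> 0
        p.bi.data = np.full_like(p.bi.data, -30.0)  # input gate -> 0
        state = ConvLSTMState.zeros(1, (1, 1), dtype=np.float64)
        for x in [5.0, -3.0, 8.0]:
            state = convlstm_step(p, np.full((1, 1, 1, 1), x), state)
            assert abs(state.c.data.item()) < 1e-8

    def test_cell_state_boundedness(self, rng):
        # c_t is a gated convex-ish update: |c_t| <= |c_{t-1}| + max ReLU(candidate)
        p, vals = scalar_params(rng)
        state = ConvLSTMState.zeros(1, (1, 1), dtype=np.float64)
        for _ in range(20):
            x = float(rng.normal())
            prev_c = state.c.data.item()
            cand = max(0.0, vals["wxc"] * x + vals["whc"] * state.h.data.item() + vals["bc"])
            state = convlstm_step(p, np.full((1, 1, 1, 1), x), state)
            assert abs(state.c.data.item()) <= abs(prev_c) + cand + 1e-9


class TestConvLSTMSequence:
    def test_single_slice_equals_single_step(self, rng):
        p = ConvLSTMParams.init(1, 2, 3, (6, 6), rng=np.random.default_rng(5))
        x = rng.normal(size=(1, 1, 6, 6))
        seq = convlstm_sequence(p, [x])
        step = convlstm_step(p, x, ConvLSTMState.zeros(2, (6, 6)))
        np.testing.assert_allclose(seq[0].data, step.h.data, atol=1e-7)

    def test_memory_cell_carries_state_even_without_recurrent_weights(self, rng):
        # with Wh. = Wc. = 0 the gates see only x_t, but the cell update
        # c_t = f o c_{t-1} + i o cand still accumulates across steps, so
        # identical slices do NOT give identical outputs ...
        p = ConvLSTMParams.init(1, 2, 3, (6, 6), rng=np.random.default_rng(5))
        for name in ("whf", "whi", "whc", "who", "wcf", "wci", "wco"):
            t = getattr(p, name)
            t.data = np.zeros_like(t.data)
        x = rng.normal(size=(1, 1, 6, 6))
        outs = convlstm_sequence(p, [x, x, x])
        assert not np.allclose(outs[1].data, outs[0].data, atol=1e-6)
        # ... unless the forget gate is also saturated closed, which removes
        # the only remaining state path: then every step is identical
        p.bf.data = np.full_like(p.bf.data, -30.0)
        outs = convlstm_sequence(p, [x, x, x])
        for h in outs[1:]:
            np.testing.assert_allclose(h.data, outs[0].data, atol=1e-6)

    def test_order_sensitivity_with_recurrent_weights(self, rng):
        # numeric two-step counterexample: generic recurrent weights make the
        # final hidden state depend on slice order
        p = ConvLSTMParams.init(1, 1, 1, (1, 1))
        for t in p.parameters().values():
            t.data = np.full_like(t.data, 0.3)
        a = np.full((1, 1, 1, 1), 1.0)
        b = np.full((1, 1, 1, 1), 0.5)
        fwd = convlstm_sequence(p, [a, b])[-1]
        rev = convlstm_sequence(p, [b, a])[-1]
        assert abs(fwd.data.item() - rev.data.item()) > 1e-4

    def test_empty_sequence_rejected(self):
        p = ConvLSTMParams.init(1, 1, 1, (1, 1))
        with pytest.raises(ValueError):
            convlstm_sequence(p, [])


class TestHDCBlock:
    def test_spatial_shape_preserved_at_every_dilation(self, rng):
        cfg = HDCBlockConfig(channels=3, dilation_cycle=(1, 2, 5))
        block = HDCBlock(cfg, rng=np.random.default_rng(2))
        x = Tensor(rng.normal(size=(2, 3, 20, 20)))
        assert block(x).data.shape == (2, 3, 20, 20)

    def test_residual_identity_with_zeroed_convolutions(self, rng):
        cfg = HDCBlockConfig(channels=2, residual=True)
        block = HDCBlock(cfg)
        block.set_mode("identity")
        for layer in block.layers:
            layer.conv.weight.data = np.zeros_like(layer.conv.weight.data)
            layer.conv.bias.data = np.zeros_like(layer.conv.bias.data)
        x = Tensor(rng.normal(size=(1, 2, 8, 8)))
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-7)

    def test_receptive_field_of_125_cycle_is_17x17(self):
        # brute force: all-ones kernels, impulse input; the (1,2,5) cycle of
        # 3x3 convolutions must light up exactly a 17x17 neighbourhood
        cfg = HDCBlockConfig(channels=1, dilation_cycle=(1, 2, 5), residual=False)
        block = HDCBlock(cfg)
        block.set_mode("identity")
        for layer in block.layers:
            layer.conv.weight.data = np.ones_like(layer.conv.weight.data)
            layer.conv.bias.data = np.zeros_like(layer.conv.bias.data)
        x = np.zeros((1, 1, 41, 41), dtype=np.float32)
        x[0, 0, 20, 20] = 1.0
        out = block(Tensor(x)).data[0, 0]
        nz_rows = np.where(out.any(axis=1))[0]
        nz_cols = np.where(out.any(axis=0))[0]
        assert nz_rows.max() - nz_rows.min() + 1 == 17
        assert nz_cols.max() - nz_cols.min() + 1 == 17

    def test_channel_mismatch_rejected(self, rng):
        block = HDCBlock(HDCBlockConfig(channels=3))
        with pytest.raises(ValueError, match="channel"):
            block(Tensor(rng.normal(size=(1, 2, 8, 8))))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            HDCBlockConfig(kernel_size=4)
        with pytest.raises(ValueError):
            HDCBlockConfig(dilation_cycle=())


class TestAttention:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, 0.5), (np.log(3.0), 0.75), (40.0, 1.0), (-40.0, 0.0)],
    )
    def test_sigmoid_mask_values(self, value, expected):
        out = sigmoid_mask(np.full((3, 3), value))
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_modulation_limits(self, rng):
        f = rng.normal(size=(2, 3, 4, 4))
        np.testing.assert_allclose(
            attention_modulate(np.zeros_like(f), f).data, f, atol=1e-7
        )
        np.testing.assert_allclose(
            attention_modulate(np.ones_like(f), f).data, 2.0 * f, atol=1e-6
        )
        np.testing.assert_allclose(
            attention_modulate(rng.normal(size=f.shape), np.zeros_like(f)).data,
            0.0, atol=1e-7,
        )

    def test_single_channel_mask_broadcasts(self, rng):
        mask = rng.uniform(size=(2, 1, 4, 4))
        trunk = rng.normal(size=(2, 3, 4, 4))
        out = attention_modulate(mask, trunk)
        np.testing.assert_allclose(out.data, (1 + mask) * trunk, rtol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_modulate(rng.normal(size=(1, 2, 4, 4)),
                               rng.normal(size=(1, 2, 5, 5)))
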