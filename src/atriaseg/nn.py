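"""Neural building blocks: ConvLSTM cell, hybrid-dilated-convolution blocks,
batch-norm layers and the sigmoid attention mask with skip-sum modulation.

The ConvLSTM gate equations are, with ``*`` a 2D convolution and ``o`` the
Hadamard product::

    f_t = sigma(Wxf * x_t + Whf * h_{t-1} + Wcf o c_{t-1} + bf)
    i_t = sigma(Wxi * x_t + Whi * h_{t-1} + Wci o c_{t-1} + bi)
    c_t = f_t o c_{t-1} + i_t o act(Wxc * x_t + Whc * h_{t-1} + bc)
    o_t = sigma(Wxo * x_t + Who * h_{t-1} + Wco o c_t + bo)
    h_t = o_t o act(c_t)

where ``act`` is ReLU by default (tanh available as the activation-function
ablation). The peephole terms (Wc. o c) are learned per-location,
per-channel weight maps, literally as the Hadamard notation states.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .autodiff import (
    Tensor,
    batch_norm2d,
    concat,
    conv2d,
    mul,
    narrow,
    relu,
    sigmoid,
    tanh,
)

_ACTIVATIONS = {"relu": relu, "tanh": tanh}


def he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> Tensor:
    """Fan-in-scaled Gaussian initialization (He et al. style)."""
    std = np.sqrt(2.0 / max(fan_in, 1))
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


# ---------------------------------------------------------------------------
# Module infrastructure
# ---------------------------------------------------------------------------

class Module:
    """Minimal container tracking parameters, buffers and train/eval mode."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                params[full] = value
            elif isinstance(value, Module):
                params.update(value.parameters(f"{full}."))
            elif isinstance(value, ConvLSTMParams):
                params.update(value.parameters(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.parameters(f"{full}.{i}."))
        return params

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        bufs: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, BatchNorm2d):
                bufs[f"{full}.running_mean"] = value.running_mean
                bufs[f"{full}.running_var"] = value.running_var
            elif isinstance(value, Module):
                bufs.update(value.buffers(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        bufs.update(item.buffers(f"{full}.{i}."))
        return bufs

    def set_mode(self, mode: str) -> None:
        """Switch every batch-norm layer to 'train', 'eval' or 'identity'."""
        for value in vars(self).values():
            if isinstance(value, BatchNorm2d):
                value.mode = mode
            elif isinstance(value, Module):
                value.set_mode(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_mode(mode)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.parameters().items()}
        state.update({k: v.copy() for k, v in self.buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        bufs = self.buffers()
        for key, value in state.items():
            if key in params:
                params[key].data = value.copy()
            elif key in bufs:
                bufs[key][...] = value
            else:
                raise KeyError(f"unknown state entry {key!r}")

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = he_init(rng, (cout, cin, k, k), fan_in=cin * k * k)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.mode = "train"

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            mode=self.mode, momentum=self.momentum, eps=self.eps,
        )


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU, the workhorse encoder layer."""

    def __init__(self, cin, cout, k, dilation=1, rng=None):
        self.conv = Conv2d(cin, cout, k, dilation=dilation, rng=rng)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))


# ---------------------------------------------------------------------------
# Hybrid dilated convolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HDCBlockConfig:
    """Configuration of one hybrid-dilated-convolution residual block.

    The default dilation cycle (1, 2, 5) has no common divisor, so the
    stacked receptive field covers its neighbourhood without the periodic
    gaps ('gridding') that a fixed dilation rate produces.
    """

    kernel_size: int = 3
    channels: int = 8
    dilation_cycle: tuple[int, ...] = (1, 2, 5)
    residual: bool = True

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if len(self.dilation_cycle) == 0 or any(d < 1 for d in self.dilation_cycle):
            raise ValueError("dilation_cycle must be non-empty positive integers")


class HDCBlock(Module):
    """Dilated convolutions cycling through the configured rates, each
    followed by batch norm and ReLU; a residual shortcut adds the input.
    Spatial size is unchanged at every rate."""

    def __init__(self, config: HDCBlockConfig, rng=None):
        self.config = config
        self.layers = [
            ConvBNReLU(config.channels, config.channels, config.kernel_size,
                       dilation=d, rng=rng)
            for d in config.dilation_cycle
        ]

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.config.channels:
            raise ValueError(
                f"channel mismatch: got {x.data.shape[1]}, expected {self.config.channels}"
            )
        out = x
        for layer in self.layers:
            out = layer(out)
        if self.config.residual:
            out = out + x
        return out


def hdc_block(config: HDCBlockConfig, x, rng=None) -> Tensor:
    """Functional form of :class:`HDCBlock` (fresh parameters per call)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    return HDCBlock(config, rng=rng)(x)


# ---------------------------------------------------------------------------
# ConvLSTM
# ---------------------------------------------------------------------------

@dataclass
class ConvLSTMParams:
    """Weights of one ConvLSTM cell.

    Convolution kernels are (out, in, k, k); peephole Hadamard maps match the
    state shape (channels, H, W); biases are per-channel.
    """

    wxf: Tensor; whf: Tensor
    wxi: Tensor; whi: Tensor
    wxc: Tensor; whc: Tensor
    wxo: Tensor; who: Tensor
    wcf: Tensor; wci: Tensor; wco: Tensor
    bf: Tensor; bi: Tensor; bc: Tensor; bo: Tensor

    @classmethod
    def init(cls, cin: int, channels: int, k: int, spatial: tuple[int, int],
             rng: np.random.Generator | None = None) -> "ConvLSTMParams":
        """Initialization keeping the recurrence subcritical.

        The ReLU state activation makes the cell unbounded, so the recurrent
        loop gain must start below one: gate kernels use Xavier scale (they
        feed sigmoids), the candidate's input kernel uses He scale (it feeds
        the ReLU), recurrent kernels are damped by 0.5, the peephole maps
        start at zero, and the forget bias starts at -1 so the memory cell
        begins as a leaky (factor ~0.27) rather than neutral accumulator.
        """
        rng = rng or np.random.default_rng(0)
        h, w = spatial

        def kern(ci, gain):
            std = gain / np.sqrt(ci * k * k)
            return Tensor(
                rng.normal(0.0, std, size=(channels, ci, k, k)).astype(np.float32),
                requires_grad=True,
            )

        def peep():
            return Tensor(np.zeros((channels, h, w), dtype=np.float32), requires_grad=True)

        def bias(value=0.0):
            return Tensor(np.full(channels, value, dtype=np.float32), requires_grad=True)

        return cls(
            wxf=kern(cin, 1.0), whf=kern(channels, 0.5),
            wxi=kern(cin, 1.0), whi=kern(channels, 0.5),
            wxc=kern(cin, np.sqrt(2.0)), whc=kern(channels, 0.5),
            wxo=kern(cin, 1.0), who=kern(channels, 0.5),
            wcf=peep(), wci=peep(), wco=peep(),
            bf=bias(-1.0), bi=bias(), bc=bias(), bo=bias(),
        )

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        return {f"{prefix}{f.name}": getattr(self, f.name) for f in dc_fields(self)}

    @property
    def channels(self) -> int:
        return self.wxf.data.shape[0]


@dataclass
class ConvLSTMState:
    """Hidden map h_t and memory cell c_t carried across ordered slices."""

    h: Tensor
    c: Tensor

    @classmethod
    def zeros(cls, channels: int, spatial: tuple[int, int], dtype=np.float32) -> "ConvLSTMState":
        shape = (1, channels, *spatial)
        return cls(Tensor(np.zeros(shape, dtype=dtype)), Tensor(np.zeros(shape, dtype=dtype)))


def convlstm_step(params: ConvLSTMParams, x_t, state: ConvLSTMState,
                  activation: str = "relu") -> ConvLSTMState:
    """One gate update of the ConvLSTM recurrence (see module docstring).

    The four input and four recurrent convolutions are evaluated as two
    convolutions with the gate kernels stacked along the output channels —
    algebraically identical to applying each kernel separately, since a
    convolution is independent per output channel.
    """
    act = _ACTIVATIONS[activation]
    x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
    h_prev, c_prev = state.h, state.c
    n_c = params.channels
    wx = concat([params.wxf, params.wxi, params.wxc, params.wxo], axis=0)
    wh = concat([params.whf, params.whi, params.whc, params.who], axis=0)
    bias = concat([params.bf, params.bi, params.bc, params.bo], axis=0)
    pre = conv2d(x_t, wx, bias) + conv2d(h_prev, wh)
    f_pre = narrow(pre, 1, 0, n_c)
    i_pre = narrow(pre, 1, n_c, n_c)
    c_pre = narrow(pre, 1, 2 * n_c, n_c)
    o_pre = narrow(pre, 1, 3 * n_c, n_c)
    f = sigmoid(f_pre + mul(params.wcf, c_prev))
    i = sigmoid(i_pre + mul(params.wci, c_prev))
    c = mul(f, c_prev) + mul(i, act(c_pre))
    o = sigmoid(o_pre + mul(params.wco, c))
    h = mul(o, act(c))
    return ConvLSTMState(h=h, c=c)


def convlstm_sequence(params: ConvLSTMParams, slices, activation: str = "relu") -> list[Tensor]:
    """Run the cell over an ordered slice sequence from a zero initial state,
    returning every hidden map h_t in order."""
    slices = list(slices)
    if len(slices) == 0:
        raise ValueError("convlstm_sequence requires at least one slice")
    first = slices[0] if isinstance(slices[0], Tensor) else Tensor(slices[0])
    spatial = first.data.shape[-2:]
    state = ConvLSTMState.zeros(params.channels, spatial, dtype=first.data.dtype)
    outputs = []
    for x_t in slices:
        state = convlstm_step(params, x_t, state, activation=activation)
        outputs.append(state.h)
    return outputs


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def sigmoid_mask(x) -> Tensor:
    """Normalize mask-branch features to (0, 1): AM = 1 / (1 + exp(-x))."""
    return sigmoid(x if isinstance(x, Tensor) else Tensor(x))


def attention_modulate(mask, trunk) -> Tensor:
    """Apply the attention mask with a skip sum: O = (1 + AM) o F.

    The mask must match the trunk spatially; a single-channel mask is
    broadcast across the trunk channels.
    """
    mask = mask if isinstance(mask, Tensor) else Tensor(mask)
    trunk = trunk if isinstance(trunk, Tensor) else Tensor(trunk)
    ms, ts = mask.data.shape, trunk.data.shape
    compatible = ms == ts or (
        len(ms) == len(ts) == 4 and ms[1] == 1 and ms[0] == ts[0] and ms[2:] == ts[2:]
    )
    if not compatible:
        raise ValueError(f"mask shape {ms} incompatible with trunk shape {ts}")
    return mul(1.0 + mask, trunk)
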