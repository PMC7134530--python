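"""The multiview two-task (MVTT) recursive attention segmentation model.

Three subnetworks share one fused feature stack: a sequence-learning branch
runs a ConvLSTM over the ordered axial slices, two dilated-residual branches
extract complementary features from the sagittal and coronal views, and the
three stacks are fused by transposing the orthogonal views into axial order
and summing,

    F_v = F_a + T F_c + T F_s .

An anatomy head maps F_v to the left-atrium probability volume m_l. A
dilated attention branch learns a mask AM from the raw axial slices; the
scar head consumes the modulated trunk O = (1 + AM) o F_v and outputs the
scar probability volume m_as. Both tasks are trained jointly with a hybrid
soft-Dice loss L = delta(m_l, g_l) + delta(m_as, g_as).

Every architectural ingredient is an ablation switch (single-view vs
multiview, with/without ConvLSTM, with/without attention, single-task
variants, kernel size, ConvLSTM activation, HDC vs plain convolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, mul, narrow, permute, sigmoid, tsum
from .nn import (
    Conv2d,
    ConvBNReLU,
    ConvLSTMParams,
    ConvLSTMState,
    HDCBlock,
    HDCBlockConfig,
    Module,
    attention_modulate,
    convlstm_step,
    sigmoid_mask,
)
from .volumes import Volume, _VIEW_TO_AXIAL_4D

_HEAD_CHANNELS = 16  # two 16-kernel layers, concatenated to 32, per head


@dataclass(frozen=True)
class MVTTConfig:
    """Architecture switches for the full model and all its ablations.

    The named variants of the ablation study map onto the flags as:
    SV+CLSTM (use_multiview=False), MV (use_convlstm=False),
    MV+AT (no ConvLSTM, attention on), MV+CLSTM (no attention),
    SV+CLSTM+AT (single view), S-LA/PV (tasks='anatomy_only'),
    S-Scar (tasks='scar_only'), K5 (kernel_size=5), AFT
    (convlstm_activation='tanh'), NDC (conv_mode='plain').
    """

    use_multiview: bool = True
    use_convlstm: bool = True
    use_attention: bool = True
    kernel_size: int = 3
    convlstm_activation: str = "relu"
    conv_mode: str = "hdc"
    tasks: str = "both"
    cube_edge: int = 48
    base_channels: int = 6
    dilation_cycle: tuple[int, ...] = (1, 2, 5)
    n_res_blocks: int = 1

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.convlstm_activation not in ("relu", "tanh"):
            raise ValueError("convlstm_activation must be 'relu' or 'tanh'")
        if self.conv_mode not in ("hdc", "plain"):
            raise ValueError("conv_mode must be 'hdc' or 'plain'")
        if self.tasks not in ("both", "anatomy_only", "scar_only"):
            raise ValueError("tasks must be 'both', 'anatomy_only' or 'scar_only'")


# Named variants used throughout the ablation studies.
VARIANTS: dict[str, dict] = {
    "MVTT": {},
    "SV+CLSTM": {"use_multiview": False, "use_attention": False},
    "MV": {"use_convlstm": False, "use_attention": False},
    "MV+AT": {"use_convlstm": False},
    "MV+CLSTM": {"use_attention": False},
    "SV+CLSTM+AT": {"use_multiview": False},
    "S-LA/PV": {"tasks": "anatomy_only"},
    "S-Scar": {"tasks": "scar_only"},
    "K5": {"kernel_size": 5},
    "AFT": {"convlstm_activation": "tanh"},
    "NDC": {"conv_mode": "plain"},
}


def variant_config(name: str, **overrides) -> MVTTConfig:
    """Build the MVTTConfig for a named ablation variant."""
    if name not in VARIANTS:
        raise KeyError(f"unknown variant {name!r}; known: {sorted(VARIANTS)}")
    kw = dict(VARIANTS[name])
    kw.update(overrides)
    return MVTTConfig(**kw)


@dataclass
class SegmentationOutput:
    """Paired probability volumes: m_l (anatomy) and m_as (scar).

    Held as graph tensors of shape (edge, 1, edge, edge) so losses can
    backpropagate; use :meth:`anatomy_volume` / :meth:`scar_volume` for the
    plain (z, y, x) probability arrays.
    """

    anatomy_prob: Tensor | None
    scar_prob: Tensor | None

    def anatomy_volume(self) -> np.ndarray:
        if self.anatomy_prob is None:
            raise ValueError("this configuration does not produce an anatomy map")
        return self.anatomy_prob.data[:, 0]

    def scar_volume(self) -> np.ndarray:
        if self.scar_prob is None:
            raise ValueError("this configuration does not produce a scar map")
        return self.scar_prob.data[:, 0]


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a binary mask."""
    return (np.asarray(prob) > threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def fuse_views(fa, fs, fc) -> Tensor:
    """Multiview fusion F_v = F_a + T(F_c) + T(F_s).

    `fa` is an axial feature stack (n, C, n, n); `fs`/`fc` are sagittal and
    coronal stacks over the same cubic grid. T is the axis permutation that
    re-orders an orthogonal-view stack into axial order.
    """
    fa = fa if isinstance(fa, Tensor) else Tensor(fa)
    fs = fs if isinstance(fs, Tensor) else Tensor(fs)
    fc = fc if isinstance(fc, Tensor) else Tensor(fc)
    for name, f in (("axial", fa), ("sagittal", fs), ("coronal", fc)):
        s = f.data.shape
        if len(s) != 4 or not (s[0] == s[2] == s[3]):
            raise ValueError(f"{name} stack must be (n, C, n, n), got {s}")
    ts = permute(fs, _VIEW_TO_AXIAL_4D["sagittal"])
    tc = permute(fc, _VIEW_TO_AXIAL_4D["coronal"])
    if ts.data.shape != fa.data.shape or tc.data.shape != fa.data.shape:
        raise ValueError("transposed stacks do not match the axial stack's shape")
    return fa + tc + ts


# ---------------------------------------------------------------------------
# Heads
# ---------------------------------------------------------------------------

class TaskHead(Module):
    """Two 3x3 conv(16)+BN+ReLU layers whose outputs are concatenated (32
    channels) into a final one-kernel convolution + sigmoid. The anatomy
    head's final convolution is 3x3; the scar head's is 1x1, so its last
    layer mixes no spatial context.

    `final_bias_init` seeds the output sigmoid near the foreground prior
    (negative for rare classes), which shortens the initial collapse phase
    of the Dice loss on heavily imbalanced targets."""

    def __init__(self, cin: int, final_kernel: int, rng=None,
                 final_bias_init: float = 0.0):
        self.layer1 = ConvBNReLU(cin, _HEAD_CHANNELS, 3, rng=rng)
        self.layer2 = ConvBNReLU(_HEAD_CHANNELS, _HEAD_CHANNELS, 3, rng=rng)
        self.final = Conv2d(2 * _HEAD_CHANNELS, 1, final_kernel, rng=rng)
        self.final.bias.data = np.full_like(self.final.bias.data, final_bias_init)

    def __call__(self, x: Tensor) -> Tensor:
        a = self.layer1(x)
        b = self.layer2(a)
        return sigmoid(self.final(concat([a, b], axis=1)))


def anatomy_head(fv, rng=None) -> Tensor:
    """Functional anatomy head (3x3 final conv) with fresh parameters."""
    fv = fv if isinstance(fv, Tensor) else Tensor(fv)
    return TaskHead(fv.data.shape[1], final_kernel=3, rng=rng)(fv)


def scar_head(modulated, rng=None) -> Tensor:
    """Functional scar head (1x1 final conv) with fresh parameters."""
    modulated = modulated if isinstance(modulated, Tensor) else Tensor(modulated)
    return TaskHead(modulated.data.shape[1], final_kernel=1, rng=rng)(modulated)


# ---------------------------------------------------------------------------
# Subnetworks
# ---------------------------------------------------------------------------

class AxialSequenceNet(Module):
    """Per-slice encoder followed by a ConvLSTM over the ordered axial stack
    (or a third plain convolution layer when the ConvLSTM is ablated)."""

    def __init__(self, cfg: MVTTConfig, rng):
        c, k = cfg.base_channels, cfg.kernel_size
        self.enc1 = ConvBNReLU(1, c, k, rng=rng)
        self.enc2 = ConvBNReLU(c, c, k, rng=rng)
        self.use_convlstm = cfg.use_convlstm
        self.activation = cfg.convlstm_activation
        if cfg.use_convlstm:
            self.clstm = ConvLSTMParams.init(
                c, c, k, (cfg.cube_edge, cfg.cube_edge), rng=rng
            )
        else:
            self.enc3 = ConvBNReLU(c, c, k, rng=rng)

    def __call__(self, stack: Tensor) -> Tensor:
        feats = self.enc2(self.enc1(stack))
        if not self.use_convlstm:
            return self.enc3(feats)
        n = feats.data.shape[0]
        spatial = feats.data.shape[-2:]
        state = ConvLSTMState.zeros(self.clstm.channels, spatial, dtype=feats.data.dtype)
        hidden = []
        for t in range(n):
            x_t = narrow(feats, 0, t, 1)
            state = convlstm_step(self.clstm, x_t, state, activation=self.activation)
            hidden.append(state.h)
        return concat(hidden, axis=0)


class DilatedResidualNet(Module):
    """Encoder + stacked HDC residual blocks for an orthogonal-view stack.
    With conv_mode='plain' the dilation cycle collapses to all-ones."""

    def __init__(self, cfg: MVTTConfig, rng):
        c, k = cfg.base_channels, cfg.kernel_size
        cycle = cfg.dilation_cycle if cfg.conv_mode == "hdc" else (1,) * len(cfg.dilation_cycle)
        self.enc = ConvBNReLU(1, c, k, rng=rng)
        self.blocks = [
            HDCBlock(HDCBlockConfig(kernel_size=k, channels=c, dilation_cycle=cycle), rng=rng)
            for _ in range(cfg.n_res_blocks)
        ]

    def __call__(self, stack: Tensor) -> Tensor:
        out = self.enc(stack)
        for block in self.blocks:
            out = block(out)
        return out


class DilatedAttentionNet(Module):
    """Mask branch: maps raw axial slices I to a single-channel attention
    mask AM in (0, 1) through dilated convolutions and a final 1x1 layer."""

    def __init__(self, cfg: MVTTConfig, rng):
        c, k = cfg.base_channels, cfg.kernel_size
        cycle = cfg.dilation_cycle if cfg.conv_mode == "hdc" else (1,) * len(cfg.dilation_cycle)
        self.enc = ConvBNReLU(1, c, k, rng=rng)
        self.block = HDCBlock(
            HDCBlockConfig(kernel_size=k, channels=c, dilation_cycle=cycle), rng=rng
        )
        self.proj = Conv2d(c, 1, 1, rng=rng)

    def __call__(self, stack: Tensor) -> Tensor:
        return sigmoid_mask(self.proj(self.block(self.enc(stack))))


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

class MVTTNetwork(Module):
    """Full multiview two-task model over a normalized cubic volume."""

    def __init__(self, config: MVTTConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.axial_net = AxialSequenceNet(config, rng)
        if config.use_multiview:
            self.sagittal_net = DilatedResidualNet(config, rng)
            self.coronal_net = DilatedResidualNet(config, rng)
        if config.tasks in ("both", "anatomy_only"):
            self.anatomy_head = TaskHead(config.base_channels, final_kernel=3,
                                         rng=rng, final_bias_init=-1.0)
        if config.tasks in ("both", "scar_only"):
            if config.use_attention:
                self.attention_net = DilatedAttentionNet(config, rng)
            self.scar_head = TaskHead(config.base_channels, final_kernel=1,
                                      rng=rng, final_bias_init=-3.0)

    # -- data plumbing ------------------------------------------------------
    def _stacks(self, voxels: np.ndarray, dtype) -> tuple[Tensor, Tensor, Tensor]:
        ax = Tensor(voxels[:, None, :, :].astype(dtype))
        sag = Tensor(np.transpose(voxels, (2, 0, 1))[:, None, :, :].astype(dtype))
        cor = Tensor(np.transpose(voxels, (1, 0, 2))[:, None, :, :].astype(dtype))
        return ax, sag, cor

    def forward(self, volume: Volume | np.ndarray, dtype=np.float32) -> SegmentationOutput:
        """One joint pass: returns both probability maps (where configured)."""
        voxels = volume.voxels if isinstance(volume, Volume) else np.asarray(volume)
        if voxels.ndim != 3 or len(set(voxels.shape)) != 1:
            raise ValueError(f"forward expects a cubic 3D volume, got {voxels.shape}")
        cfg = self.config
        ax, sag, cor = self._stacks(voxels, dtype)

        fa = self.axial_net(ax)
        if cfg.use_multiview:
            fv = fuse_views(fa, self.sagittal_net(sag), self.coronal_net(cor))
        else:
            fv = fa

        anatomy_prob = scar_prob = None
        if cfg.tasks in ("both", "anatomy_only"):
            anatomy_prob = self.anatomy_head(fv)
        if cfg.tasks in ("both", "scar_only"):
            trunk = fv
            if cfg.use_attention:
                am = self.attention_net(ax)
                trunk = attention_modulate(am, fv)
            scar_prob = self.scar_head(trunk)
        return SegmentationOutput(anatomy_prob=anatomy_prob, scar_prob=scar_prob)

    __call__ = forward


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: MVTTNetwork, path) -> None:
    """Write a checkpoint: named tensors plus the architecture config (JSON),
    in a single NPZ archive."""
    import dataclasses
    import json

    config_json = json.dumps(dataclasses.asdict(model.config))
    np.savez(path, __config__=np.frombuffer(config_json.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> MVTTNetwork:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path) as archive:
        config = json.loads(bytes(archive["__config__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    config["dilation_cycle"] = tuple(config["dilation_cycle"])
    model = MVTTNetwork(MVTTConfig(**config))
    model.load_state_dict(state)
    model.set_mode("eval")
    return model


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

DICE_EPS = 1.0  # smoothing constant: avoids 0/0 on empty masks


def dice_loss(m, g, eps: float = DICE_EPS) -> Tensor:
    """Soft Dice loss delta(m, g) = 1 - (2 sum(m g) + eps) / (sum(m) + sum(g) + eps)."""
    m = m if isinstance(m, Tensor) else Tensor(m)
    g = np.asarray(g, dtype=m.data.dtype)
    if g.shape != m.data.shape:
        g = g.reshape(m.data.shape)  # raises on genuinely incompatible shapes
    inter = tsum(mul(m, Tensor(g)))
    denom = tsum(m) + float(g.sum()) + eps
    return 1.0 - (2.0 * inter + eps) / denom


def hybrid_loss(ml, mas, gl, gas, eps: float = DICE_EPS) -> Tensor:
    """Two-task loss L = delta(m_l, g_l) + delta(m_as, g_as)."""
    if ml is None or mas is None:
        raise ValueError("hybrid loss requires both task outputs (tasks='both')")
    return dice_loss(ml, gl, eps=eps) + dice_loss(mas, gas, eps=eps)
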