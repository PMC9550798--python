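"""The 3D DA-UNet segmentation architecture.

A symmetric volumetric encoder-decoder for binary organ segmentation:

* encoder — four resolution levels, two residual blocks per level (eight
  residual blocks in total), each level followed by a learned stride-2
  2x2x2 down-sampling convolution (four down-sampling blocks);
* bridge — an atrous-inception (AI) block at 1/16 resolution: a shared
  1x1x1 reduction feeding three parallel dilated 3x3x3 branches (rates
  2, 4, 8) whose outputs are concatenated with the reduction itself and
  fused by a 1x1x1 convolution, capturing context at several scales;
* decoder — three up-sampling blocks (trilinear x2 + convolution) with
  skip concatenation, stopping at 1/2 resolution;
* four output modules — a main head on the last decoder stage and three
  auxiliary deep-supervision heads on the bridge and the two intermediate
  decoder stages.  Each head is a point convolution, a trilinear upsample
  to the full patch grid, and a sigmoid.

Ablation flags reproduce the ladder studied on CT livers: plain 3D U-Net
baseline (``use_residual=False, use_ai=False, use_ds=False``), +Res,
+AI, and the full model (+DS).  Disabling the AI bridge connects the
encoder to the decoder directly, so each flag strictly adds parameters.

All convolutions in the trunk use 3x3x3 kernels; down-sampling uses
2x2x2 stride-2 convolutions instead of max pooling; the activation is
PReLU throughout.  Normalization defaults to instance norm (training
uses batch size 1, which makes batch-norm statistics degenerate) and can
be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class NetworkConfig:
    in_channels: int = 1
    base_channels: int = 16
    n_levels: int = 4
    dilations: tuple = (2, 4, 8)
    use_residual: bool = True
    use_ai: bool = True
    use_ds: bool = True
    norm: str = "instance"  # {"instance", "none"}
    patch_shape: tuple = (16, 256, 256)

    def __post_init__(self):
        self.dilations = tuple(int(d) for d in self.dilations)
        self.patch_shape = tuple(int(s) for s in self.patch_shape)
        if self.norm not in ("instance", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if any(d <= 0 for d in self.dilations) or list(self.dilations) != sorted(
            set(self.dilations)
        ):
            raise ValueError("dilations must be strictly increasing positive integers")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.use_ds and self.n_levels != 4:
            raise ValueError("deep supervision is defined for the 4-level network (3 aux heads)")
        f = 2 ** self.n_levels
        if any(s % f for s in self.patch_shape):
            raise ValueError(
                f"patch shape {self.patch_shape} not divisible by 2^{self.n_levels}"
            )

    def to_dict(self):
        d = asdict(self)
        d["dilations"] = list(self.dilations)
        d["patch_shape"] = list(self.patch_shape)
        return d

    @classmethod
    def from_dict(cls, d):
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown NetworkConfig keys: {sorted(unknown)}")
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


@dataclass
class ForwardOutput:
    """Probability maps of one forward pass, all on the full patch grid."""

    main_prob: Tensor
    aux_probs: list
    main_logits: Tensor
    aux_logits: list


# ---------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------


class Layer:
    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.parameters())
        return out


def _he(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3(Layer):
    def __init__(self, rng, cin, cout, dilation=1, dtype=np.float32):
        self.w = ad.parameter(_he(rng, (cout, cin, 3, 3, 3), cin * 27, dtype))
        self.b = ad.parameter(np.zeros(cout, dtype=dtype))
        self.dilation = dilation

    def __call__(self, x):
        return ad.conv3d(x, self.w, self.b, self.dilation)


class Conv1(Layer):
    def __init__(self, rng, cin, cout, dtype=np.float32):
        self.w = ad.parameter(_he(rng, (cout, cin), cin, dtype))
        self.b = ad.parameter(np.zeros(cout, dtype=dtype))

    def __call__(self, x):
        return ad.conv1x1(x, self.w, self.b)


class Down2(Layer):
    def __init__(self, rng, cin, cout, dtype=np.float32):
        self.w = ad.parameter(_he(rng, (cout, cin, 2, 2, 2), cin * 8, dtype))
        self.b = ad.parameter(np.zeros(cout, dtype=dtype))

    def __call__(self, x):
        return ad.conv_down2(x, self.w, self.b)


class Norm(Layer):
    def __init__(self, channels, kind, dtype=np.float32):
        self.kind = kind
        if kind == "instance":
            self.gain = ad.parameter(np.ones(channels, dtype=dtype))
            self.bias = ad.parameter(np.zeros(channels, dtype=dtype))

    def __call__(self, x):
        if self.kind == "none":
            return x
        return ad.instance_norm(x, self.gain, self.bias)


class PReLU(Layer):
    def __init__(self, channels, dtype=np.float32):
        self.a = ad.parameter(np.full(channels, 0.25, dtype=dtype))

    def __call__(self, x):
        return ad.prelu(x, self.a)


class ConvBlock(Layer):
    """conv -> norm -> PReLU -> conv -> norm -> PReLU (plain U-Net block)."""

    def __init__(self, rng, cin, cout, norm, dtype=np.float32):
        self.c1 = Conv3(rng, cin, cout, dtype=dtype)
        self.n1 = Norm(cout, norm, dtype)
        self.a1 = PReLU(cout, dtype)
        self.c2 = Conv3(rng, cout, cout, dtype=dtype)
        self.n2 = Norm(cout, norm, dtype)
        self.a2 = PReLU(cout, dtype)

    def __call__(self, x):
        h = self.a1(self.n1(self.c1(x)))
        return self.a2(self.n2(self.c2(h)))


class ResBlock(Layer):
    """Two-convolution residual block with 1x1x1 projection shortcut.

    out = PReLU(F(x) + proj(x)) with
    F = conv3 -> norm -> PReLU -> conv3 -> norm; proj is the identity when
    channel counts match, else a pointwise convolution.
    """

    def __init__(self, rng, cin, cout, norm, dtype=np.float32):
        self.c1 = Conv3(rng, cin, cout, dtype=dtype)
        self.n1 = Norm(cout, norm, dtype)
        self.a1 = PReLU(cout, dtype)
        self.c2 = Conv3(rng, cout, cout, dtype=dtype)
        self.n2 = Norm(cout, norm, dtype)
        self.proj = None if cin == cout else Conv1(rng, cin, cout, dtype)
        self.a2 = PReLU(cout, dtype)

    def __call__(self, x):
        h = self.n2(self.c2(self.a1(self.n1(self.c1(x)))))
        shortcut = x if self.proj is None else self.proj(x)
        return self.a2(h + shortcut)


class AIModule(Layer):
    """Atrous-inception bridge.

    A shared pointwise reduction x1 = w11*x + b11 feeds three dilated
    3x3x3 branches (rates ``dilations``); the reduction output and the
    three branch outputs are concatenated and fused by a pointwise
    convolution. Each branch emits channels/4 features so the concat
    restores the bridge width.
    """

    def __init__(self, rng, channels, dilations=(2, 4, 8), dtype=np.float32):
        if channels % 4:
            raise ValueError("AI bridge width must be divisible by 4")
        cb = channels // 4
        self.reduce = Conv1(rng, channels, cb, dtype)
        self.branches = [Conv3(rng, cb, cb, dilation=d, dtype=dtype) for d in dilations]
        self.fuse = Conv1(rng, channels, channels, dtype)

    def __call__(self, x):
        x1 = self.reduce(x)
        outs = [x1] + [branch(x1) for branch in self.branches]
        return self.fuse(ad.concat(outs, axis=0))


class OutputHead(Layer):
    """Point convolution -> trilinear upsample to the patch grid -> sigmoid."""

    def __init__(self, rng, cin, patch_shape, dtype=np.float32):
        self.conv = Conv1(rng, cin, 1, dtype)
        self.patch_shape = tuple(patch_shape)

    def __call__(self, x):
        logits = self.conv(x)
        if logits.shape[1:] != self.patch_shape:
            logits = ad.resize3(logits, self.patch_shape)
        return logits, ad.sigmoid(logits)


# ---------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------


class DAUNet(Layer):
    def __init__(self, cfg: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        bc, L = cfg.base_channels, cfg.n_levels
        Block = ResBlock if cfg.use_residual else ConvBlock
        enc_ch = [bc * 2 ** i for i in range(L)]
        bridge_ch = bc * 2 ** L

        self.enc_blocks = []
        cin = cfg.in_channels
        for ch in enc_ch:
            self.enc_blocks.append(
                [Block(rng, cin, ch, cfg.norm, dtype), Block(rng, ch, ch, cfg.norm, dtype)]
            )
            cin = ch
        self.downs = []
        for i, ch in enumerate(enc_ch):
            cout = bridge_ch if i == L - 1 else ch
            self.downs.append(Down2(rng, ch, cout, dtype))

        self.bridge = AIModule(rng, bridge_ch, cfg.dilations, dtype) if cfg.use_ai else None

        # decoder: L-1 up-sampling stages, ending at 1/2 resolution
        self.up_convs = []
        self.dec_blocks = []
        ch = bridge_ch
        for i in range(L - 1, 0, -1):
            skip_ch = enc_ch[i]
            self.up_convs.append(Conv3(rng, ch, skip_ch, dtype=dtype))
            self.dec_blocks.append(ConvBlock(rng, 2 * skip_ch, skip_ch, cfg.norm, dtype))
            ch = skip_ch

        self.main_head = OutputHead(rng, ch, cfg.patch_shape, dtype)
        self.aux_heads = []
        if cfg.use_ds:
            aux_ch = [bridge_ch] + [enc_ch[i] for i in range(L - 1, 1, -1)]
            self.aux_heads = [OutputHead(rng, c, cfg.patch_shape, dtype) for c in aux_ch]

    # nested lists of Layers need explicit traversal
    def parameters(self):
        out = []

        def walk(obj):
            if isinstance(obj, Tensor) and obj.requires_grad:
                out.append(obj)
            elif isinstance(obj, Layer):
                for v in obj.__dict__.values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    walk(item)

        for v in self.__dict__.values():
            walk(v)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, patch: np.ndarray) -> ForwardOutput:
        """Run one (C, Z, Y, X) or (Z, Y, X) patch through the network."""
        x = np.asarray(patch)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.cfg.patch_shape:
            raise ValueError(
                f"patch spatial shape {x.shape[1:]} != configured {self.cfg.patch_shape}"
            )
        t = Tensor(x.astype(self.main_head.conv.w.dtype, copy=False))

        skips = []
        for blocks, down in zip(self.enc_blocks, self.downs):
            for blk in blocks:
                t = blk(t)
            skips.append(t)
            t = down(t)

        if self.bridge is not None:
            t = self.bridge(t)
        bridge_out = t

        stages = []
        for up, dec, skip in zip(self.up_convs, self.dec_blocks, reversed(skips[1:])):
            t = ad.resize3(t, skip.shape[1:])
            t = up(t)
            t = dec(ad.concat([t, skip], axis=0))
            stages.append(t)

        main_logits, main_prob = self.main_head(stages[-1])
        aux_logits, aux_probs = [], []
        if self.aux_heads:
            taps = [bridge_out] + stages[:-1]
            for head, tap in zip(self.aux_heads, taps):
                lg, pr = head(tap)
                aux_logits.append(lg)
                aux_probs.append(pr)
        return ForwardOutput(main_prob, aux_probs, main_logits, aux_logits)

    __call__ = forward

    # -- checkpointing -------------------------------------------------

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = a.astype(p.dtype, copy=True)


def build_model(cfg: NetworkConfig, seed: int = 0, dtype=np.float32) -> DAUNet:
    return DAUNet(cfg, seed=seed, dtype=dtype)


def describe_model(model: DAUNet) -> str:
    cfg = model.cfg
    lines = [
        f"DA-UNet: levels={cfg.n_levels} base_channels={cfg.base_channels} "
        f"residual={cfg.use_residual} ai={cfg.use_ai} ds={cfg.use_ds} norm={cfg.norm}",
        f"patch shape (z,y,x): {cfg.patch_shape}",
        f"aux heads: {len(model.aux_heads)}",
    ]
    for p in model.parameters():
        lines.append(f"  param {p.data.shape} ({p.data.size})")
    lines.append(f"total parameters: {model.n_parameters()}")
    return "\n".join(lines)
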