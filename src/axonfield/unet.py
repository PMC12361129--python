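"""3D U-Net for distance-field regression.

Encoder of ``levels`` convolutional blocks with channels doubling from
``base_channels`` (capped at 512), 2x max-pool downsampling between levels,
a mirrored decoder with stride-2 transposed convolutions, and residual
(additive) skip connections between matching scales; a concatenation mode is
available behind ``skip_mode="concat"``.  Each block is two 3x3x3
convolutions with LeakyReLU (optionally instance-normalized).  The
single-channel head is linear, clamped to [0, 1]; the clamp uses a
straight-through gradient during training so saturated voxels keep learning.

Inputs of arbitrary shape are reflect-padded to a multiple of
``2**(levels-1)`` and the output is cropped back, so output shape always
equals input shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Conv1x1, Conv3d, ConvTranspose3d2x, InstanceNorm, LeakyReLU, MaxPool2, Module, Param

__all__ = ["NetConfig", "UNet3D", "full_profile", "toy_profile"]

_MAX_CHANNELS = 512


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``levels=6, base_channels=16`` reproduces the full-scale profile
    (channels 16..512); ``levels=3, base_channels=8`` is the CPU-sized toy
    profile used throughout the synthetic experiments.
    """

    levels: int = 3
    base_channels: int = 8
    skip_mode: str = "add"  # "add" (residual) or "concat"
    norm: str | None = None  # None or "instance"
    clamp_output: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.skip_mode not in ("add", "concat"):
            raise ValueError("skip_mode must be 'add' or 'concat'")

    @property
    def channels(self) -> list[int]:
        return [min(self.base_channels * 2**k, _MAX_CHANNELS) for k in range(self.levels)]

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)


def full_profile() -> NetConfig:
    """Full-scale profile: 6 levels, channels doubling 16 -> 512."""
    return NetConfig(levels=6, base_channels=16)


def toy_profile() -> NetConfig:
    """CPU-scale profile: 3 levels, channels 8 -> 32."""
    return NetConfig(levels=3, base_channels=8)


class _ConvBlock:
    def __init__(self, c_in: int, c_out: int, cfg: NetConfig, rng: np.random.Generator):
        self.layers: list[Module] = []
        for ci, co in ((c_in, c_out), (c_out, c_out)):
            self.layers.append(Conv3d(ci, co, rng))
            if cfg.norm == "instance":
                self.layers.append(InstanceNorm(co))
            self.layers.append(LeakyReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class UNet3D:
    """The regression network; operates on single-channel 3D volumes."""

    def __init__(self, config: NetConfig | None = None, seed: int = 0):
        self.config = cfg = config or NetConfig()
        rng = np.random.default_rng(seed)
        ch = cfg.channels

        self.enc = [_ConvBlock(1 if k == 0 else ch[k - 1], ch[k], cfg, rng) for k in range(cfg.levels)]
        self.pools = [MaxPool2() for _ in range(cfg.levels - 1)]
        self.ups = [ConvTranspose3d2x(ch[k + 1], ch[k], rng) for k in range(cfg.levels - 1)]
        dec_in = [ch[k] * (2 if cfg.skip_mode == "concat" else 1) for k in range(cfg.levels - 1)]
        self.dec = [_ConvBlock(dec_in[k], ch[k], cfg, rng) for k in range(cfg.levels - 1)]
        self.head = Conv1x1(ch[0], 1, rng)

        self._pad: tuple | None = None
        self._clamp_mask: np.ndarray | None = None

    # ---- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.enc:
            out += blk.params()
        for up in self.ups:
            out += up.params()
        for blk in self.dec:
            out += blk.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for i, p in enumerate(params):
            p.value[...] = state[f"p{i}"]

    def save(self, path) -> None:
        import json

        meta = dict(levels=self.config.levels, base_channels=self.config.base_channels,
                    skip_mode=self.config.skip_mode, norm=self.config.norm or "",
                    clamp_output=self.config.clamp_output)
        np.savez(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path) -> "UNet3D":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = NetConfig(levels=int(meta["levels"]), base_channels=int(meta["base_channels"]),
                            skip_mode=meta["skip_mode"], norm=meta["norm"] or None,
                            clamp_output=bool(meta["clamp_output"]))
            model = cls(cfg)
            model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model

    # ---- forward / backward -------------------------------------------------
    def _pad_input(self, x: np.ndarray) -> np.ndarray:
        m = self.config.divisor
        pads = [(0, (-s) % m) for s in x.shape]
        self._pad = (x.shape, pads)
        if any(p[1] for p in pads):
            if any(p[1] >= s for p, s in zip(pads, x.shape)):
                raise ValueError(
                    f"input shape {x.shape} too small to reflect-pad to a multiple of {m}; "
                    f"use at least {m} voxels per axis"
                )
            x = np.pad(x, pads, mode="reflect")
        return x

    def forward(self, x: np.ndarray, clamp: bool | None = None) -> np.ndarray:
        """Map a ``(D, H, W)`` volume in [0, 1] to a same-shaped field.

        ``clamp=False`` returns the raw linear head output (used by gradient
        checks); by default the configured clamping applies.
        """
        x = np.asarray(x)
        if x.dtype != np.float64:
            x = x.astype(np.float32)
        if x.ndim != 3:
            raise ValueError("expected a 3D single-channel volume")
        xp = self._pad_input(x)[None]

        skips = []
        f = xp
        for k in range(self.config.levels - 1):
            f = self.enc[k].forward(f)
            skips.append(f)
            f = self.pools[k].forward(f)
        f = self.enc[-1].forward(f)
        self._skip_shapes = [s.shape for s in skips]
        for k in reversed(range(self.config.levels - 1)):
            f = self.ups[k].forward(f)
            if self.config.skip_mode == "add":
                f = f + skips[k]
            else:
                f = np.concatenate([f, skips[k]], axis=0)
            f = self.dec[k].forward(f)
        y = self.head.forward(f)[0]

        do_clamp = self.config.clamp_output if clamp is None else clamp
        if do_clamp:
            self._clamp_mask = None  # straight-through: gradient passes unchanged
            y = np.clip(y, 0.0, 1.0)
        (orig_shape, _) = self._pad
        return y[: orig_shape[0], : orig_shape[1], : orig_shape[2]]

    def backward(self, gy: np.ndarray) -> None:
        """Accumulate parameter gradients for the preceding :meth:`forward`.

        Reverses the forward graph: head, decoder stages shallow-to-deep
        (collecting skip gradients), bottom encoder block, then the encoder
        deep-to-shallow, merging each level's skip gradient back in.
        """
        (orig_shape, pads) = self._pad
        full = [orig_shape[i] + pads[i][1] for i in range(3)]
        g = np.zeros(full, dtype=gy.dtype)
        g[: orig_shape[0], : orig_shape[1], : orig_shape[2]] = gy
        g = self.head.backward(g[None])
        skip_grads: dict[int, np.ndarray] = {}
        for k in range(self.config.levels - 1):
            g = self.dec[k].backward(g)
            if self.config.skip_mode == "add":
                skip_grads[k] = g
            else:
                c = self.config.channels[k]
                g, skip_grads[k] = g[:c], g[c:]
            g = self.ups[k].backward(g)
        g = self.enc[-1].backward(g)
        for k in reversed(range(self.config.levels - 1)):
            g = self.pools[k].backward(g)
            g = g + skip_grads.pop(k)
            g = self.enc[k].backward(g)

    def astype(self, dtype) -> "UNet3D":
        """Cast all parameters in place (float64 helps gradient checks)."""
        for p in self.params():
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)
        return self

    def make_optimizer(self, lr: float = 2e-4) -> Adam:
        return Adam(self.params(), lr=lr)
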