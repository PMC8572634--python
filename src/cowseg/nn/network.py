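"""The multitask encoder-decoder segmentation network.

Architecture: a U-Net-style encoder (``levels`` conv blocks with 2x2
max-pooling between them), an atrous spatial pyramid pooling (ASPP)
bottleneck that concatenates parallel dilated convolutions (rates 1, 2, 4, 8
by default) with a global-average-pooling image branch, and a decoder with
factor-2 bilinear upsampling plus skip concatenation. Three 1x1-conv heads
emit the segmentation probability map O (sigmoid), the reconstructed
foreground F, and the reconstructed background B (both linear, in windowed
[0, 1] intensity units); the single-task baseline keeps only the O head and
is otherwise identical (a U-Net with ASPP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (BatchNorm2d, Conv2d, ConvBlock, GlobalPoolBranch,
                     MaxPool2, Sigmoid, UpsampleBilinear2)


@dataclass
class ModelConfig:
    levels: int = 4
    kernel_size: int = 3
    base_filters: int = 16
    aspp_dilations: tuple[int, ...] = (1, 2, 4, 8)
    include_global_pool: bool = True
    heads: str = "multitask"  # "multitask" (O, F, B) or "singletask" (O)
    in_channels: int = 1
    o_bias_init: float = -3.0  # logit of the initial foreground prior

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        dil = tuple(self.aspp_dilations)
        if any(d <= 0 for d in dil) or list(dil) != sorted(dil) or len(set(dil)) != len(dil):
            raise ValueError("aspp_dilations must be positive and increasing")
        if self.heads not in ("multitask", "singletask"):
            raise ValueError(f"unknown heads mode {self.heads!r}")

    def to_dict(self) -> dict:
        return {"levels": self.levels, "kernel_size": self.kernel_size,
                "base_filters": self.base_filters,
                "aspp_dilations": list(self.aspp_dilations),
                "include_global_pool": self.include_global_pool,
                "heads": self.heads, "in_channels": self.in_channels}


@dataclass
class MultitaskOutput:
    """(O, F, B): segmentation probabilities and the two reconstruction maps.
    For a single-task model F and B are None."""

    O: np.ndarray
    F: np.ndarray | None = None
    B: np.ndarray | None = None


class MultitaskNet:
    """Explicit forward/backward implementation of the architecture above."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = cfg.base_filters
        k = cfg.kernel_size
        L = cfg.levels
        enc_ch = [f * 2 ** i for i in range(L)]

        self.enc_blocks = []
        self.pools = []
        in_ch = cfg.in_channels
        for i, ch in enumerate(enc_ch):
            self.enc_blocks.append(ConvBlock(in_ch, ch, k, rng=rng))
            in_ch = ch
            if i < L - 1:
                self.pools.append(MaxPool2())

        bottleneck_ch = enc_ch[-1]
        branch_ch = max(bottleneck_ch // 4, 1)
        self.aspp_branches = [
            ConvBlock(bottleneck_ch, branch_ch, k, dilation=d, rng=rng)
            for d in cfg.aspp_dilations
        ]
        self.gap_branch = (GlobalPoolBranch(bottleneck_ch, branch_ch, rng=rng)
                           if cfg.include_global_pool else None)
        n_branches = len(self.aspp_branches) + (1 if self.gap_branch else 0)
        self.aspp_fuse = ConvBlock(branch_ch * n_branches, bottleneck_ch, 1, rng=rng)

        self.ups = []
        self.dec_blocks = []
        dec_in = bottleneck_ch
        for i in range(L - 2, -1, -1):
            self.ups.append(UpsampleBilinear2())
            self.dec_blocks.append(ConvBlock(dec_in + enc_ch[i], enc_ch[i], k, rng=rng))
            dec_in = enc_ch[i]

        self.head_O = Conv2d(dec_in, 1, kernel=1, rng=rng)
        # vessels are a sparse foreground: bias the segmentation head so the
        # initial probability matches a small prior (sigmoid(-3) ~ 0.05)
        # instead of 0.5, the standard prior-initialization for rare-class
        # dense prediction; starting at 0.5 everywhere stalls the Dice term
        self.head_O.params["b"][:] = cfg.o_bias_init
        self.sigmoid = Sigmoid()
        if cfg.heads == "multitask":
            self.head_F = Conv2d(dec_in, 1, kernel=1, rng=rng)
            self.head_B = Conv2d(dec_in, 1, kernel=1, rng=rng)
        else:
            self.head_F = self.head_B = None

    # -- bookkeeping ------------------------------------------------------

    def layers(self):
        out = []
        for b in self.enc_blocks + self.aspp_branches + [self.aspp_fuse] + self.dec_blocks:
            out.extend(b.sublayers())
        if self.gap_branch is not None:
            out.append(self.gap_branch)
        out.append(self.head_O)
        if self.head_F is not None:
            out.extend([self.head_F, self.head_B])
        return out

    def parameters(self):
        """List of (layer, name) pairs addressing every trainable array."""
        return [(l, name) for l in self.layers() for name in l.params]

    def n_params(self) -> int:
        return sum(l.params[n].size for l, n in self.parameters())

    # -- forward / backward ----------------------------------------------

    def _check_input(self, x: np.ndarray):
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected NCHW input with {self.cfg.in_channels} "
                             f"channel(s), got shape {x.shape}")
        div = 2 ** (self.cfg.levels - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"input side {x.shape[2]}x{x.shape[3]} not divisible by "
                f"2^(levels-1) = {div}")

    def forward(self, x: np.ndarray, train: bool = True) -> MultitaskOutput:
        x = np.asarray(x)
        if x.dtype not in (np.float32, np.float64):
            x = x.astype(np.float32)
        self._check_input(x)
        skips = []
        h = x
        for i, block in enumerate(self.enc_blocks):
            h = block.forward(h, train)
            if i < len(self.enc_blocks) - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)

        branches = [b.forward(h, train) for b in self.aspp_branches]
        if self.gap_branch is not None:
            branches.append(self.gap_branch.forward(h, train))
        self._branch_ch = [b.shape[1] for b in branches]
        h = self.aspp_fuse.forward(np.concatenate(branches, axis=1), train)

        self._skip_ch = []
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            self._skip_ch.append((h.shape[1], skip.shape[1]))
            h = block.forward(np.concatenate([h, skip], axis=1), train)

        logits = self.head_O.forward(h, train)
        O = self.sigmoid.forward(logits, train)
        if self.head_F is None:
            return MultitaskOutput(O=O)
        F = self.head_F.forward(h, train)
        B = self.head_B.forward(h, train)
        return MultitaskOutput(O=O, F=F, B=B)

    def backward(self, dO: np.ndarray, dF: np.ndarray | None = None,
                 dB: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients from output-side gradients."""
        dh = self.head_O.backward(self.sigmoid.backward(dO))
        if self.head_F is not None:
            if dF is not None:
                dh = dh + self.head_F.backward(dF)
            if dB is not None:
                dh = dh + self.head_B.backward(dB)

        dskips = []
        for up, block, (up_ch, skip_ch) in zip(reversed(self.ups),
                                               reversed(self.dec_blocks),
                                               reversed(self._skip_ch)):
            d = block.backward(dh)
            dskips.append(d[:, up_ch:])
            dh = up.backward(d[:, :up_ch])

        d = self.aspp_fuse.backward(dh)
        splits = np.cumsum(self._branch_ch)[:-1]
        parts = np.split(d, splits, axis=1)
        dbottom = np.zeros_like(parts[0], shape=(d.shape[0], self.enc_blocks[-1].conv.out_ch,
                                                 d.shape[2], d.shape[3]))
        for branch, dpart in zip(self.aspp_branches, parts):
            dbottom = dbottom + branch.backward(dpart)
        if self.gap_branch is not None:
            dbottom = dbottom + self.gap_branch.backward(parts[-1])

        dh = dbottom
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.enc_blocks) - 1:
                dh = self.pools[i].backward(dh)
                dh = dh + dskips[i]  # dskips[i] pairs encoder level i
            dh = self.enc_blocks[i].backward(dh)

    # -- (de)serialization -------------------------------------------------

    def state_dict(self) -> dict:
        state = {}
        for i, l in enumerate(self.layers()):
            for name, arr in l.params.items():
                state[f"{i}.{name}"] = arr
            if isinstance(l, BatchNorm2d):
                state[f"{i}.running_mean"] = l.running_mean
                state[f"{i}.running_var"] = l.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, l in enumerate(self.layers()):
            for name in l.params:
                l.params[name] = np.asarray(state[f"{i}.{name}"], dtype=np.float32)
            if isinstance(l, BatchNorm2d):
                l.running_mean = np.asarray(state[f"{i}.running_mean"], dtype=np.float32)
                l.running_var = np.asarray(state[f"{i}.running_var"], dtype=np.float32)

    def save(self, path: str) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path: str, cfg: ModelConfig, seed: int = 0) -> "MultitaskNet":
        net = cls(cfg, seed)
        with np.load(path) as data:
            net.load_state_dict(dict(data))
        return net


def build_model(cfg: ModelConfig, seed: int = 0) -> MultitaskNet:
    """Construct the network for a configuration; parameter count is a pure
    function of the configuration."""
    return MultitaskNet(cfg, seed)
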