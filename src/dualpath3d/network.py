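"""Dual-path residual 3D convolutional network.

Two identical paths — a fine-resolution local path and a downsampled
global-context path — of conv/batch-norm/PReLU blocks with identity
residual additions, fused by voxel-wise addition and followed by
unit-kernel (1x1x1) fully connected stages and a softmax classifier.
There is no pooling: every block preserves the spatial grid, so each
output voxel keeps its exact location.

Single-path configurations reproduce the "Local" ablation; setting
``fm_multiplier=2.0`` on a single path reproduces "Local+" (feature maps
doubled to match the dual-path parameter count).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import BatchNorm3D, Conv3D, Dropout, Layer, Param, PReLU, softmax
from .patch_sampler import LayerSpec, PatchPair, receptive_field


class ConstructionError(ValueError):
    """Invalid network configuration."""


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``feature_maps`` gives per-block output channels; the default follows
    the published per-layer table (30, 30, 40, 40 over paired blocks).
    ``residual_pairs`` are 1-indexed (source_block, target_block) identity
    additions. ``fc_widths`` are the channel widths of the unit-kernel
    fully connected stages before the classifier.
    """

    n_blocks_per_path: int = 8
    kernel: int = 3
    feature_maps: tuple[int, ...] = (30, 30, 30, 30, 40, 40, 40, 40)
    residual_pairs: tuple[tuple[int, int], ...] = ((2, 4), (4, 6), (6, 8))
    fc_widths: tuple[int, ...] = (150, 150)
    n_classes: int = 3
    dual_path: bool = True
    fm_multiplier: float = 1.0
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.feature_maps) != self.n_blocks_per_path:
            raise ConstructionError(
                f"feature_maps has {len(self.feature_maps)} entries for "
                f"{self.n_blocks_per_path} blocks")
        for (a, b) in self.residual_pairs:
            if not (1 <= a < b <= self.n_blocks_per_path):
                raise ConstructionError(f"residual pair {(a, b)} outside [1, {self.n_blocks_per_path}]")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(int(round(f * self.fm_multiplier)) for f in self.feature_maps)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        d = json.loads(s)
        d["feature_maps"] = tuple(d["feature_maps"])
        d["residual_pairs"] = tuple(tuple(p) for p in d["residual_pairs"])
        d["fc_widths"] = tuple(d["fc_widths"])
        return cls(**d)


class ConvBlock:
    """conv(3x3x3, same) -> batch norm -> PReLU.

    The convolution carries no bias: batch norm's shift makes it redundant.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, name: str):
        self.conv = Conv3D(in_ch, out_ch, kernel=kernel, rng=rng, bias=False,
                           name=f"{name}.conv")
        self.bn = BatchNorm3D(out_ch, name=f"{name}.bn")
        self.act = PReLU(out_ch, name=f"{name}.prelu")
        self.layers: list[Layer] = [self.conv, self.bn, self.act]

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def _pad_channels(x: np.ndarray, out_ch: int) -> np.ndarray:
    """Zero-pad the channel axis up to ``out_ch`` (identity-shortcut reconciliation)."""
    if x.shape[1] == out_ch:
        return x
    if x.shape[1] > out_ch:
        raise ConstructionError(
            f"residual source has {x.shape[1]} channels > target {out_ch}")
    pad = out_ch - x.shape[1]
    return np.pad(x, ((0, 0), (0, pad), (0, 0), (0, 0), (0, 0)))


class PathNet:
    """One path: a chain of conv blocks with identity residual additions.

    The residual pair (a, b) adds block a's (post-addition) output to
    block b's output; a channel increase along the way is reconciled by
    zero-padding the skipped tensor's channels.
    """

    def __init__(self, cfg: NetworkConfig, in_ch: int, rng, name: str):
        chans = cfg.channels
        self.blocks: list[ConvBlock] = []
        prev = in_ch
        for i, c in enumerate(chans, start=1):
            self.blocks.append(ConvBlock(prev, c, cfg.kernel, rng, name=f"{name}.block{i}"))
            prev = c
        self.out_ch = prev
        self.res_by_target: dict[int, int] = {b: a for a, b in cfg.residual_pairs}
        self._outs: dict[int, np.ndarray] | None = None

    def params(self) -> list[Param]:
        return [p for blk in self.blocks for p in blk.params()]

    def forward(self, x, train=False):
        outs: dict[int, np.ndarray] = {}
        h = x
        for i, blk in enumerate(self.blocks, start=1):
            h = blk.forward(h, train=train)
            src = self.res_by_target.get(i)
            if src is not None:
                h = h + _pad_channels(outs[src], h.shape[1])
            outs[i] = h
        self._outs = outs if train else None
        return h

    def backward(self, grad):
        n = len(self.blocks)
        # gradient accumulated at each block's (post-addition) output
        acc: dict[int, np.ndarray] = {n: grad}
        for i in range(n, 0, -1):
            g = acc.pop(i)
            src = self.res_by_target.get(i)
            if src is not None:
                src_ch = self._outs[src].shape[1]
                g_src = g[:, :src_ch]
                acc[src] = acc.get(src, 0) + g_src
            g_in = self.blocks[i - 1].backward(g)
            if i > 1:
                acc[i - 1] = acc.get(i - 1, 0) + g_in
            else:
                return g_in
        raise AssertionError("unreachable")


class DualPathNetwork:
    """The full segmentation network: paths, fusion, FC head, classifier.

    ``forward`` maps a patch pair (or batched local/global arrays) to
    per-voxel, per-class scores; apply :func:`dualpath3d.layers.softmax`
    for probabilities.
    """

    def __init__(self, cfg: NetworkConfig, in_ch: int = 1):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.local_path = PathNet(cfg, in_ch, rng, name="local")
        self.global_path = PathNet(cfg, in_ch, rng, name="global") if cfg.dual_path else None
        fuse_ch = self.local_path.out_ch
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 0xD0]).generate_state(1)[0])
        self.head: list[Layer] = []
        prev = fuse_ch
        for j, w in enumerate(cfg.fc_widths, start=1):
            self.head.append(Conv3D(prev, w, kernel=1, rng=rng, name=f"fc{j}"))
            self.head.append(PReLU(w, name=f"fc{j}.prelu"))
            self.head.append(Dropout(cfg.dropout, rng=self._dropout_rng))
            prev = w
        self.classifier = Conv3D(prev, cfg.n_classes, kernel=1, rng=rng, name="classifier")
        self.head.append(self.classifier)

    # -- parameters ---------------------------------------------------
    def params(self) -> list[Param]:
        out = self.local_path.params()
        if self.global_path is not None:
            out += self.global_path.params()
        for l in self.head:
            out += l.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- forward / backward -------------------------------------------
    @staticmethod
    def _as_batch(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        return x

    def forward(self, local: np.ndarray, global_: np.ndarray | None = None,
                train: bool = False) -> np.ndarray:
        """Per-voxel class scores of shape (N, n_classes, D, H, W)."""
        xl = self._as_batch(local)
        hl = self.local_path.forward(xl, train=train)
        if self.global_path is not None:
            if global_ is None:
                raise ValueError("dual-path network requires a global patch")
            xg = self._as_batch(global_)
            if xg.shape != xl.shape:
                raise ValueError(f"local/global shape mismatch: {xl.shape} vs {xg.shape}")
            hg = self.global_path.forward(xg, train=train)
            h = hl + hg
        else:
            h = hl
        for l in self.head:
            h = l.forward(h, train=train)
        return h

    def forward_pair(self, pp: PatchPair, train: bool = False) -> np.ndarray:
        return self.forward(pp.local, pp.global_, train=train)

    def backward(self, grad: np.ndarray) -> None:
        g = grad.astype(np.float32)
        for l in reversed(self.head):
            g = l.backward(g)
        self.local_path.backward(g)
        if self.global_path is not None:
            self.global_path.backward(g)

    # -- introspection -------------------------------------------------
    def count_parameters(self, kind: str = "all") -> int:
        """Trainable parameter count; ``kind='conv_weight'`` counts conv kernels only."""
        if kind == "all":
            return int(sum(p.value.size for p in self.params()))
        if kind == "conv_weight":
            return int(sum(p.value.size for p in self.params()
                           if p.regularized))
        raise ValueError(f"unknown kind {kind!r}")

    def path_receptive_field(self) -> tuple[int, int, int]:
        layers = [LayerSpec(kernel=self.cfg.kernel)] * self.cfg.n_blocks_per_path
        return receptive_field(layers)

    # -- serialization --------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file checkpoint: config JSON + all parameter and BN arrays."""
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i:04d}_{p.name}"] = p.value
        for j, bn in enumerate(self._batchnorms()):
            arrays[f"bnstat_{j:04d}_mean"] = bn.running_mean
            arrays[f"bnstat_{j:04d}_var"] = bn.running_var
        np.savez(path, __config__=np.frombuffer(self.cfg.to_json().encode(), dtype=np.uint8),
                 **arrays)

    def _batchnorms(self) -> list[BatchNorm3D]:
        out = [blk.bn for blk in self.local_path.blocks]
        if self.global_path is not None:
            out += [blk.bn for blk in self.global_path.blocks]
        return out

    @classmethod
    def load(cls, path: str) -> "DualPathNetwork":
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
            cfg = NetworkConfig.from_json(bytes(z["__config__"]).decode())
            net = cls(cfg)
            for i, p in enumerate(net.params()):
                key = f"param_{i:04d}_{p.name}"
                p.value[...] = z[key]
            for j, bn in enumerate(net._batchnorms()):
                bn.running_mean[...] = z[f"bnstat_{j:04d}_mean"]
                bn.running_var[...] = z[f"bnstat_{j:04d}_var"]
        return net


def build_network(cfg: NetworkConfig, in_ch: int = 1) -> DualPathNetwork:
    """Construct the network described by ``cfg``."""
    return DualPathNetwork(cfg, in_ch=in_ch)


def predict_probs(net: DualPathNetwork, pp: PatchPair) -> np.ndarray:
    """Softmax class probabilities for one patch pair, shape (n_classes, D, H, W)."""
    scores = net.forward_pair(pp, train=False)
    return softmax(scores, axis=1)[0]
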