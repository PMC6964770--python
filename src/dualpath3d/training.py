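"""Training loop and whole-volume inference.

The loss is mean per-voxel cross-entropy over softmax scores plus L1 and
L2 penalties on convolution kernels. The optimizer is RMSProp with
momentum (decay 0.9, momentum 0.6, epsilon 1e-4 by default), the reading
of the published RMS_* hyperparameters. Whole-volume inference tiles the
volume with co-centred dual-scale patches and averages overlapping
softmax outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .layers import softmax
from .network import DualPathNetwork
from .patch_sampler import PatchPair, extract_dual_patch, grid_centers
from .volume import Volume3D

log = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


class LabelError(ValueError):
    """Target labels outside the class range."""


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published table)."""

    learning_rate: float = 0.001
    rms_decay: float = 0.9
    rms_momentum: float = 0.6
    rms_epsilon: float = 0.0001
    l1_coeff: float = 0.00001
    l2_coeff: float = 0.0001
    dropout: float = 0.5
    batch_size: int = 10
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "rms_decay", "rms_momentum", "rms_epsilon",
                     "l1_coeff", "l2_coeff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class ProbabilityMaps:
    """Per-class probability grids aligned to a source volume.

    ``data`` has shape (n_classes, D, H, W) and sums to 1 per voxel.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError(f"expected (n_classes, D, H, W), got {self.data.shape}")

    @property
    def n_classes(self) -> int:
        return self.data.shape[0]

    def argmax_labels(self) -> np.ndarray:
        return self.data.argmax(axis=0).astype(np.int16)


def regularization_penalty(net: DualPathNetwork, cfg: TrainConfig) -> float:
    """l1 * sum|w| + l2 * sum w^2 over convolution kernel weights."""
    l1 = l2 = 0.0
    for p in net.params():
        if p.regularized:
            l1 += np.abs(p.value).sum()
            l2 += (p.value**2).sum()
    return float(cfg.l1_coeff * l1 + cfg.l2_coeff * l2)


def cross_entropy(scores: np.ndarray, target: np.ndarray,
                  n_classes: int) -> tuple[float, np.ndarray]:
    """Mean per-voxel cross-entropy and its gradient w.r.t. the scores.

    ``scores``: (N, C, D, H, W); ``target``: (N, D, H, W) integer labels.
    """
    target = np.asarray(target)
    if target.min() < 0 or target.max() >= n_classes:
        raise LabelError(
            f"labels outside [0, {n_classes - 1}]: range "
            f"[{target.min()}, {target.max()}]")
    # stable log-softmax
    z = scores - scores.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n_vox = target.size
    idx = np.ogrid[tuple(slice(s) for s in target.shape)]
    picked = logp[idx[0], target, idx[1], idx[2], idx[3]]
    ce = float(-picked.sum() / n_vox)
    probs = np.exp(logp)
    onehot = np.zeros_like(probs)
    onehot[idx[0], target, idx[1], idx[2], idx[3]] = 1.0
    grad = (probs - onehot) / n_vox
    return ce, grad.astype(np.float32)


def loss(scores: np.ndarray, target: np.ndarray, net: DualPathNetwork,
         cfg: TrainConfig) -> float:
    """Total training loss: cross-entropy plus L1/L2 kernel penalties."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim == 4:
        scores = scores[None]
    target = np.asarray(target)
    if target.ndim == 3:
        target = target[None]
    ce, _ = cross_entropy(scores, target, net.cfg.n_classes)
    return ce + regularization_penalty(net, cfg)


class RMSPropMomentum:
    """RMSProp with heavy-ball momentum on the preconditioned gradient."""

    def __init__(self, net: DualPathNetwork, cfg: TrainConfig):
        self.net = net
        self.cfg = cfg
        self.sq = [np.zeros_like(p.value) for p in net.params()]
        self.mom = [np.zeros_like(p.value) for p in net.params()]

    def step(self) -> None:
        c = self.cfg
        for p, sq, mom in zip(self.net.params(), self.sq, self.mom):
            g = p.grad
            if p.regularized and (c.l1_coeff or c.l2_coeff):
                g = g + c.l1_coeff * np.sign(p.value) + 2.0 * c.l2_coeff * p.value
            sq *= c.rms_decay
            sq += (1.0 - c.rms_decay) * g * g
            mom *= c.rms_momentum
            mom += c.learning_rate * g / np.sqrt(sq + c.rms_epsilon)
            p.value -= mom


def train(net: DualPathNetwork, patches: list[PatchPair], cfg: TrainConfig,
          shuffle: bool = True) -> list[float]:
    """Train in place on a list of patch pairs; returns the per-epoch loss trace.

    Deterministic under a fixed ``cfg.seed`` and fixed patch order: batch
    shuffling and dropout both derive from the seed. Raises
    :class:`TrainingError` with diagnostics if the loss goes non-finite.
    """
    if not patches:
        raise ValueError("patch stream must be non-empty")
    for pp in patches:
        if pp.label_patch is None:
            raise ValueError("training patches need label_patch")
    opt = RMSPropMomentum(net, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5F]).generate_state(1)[0])
    n = len(patches)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = [patches[i] for i in order[start:start + cfg.batch_size]]
            xl = np.stack([b.local for b in batch]).astype(np.float32)
            xg = np.stack([b.global_ for b in batch]).astype(np.float32)
            yt = np.stack([b.label_patch for b in batch]).astype(np.int64)
            net.zero_grad()
            scores = net.forward(xl, xg, train=True)
            ce, gscores = cross_entropy(scores.astype(np.float64), yt, net.cfg.n_classes)
            total = ce + regularization_penalty(net, cfg)
            if not np.isfinite(total):
                raise TrainingError(
                    f"loss became non-finite at epoch {epoch}, step {start // cfg.batch_size} "
                    f"(cross-entropy {ce}); try a lower learning rate")
            net.backward(gscores)
            opt.step()
            epoch_losses.append(total)
        trace.append(float(np.mean(epoch_losses)))
    return trace


def predict_volume(net: DualPathNetwork, vol: Volume3D, tile_stride: int = 9,
                   edge: int | None = None, factor: int = 3) -> ProbabilityMaps:
    """Dense per-voxel class probabilities for a whole volume.

    The volume is tiled with dual-scale patches on a grid of stride
    ``tile_stride``; overlapping softmax outputs are averaged. Volumes
    smaller than the patch edge are handled by the patch extractor's
    padding (a warning is logged).
    """
    if edge is None:
        # infer something sensible: patch edge must be odd; callers normally pass it
        raise ValueError("patch edge must be given (the edge the network was trained with)")
    if min(vol.shape) < edge:
        log.warning("volume shape %s smaller than patch edge %d; padding applied",
                    vol.shape, edge)
    acc = np.zeros((net.cfg.n_classes,) + vol.shape, dtype=np.float64)
    cnt = np.zeros(vol.shape, dtype=np.float64)
    half = edge // 2
    for center in grid_centers(vol.shape, edge, tile_stride):
        pp = extract_dual_patch(vol, None, center, edge=edge, factor=factor)
        probs = softmax(net.forward_pair(pp, train=False), axis=1)[0]
        # paste only the in-bounds part of the patch
        src, dst = [], []
        ok = True
        for ax in range(3):
            lo = center[ax] - half
            hi = lo + edge
            s_lo, s_hi = max(lo, 0), min(hi, vol.shape[ax])
            if s_lo >= s_hi:
                ok = False
                break
            dst.append(slice(s_lo, s_hi))
            src.append(slice(s_lo - lo, s_hi - lo))
        if not ok:
            continue
        acc[(slice(None),) + tuple(dst)] += probs[(slice(None),) + tuple(src)]
        cnt[tuple(dst)] += 1.0
    if (cnt == 0).any():
        raise RuntimeError("tiling left uncovered voxels; decrease tile_stride")
    maps = acc / cnt[None]
    return ProbabilityMaps(maps, spacing=vol.spacing)
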