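"""Receptive-field arithmetic and dual-scale 3D patch extraction.

The receptive field of a stack of convolutions follows the recursion

    R_l = R_{l-1} + (k_l - 1) * prod_{i<l} s_i,   R_0 = 1,

per axis, where k_l is the kernel edge and s_i the stride of layer i.
Dual-scale sampling pairs a fine ``edge``-cube crop (the local patch) with
a co-centred ``factor*edge``-cube crop downsampled by ``factor`` to the
same edge (the global patch): same grid size, three times the anatomical
context at a third of the resolution for the defaults (edge 43, factor 3,
global source 129).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .volume import LabelVolume, Volume3D, check_aligned


class SamplingError(ValueError):
    """Requested sampling cannot be satisfied by the label volume."""


@dataclass(frozen=True)
class LayerSpec:
    """One convolutional layer: per-axis kernel edge and stride."""

    kernel: tuple[int, int, int]
    stride: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        k = _as_triple(self.kernel)
        s = _as_triple(self.stride)
        object.__setattr__(self, "kernel", k)
        object.__setattr__(self, "stride", s)
        if any(ki < 1 or ki % 2 == 0 for ki in k):
            raise ValueError(f"kernel edges must be odd and >= 1, got {k}")
        if any(si < 1 for si in s):
            raise ValueError(f"strides must be >= 1, got {s}")


def _as_triple(x) -> tuple[int, int, int]:
    if isinstance(x, (int, np.integer)):
        return (int(x),) * 3
    t = tuple(int(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected a scalar or 3 values, got {x!r}")
    return t


def receptive_field(layers: list[LayerSpec]) -> tuple[int, int, int]:
    """Per-axis receptive-field edge after a stack of convolutions."""
    if not layers:
        raise ValueError("layer list must be non-empty")
    r = np.ones(3, dtype=np.int64)
    jump = np.ones(3, dtype=np.int64)  # product of strides below the current layer
    for layer in layers:
        k = np.array(layer.kernel, dtype=np.int64)
        s = np.array(layer.stride, dtype=np.int64)
        r = r + (k - 1) * jump
        jump = jump * s
    return tuple(int(v) for v in r)


def min_segment_edge(layers: list[LayerSpec]) -> tuple[int, int, int]:
    """Smallest input cube for which the last layer sees a full receptive field.

    Identical to :func:`receptive_field`: one output voxel of the final
    layer summarizes exactly that many input voxels per axis.
    """
    return receptive_field(layers)


@dataclass
class PatchPair:
    """Co-centred fine (local) and coarse (global) cubic patches.

    ``local`` and ``global_`` share the edge length; ``global_`` is the
    block-mean downsampling of a ``factor``-times larger co-centred crop.
    ``label_patch`` is the label crop aligned to ``local``.
    """

    local: np.ndarray
    global_: np.ndarray
    center: tuple[int, int, int]
    label_patch: np.ndarray | None = None
    factor: int = 3

    def __post_init__(self) -> None:
        if self.local.shape != self.global_.shape:
            raise ValueError(
                f"local/global edge mismatch: {self.local.shape} vs {self.global_.shape}"
            )

    @property
    def edge(self) -> int:
        return self.local.shape[0]


def _crop_padded(data: np.ndarray, center, edge: int, pad_value: float) -> np.ndarray:
    """Cubic crop of odd edge centred on ``center``, constant-padded out of bounds."""
    half = edge // 2
    out = np.full((edge, edge, edge), pad_value, dtype=data.dtype)
    src, dst = [], []
    for ax in range(3):
        lo = center[ax] - half
        hi = lo + edge
        s_lo, s_hi = max(lo, 0), min(hi, data.shape[ax])
        if s_lo >= s_hi:
            return out
        src.append(slice(s_lo, s_hi))
        dst.append(slice(s_lo - lo, s_hi - lo))
    out[tuple(dst)] = data[tuple(src)]
    return out


def block_downsample(data: np.ndarray, factor: int, method: str = "mean") -> np.ndarray:
    """Downsample a cube whose edge is divisible by ``factor``."""
    if factor == 1:
        return data.copy()
    e = data.shape[0] // factor
    blocks = data.reshape(e, factor, e, factor, e, factor)
    if method == "mean":
        return blocks.mean(axis=(1, 3, 5))
    if method == "nearest":
        c = factor // 2
        return blocks[:, c, :, c, :, c].copy()
    raise ValueError(f"unknown downsampling method {method!r}")


def extract_dual_patch(
    vol: Volume3D,
    labels: LabelVolume | None,
    center: tuple[int, int, int],
    edge: int = 43,
    factor: int = 3,
    downsample: str = "mean",
) -> PatchPair:
    """Extract a co-centred local/global patch pair around a voxel.

    Out-of-bounds regions of either crop are padded with the volume
    minimum (air-like). The global source crop has edge ``factor*edge``.
    """
    if edge % 2 == 0 or edge < 1:
        raise ValueError(f"patch edge must be odd and >= 1, got {edge}")
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    center = tuple(int(c) for c in center)
    for ax in range(3):
        if not (0 <= center[ax] < vol.shape[ax]):
            raise IndexError(f"center {center} outside volume of shape {vol.shape}")
    pad = float(vol.data.min())
    local = _crop_padded(vol.data, center, edge, pad)
    g_src = _crop_padded(vol.data, center, edge * factor, pad)
    global_ = block_downsample(g_src, factor, method=downsample).astype(vol.data.dtype)
    label_patch = None
    if labels is not None:
        check_aligned(vol, labels)
        label_patch = _crop_padded(labels.data, center, edge, 0)
    return PatchPair(local=local, global_=global_, center=center,
                     label_patch=label_patch, factor=factor)


def sample_training_centers(
    labels: LabelVolume,
    n: int,
    seed: int,
    class_fractions: dict[int, float] | None = None,
) -> list[tuple[int, int, int]]:
    """Draw ``n`` patch centers stratified by class.

    Per-class counts follow exact largest-remainder allocation of the
    requested fractions; within a class, voxels are drawn uniformly with
    replacement. Deterministic for a fixed seed. When no fractions are
    given, classes present in the volume share equally (a volume with no
    lesions is legitimate: lesion counts start at zero).
    """
    if class_fractions is None:
        present = [int(c) for c in np.unique(labels.data)]
        class_fractions = {c: 1.0 / len(present) for c in present}
    if n < 0:
        raise ValueError("n must be nonnegative")
    items = sorted(class_fractions.items())
    total = sum(f for _, f in items)
    if total <= 0:
        raise SamplingError("class fractions must sum to a positive value")
    fracs = [(c, f / total) for c, f in items]
    quotas = [n * f for _, f in fracs]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(fracs)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    centers: list[tuple[int, int, int]] = []
    for (cls, frac), cnt in zip(fracs, counts):
        if cnt == 0:
            continue
        flat = np.flatnonzero(labels.data == cls)
        if flat.size == 0:
            raise SamplingError(f"class {cls} requested (fraction {frac:.3g}) but absent")
        picks = rng.choice(flat, size=cnt, replace=True)
        for p in picks:
            centers.append(tuple(int(v) for v in np.unravel_index(p, labels.shape)))
    return centers


def grid_centers(shape: tuple[int, int, int], edge: int, stride: int) -> list[tuple[int, int, int]]:
    """Deterministic tiling centers covering every voxel of a volume."""
    half = edge // 2
    centers_per_axis = []
    for ax in range(3):
        n = shape[ax]
        if n <= edge:
            cs = [n // 2]
        else:
            cs = list(range(half, n - half, stride))
            last = n - half - 1
            if cs[-1] < last:
                cs.append(last)
        centers_per_axis.append(cs)
    out = []
    for cx in centers_per_axis[0]:
        for cy in centers_per_axis[1]:
            for cz in centers_per_axis[2]:
                out.append((cx, cy, cz))
    return out


def write_patch_archive(
    dirname: str,
    pairs: list[PatchPair],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int | None = None,
) -> None:
    """Write patches as NIfTI files plus a JSON manifest (centers, seed)."""
    os.makedirs(dirname, exist_ok=True)
    manifest = {"n": len(pairs), "seed": seed, "patches": []}
    for i, pp in enumerate(pairs):
        base = f"patch_{i:05d}"
        Volume3D(pp.local, spacing=spacing).to_nifti(os.path.join(dirname, base + "_local.nii.gz"))
        Volume3D(pp.global_, spacing=spacing).to_nifti(os.path.join(dirname, base + "_global.nii.gz"))
        entry = {"center": list(pp.center), "factor": pp.factor, "edge": pp.edge}
        if pp.label_patch is not None:
            LabelVolume(pp.label_patch, spacing=spacing).to_nifti(
                os.path.join(dirname, base + "_labels.nii.gz"))
            vals, cnts = np.unique(pp.label_patch, return_counts=True)
            entry["class_counts"] = {int(v): int(c) for v, c in zip(vals, cnts)}
        manifest["patches"].append(entry)
    with open(os.path.join(dirname, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
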