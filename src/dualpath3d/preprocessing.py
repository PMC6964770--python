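"""Preprocessing of CT volumes: Gaussian smoothing, z-score normalization,
in-plane subsampling, and geometric augmentation.

The smoothing kernel is the 2D Gaussian

    H(i, j) ∝ exp(-(i² + j²) / 2σ²)

evaluated on integer offsets from the kernel center and normalized to sum
to one, applied slice-by-slice in the axial plane (the last axis). A full
3D Gaussian is available via ``mode="3d"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import LabelVolume, Volume3D, check_aligned

log = logging.getLogger(__name__)


class ParameterError(ValueError):
    """Invalid preprocessing parameter."""


class DegenerateInputError(ValueError):
    """Input volume cannot be processed (e.g. zero variance)."""


@dataclass(frozen=True)
class SmoothingKernel:
    """Normalized square Gaussian kernel for slice-wise filtering."""

    width: int
    sigma: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape != (self.width, self.width):
            raise ParameterError("weights must be a width x width grid")
        if not np.allclose(w, w[::-1, ::-1]):
            raise ParameterError("kernel must be symmetric about its center")


def make_gaussian_kernel(sigma: float, width: int) -> SmoothingKernel:
    """Build the normalized 2D Gaussian kernel of odd edge ``width``."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    if width < 1 or width % 2 == 0:
        raise ParameterError(f"kernel width must be a positive odd integer, got {width}")
    half = width // 2
    offs = np.arange(-half, half + 1, dtype=np.float64)
    ii, jj = np.meshgrid(offs, offs, indexing="ij")
    w = np.exp(-(ii**2 + jj**2) / (2.0 * sigma**2))
    w /= w.sum()
    return SmoothingKernel(width=width, sigma=float(sigma), weights=w)


def gaussian_smooth(
    vol: Volume3D, sigma: float = 1.0, width: int = 3, mode: str = "slice"
) -> Volume3D:
    """Smooth a volume with a normalized Gaussian kernel.

    ``mode="slice"`` (default) convolves each axial slice with the 2D
    kernel; ``mode="3d"`` uses the separable 3D Gaussian of the same
    sigma/width. Boundaries use mirror (reflect) padding so constant
    regions are preserved up to the edge.
    """
    kern = make_gaussian_kernel(sigma, width)
    out = np.empty_like(vol.data, dtype=np.float64)
    src = vol.data.astype(np.float64)
    if mode == "slice":
        for z in range(vol.shape[2]):
            out[:, :, z] = ndimage.convolve(src[:, :, z], kern.weights, mode="reflect")
    elif mode == "3d":
        half = width // 2
        offs = np.arange(-half, half + 1, dtype=np.float64)
        w1 = np.exp(-(offs**2) / (2.0 * sigma**2))
        k3 = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
        k3 /= k3.sum()
        out = ndimage.convolve(src, k3, mode="reflect")
    else:
        raise ParameterError(f"unknown smoothing mode {mode!r}")
    return vol.with_data(out)


def normalize_zscore(vol: Volume3D) -> Volume3D:
    """Standardize intensities to zero mean and unit standard deviation."""
    data = vol.data.astype(np.float64)
    if data.size < 2:
        raise DegenerateInputError("need at least 2 voxels to normalize")
    sd = data.std()
    if sd == 0:
        raise DegenerateInputError("zero-variance volume cannot be z-scored")
    return vol.with_data((data - data.mean()) / sd)


def subsample_inplane(vol: Volume3D, factor: int, method: str = "mean") -> Volume3D:
    """Downsample the two in-plane axes by an integer factor.

    Block-mean pooling by default (anti-aliasing); ``method="nearest"``
    picks the first voxel of each block. The axial (last) axis is kept.
    If the in-plane extent is not divisible by the factor the volume is
    cropped to the largest divisible extent and a warning is logged.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ParameterError(f"subsampling factor must be a positive integer, got {factor}")
    if factor == 1:
        return vol.with_data(vol.data.copy())
    nx, ny, nz = vol.shape
    cx, cy = (nx // factor) * factor, (ny // factor) * factor
    data = vol.data
    if (cx, cy) != (nx, ny):
        log.warning("in-plane extent (%d, %d) not divisible by %d; cropping to (%d, %d)",
                    nx, ny, factor, cx, cy)
        data = data[:cx, :cy, :]
    blocks = data.reshape(cx // factor, factor, cy // factor, factor, nz)
    if method == "mean":
        out = blocks.mean(axis=(1, 3))
    elif method == "nearest":
        out = blocks[:, 0, :, 0, :]
    else:
        raise ParameterError(f"unknown subsampling method {method!r}")
    sx, sy, sz = vol.spacing
    return Volume3D(out, spacing=(sx * factor, sy * factor, sz), origin=vol.origin)


_AUG_OPS = ("rotate90", "flip", "crop", "scale")


def augment(
    vol: Volume3D,
    labels: LabelVolume,
    ops: list[str],
    seed: int,
    crop_fraction: float = 0.9,
    scale_range: tuple[float, float] = (0.9, 1.1),
) -> tuple[Volume3D, LabelVolume]:
    """Apply a random geometric transform jointly to a volume and its labels.

    Each requested op draws its parameters from a generator seeded with
    ``seed``, so a fixed seed gives byte-identical outputs. Image values
    are interpolated linearly where needed; labels always use
    nearest-neighbour so the set of label values is preserved.
    """
    check_aligned(vol, labels)
    for op in ops:
        if op not in _AUG_OPS:
            raise ParameterError(f"unknown augmentation op {op!r}; expected one of {_AUG_OPS}")
    rng = np.random.default_rng(seed)
    img = vol.data.copy()
    lab = labels.data.copy()
    for op in ops:
        if op == "rotate90":
            k = int(rng.integers(0, 4))
            img = np.rot90(img, k=k, axes=(0, 1))
            lab = np.rot90(lab, k=k, axes=(0, 1))
        elif op == "flip":
            axis = int(rng.integers(0, 3))
            img = np.flip(img, axis=axis)
            lab = np.flip(lab, axis=axis)
        elif op == "crop":
            new_shape = [max(1, int(round(s * crop_fraction))) for s in img.shape]
            starts = [int(rng.integers(0, s - n + 1)) for s, n in zip(img.shape, new_shape)]
            sl = tuple(slice(st, st + n) for st, n in zip(starts, new_shape))
            img, lab = img[sl], lab[sl]
        elif op == "scale":
            f = float(rng.uniform(*scale_range))
            img = ndimage.zoom(img, f, order=1, mode="nearest")
            lab = ndimage.zoom(lab, f, order=0, mode="nearest")
    out_vol = Volume3D(np.ascontiguousarray(img), spacing=vol.spacing, origin=vol.origin)
    out_lab = LabelVolume(np.ascontiguousarray(lab), spacing=labels.spacing, origin=labels.origin)
    return out_vol, out_lab


def preprocess(
    vol: Volume3D,
    sigma: float = 1.0,
    width: int = 3,
    subsample: int = 1,
    order: tuple[str, ...] = ("smooth", "normalize", "subsample"),
) -> Volume3D:
    """Standard pipeline: smooth, then z-score, then subsample (configurable order)."""
    out = vol
    for step in order:
        if step == "smooth":
            out = gaussian_smooth(out, sigma=sigma, width=width)
        elif step == "normalize":
            out = normalize_zscore(out)
        elif step == "subsample":
            out = subsample_inplane(out, subsample)
        else:
            raise ParameterError(f"unknown pipeline step {step!r}")
    return out
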