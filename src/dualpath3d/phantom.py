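"""Synthetic abdominal-CT phantoms with exact liver/tumor ground truth.

Each phantom emulates the statistics of contrast CT liver studies: a
large smooth ellipsoidal liver, an adjacent organ of similar HU (the
classic segmentation difficulty), and 0..N low-contrast lesions placed
inside the liver. The tumor-liver HU difference is drawn from a normal
with mean 31.94 and SD 20 truncated to [0, 98], lesion volumes are
uniform on 38-349 mm^3, and Gaussian noise is added on top. Labels are
exact by construction, so every pipeline stage can be tested end to end
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BACKGROUND, LIVER, TUMOR, LabelVolume, Volume3D


class GenerationError(RuntimeError):
    """A phantom could not be generated under the given spec."""


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom.

    Intensity statistics follow the clinical description of contrast CT
    liver series; ``tumor_count_range`` is scaled down (the clinical range
    runs to 75 lesions in a full abdominal series, far more than a 96^3
    test grid needs to exercise any algorithmic stage).
    """

    volume_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = -60.0
    liver_hu: float = 120.0
    contrast_mean: float = 31.94
    contrast_sd: float = 20.0
    contrast_bounds: tuple[float, float] = (0.0, 98.0)
    tumor_count_range: tuple[int, int] = (0, 6)
    tumor_volume_range_mm3: tuple[float, float] = (38.0, 349.0)
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.tumor_count_range[0] > self.tumor_count_range[1]:
            raise ValueError("tumor_count_range must be nondecreasing")
        lo, hi = self.tumor_volume_range_mm3
        if not (0 < lo < hi):
            raise ValueError("tumor volume range must be a nondegenerate positive interval")


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape, dtype=np.float64)
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal (cheap at these bounds)."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise GenerationError("truncated-normal sampling failed (bounds too tight)")


def _spheroid_axes(rng: np.random.Generator, volume_mm3: float,
                   spacing, anisotropy: float = 0.15) -> np.ndarray:
    """Semi-axes (voxels) of a mildly anisotropic spheroid of given volume."""
    r_mm = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    jitter = rng.uniform(1.0 - anisotropy, 1.0 + anisotropy, size=3)
    jitter /= np.prod(jitter) ** (1.0 / 3.0)  # preserve volume
    return r_mm * jitter / np.asarray(spacing, dtype=np.float64)


def _rasterize_lesion(shape, center, axes, vmin_vox: float, vmax_vox: float) -> np.ndarray:
    """Voxelize a spheroid, nudging its scale so the voxel count lands in range.

    Rasterization quantizes the continuous volume (worst for the smallest
    lesions), so the semi-axes are scaled by a few percent at a time until
    the voxel-center count falls inside [vmin_vox, vmax_vox].
    """
    scale = 1.0
    mask = _ellipsoid_mask(shape, center, axes)
    for _ in range(60):
        n = int(mask.sum())
        if n < vmin_vox:
            scale *= 1.04
        elif n > vmax_vox:
            scale /= 1.04
        else:
            return mask
        mask = _ellipsoid_mask(shape, center, np.asarray(axes) * scale)
    raise GenerationError("could not rasterize a lesion inside the volume range")


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, LabelVolume]:
    """Generate one phantom volume and its exact label map.

    Deterministic for a fixed ``spec.seed``. Raises
    :class:`GenerationError` if a lesion cannot be placed inside the
    liver after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.volume_shape)
    sp = np.asarray(spec.spacing, dtype=np.float64)
    img = np.full(shape, spec.background_hu, dtype=np.float64)
    lab = np.zeros(shape, dtype=np.int16)

    ext = np.asarray(shape, dtype=np.float64)
    # liver: off-center smooth ellipsoid filling a good share of the grid
    liver_axes = ext * rng.uniform(0.26, 0.34, size=3)
    liver_center = ext / 2.0 + rng.uniform(-0.08, 0.08, size=3) * ext
    liver_center[0] -= 0.06 * ext[0]
    liver = _ellipsoid_mask(shape, liver_center, liver_axes)
    img[liver] = spec.liver_hu
    lab[liver] = LIVER

    # adjacent organ at similar HU, touching the liver but unlabeled
    organ_axes = ext * rng.uniform(0.10, 0.16, size=3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    organ_center = liver_center + direction * (liver_axes + organ_axes) * 0.95
    organ_center = np.clip(organ_center, 0, ext - 1)
    organ = _ellipsoid_mask(shape, organ_center, organ_axes) & ~liver
    img[organ] = spec.liver_hu + rng.normal(0.0, 5.0)

    # lesions inside the liver; exact Euclidean containment via distance transform
    n_tumors = int(rng.integers(spec.tumor_count_range[0], spec.tumor_count_range[1] + 1))
    depth = ndimage.distance_transform_edt(liver, sampling=None) if n_tumors else None
    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    vmin, vmax = spec.tumor_volume_range_mm3
    voxel_mm3 = float(np.prod(sp))
    for _ in range(n_tumors):
        ok = False
        for _resample in range(30):  # smaller lesions may fit where large ones cannot
            target_v = float(rng.uniform(vmin, vmax))
            axes = _spheroid_axes(rng, target_v, sp)
            rmax = float(axes.max())
            cand = np.argwhere(depth >= rmax * 1.3 + 2.0)
            if cand.size == 0:
                continue
            for _attempt in range(100):
                c = cand[rng.integers(0, len(cand))].astype(np.float64)
                if all(np.linalg.norm(c - pc) > rmax + pr + 2.0
                       for pc, pr in zip(placed_centers, placed_radii)):
                    ok = True
                    break
            if ok:
                break
        if not ok:
            raise GenerationError(
                "could not place a non-overlapping lesion inside the liver "
                "after bounded retries")
        tumor = _rasterize_lesion(shape, c, axes, vmin / voxel_mm3, vmax / voxel_mm3)
        delta = _truncated_normal(rng, spec.contrast_mean, spec.contrast_sd,
                                  *spec.contrast_bounds)
        img[tumor] = spec.liver_hu - delta
        lab[tumor] = TUMOR
        placed_centers.append(c)
        placed_radii.append(rmax)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)

    vol = Volume3D(img, spacing=tuple(spec.spacing))
    labels = LabelVolume(lab, spacing=tuple(spec.spacing))
    return vol, labels


def inject_speckle_errors(labels: LabelVolume, n_errors: int, seed: int,
                          min_distance: float = 3.0, border_margin: int = 3,
                          n_classes: int = 3) -> LabelVolume:
    """Flip ``n_errors`` isolated voxels to a wrong label.

    Each flipped voxel is at least ``min_distance`` voxels from any voxel
    already carrying its new label — including previously injected
    speckles of that label — and ``border_margin`` voxels from the volume
    border, so the errors are isolated interior speckles: the kind of
    scattered mis-segmentation a dense CRF should remove. Deterministic
    under ``seed``.
    """
    if n_errors < 0:
        raise ValueError("n_errors must be nonnegative")
    out = labels.data.copy()
    if n_errors == 0:
        return labels.with_data(out)
    rng = np.random.default_rng(seed)
    interior = np.zeros(labels.shape, dtype=bool)
    b = border_margin
    interior[b:labels.shape[0] - b, b:labels.shape[1] - b, b:labels.shape[2] - b] = True
    # eligible (voxel, wrong_label) pairs: far from any same-label structure
    pools = []
    for wrong in range(n_classes):
        mask = labels.data == wrong
        if not mask.any():
            continue
        dist = ndimage.distance_transform_edt(~mask)
        eligible = np.argwhere((dist >= min_distance) & (labels.data != wrong) & interior)
        if len(eligible):
            pools.append((wrong, eligible))
    if not pools:
        raise GenerationError("no eligible speckle positions")
    chosen: dict[tuple[int, int, int], int] = {}
    guard = 0
    while len(chosen) < n_errors:
        guard += 1
        if guard > 100 * n_errors + 100:
            raise GenerationError(
                f"could only place {len(chosen)} of {n_errors} speckle errors")
        wrong, eligible = pools[rng.integers(0, len(pools))]
        pos = tuple(int(v) for v in eligible[rng.integers(0, len(eligible))])
        if pos in chosen:
            continue
        if any(w == wrong and np.linalg.norm(np.subtract(pos, q)) < min_distance
               for q, w in chosen.items()):
            continue
        chosen[pos] = wrong
    for pos, wrong in chosen.items():
        out[pos] = wrong
    return labels.with_data(out)
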