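"""Background subtraction, smoothing, and mitochondria segmentation.

The processing chain for a two-channel ratiometric z-stack is fixed:

1. per-slice background subtraction (mean of the bottom 5% of each slice's
   intensities, per channel),
2. per-slice 2D mean filtering (radius 2 by default),
3. per-slice local-mean adaptive thresholding of the CFP+YFP sum image,
4. 3D connected-component labelling with a physical size constraint.

Segmenting on the channel sum keeps detection independent of an object's
Ca2+ level: a high-Ca2+ mitochondrion shifts intensity from CFP to YFP but
conserves their sum under the forward model.  Ratios are later measured on
the background-subtracted but unsmoothed channels (smoothing assists
segmentation only); see :mod:`mitocal.quantify`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_local, threshold_otsu

from .imaging import CFP, RED, YFP, ImageStack

__all__ = [
    "SegmentationParams",
    "LabelVolume",
    "PlaqueSet",
    "subtract_background",
    "smooth",
    "segment_mitochondria",
    "extract_plaques",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Adaptive-threshold and size-filter settings.

    block_size : odd local-mean window, pixels (default 51).
    offset     : additive threshold offset in intensity units (default 0).
    noise_k    : noise-floor multiplier: the threshold is raised above the
                 local mean by noise_k times the slice's robust noise scale
                 (1.4826 * MAD).  This keeps pure local-mean behaviour on
                 noise-free data (MAD = 0) and, because MAD scales with the
                 image, preserves invariance of the mask under common
                 intensity scaling.
    min_size_um3 / max_size_um3 : physical object-volume bounds; converted
                 to voxels through the stack's voxel size.
    connectivity : 3D connectivity for labelling (3 = 26-connected).
    soma_volume_cut_um3 : objects larger than this are tagged "soma",
                 smaller ones "neurite" (overridable by a soma mask).
    """

    block_size: int = 51
    offset: float = 0.0
    noise_k: float = 3.5
    min_size_um3: float = 0.2
    max_size_um3: float = 500.0
    connectivity: int = 3
    soma_volume_cut_um3: float = 20.0

    def __post_init__(self):
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError(f"block_size must be odd and >= 3, got {self.block_size}")
        if self.connectivity not in (1, 2, 3):
            raise ValueError("connectivity must be 1, 2 or 3")
        if not 0 < self.min_size_um3 < self.max_size_um3:
            raise ValueError("require 0 < min_size_um3 < max_size_um3")


@dataclass
class LabelVolume:
    """3D integer label grid; 0 = background, k = object k (1..object_count)."""

    labels: np.ndarray
    object_count: int
    voxel_size: tuple[float, float, float]
    params: SegmentationParams | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(self.labels)
        if not np.array_equal(present[present > 0], np.arange(1, self.object_count + 1)):
            raise ValueError("labels must be contiguous 1..object_count, each occurring")


@dataclass
class PlaqueSet:
    """Labelled amyloid-plaque masks with per-plaque edge voxel indices."""

    labels: np.ndarray
    plaque_count: int
    voxel_size: tuple[float, float, float]
    #: per-plaque (n_i, 3) arrays of edge-voxel (z, y, x) indices
    edges: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return self.plaque_count


# ---------------------------------------------------------------------------


def subtract_background(
    stack: ImageStack, fraction: float = 0.05, channels: tuple[str, ...] = (CFP, YFP)
) -> tuple[ImageStack, pd.DataFrame]:
    """Per-slice, per-channel background subtraction.

    The offset of each z-slice is the mean of the lowest ``fraction`` of its
    intensity values; results are clamped at zero.  Returns the corrected
    stack and a QC table of the subtracted offsets.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    new = {}
    qc_rows = []
    for role in channels:
        ch = stack[role]
        out = np.empty_like(ch)
        for z in range(ch.shape[0]):
            sl = ch[z]
            if sl.size == 0:
                raise ValueError(f"empty slice z={z} in channel {role}")
            k = max(1, int(np.floor(fraction * sl.size)))
            offset = float(np.mean(np.partition(sl.ravel(), k - 1)[:k]))
            out[z] = np.clip(sl - offset, 0.0, None)
            qc_rows.append({"channel": role, "z": z, "offset": offset})
        new[role] = out
    return stack.with_channels(new), pd.DataFrame(qc_rows)


def smooth(stack: ImageStack, radius: int = 2, kernel: str = "square",
           channels: tuple[str, ...] = (CFP, YFP)) -> ImageStack:
    """Per-slice 2D mean filter of radius ``radius`` on each channel.

    ``kernel="square"`` averages over the (2r+1)^2 neighbourhood;
    ``kernel="disk"`` over the digital disk of radius r.  Radius 0 is the
    identity.
    """
    if radius < 0 or int(radius) != radius:
        raise ValueError("radius must be a non-negative integer")
    if radius == 0:
        return stack.copy()
    if kernel == "square":
        k = np.ones((1, 2 * radius + 1, 2 * radius + 1))
    elif kernel == "disk":
        yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
        k = ((yy**2 + xx**2) <= radius**2).astype(float)[None]
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    k /= k.sum()
    new = {role: ndimage.convolve(stack[role], k, mode="nearest") for role in channels}
    return stack.with_channels(new)


def segment_mitochondria(
    stack: ImageStack, params: SegmentationParams | None = None
) -> LabelVolume:
    """Adaptive-threshold segmentation of mitochondria on the CFP+YFP sum.

    Each slice of the sum image is binarised against its local mean
    (``block_size`` window, additive ``offset``); the binary stack is then
    labelled in 3D and components outside the physical size bounds are
    dropped, with surviving labels renumbered 1..N.
    """
    params = params or SegmentationParams()
    stack.require_ratiometric()
    signal = stack[CFP] + stack[YFP]

    binary = np.empty(signal.shape, dtype=bool)
    for z in range(signal.shape[0]):
        sl = signal[z]
        sigma = 1.4826 * np.median(np.abs(sl - np.median(sl)))
        # skimage's offset is *subtracted* from the local mean
        thr = threshold_local(sl, block_size=params.block_size, method="mean",
                              offset=-(params.offset + params.noise_k * sigma))
        # the > 0 guard absorbs filter round-off (local mean of an empty
        # region can be a tiny negative number) without breaking the
        # invariance of the mask under common intensity scaling
        binary[z] = (sl > thr) & (sl > 0)

    structure = ndimage.generate_binary_structure(3, params.connectivity)
    labels, n = ndimage.label(binary, structure=structure)

    vox_vol = stack.voxel_volume_um3
    min_vox = params.min_size_um3 / vox_vol
    max_vox = params.max_size_um3 / vox_vol
    if n:
        counts = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = (counts[1:] >= min_vox) & (counts[1:] <= max_vox)
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[keep] = np.arange(1, int(keep.sum()) + 1)
        labels = remap[labels]
        n = int(keep.sum())
    return LabelVolume(labels, n, stack.voxel_size, params)


def _edge_voxels(mask: np.ndarray) -> np.ndarray:
    """(n, 3) indices of mask voxels 6-adjacent to background."""
    core = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return np.argwhere(mask & ~core)


def extract_plaques(
    stack: ImageStack,
    mode: str = "threshold",
    mask: np.ndarray | None = None,
    threshold: float | None = None,
    min_size_um3: float = 50.0,
) -> PlaqueSet:
    """Plaque masks from a manual mask volume or by thresholding RED.

    ``mode="manual"`` labels a supplied boolean/label volume as-is;
    ``mode="threshold"`` binarises the plaque-label (RED) channel at
    ``threshold`` (Otsu if omitted) and drops specks below ``min_size_um3``.
    Edge voxels (6-adjacency to background) are precomputed per plaque.
    """
    if mode == "manual":
        if mask is None:
            raise ValueError("manual mode requires a mask volume")
        m = np.asarray(mask)
        if m.dtype == bool or m.max() <= 1:
            labels, n = ndimage.label(m > 0)
        else:
            labels, n = m.astype(int), int(m.max())
    elif mode == "threshold":
        if RED not in stack:
            raise ValueError("threshold mode requires a RED plaque-label channel")
        red = stack[RED]
        if red.max() <= 0:
            return PlaqueSet(np.zeros(red.shape, int), 0, stack.voxel_size, [])
        thr = threshold if threshold is not None else threshold_otsu(red)
        binary = red > thr
        labels, n = ndimage.label(binary)
        min_vox = min_size_um3 / stack.voxel_volume_um3
        if n:
            counts = np.bincount(labels.ravel())
            keep = np.zeros(n + 1, dtype=bool)
            keep[1:] = counts[1:] >= min_vox
            remap = np.zeros(n + 1, dtype=labels.dtype)
            remap[keep] = np.arange(1, int(keep.sum()) + 1)
            labels = remap[labels]
            n = int(keep.sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    edges = [_edge_voxels(labels == k) for k in range(1, n + 1)]
    return PlaqueSet(labels, n, stack.voxel_size, edges)
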