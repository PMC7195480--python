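"""Single-slice mitochondrial morphology: area, perimeter, circularity.

Circularity here is perimeter^2 / (4*pi*area): exactly 1 for a continuous
circle and larger for irregular shapes (note this is the *inverse* of the
also-common 4*pi*A/P^2 convention).  Two perimeter estimators are offered:

``pixel-count``
    the number of object pixels 4-adjacent to background, times the pixel
    side — a literal boundary-pixel count.  Simple, but it overestimates
    diagonal boundaries and underestimates tiny objects (a 1-px object has
    perimeter "1 px", giving circularity 1/(4*pi)).
``crofton``
    the Crofton-formula estimator, which converges to the true
    perimeter of smooth shapes as resolution grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import perimeter_crofton

__all__ = ["MorphologyRecord", "measure_morphology", "measure_labelled_slice",
           "select_analysis_slices"]


@dataclass(frozen=True)
class MorphologyRecord:
    object_id: int
    slice_z: int
    area_um2: float
    perimeter_um: float
    circularity: float
    below_resolution: bool = False


def _boundary_pixel_count(mask: np.ndarray) -> int:
    core = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return int(np.sum(mask & ~core))


def measure_morphology(
    mask: np.ndarray,
    pixel_size_um: float,
    estimator: str = "pixel-count",
    object_id: int = 0,
    slice_z: int = 0,
) -> MorphologyRecord:
    """Area (µm²), perimeter (µm) and circularity of one 2D object mask.

    ``estimator`` picks the perimeter convention (see module docstring).
    Objects of <= 2 boundary pixels are flagged ``below_resolution``: their
    circularity is dominated by discretisation, not shape.
    """
    mask = np.asarray(mask).astype(bool)
    npix = int(mask.sum())
    if npix == 0:
        raise ValueError("empty mask")
    area = npix * pixel_size_um**2
    nboundary = _boundary_pixel_count(mask)
    if estimator == "pixel-count":
        perim = nboundary * pixel_size_um
    elif estimator == "crofton":
        perim = float(perimeter_crofton(mask, directions=4)) * pixel_size_um
    else:
        raise ValueError(f"unknown perimeter estimator {estimator!r}")
    circ = perim**2 / (4.0 * np.pi * area)
    return MorphologyRecord(object_id, slice_z, area, perim, circ,
                            below_resolution=nboundary <= 2)


def measure_labelled_slice(labels2d: np.ndarray, pixel_size_um: float,
                           slice_z: int = 0,
                           estimator: str = "pixel-count") -> pd.DataFrame:
    """Morphology records for every object in one labelled slice."""
    rows = []
    for k in np.unique(labels2d):
        if k == 0:
            continue
        rec = measure_morphology(labels2d == k, pixel_size_um, estimator,
                                 object_id=int(k), slice_z=slice_z)
        rows.append(rec.__dict__)
    return pd.DataFrame(rows)


def select_analysis_slices(
    labels: np.ndarray,
    voxel_size: tuple[float, float, float],
    depth_range_um: tuple[float, float] = (30.0, 60.0),
    n_objects: int = 125,
    seed: int | None = None,
) -> list[tuple[int, int]]:
    """Seeded random sample of (slice_z, object_id) ROIs in a depth window.

    Slices whose depth (z index × dz) lies within ``depth_range_um``
    (inclusive) contribute their in-slice object cross-sections; up to
    ``n_objects`` of these are sampled without replacement.  Fewer available
    than requested returns all, with a warning.
    """
    dz = voxel_size[0]
    lo, hi = depth_range_um
    zs = [z for z in range(labels.shape[0]) if lo <= z * dz <= hi]
    if not zs:
        raise ValueError(f"no slices within depth range {depth_range_um} µm")
    candidates = []
    for z in zs:
        for k in np.unique(labels[z]):
            if k != 0:
                candidates.append((z, int(k)))
    if len(candidates) <= n_objects:
        if len(candidates) < n_objects:
            warnings.warn(
                f"requested {n_objects} objects, only {len(candidates)} available"
            )
        return candidates
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(candidates), size=n_objects, replace=False)
    return [candidates[i] for i in sorted(picks)]
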