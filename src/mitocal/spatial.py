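"""Amyloid-plaque proximity analysis.

Distances run from each mitochondrion's 3D centroid to the nearest plaque
*edge* voxel (mask voxels 6-adjacent to background), in µm and aware of
anisotropic voxel spacing; a centroid inside a plaque scores 0.  Overload
probability is then binned by distance and compared across bins with a
Kruskal-Wallis rank test, the appropriate choice for the skewed per-plaque
overload percentages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .preprocess import PlaqueSet
from .quantify import OverloadThreshold

__all__ = [
    "distance_to_plaque",
    "distances_to_plaques",
    "overload_vs_distance",
    "kruskal_wallis",
]


def _edge_tree(plaques: PlaqueSet) -> cKDTree:
    dz, dy, dx = plaques.voxel_size
    pts = np.concatenate([e for e in plaques.edges if len(e)], axis=0).astype(float)
    return cKDTree(pts * np.array([dz, dy, dx]))


def distance_to_plaque(centroid_um, plaques: PlaqueSet) -> float:
    """Min Euclidean µm distance from one centroid to any plaque edge voxel."""
    return float(distances_to_plaques(np.asarray(centroid_um, float)[None, :], plaques)[0])


def distances_to_plaques(centroids_um: np.ndarray, plaques: PlaqueSet) -> np.ndarray:
    """Vectorised nearest-plaque-edge distances (µm) for (n, 3) centroids.

    Centroids whose containing voxel lies inside a plaque get distance 0.
    With no plaques present, all distances are NaN (with a warning).
    """
    centroids_um = np.asarray(centroids_um, float)
    if plaques.plaque_count == 0:
        warnings.warn("empty PlaqueSet: distances undefined")
        return np.full(len(centroids_um), np.nan)
    d, _ = _edge_tree(plaques).query(centroids_um)
    # containment: voxel index of each centroid
    spacing = np.array(plaques.voxel_size)
    idx = np.round(centroids_um / spacing).astype(int)
    shape = np.array(plaques.labels.shape)
    inside = np.zeros(len(centroids_um), bool)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    inside[ok] = plaques.labels[tuple(idx[ok].T)] > 0
    return np.where(inside, 0.0, d)


def attach_distances(objects: pd.DataFrame, plaques: PlaqueSet) -> pd.DataFrame:
    """Fill the ``distance_um`` column of an object table from a PlaqueSet."""
    out = objects.copy()
    cents = out[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy(float)
    out["distance_um"] = distances_to_plaques(cents, plaques)
    return out


def overload_vs_distance(
    objects: pd.DataFrame,
    thr: OverloadThreshold | float,
    bin_width: float = 10.0,
    max_dist: float = 100.0,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Overload percent per distance-to-plaque bin.

    Bins are [0, bin_width), [bin_width, 2*bin_width), ... up to
    ``max_dist``; objects beyond ``max_dist`` (or with missing distance) are
    excluded and counted in the frame's ``n_excluded`` attr.  With
    ``group_col`` (e.g. a per-plaque id) the table is computed per group,
    giving the samples for the Kruskal-Wallis comparison.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    cut = thr.threshold if isinstance(thr, OverloadThreshold) else float(thr)
    df = objects.dropna(subset=["ratio"]).copy()
    valid = df["distance_um"].notna() & (df["distance_um"] <= max_dist)
    n_excluded = int((~valid).sum())
    df = df[valid]
    edges = np.arange(0.0, max_dist + bin_width / 2, bin_width)
    df["bin"] = pd.cut(df["distance_um"], bins=edges, right=False, include_lowest=True)
    df["overload"] = df["ratio"] > cut

    keys = ([group_col, "bin"] if group_col else ["bin"])
    rows = []
    for key, g in df.groupby(keys, observed=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        interval = key[-1]
        row = {
            "bin_left": interval.left,
            "bin_right": interval.right,
            "n_objects": int(len(g)),
            "n_overload": int(g["overload"].sum()),
            "overload_pct": 100.0 * g["overload"].mean() if len(g) else np.nan,
        }
        if group_col:
            row[group_col] = key[0]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["threshold"] = cut
    return out


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across >= 2 groups.

    All-identical data (H undefined under scipy's convention) returns
    (0.0, 1.0): with every observation tied there is no rank evidence of a
    group difference.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
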