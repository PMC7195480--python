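"""Per-mitochondrion ratio/concentration measurement and cohort summaries.

The per-object YFP/CFP ratio is the ratio of *summed* intensities over the
object's voxels (not the mean of voxel-wise ratios), taken from the
background-subtracted channels; smoothing is used for segmentation only
unless ``use_smoothed`` is requested.  Ca2+ overload is defined against a
control pool as ratio strictly greater than control mean + 2 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from scipy import ndimage

from .calibration import CalibrationCurve, DEFAULT_CURVE
from .imaging import CFP, YFP, ImageStack
from .preprocess import LabelVolume

__all__ = [
    "OverloadThreshold",
    "RatioTrace",
    "measure_objects",
    "volume_summary",
    "overload_threshold",
    "overload_fraction",
    "ratio_histogram",
    "delta_r_over_r",
    "flag_responders",
    "pseudocolor",
    "normalize_trace",
]

OBJECT_COLUMNS = [
    "object_id", "volume_id", "mouse_id",
    "centroid_z_um", "centroid_y_um", "centroid_x_um",
    "voxel_count", "volume_um3", "sum_yfp", "sum_cfp",
    "ratio", "conc_nm", "compartment", "distance_um",
]


@dataclass
class RatioTrace:
    """A time series of ratio (or fluorescence) values with a baseline index."""

    timestamps: np.ndarray
    values: np.ndarray
    baseline_index: int = 0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, float)
        self.values = np.asarray(self.values, float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must match in length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.values[self.baseline_index] > 0:
            raise ValueError("baseline value must be positive")

    def normalized(self) -> np.ndarray:
        return normalize_trace(self.values, self.baseline_index)


@dataclass(frozen=True)
class OverloadThreshold:
    """Control-cohort mean + 2 SD overload cut on the YFP/CFP ratio."""

    control_mean: float
    control_sd: float
    n_control_objects: int

    @property
    def threshold(self) -> float:
        return self.control_mean + 2.0 * self.control_sd


def measure_objects(
    labels: LabelVolume,
    stack: ImageStack,
    curve: CalibrationCurve = DEFAULT_CURVE,
    volume_id: str = "vol0",
    mouse_id: str = "mouse0",
    soma_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """One record per labelled object: sums, ratio, [Ca2+] (nM), compartment.

    The ratio is sum(YFP voxels)/sum(CFP voxels); concentration comes from
    the calibration curve and is NaN for out-of-range ratios.  Objects with
    zero CFP sum get a NaN ratio and are flagged via the ``qc_zero_cfp``
    attribute on the returned frame.  Compartment is "soma" when the object
    volume exceeds the configured cut (or it touches ``soma_mask``), else
    "neurite".
    """
    stack.require_ratiometric()
    lab = labels.labels
    n = labels.object_count
    if n == 0:
        df = pd.DataFrame(columns=OBJECT_COLUMNS)
        df.attrs["qc_zero_cfp"] = []
        return df
    idx = np.arange(1, n + 1)
    sum_yfp = ndimage.sum_labels(stack[YFP], lab, idx)
    sum_cfp = ndimage.sum_labels(stack[CFP], lab, idx)
    counts = ndimage.sum_labels(np.ones(lab.shape), lab, idx)
    centroids = np.array(ndimage.center_of_mass(np.ones(lab.shape), lab, idx))
    dz, dy, dx = labels.voxel_size
    vox_vol = dz * dy * dx

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sum_cfp > 0, sum_yfp / np.where(sum_cfp > 0, sum_cfp, 1.0), np.nan)
    conc = curve.ratio_to_concentration(ratio)

    cut = labels.params.soma_volume_cut_um3 if labels.params is not None else 20.0
    volume_um3 = counts * vox_vol
    compartment = np.where(volume_um3 > cut, "soma", "neurite")
    if soma_mask is not None:
        in_soma = ndimage.sum_labels(np.asarray(soma_mask, float), lab, idx) > 0
        compartment = np.where(in_soma, "soma", compartment)

    df = pd.DataFrame({
        "object_id": idx,
        "volume_id": volume_id,
        "mouse_id": mouse_id,
        "centroid_z_um": centroids[:, 0] * dz,
        "centroid_y_um": centroids[:, 1] * dy,
        "centroid_x_um": centroids[:, 2] * dx,
        "voxel_count": counts.astype(int),
        "volume_um3": volume_um3,
        "sum_yfp": sum_yfp,
        "sum_cfp": sum_cfp,
        "ratio": ratio,
        "conc_nm": conc,
        "compartment": compartment,
        "distance_um": np.nan,
    })
    df.attrs["qc_zero_cfp"] = df.loc[~(sum_cfp > 0), "object_id"].tolist()
    return df


def volume_summary(objects: pd.DataFrame,
                   thr: OverloadThreshold | None = None,
                   weighted: bool = False) -> pd.DataFrame:
    """Per-volume mean ratio, object counts and (optionally) overload %.

    Each mitochondrion counts once by default; ``weighted=True`` weights by
    voxel count instead.
    """
    if objects.empty or objects["ratio"].notna().sum() == 0:
        warnings.warn("no objects with defined ratios; empty summary")
        return pd.DataFrame(columns=["volume_id", "mouse_id", "mean_ratio",
                                     "n_objects", "n_missing_ratio", "overload_pct"])
    rows = []
    for (vol, mouse), g in objects.groupby(["volume_id", "mouse_id"], sort=True):
        ok = g["ratio"].notna()
        if weighted:
            w = g.loc[ok, "voxel_count"].to_numpy(float)
            mean_r = float(np.average(g.loc[ok, "ratio"], weights=w)) if ok.any() else np.nan
        else:
            mean_r = float(g.loc[ok, "ratio"].mean()) if ok.any() else np.nan
        row = {
            "volume_id": vol,
            "mouse_id": mouse,
            "mean_ratio": mean_r,
            "n_objects": int(ok.sum()),
            "n_missing_ratio": int((~ok).sum()),
            "overload_pct": np.nan,
        }
        if thr is not None and ok.any():
            r = g.loc[ok, "ratio"]
            row["overload_pct"] = 100.0 * float((r > thr.threshold).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def overload_threshold(control_objects: pd.DataFrame | np.ndarray) -> OverloadThreshold:
    """Mean + 2 SD (sample SD, ddof=1) over a pooled control-object ratio set."""
    ratios = (control_objects["ratio"] if isinstance(control_objects, pd.DataFrame)
              else pd.Series(np.asarray(control_objects, float)))
    ratios = ratios.dropna().to_numpy(float)
    if ratios.size < 2:
        raise ValueError("need at least 2 control objects with defined ratios")
    sd = float(np.std(ratios, ddof=1))
    if np.isclose(sd, 0.0, atol=1e-12):
        warnings.warn("control ratios are all equal; degenerate SD = 0 threshold")
    return OverloadThreshold(float(np.mean(ratios)), sd, int(ratios.size))


def overload_fraction(objects: pd.DataFrame | np.ndarray,
                      thr: OverloadThreshold | float) -> float:
    """Percent of objects with ratio strictly above the overload threshold."""
    cut = thr.threshold if isinstance(thr, OverloadThreshold) else float(thr)
    ratios = (objects["ratio"] if isinstance(objects, pd.DataFrame)
              else pd.Series(np.asarray(objects, float)))
    ratios = ratios.dropna().to_numpy(float)
    if ratios.size == 0:
        return np.nan
    return 100.0 * float(np.mean(ratios > cut))


def ratio_histogram(objects: pd.DataFrame | np.ndarray, bin_width: float = 0.05,
                    range_: tuple[float, float] | None = None,
                    normalized: bool = True,
                    thr: OverloadThreshold | None = None) -> pd.DataFrame:
    """Ratio frequency distribution on a fixed bin grid.

    Returns a frame of bin edges/centres and counts or relative frequencies
    (summing to 1); the overload threshold, if given, is annotated in attrs.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ratios = (objects["ratio"] if isinstance(objects, pd.DataFrame)
              else pd.Series(np.asarray(objects, float)))
    ratios = ratios.dropna().to_numpy(float)
    if ratios.size == 0:
        raise ValueError("no defined ratios to histogram")
    lo, hi = range_ if range_ is not None else (ratios.min(), ratios.max())
    nbins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(ratios, bins=edges)
    freq = counts / counts.sum() if normalized else counts
    df = pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "bin_center": 0.5 * (edges[:-1] + edges[1:]),
        "frequency": freq,
    })
    df.attrs["overload_threshold"] = thr.threshold if thr is not None else None
    df.attrs["n"] = int(ratios.size)
    return df


def delta_r_over_r(before: float, after: float) -> float:
    """Percent change of a volume-mean ratio relative to its baseline."""
    if not before > 0:
        raise ValueError("baseline ratio must be positive")
    return 100.0 * (after - before) / before


def flag_responders(before: np.ndarray, after: np.ndarray, cut: float = 5.0) -> pd.DataFrame:
    """Per-volume ΔR/R0 with responder flag at ΔR/R0 >= cut percent."""
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    change = np.array([delta_r_over_r(b, a) for b, a in zip(before, after)])
    return pd.DataFrame({
        "before": before,
        "after": after,
        "delta_r_over_r_pct": change,
        "responder": change >= cut,
    })


def pseudocolor(ratio_image: np.ndarray, yfp: np.ndarray, cfp: np.ndarray,
                curve: CalibrationCurve = DEFAULT_CURVE,
                cmap: str = "viridis") -> np.ndarray:
    """Ca2+ pseudocolour rendering of a ratio image.

    The ratio is mapped onto ``cmap`` anchored at [r_min, r_max]; the RGB
    colours are converted to HSV and the value channel replaced by the
    normalised mean of the YFP and CFP intensity images, so colour encodes
    Ca2+ and brightness encodes signal.  Output is float RGB in [0, 1].
    """
    r = np.asarray(ratio_image, float)
    norm = np.clip((r - curve.r_min) / (curve.r_max - curve.r_min), 0.0, 1.0)
    norm = np.where(np.isfinite(norm), norm, 0.0)
    rgb = colormaps[cmap](norm)[..., :3]
    hsv = rgb_to_hsv(rgb)
    intensity = 0.5 * (np.asarray(yfp, float) + np.asarray(cfp, float))
    peak = intensity.max()
    hsv[..., 2] = intensity / peak if peak > 0 else 0.0
    return hsv_to_rgb(hsv)


def normalize_trace(trace: np.ndarray, t0_index: int = 0) -> np.ndarray:
    """Divide a fluorescence time series by its value at t0 (index)."""
    trace = np.asarray(trace, float)
    baseline = trace[t0_index]
    if not baseline > 0:
        raise ValueError("baseline (t0) value must be positive")
    return trace / baseline
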