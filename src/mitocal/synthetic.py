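"""Synthetic data emulating two-photon ratiometric Ca2+ imaging.

Everything the pipeline consumes can be generated here with known ground
truth: titration tables, two-channel z-stacks of mitochondria-shaped
objects, cohort object tables, treatment time courses, and paired
longitudinal sessions.  All generators are pure functions of
(specification, seed).

Forward model for image stacks
------------------------------
Each object is an ellipsoid with a total per-voxel intensity I and a true
ratio R.  Its channel intensities are

    CFP = I / (1 + R),        YFP = I * R / (1 + R)

so that YFP/CFP = R exactly and CFP+YFP = I independent of Ca2+ (the
segmentation signal is therefore unbiased w.r.t. Ca2+ level).  Photon shot
noise is Poisson on this pre-offset signal; each slice then receives an
additive background offset b(z), and finally Gaussian read noise.
Plaques are rendered as spheres in the RED channel.

Cohort presets
--------------
"wt_like" draws object ratios from N(0.67, 0.16^2), whose mean + 2 SD is
0.99 — the wild-type overload anchor.  "tg_like" is a 95/5 mixture of the
same base component with a high-Ca2+ component N(1.2, 0.1^2), giving a
heavier right tail (analytic overload exceedance ~7% at threshold 0.99).
These are generator settings for demos and recovery tests, not claims of
reproducing animal data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, DEFAULT_CURVE, TITRATION_CONCS_UM, TitrationTable
from .imaging import CFP, RED, YFP, ImageStack
from .quantify import RatioTrace

__all__ = [
    "ObjectTruth", "PlaqueTruth", "StackSpec", "SyntheticTruth",
    "CohortSpec", "COHORT_PRESETS",
    "generate_titration", "generate_stack", "generate_cohort",
    "generate_timelapse", "generate_longitudinal",
    "mixture_exceedance",
]


# ---------------------------------------------------------------------------
# titration


def generate_titration(
    curve: CalibrationCurve = DEFAULT_CURVE,
    conc_list_um=TITRATION_CONCS_UM,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> TitrationTable:
    """Forward-model titration: ratio(C) times multiplicative Gaussian noise."""
    conc = np.asarray(conc_list_um, float)
    if np.any(conc < 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("conc_list_um must be non-negative and strictly increasing")
    ratio = np.asarray(curve.concentration_to_ratio(conc * 1000.0), float)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio * (1.0 + noise_cv * rng.standard_normal(ratio.shape))
    return TitrationTable(conc, ratio)


# ---------------------------------------------------------------------------
# stacks


@dataclass
class ObjectTruth:
    center_um: tuple[float, float, float]   # (z, y, x)
    axes_um: tuple[float, float, float]     # ellipsoid semi-axes (z, y, x)
    angle_deg: float                        # in-plane rotation
    intensity: float                        # per-voxel CFP+YFP signal
    ratio: float
    compartment: str                        # "soma" | "neurite"


@dataclass
class PlaqueTruth:
    center_um: tuple[float, float, float]
    radius_um: float
    intensity: float = 500.0


@dataclass
class StackSpec:
    """Geometry, content and noise of one synthetic two-channel z-stack."""

    shape: tuple[int, int, int] = (12, 512, 512)          # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (1.5, 0.125, 0.125)  # µm
    n_objects: int = 50
    soma_fraction: float = 0.2
    #: semi-axis ranges (µm): (z, long in-plane, short in-plane)
    neurite_axes_um: tuple = ((1.2, 1.8), (2.0, 3.0), (1.1, 1.5))
    soma_axes_um: tuple = ((2.0, 3.0), (2.5, 3.5), (2.5, 3.5))
    intensity_range: tuple[float, float] = (150.0, 300.0)
    ratio_mean: float = 0.67
    ratio_sd: float = 0.16
    background_offset: float = 20.0         # base b; per-slice b(z) varies ±30%
    poisson_noise: bool = True
    read_noise_sd: float = 2.0
    plaques: list[PlaqueTruth] = field(default_factory=list)
    min_separation_um: float = 2.0
    edge_margin_um: float = 3.0


@dataclass
class SyntheticTruth:
    """Serializable ground truth of one generated stack."""

    spec: StackSpec
    seed: int | None
    objects: list[ObjectTruth]
    plaques: list[PlaqueTruth]
    background_per_slice: list[float]
    label_volume: np.ndarray = field(repr=False, default=None)

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d.pop("label_volume")
        doc = json.dumps(d, indent=2, default=list)
        if path is not None:
            Path(path).write_text(doc)
        return doc


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out <= lo) | (out >= hi)
    return out


def _render_ellipsoid(channel_shape, voxel_size, obj: ObjectTruth) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices inside the (in-plane rotated) ellipsoid."""
    dz, dy, dx = voxel_size
    cz, cy, cx = obj.center_um
    az, ay, ax = obj.axes_um
    reach = max(obj.axes_um)
    z0 = max(int((cz - reach) / dz) - 1, 0)
    z1 = min(int((cz + reach) / dz) + 2, channel_shape[0])
    y0 = max(int((cy - reach) / dy) - 1, 0)
    y1 = min(int((cy + reach) / dy) + 2, channel_shape[1])
    x0 = max(int((cx - reach) / dx) - 1, 0)
    x1 = min(int((cx + reach) / dx) + 2, channel_shape[2])
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1) * dz - cz,
        np.arange(y0, y1) * dy - cy,
        np.arange(x0, x1) * dx - cx,
        indexing="ij",
    )
    th = np.deg2rad(obj.angle_deg)
    yr = yy * np.cos(th) - xx * np.sin(th)
    xr = yy * np.sin(th) + xx * np.cos(th)
    inside = (zz / az) ** 2 + (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0
    idx = np.argwhere(inside)
    idx[:, 0] += z0
    idx[:, 1] += y0
    idx[:, 2] += x0
    return idx


def generate_stack(
    spec: StackSpec | None = None,
    curve: CalibrationCurve = DEFAULT_CURVE,
    seed: int | None = None,
) -> tuple[ImageStack, SyntheticTruth]:
    """Render a two-channel (plus RED) stack per the forward model.

    Object placement is rejection-sampled to keep centres at least
    ``min_separation_um`` plus both objects' long semi-axes apart; failure
    to place all objects raises (the spec is too dense for the volume).
    Ground truth includes a voxel-accurate label volume for recall/IoU
    scoring.
    """
    spec = spec or StackSpec()
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.voxel_size
    extent = np.array([nz * dz, ny * dy, nx * dx])
    m = spec.edge_margin_um

    n_soma = int(round(spec.n_objects * spec.soma_fraction))
    kinds = ["soma"] * n_soma + ["neurite"] * (spec.n_objects - n_soma)

    objects: list[ObjectTruth] = []
    centers: list[np.ndarray] = []
    reaches: list[float] = []
    for kind in kinds:
        ax_ranges = spec.soma_axes_um if kind == "soma" else spec.neurite_axes_um
        axes = tuple(rng.uniform(lo, hi) for lo, hi in ax_ranges)
        reach = max(axes)
        placed = False
        for _ in range(2000):
            c = rng.uniform(m, extent - m)
            ok = all(
                np.linalg.norm((c - c2) * 1.0) > reach + r2 + spec.min_separation_um
                for c2, r2 in zip(centers, reaches)
            )
            if ok:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place all objects without overlap; spec too dense"
            )
        ratio = float(_truncated_normal(
            rng, spec.ratio_mean, spec.ratio_sd,
            curve.r_min + 0.01, curve.r_max - 0.01, 1)[0])
        obj = ObjectTruth(
            center_um=tuple(c),
            axes_um=axes,
            angle_deg=float(rng.uniform(0, 180)),
            intensity=float(rng.uniform(*spec.intensity_range)),
            ratio=ratio,
            compartment=kind,
        )
        objects.append(obj)
        centers.append(c)
        reaches.append(reach)

    cfp = np.zeros(spec.shape)
    yfp = np.zeros(spec.shape)
    red = np.zeros(spec.shape)
    truth_labels = np.zeros(spec.shape, dtype=np.int32)
    for k, obj in enumerate(objects, start=1):
        idx = _render_ellipsoid(spec.shape, spec.voxel_size, obj)
        if len(idx) == 0:
            continue
        sel = tuple(idx.T)
        cfp[sel] = obj.intensity / (1.0 + obj.ratio)
        yfp[sel] = obj.intensity * obj.ratio / (1.0 + obj.ratio)
        truth_labels[sel] = k

    for pl in spec.plaques:
        zz, yy, xx = np.meshgrid(
            np.arange(nz) * dz - pl.center_um[0],
            np.arange(ny) * dy - pl.center_um[1],
            np.arange(nx) * dx - pl.center_um[2],
            indexing="ij",
        )
        red[zz**2 + yy**2 + xx**2 <= pl.radius_um**2] = pl.intensity

    if spec.poisson_noise:
        cfp = rng.poisson(cfp).astype(float)
        yfp = rng.poisson(yfp).astype(float)

    if spec.background_offset > 0:
        b = spec.background_offset * (1.0 + 0.3 * (2 * rng.random(nz) - 1))
    else:
        b = np.zeros(nz)
    cfp += b[:, None, None]
    yfp += b[:, None, None]

    if spec.read_noise_sd > 0:
        cfp = np.clip(cfp + rng.normal(0, spec.read_noise_sd, spec.shape), 0, None)
        yfp = np.clip(yfp + rng.normal(0, spec.read_noise_sd, spec.shape), 0, None)

    stack = ImageStack({CFP: cfp, YFP: yfp, RED: red}, spec.voxel_size)
    truth = SyntheticTruth(
        spec=spec, seed=seed, objects=objects, plaques=list(spec.plaques),
        background_per_slice=b.tolist(), label_volume=truth_labels,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cohorts (object tables without rendering images)


@dataclass
class CohortSpec:
    """Mixture distribution of object ratios for one treatment group.

    ``components`` are (weight, mean, sd) triples over normal components.
    """

    name: str
    components: tuple = ((1.0, 0.67, 0.16),)
    n_mice: int = 8
    volumes_per_mouse: int = 10
    objects_per_volume: int = 120
    mouse_sd: float = 0.0   # between-mouse shift of the mixture means


COHORT_PRESETS = {
    "wt_like": CohortSpec("wt_like", components=((1.0, 0.67, 0.16),),
                          n_mice=11, volumes_per_mouse=9),
    "tg_like": CohortSpec("tg_like",
                          components=((0.95, 0.67, 0.16), (0.05, 1.2, 0.1)),
                          n_mice=7, volumes_per_mouse=10),
}


def mixture_exceedance(components, threshold: float) -> float:
    """Analytic P(R > threshold) of a normal mixture — closed-form oracle."""
    from scipy.stats import norm

    return float(sum(w * norm.sf(threshold, mu, sd) for w, mu, sd in components))


def generate_cohort(spec: CohortSpec | str, seed: int | None = None) -> pd.DataFrame:
    """Object-level ratio table (mouse -> volume -> object) for one group."""
    if isinstance(spec, str):
        spec = COHORT_PRESETS[spec]
    rng = np.random.default_rng(seed)
    weights = np.array([w for w, _, _ in spec.components], float)
    weights = weights / weights.sum()
    rows = []
    for mi in range(spec.n_mice):
        shift = rng.normal(0, spec.mouse_sd) if spec.mouse_sd > 0 else 0.0
        for vi in range(spec.volumes_per_mouse):
            n = spec.objects_per_volume
            comp = rng.choice(len(weights), size=n, p=weights)
            mus = np.array([spec.components[c][1] for c in comp]) + shift
            sds = np.array([spec.components[c][2] for c in comp])
            ratios = rng.normal(mus, sds)
            rows.append(pd.DataFrame({
                "mouse_id": f"{spec.name}_m{mi:02d}",
                "group": spec.name,
                "volume_id": f"{spec.name}_m{mi:02d}_v{vi:02d}",
                "object_id": np.arange(1, n + 1),
                "ratio": ratios,
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# time courses


def generate_timelapse(
    kind: str = "step",
    n_points: int = 60,
    dt_s: float = 10.0,
    baseline: float = 0.67,
    amplitude: float = 0.5,
    onset_index: int = 10,
    tau_s: float = 30.0,
    decay_rate_per_s: float = 0.002,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> RatioTrace:
    """Seeded synthetic treatment time courses.

    kind="step"  : depolarisation-like jump at onset with exponential
                   approach to baseline*(1+amplitude) (time constant tau_s);
    kind="rise"  : slow monotone rise to the same plateau (oligomer-like);
    kind="decay" : exponential decay exp(-k t) of a fluorescence signal
                   (membrane-potential / mPTP / caspase-style assays).
    """
    t = np.arange(n_points) * dt_s
    if kind == "step":
        v = np.full(n_points, baseline)
        after = t[onset_index:] - t[onset_index]
        v[onset_index:] = baseline * (1 + amplitude * (1 - np.exp(-after / max(tau_s, 1e-9))))
    elif kind == "rise":
        v = baseline * (1 + amplitude * (1 - np.exp(-t / (t[-1] / 3 + 1e-9))))
    elif kind == "decay":
        v = baseline * np.exp(-decay_rate_per_s * t)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        v = v * (1 + noise_cv * rng.standard_normal(n_points))
    return RatioTrace(t, v, baseline_index=0)


# ---------------------------------------------------------------------------
# longitudinal sessions


def generate_longitudinal(
    n_cells: int = 40,
    high_fraction: float = 0.15,
    disappearance_cut: float = 1.4,
    jitter_sd_um: float = 1.0,
    field_um: tuple[float, float, float] = (100.0, 127.0, 127.0),
    min_separation_um: float = 12.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired baseline/follow-up soma tables with rule-driven disappearance.

    Baseline ratios are a low component N(0.8, 0.15^2) truncated below
    ``disappearance_cut`` plus a ``high_fraction`` component N(1.6, 0.15^2)
    truncated above it; every cell above the cut disappears at follow-up
    (the deterministic rule), surviving cells reappear at a jittered
    centroid.  Returns (baseline, followup, truth).
    """
    rng = np.random.default_rng(seed)
    centers = []
    for _ in range(n_cells):
        for _ in range(5000):
            c = rng.uniform([5, 5, 5], np.array(field_um) - 5)
            if all(np.linalg.norm(c - c2) > min_separation_um for c2 in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError("field too dense for requested min_separation_um")
    centers = np.array(centers)

    # high/low ratio components always split at 1.4; the disappearance *rule*
    # is applied separately so a non-finite cut cleanly disables removals
    split = 1.4
    n_high = int(round(n_cells * high_fraction))
    ratios = np.empty(n_cells)
    ratios[:n_high] = _truncated_normal(rng, 1.6, 0.15, split + 1e-6, 2.6, n_high)
    ratios[n_high:] = _truncated_normal(rng, 0.8, 0.15, 0.62, split - 1e-6,
                                        n_cells - n_high)
    order = rng.permutation(n_cells)
    ratios = ratios[order]

    disappears = ratios > disappearance_cut
    base = pd.DataFrame({
        "object_id": np.arange(1, n_cells + 1),
        "centroid_z_um": centers[:, 0],
        "centroid_y_um": centers[:, 1],
        "centroid_x_um": centers[:, 2],
        "ratio": ratios,
    })
    surv = base[~disappears].reset_index(drop=True).copy()
    jitter = rng.normal(0, jitter_sd_um, (len(surv), 3))
    surv[["centroid_z_um", "centroid_y_um", "centroid_x_um"]] += jitter
    followup = pd.DataFrame({
        "object_id": np.arange(1, len(surv) + 1),
        "centroid_z_um": surv["centroid_z_um"].to_numpy(),
        "centroid_y_um": surv["centroid_y_um"].to_numpy(),
        "centroid_x_um": surv["centroid_x_um"].to_numpy(),
        "ratio": surv["ratio"].to_numpy(),
    })
    truth = pd.DataFrame({
        "baseline_object_id": base["object_id"],
        "disappeared": disappears,
        "followup_object_id": np.where(
            disappears, -1,
            np.cumsum(~disappears)  # follow-up ids are 1..n in baseline order
        ),
    })
    return base, followup, truth
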