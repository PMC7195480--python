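"""Hill-sigmoid calibration of a ratiometric Ca2+ indicator.

A FRET-based cameleon sensor reports free Ca2+ through its YFP/CFP emission
ratio R, which rises sigmoidally from ``r_min`` (Ca2+-free) to ``r_max``
(saturating Ca2+) with apparent dissociation constant ``kd_um`` and Hill
coefficient ``hill_n``:

    R(C) = r_min + (r_max - r_min) * C**n / (kd**n + C**n)

The inverse — the standard ratiometric conversion — recovers free Ca2+
from a measured ratio:

    [Ca2+] = kd * ((R - r_min) / (r_max - R)) ** (1 / n)

Concentrations are held in micromolar internally and reported in nanomolar,
matching the convention of in-vivo mitochondrial Ca2+ work where resting
levels sit in the hundreds of nM and overload in the low µM.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CalibrationCurve",
    "TitrationTable",
    "CalibrationError",
    "DEFAULT_CURVE",
    "TITRATION_CONCS_UM",
    "fit_calibration",
    "ratio_to_concentration",
    "concentration_to_ratio",
]

UM_TO_NM = 1000.0

#: Free-Ca2+ concentrations (µM) of the 13-point in-situ titration design.
TITRATION_CONCS_UM = (
    0.0, 0.2, 0.575, 1.0, 2.0, 5.7, 10.0, 20.0, 53.0, 100.0, 200.0, 500.0, 1000.0
)


class CalibrationError(ValueError):
    """Raised for degenerate titration data or a failed sigmoid fit."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted sensor constants: ratio bounds, apparent Kd (µM), Hill n."""

    r_min: float
    r_max: float
    kd_um: float
    hill_n: float
    fit: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise CalibrationError(
                f"require 0 < r_min < r_max, got r_min={self.r_min}, r_max={self.r_max}"
            )
        if self.kd_um <= 0 or self.hill_n <= 0:
            raise CalibrationError(
                f"require kd_um > 0 and hill_n > 0, got kd_um={self.kd_um}, hill_n={self.hill_n}"
            )

    # -- conversions -------------------------------------------------------

    def ratio_to_concentration(self, ratio):
        """Free Ca2+ (nM) for ratio(s) R via kd*((R-r_min)/(r_max-R))**(1/n).

        Ratios at or outside (r_min, r_max) — possible under noise — map to
        NaN rather than 0/inf so that out-of-range measurements are counted,
        not fabricated.  R == r_min maps to exactly 0 nM.
        """
        r = np.asarray(ratio, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            bracket = (r - self.r_min) / (self.r_max - r)
            conc_um = self.kd_um * np.power(bracket, 1.0 / self.hill_n)
        conc_um = np.where(np.isclose(r, self.r_min), 0.0, conc_um)
        out_of_range = (r < self.r_min) | (r >= self.r_max)
        conc_nm = np.where(out_of_range, np.nan, conc_um * UM_TO_NM)
        if np.isscalar(ratio) or np.ndim(ratio) == 0:
            return float(conc_nm)
        return conc_nm

    def concentration_to_ratio(self, conc_nm):
        """Exact algebraic inverse: ratio for free Ca2+ given in nM."""
        c = np.asarray(conc_nm, dtype=float)
        if np.any(c < 0):
            raise CalibrationError("concentration must be non-negative")
        c_um = c / UM_TO_NM
        cn = np.power(c_um, self.hill_n)
        ratio = self.r_min + (self.r_max - self.r_min) * cn / (self.kd_um ** self.hill_n + cn)
        if np.isscalar(conc_nm) or np.ndim(conc_nm) == 0:
            return float(ratio)
        return ratio

    # -- (de)serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationCurve":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(d["r_min"], d["r_max"], d["kd_um"], d["hill_n"], d.get("fit", {}))


#: In-situ calibration constants of the mitochondria-targeted YC3.6 sensor.
DEFAULT_CURVE = CalibrationCurve(r_min=0.606, r_max=2.6921, kd_um=4.21, hill_n=1.57)


@dataclass
class TitrationTable:
    """Titration of measured ratio against known free Ca2+ (µM)."""

    free_ca_um: np.ndarray
    ratio: np.ndarray
    n_cells: np.ndarray | None = None
    ratio_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.free_ca_um = np.asarray(self.free_ca_um, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.free_ca_um.shape != self.ratio.shape:
            raise CalibrationError("free_ca_um and ratio must have equal length")
        if np.any(self.free_ca_um < 0):
            raise CalibrationError("free Ca2+ concentrations must be non-negative")
        if np.any(np.diff(self.free_ca_um) <= 0):
            raise CalibrationError("free Ca2+ concentrations must be strictly increasing")

    def __len__(self) -> int:
        return self.free_ca_um.size

    @classmethod
    def from_csv(cls, path: str | Path) -> "TitrationTable":
        df = pd.read_csv(path)
        return cls(
            df["free_ca_um"].to_numpy(),
            df["ratio"].to_numpy(),
            df["n_cells"].to_numpy() if "n_cells" in df else None,
            df["ratio_sd"].to_numpy() if "ratio_sd" in df else None,
        )

    def to_csv(self, path: str | Path) -> None:
        d = {"free_ca_um": self.free_ca_um, "ratio": self.ratio}
        if self.n_cells is not None:
            d["n_cells"] = self.n_cells
        if self.ratio_sd is not None:
            d["ratio_sd"] = self.ratio_sd
        pd.DataFrame(d).to_csv(path, index=False)


def _hill(conc_um, r_min, r_max, kd_um, n):
    cn = np.power(conc_um, n, where=conc_um > 0, out=np.zeros_like(conc_um))
    return r_min + (r_max - r_min) * cn / (kd_um ** n + cn)


def fit_calibration(
    titration: TitrationTable,
    weights: Sequence[float] | None = None,
) -> CalibrationCurve:
    """Least-squares Hill fit of a titration table.

    kd and n are fitted on log scale to enforce positivity; r_min / r_max are
    initialised from the observed ratio extremes, kd from the concentration
    whose ratio is nearest the ratio midpoint, and n from 1.  Diagnostics
    (RMS residual, per-parameter standard errors from the Jacobian, residuals)
    travel on the returned curve's ``fit`` attribute.
    """
    if len(titration) < 5:
        raise CalibrationError("at least 5 titration rows are required for fitting")
    conc = titration.free_ca_um
    ratio = titration.ratio
    if np.any(ratio <= 0):
        raise CalibrationError("ratios must be positive")
    if np.allclose(ratio, ratio[0]):
        raise CalibrationError("degenerate titration: all ratios equal")
    w = np.ones_like(ratio) if weights is None else np.sqrt(np.asarray(weights, float))

    r_lo, r_hi = float(ratio.min()), float(ratio.max())
    mid = 0.5 * (r_lo + r_hi)
    kd0 = float(conc[np.argmin(np.abs(ratio - mid))])
    kd0 = max(kd0, np.min(conc[conc > 0], initial=1.0))
    x0 = np.array([r_lo, r_hi, np.log(kd0), 0.0])

    def resid(x):
        r_min, r_max, log_kd, log_n = x
        return w * (_hill(conc, r_min, r_max, np.exp(log_kd), np.exp(log_n)) - ratio)

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=20000)
    if not sol.success:
        raise CalibrationError(f"sigmoid fit did not converge (last iterate: {sol.x})")
    r_min, r_max, kd_um, hill_n = sol.x[0], sol.x[1], float(np.exp(sol.x[2])), float(np.exp(sol.x[3]))
    if not (0 < r_min < r_max):
        raise CalibrationError(f"fit produced invalid ratio bounds ({r_min}, {r_max})")

    res = sol.fun
    dof = max(len(res) - 4, 1)
    rms = float(np.sqrt(np.mean(res**2)))
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * np.sum(res**2) / dof
        se = np.sqrt(np.diag(cov)).tolist()
    except np.linalg.LinAlgError:  # pragma: no cover - singular Jacobian
        cov, se = None, None
    diag = {
        "rms_residual": rms,
        "residuals": res.tolist(),
        "param_se": se,
        "n_points": int(len(res)),
    }
    return CalibrationCurve(float(r_min), float(r_max), kd_um, hill_n, fit=diag)


def ratio_to_concentration(ratio, curve: CalibrationCurve = DEFAULT_CURVE):
    """Module-level convenience wrapper; see CalibrationCurve.ratio_to_concentration."""
    return curve.ratio_to_concentration(ratio)


def concentration_to_ratio(conc_nm, curve: CalibrationCurve = DEFAULT_CURVE):
    """Module-level convenience wrapper; see CalibrationCurve.concentration_to_ratio."""
    return curve.concentration_to_ratio(conc_nm)


def conversion_qc(ratios, curve: CalibrationCurve = DEFAULT_CURVE) -> dict:
    """Count in-range vs out-of-range ratios for a QC report."""
    r = np.asarray(ratios, dtype=float)
    below = int(np.sum(r < curve.r_min))
    above = int(np.sum(r >= curve.r_max))
    return {
        "n_total": int(r.size),
        "n_below_r_min": below,
        "n_at_or_above_r_max": above,
        "n_convertible": int(r.size - below - above),
    }
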