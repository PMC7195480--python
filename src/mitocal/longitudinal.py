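"""Cross-session object matching and survival vs. baseline Ca2+.

Repeated imaging of the same cortical field lets the same somata be
followed over days.  Records are matched between a baseline and a
follow-up session by centroid proximity; baseline objects with no
follow-up partner within the matching radius are scored DISAPPEARED.
Survival is then related to baseline YFP/CFP ratio: the study design
revolves around the observation that somata above ratio ~1.4 at baseline
vanish within 24 h.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

__all__ = ["match_sessions", "survival_by_baseline_ratio", "DISAPPEARED"]

DISAPPEARED = -1

_CENT = ["centroid_z_um", "centroid_y_um", "centroid_x_um"]


def match_sessions(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    radius_um: float = 10.0,
    method: str = "greedy",
    registration_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> pd.DataFrame:
    """Match baseline to follow-up records by nearest centroid within radius.

    ``method="greedy"`` pairs candidates in ascending distance order with
    deterministic index tie-breaking; ``method="optimal"`` solves the
    assignment problem (minimum total distance).  Each follow-up object is
    used at most once.  Returns one row per baseline object with the matched
    follow-up id (or DISAPPEARED), displacement, and baseline ratio.
    """
    if radius_um < 0:
        raise ValueError("radius must be non-negative")
    b = baseline[_CENT].to_numpy(float) + np.asarray(registration_offset_um, float)
    f = followup[_CENT].to_numpy(float)
    nb, nf = len(b), len(f)
    match = np.full(nb, -1)
    disp = np.full(nb, np.nan)
    if nb and nf:
        d = np.linalg.norm(b[:, None, :] - f[None, :, :], axis=2)
        if method == "greedy":
            order = np.argsort(d, axis=None, kind="stable")
            used_b, used_f = np.zeros(nb, bool), np.zeros(nf, bool)
            for flat in order:
                i, j = divmod(flat, nf)
                if d[i, j] > radius_um:
                    break
                if used_b[i] or used_f[j]:
                    continue
                match[i], disp[i] = j, d[i, j]
                used_b[i], used_f[j] = True, True
        elif method == "optimal":
            big = radius_um * 1e6 + 1.0
            cost = np.where(d <= radius_um, d, big)
            ri, cj = linear_sum_assignment(cost)
            for i, j in zip(ri, cj):
                if d[i, j] <= radius_um:
                    match[i], disp[i] = j, d[i, j]
        else:
            raise ValueError(f"unknown method {method!r}")

    fu_ids = followup["object_id"].to_numpy()
    return pd.DataFrame({
        "baseline_object_id": baseline["object_id"].to_numpy(),
        "followup_object_id": [int(fu_ids[j]) if j >= 0 else DISAPPEARED for j in match],
        "displacement_um": disp,
        "baseline_ratio": baseline["ratio"].to_numpy(float),
        "disappeared": match < 0,
    })


def survival_by_baseline_ratio(matches: pd.DataFrame, cut: float = 1.4) -> dict:
    """2x2 table of (baseline ratio above/below cut) x (remained/disappeared).

    Also compares baseline ratios between remained and disappeared groups
    with a two-sample Student t-test (equal variances), the test used for
    this comparison in longitudinal in-vivo work; degenerate one-group data
    yields NaN statistics.
    """
    if matches.empty:
        raise ValueError("no match records")
    above = matches["baseline_ratio"] > cut
    gone = matches["disappeared"]
    table = pd.DataFrame(
        {
            "remained": [int((~gone & above).sum()), int((~gone & ~above).sum())],
            "disappeared": [int((gone & above).sum()), int((gone & ~above).sum())],
        },
        index=[f"ratio>{cut}", f"ratio<={cut}"],
    )
    r_rem = matches.loc[~gone, "baseline_ratio"].to_numpy(float)
    r_gone = matches.loc[gone, "baseline_ratio"].to_numpy(float)
    if len(r_rem) >= 2 and len(r_gone) >= 2:
        t, p = stats.ttest_ind(r_gone, r_rem, equal_var=True)
        t, p = float(t), float(p)
    else:
        t, p = np.nan, np.nan
    return {
        "table": table,
        "cut": cut,
        "mean_ratio_remained": float(r_rem.mean()) if len(r_rem) else np.nan,
        "mean_ratio_disappeared": float(r_gone.mean()) if len(r_gone) else np.nan,
        "t_statistic": t,
        "p_value": p,
    }
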