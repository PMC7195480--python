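"""Hierarchy-aware group comparisons for imaging cohorts.

Volumes (z-stacks) are nested in mice, and mice in treatment groups, so
volume-level responses (mean ratio, overload %, ΔR/R0) are correlated
within a mouse.  Group effects are therefore estimated with a linear
mixed-effects model — treatment group as fixed effect, a random intercept
per mouse — fitted by REML, and cross-checked with a nonparametric
mouse-level (cluster) bootstrap.

The fixed-effect test uses a t reference distribution with
``n_mice - n_groups`` degrees of freedom: for a balanced design this is
the exact between-cluster df, and in general it is a conservative
Satterthwaite-style small-sample correction for the handful-of-animals
regime these cohorts live in.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["fit_lmm", "cluster_bootstrap", "validate_cohort_table"]


def validate_cohort_table(table: pd.DataFrame, response: str) -> None:
    for col in ("mouse_id", "group", response):
        if col not in table.columns:
            raise ValueError(f"cohort table is missing column {col!r}")
    per_mouse_groups = table.groupby("mouse_id")["group"].nunique()
    if (per_mouse_groups > 1).any():
        raise ValueError("each mouse must belong to exactly one group")


def fit_lmm(table: pd.DataFrame, response: str = "response") -> dict:
    """Random-intercept-per-mouse comparison of group means.

    Returns least-squares means ± SE per group, the fitted variance
    components, and for two groups the difference with its t-based p-value
    (df = n_mice - n_groups).  Any group represented by a single mouse is an
    error: between-mouse variance is then inestimable and a paired or naive
    analysis should be used instead.
    """
    validate_cohort_table(table, response)
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    mice_per_group = table.groupby("group")["mouse_id"].nunique()
    if (mice_per_group < 2).any():
        bad = mice_per_group[mice_per_group < 2].index.tolist()
        raise ValueError(
            f"groups {bad} have a single mouse; use a paired or naive analysis"
        )

    df = table.rename(columns={response: "_y"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm("_y ~ C(group)", df, groups=df["mouse_id"])
        try:
            fit = model.fit(reml=True)
            var_mouse = float(fit.cov_re.iloc[0, 0])
            var_resid = float(fit.scale)
        except (np.linalg.LinAlgError, ValueError):
            # REML can fail at the var_mouse = 0 boundary (singular random-
            # effects covariance); there the mixed model reduces to OLS
            fit = smf.ols("_y ~ C(group)", df).fit()
            var_mouse = 0.0
            var_resid = float(fit.scale)

    # LS means: intercept is the first (alphabetical) group's mean
    fe = fit.fe_params if hasattr(fit, "fe_params") else fit.params
    cov = fit.cov_params().iloc[: len(fe), : len(fe)]
    names = list(fe.index)
    ls_means = {}
    for g in groups:
        vec = np.zeros(len(fe))
        vec[names.index("Intercept")] = 1.0
        term = f"C(group)[T.{g}]"
        if term in names:
            vec[names.index(term)] = 1.0
        ls_means[g] = {
            "mean": float(vec @ fe.to_numpy()),
            "se": float(np.sqrt(vec @ cov.to_numpy() @ vec)),
        }

    n_mice = table["mouse_id"].nunique()
    ddf = n_mice - len(groups)
    out = {
        "groups": groups,
        "ls_means": ls_means,
        "var_mouse": var_mouse,
        "var_residual": var_resid,
        "n_mice": int(n_mice),
        "ddf": int(ddf),
    }
    if len(groups) == 2:
        term = f"C(group)[T.{groups[1]}]"
        est = float(fe[term])
        se = float(np.sqrt(cov.loc[term, term]))
        tval = est / se if se > 0 else np.nan
        pval = 2 * stats.t.sf(abs(tval), ddf) if np.isfinite(tval) else np.nan
        out.update({
            "difference": est,
            "difference_se": se,
            "t": float(tval),
            "p_value": float(pval),
        })
    return out


def cluster_bootstrap(
    table: pd.DataFrame,
    response: str = "response",
    n_boot: int = 2000,
    seed: int | None = None,
    ci: float = 0.95,
) -> dict:
    """Mouse-level bootstrap CI for the two-group difference.

    Mice are resampled with replacement within each group; the statistic is
    the difference of group means of per-mouse means (the balanced-design
    LMM estimand).  Percentile interval at level ``ci``.
    """
    validate_cohort_table(table, response)
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable intervals")
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError("cluster_bootstrap compares exactly 2 groups")
    rng = np.random.default_rng(seed)
    mouse_means = (
        table.groupby(["group", "mouse_id"])[response].mean().reset_index()
    )
    per_group = {
        g: mouse_means.loc[mouse_means["group"] == g, response].to_numpy(float)
        for g in groups
    }
    point = per_group[groups[1]].mean() - per_group[groups[0]].mean()
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        m0 = rng.choice(per_group[groups[0]], size=len(per_group[groups[0]]))
        m1 = rng.choice(per_group[groups[1]], size=len(per_group[groups[1]]))
        diffs[b] = m1.mean() - m0.mean()
    alpha = (1.0 - ci) / 2
    lo, hi = np.quantile(diffs, [alpha, 1 - alpha])
    return {
        "groups": groups,
        "difference": float(point),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "ci_level": ci,
        "n_boot": int(n_boot),
    }
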