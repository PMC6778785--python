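"""Manual starvation-assay analysis: logistic survival fits and comparisons.

The manual assay plates a sample of starving L1 larvae every other day and
scores the fraction that resume development on food: percent survival on
day *d* is ``alive / plated`` (T_a / T_p).  A three-parameter logistic

    S(d) = U / (1 + exp(k * (d - t50)))

is fitted to each strain x biological replicate by least squares weighted
by the number plated.  *Median survival time* here means the fitted ``t50``
— the day the curve reaches half its upper asymptote ``U``, which differs
from an absolute-50% crossing whenever ``U < 1``.

Replicate medians feed Bartlett's variance-homogeneity test across strains;
when variances are homogeneous, pairwise comparisons use t statistics with
the variance pooled across *all* strains (not just the pair), with the
corresponding degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SurvivalFit",
    "fit_logistic_survival",
    "fit_all_replicates",
    "compare_median_survival",
    "normalize_recovery",
    "correlate_trait_with_survival",
]


def logistic_survival(day, upper, steepness, t50):
    return upper / (1.0 + np.exp(steepness * (np.asarray(day, dtype=float) - t50)))


@dataclass
class SurvivalFit:
    strain: str
    replicate: str
    t50: float
    steepness: float
    upper: float
    rss: float
    converged: bool
    message: str = ""


def fit_logistic_survival(
    obs: pd.DataFrame, upper: str | float = "fit"
) -> SurvivalFit:
    """Fit the logistic survival curve to one strain/replicate.

    ``obs`` needs columns ``strain, replicate, day, plated, alive`` for a
    single strain and replicate.  Observations are weighted by the number
    plated.  ``upper`` selects the asymptote handling: ``"fit"`` (default)
    estimates ``U`` in (0, 1]; ``"fixed"`` pins it to the day-1 (earliest
    observed day) survival proportion; a float pins it to that value.

    Non-convergence or a non-identifiable midpoint (e.g. survival never
    falls near half the asymptote within the observed days) yields a
    flagged fit (``converged=False``) rather than an exception.
    """
    if obs["strain"].nunique() > 1 or obs["replicate"].nunique() > 1:
        raise ValueError("fit_logistic_survival expects a single strain/replicate")
    strain = str(obs["strain"].iloc[0])
    replicate = str(obs["replicate"].iloc[0])
    day = obs["day"].to_numpy(dtype=float)
    plated = obs["plated"].to_numpy(dtype=float)
    alive = obs["alive"].to_numpy(dtype=float)
    if np.any(alive > plated) or np.any(alive < 0):
        raise ValueError("need 0 <= alive <= plated")
    if np.any(day < 0):
        raise ValueError("days must be non-negative")
    if len(np.unique(day)) < 3:
        raise ValueError(f"{strain}/{replicate}: need >= 3 distinct days")

    p = alive / plated
    sigma = 1.0 / np.sqrt(plated)  # weight ~ number plated
    dmax = float(day.max())

    if upper == "fit":
        fixed_upper = None
    elif upper == "fixed":
        fixed_upper = float(p[np.argmin(day)])
    else:
        fixed_upper = float(upper)
    if fixed_upper is not None and not 0 < fixed_upper <= 1:
        raise ValueError("fixed upper asymptote must be in (0, 1]")

    u0 = fixed_upper if fixed_upper is not None else min(max(float(p.max()), 0.05), 1.0)
    below = day[p <= u0 / 2]
    t0 = float(below.min()) if below.size else dmax
    k0 = 0.5

    identifiable = bool((p <= 0.75 * u0).any())
    if not identifiable:
        warnings.warn(
            f"{strain}/{replicate}: survival never drops near half its asymptote; "
            "t50 is poorly identified",
            stacklevel=2,
        )

    def model_full(d, u, k, t):
        return logistic_survival(d, u, k, t)

    def model_fixed(d, k, t):
        return logistic_survival(d, fixed_upper, k, t)

    try:
        if fixed_upper is None:
            popt, _ = optimize.curve_fit(
                model_full,
                day,
                p,
                p0=[u0, k0, t0],
                sigma=sigma,
                bounds=([1e-6, 1e-6, 1e-6], [1.0, 50.0, 10.0 * dmax]),
                maxfev=20000,
            )
            u_hat, k_hat, t_hat = (float(x) for x in popt)
        else:
            popt, _ = optimize.curve_fit(
                model_fixed,
                day,
                p,
                p0=[k0, t0],
                sigma=sigma,
                bounds=([1e-6, 1e-6], [50.0, 10.0 * dmax]),
                maxfev=20000,
            )
            u_hat = fixed_upper
            k_hat, t_hat = (float(x) for x in popt)
        resid = (p - logistic_survival(day, u_hat, k_hat, t_hat)) / sigma
        rss = float(resid @ resid)
        converged = identifiable and t_hat <= 2.0 * dmax
        msg = "" if converged else "t50 outside well-supported range"
    except RuntimeError as exc:  # curve_fit non-convergence
        u_hat = u_hat if fixed_upper is not None else np.nan
        k_hat = t_hat = rss = np.nan
        converged = False
        msg = f"fit failed: {exc}"
    return SurvivalFit(
        strain=strain,
        replicate=replicate,
        t50=t_hat,
        steepness=k_hat,
        upper=u_hat,
        rss=rss,
        converged=converged,
        message=msg,
    )


def fit_all_replicates(obs: pd.DataFrame, upper: str | float = "fit") -> pd.DataFrame:
    """Fit every strain x replicate group; returns one row per fit."""
    fits = [
        fit_logistic_survival(grp, upper=upper)
        for _, grp in obs.groupby(["strain", "replicate"], sort=True)
    ]
    return pd.DataFrame([f.__dict__ for f in fits])


@dataclass
class MedianSurvivalComparison:
    bartlett_statistic: float
    bartlett_pvalue: float
    pooled_variance: float
    pooled_df: int
    pairwise: pd.DataFrame  # strain_a, strain_b, mean_a, mean_b, t, pvalue
    excluded: list


def compare_median_survival(
    fits: pd.DataFrame, pairs=None, alpha: float = 0.05
) -> MedianSurvivalComparison:
    """Bartlett's test plus pooled-variance pairwise t-tests on t50s.

    ``fits`` is the frame from :func:`fit_all_replicates`; only converged
    fits enter.  Strains with a single replicate are excluded (with a
    warning) from Bartlett's test and the pooled variance.  The pooled
    variance is ``sum (n_i - 1) s_i^2 / sum (n_i - 1)`` over all retained
    strains, and every pairwise t-test uses it with ``sum (n_i - 1)``
    degrees of freedom.  If Bartlett rejects at ``alpha``, pairwise tests
    are still reported but a warning notes the variance heterogeneity.
    """
    usable = fits[fits["converged"]] if "converged" in fits else fits
    groups = {s: g["t50"].to_numpy(dtype=float) for s, g in usable.groupby("strain")}
    excluded = [s for s, v in groups.items() if v.size < 2]
    if excluded:
        warnings.warn(
            f"strain(s) with < 2 replicates excluded from variance pooling: "
            f"{', '.join(map(str, excluded))}",
            stacklevel=2,
        )
    groups = {s: v for s, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 strains with >= 2 replicates")

    bart_stat, bart_p = stats.bartlett(*groups.values())
    if bart_p < alpha:
        warnings.warn(
            "Bartlett's test rejects homogeneous variances; "
            "pooled-variance t-tests may be inappropriate",
            stacklevel=2,
        )

    dfs = np.array([v.size - 1 for v in groups.values()])
    variances = np.array([v.var(ddof=1) for v in groups.values()])
    pooled_df = int(dfs.sum())
    pooled_var = float((dfs * variances).sum() / pooled_df)

    if pairs is None:
        pairs = list(combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        xa, xb = groups[a], groups[b]
        diff = float(xa.mean() - xb.mean())
        se = np.sqrt(pooled_var * (1.0 / xa.size + 1.0 / xb.size))
        if diff == 0.0:
            t, pval = 0.0, 1.0
        elif se == 0.0:
            t, pval = np.inf * np.sign(diff), 0.0
        else:
            t = diff / se
            pval = float(2.0 * stats.t.sf(abs(t), pooled_df))
        rows.append((a, b, float(xa.mean()), float(xb.mean()), float(t), pval))
    pairwise = pd.DataFrame(
        rows, columns=["strain_a", "strain_b", "mean_a", "mean_b", "t", "pvalue"]
    )
    return MedianSurvivalComparison(
        bartlett_statistic=float(bart_stat),
        bartlett_pvalue=float(bart_p),
        pooled_variance=pooled_var,
        pooled_df=pooled_df,
        pairwise=pairwise,
        excluded=excluded,
    )


def normalize_recovery(measurements: pd.DataFrame) -> pd.DataFrame:
    """Normalize 8-day starvation-recovery measurements by the 1-day mean.

    ``measurements`` has columns ``strain, replicate, days_starved, assay,
    value``.  For each (strain, assay), every value is divided by the mean
    of that strain's 1-day values for the same assay, so normalized 1-day
    values average exactly 1 and 8-day values express the proportional cost
    of extended starvation.  A strain/assay with no 1-day rows, or a 1-day
    mean of zero, is an error.
    """
    out = measurements.copy()
    out["normalized_value"] = np.nan
    for (strain, assay), grp in out.groupby(["strain", "assay"]):
        base = grp.loc[grp["days_starved"] == 1, "value"]
        if base.empty:
            raise ValueError(f"{strain}/{assay}: no 1-day baseline measurements")
        mean1 = float(base.mean())
        if mean1 == 0.0:
            raise ValueError(f"{strain}/{assay}: 1-day baseline mean is zero")
        out.loc[grp.index, "normalized_value"] = grp["value"] / mean1
    return out


@dataclass
class TraitSurvivalCorrelation:
    slope: float
    intercept: float
    r_squared: float
    n_strains: int
    per_strain: pd.DataFrame  # strain, trait_value, mean_t50


def correlate_trait_with_survival(
    traits: pd.DataFrame, fits: pd.DataFrame
) -> TraitSurvivalCorrelation:
    """Regress per-strain mean median survival on the selection trait value.

    ``traits`` needs columns ``strain, trait_value``; ``fits`` is the
    per-replicate fit frame.  Returns the simple-regression line and R^2
    over strains present in both inputs (>= 3 required).
    """
    usable = fits[fits["converged"]] if "converged" in fits else fits
    mean_t50 = usable.groupby("strain")["t50"].mean().rename("mean_t50")
    merged = (
        traits.set_index("strain")[["trait_value"]].join(mean_t50, how="inner").dropna()
    )
    if len(merged) < 3:
        raise ValueError("need >= 3 strains common to trait table and survival fits")
    res = stats.linregress(merged["trait_value"], merged["mean_t50"])
    return TraitSurvivalCorrelation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_strains=len(merged),
        per_strain=merged.reset_index(),
    )
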