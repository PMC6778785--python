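"""Selection-slope trait values from strain-frequency time courses.

The trait value of a strain is the per-replicate ordinary-least-squares
slope of its pooled frequency regressed on day of starvation, averaged
across replicates.  A positive value means the strain gained representation
among survivors over the starvation time course (relatively starvation
resistant); a negative value means it lost representation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["regression_slope", "compute_trait_values", "export_gwas_traits"]


def regression_slope(days, frequencies) -> float:
    """OLS slope (with intercept) of frequency against day.

    ``slope = sum((d - dbar) * (f - fbar)) / sum((d - dbar)^2)``; missing
    frequencies are dropped first.  Raises ``ValueError`` on fewer than two
    points or zero day-variance.
    """
    d = np.asarray(days, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    if d.shape != f.shape:
        raise ValueError("days and frequencies must have equal length")
    ok = ~np.isnan(f) & ~np.isnan(d)
    d, f = d[ok], f[ok]
    if d.size < 2:
        raise ValueError("need at least 2 non-missing points for a slope")
    dc = d - d.mean()
    ss = float(dc @ dc)
    if ss == 0.0:
        raise ValueError("zero variance in days; slope undefined")
    return float(dc @ (f - f.mean()) / ss)


def compute_trait_values(
    freqs: pd.DataFrame, replicate_day_map: dict | None = None
) -> pd.DataFrame:
    """Per-strain trait values from a long frequency table.

    For each strain and replicate, the slope of frequency on day is computed
    over that replicate's sampled days (optionally restricted by
    ``replicate_day_map``: replicate -> allowed days).  The trait value is
    the unweighted mean of the replicate slopes, regardless of how many
    timepoints each replicate has.  Libraries where the strain has a missing
    frequency are dropped from that regression, not imputed.  Strains with
    no computable slope in any replicate are omitted with a warning.

    Returns a frame with columns ``strain``, one ``slope_rep_<r>`` per
    replicate, ``trait_value`` and ``n_replicates_used``.
    """
    replicates = sorted(freqs["replicate"].astype(str).unique())
    rows = []
    dropped = []
    for strain, grp in freqs.groupby("strain", sort=True):
        slopes: dict[str, float] = {}
        for rep in replicates:
            sub = grp[grp["replicate"].astype(str) == rep]
            if replicate_day_map is not None and rep in {str(k) for k in replicate_day_map}:
                allowed = {
                    d
                    for k, v in replicate_day_map.items()
                    if str(k) == rep
                    for d in v
                }
                sub = sub[sub["day"].isin(allowed)]
            try:
                slopes[rep] = regression_slope(sub["day"], sub["frequency"])
            except ValueError:
                slopes[rep] = np.nan
        used = [s for s in slopes.values() if not np.isnan(s)]
        if not used:
            dropped.append(strain)
            continue
        row = {"strain": strain}
        row.update({f"slope_rep_{rep}": slopes[rep] for rep in replicates})
        row["trait_value"] = float(np.mean(used))
        row["n_replicates_used"] = len(used)
        rows.append(row)
    if dropped:
        warnings.warn(
            f"no computable frequency slope for strain(s) {', '.join(map(str, dropped))};"
            " omitted from trait table",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def export_gwas_traits(
    traits: pd.DataFrame, exclusions: tuple | list = ()
) -> pd.DataFrame:
    """Two-column (strain, trait_value) mapping for association tools.

    ``exclusions`` lists strains to drop, e.g. redundant isotype
    representatives; names not present in the table only trigger a warning.
    """
    present = set(traits["strain"])
    absent = [s for s in exclusions if s not in present]
    if absent:
        warnings.warn(
            f"exclusion strain(s) not in trait table: {', '.join(map(str, absent))}",
            stacklevel=2,
        )
    keep = ~traits["strain"].isin(set(exclusions))
    return traits.loc[keep, ["strain", "trait_value"]].reset_index(drop=True)
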