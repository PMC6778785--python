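"""Strain-frequency inference from unique-SNV read counts.

Each unique SNV of a strain provides an independent estimate of that
strain's frequency in the pooled library: the alternative-allele read
fraction ``alt / (ref + alt)``.  The strain's frequency in a library is the
unweighted mean of these per-SNV fractions across its usable unique SNVs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .variants import PooledCountTable, UniqueSNVMap

#: strains with fewer usable markers than this are flagged low-confidence;
#: at ~1,700x per-SNV coverage and 1% frequency, 16 markers keep the mean
#: proportional estimation error under 5% (see poolselect.errors).
LOW_CONFIDENCE_SNVS = 16


def infer_frequencies(
    snv_map: UniqueSNVMap,
    counts: PooledCountTable,
    min_total_reads: int = 1,
    weighted: bool = False,
) -> pd.DataFrame:
    """Estimate every strain's frequency in every pooled library.

    Parameters
    ----------
    snv_map
        Unique-SNV ownership from :func:`poolselect.variants.identify_unique_snvs`.
    counts
        Count table already filtered to unique SNVs.
    min_total_reads
        A SNV contributes to a library's estimate only if ``ref + alt``
        reaches this many reads there (default 1: zero-coverage SNVs are
        excluded rather than counted as frequency 0).
    weighted
        If True, weight SNVs by their coverage (pooled ``sum(alt)/sum(total)``)
        instead of the default unweighted mean of per-SNV fractions.

    Returns
    -------
    Long-format frame with columns ``strain, replicate, day, frequency,
    n_snvs, low_confidence``.  A strain with no usable SNV in a library
    gets ``frequency = NaN`` (missing, not zero) and ``n_snvs = 0``.
    Frequencies are raw per-strain means and are deliberately not
    renormalized to sum to 1 across strains.
    """
    if min_total_reads < 1:
        raise ValueError("min_total_reads must be >= 1")
    ids = counts.variant_ids
    owners = snv_map.strains_of(ids)
    if owners.isna().any():
        raise ValueError("count table contains variants not in the unique-SNV map")
    owner_arr = owners.to_numpy()
    strains = snv_map.per_strain_count.index

    records = []
    for rep, day in counts.libraries:
        ref, alt = counts.ref_alt(rep, day)
        total = ref + alt
        usable = total >= min_total_reads
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(usable, alt / total, np.nan)
        for strain in strains:
            mask = (owner_arr == strain) & usable
            n_used = int(mask.sum())
            if n_used == 0:
                freq = np.nan
            elif weighted:
                freq = float(alt[mask].sum() / total[mask].sum())
            else:
                freq = float(frac[mask].mean())
            records.append(
                (strain, rep, day, freq, n_used, n_used < LOW_CONFIDENCE_SNVS)
            )
    out = pd.DataFrame(
        records,
        columns=["strain", "replicate", "day", "frequency", "n_snvs", "low_confidence"],
    )
    bad = out["frequency"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise AssertionError("inferred frequency outside [0, 1]")
    return out


def frequency_distribution_summary(
    freqs: pd.DataFrame, replicate: str, day: int
) -> dict:
    """Distributional summary of strain frequencies in one library.

    Returns median and variance of the frequencies, plus the natural-log
    frequency per strain (a Series; zero and missing entries are excluded
    from the log table and counted in ``n_excluded``).
    """
    lib = freqs[(freqs["replicate"].astype(str) == str(replicate)) & (freqs["day"] == day)]
    if lib.empty:
        raise KeyError(f"no library (replicate={replicate!r}, day={day})")
    f = lib.set_index("strain")["frequency"]
    valid = f.dropna()
    positive = valid[valid > 0]
    return {
        "median": float(valid.median()),
        "variance": float(valid.var(ddof=1)),
        "log_frequencies": np.log(positive),
        "n_excluded": int(len(f) - len(positive)),
    }


def to_wide(freqs: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long frequency table to strain x (replicate, day)."""
    wide = freqs.pivot_table(
        index="strain", columns=["replicate", "day"], values="frequency", dropna=False
    )
    # pivot_table builds the full replicate x day cross product; drop
    # combinations that are not actual libraries
    observed = set(map(tuple, freqs[["replicate", "day"]].drop_duplicates().to_numpy()))
    return wide[[c for c in wide.columns if c in observed]]
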