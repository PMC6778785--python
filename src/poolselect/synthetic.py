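"""Synthetic pooled-selection experiments with known ground truth.

The generator emulates the structure of a pooled starvation-selection
experiment on ~96 homozygous strains: every strain owns a set of private
marker SNVs (counts spanning roughly 1 to a few thousand, median ~33), the
pool is starved and sampled on fixed days in two replicates (days {16, 21}
and {1, 7, 14, 21, 24}), and each unique SNV receives ~1,691 reads per
library on average.

Frequency dynamics are deterministic (infinite-population): with per-strain
per-day mortality rate ``m_s`` and a single multiplicative recovery weight
``w_s`` (collapsing post-starvation growth and fecundity into one fitness
term),

    f_s(d) = w_s * f_s(0) * exp(-m_s * d) / sum_k w_k * f_k(0) * exp(-m_k * d).

Demographic noise is omitted because the emulated cultures hold millions of
larvae; a finite-population multinomial option is available.  Read sampling
is stochastic: independent Poisson alternative/reference counts per SNV
(``poisson_split``, the default), or binomial alternative counts given a
Poisson total (``binomial_given_total``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .traits import regression_slope
from .variants import PooledCountTable, StrainPanel

DEFAULT_SAMPLE_DAYS: tuple[tuple[int, ...], ...] = ((16, 21), (1, 7, 14, 21, 24))

# log-normal marker-count law matched to the observed per-strain spread
# (median 33, quartiles 22/67 -> sigma = (ln 67 - ln 22) / (2 * 0.6745))
_SNV_LOG_MEDIAN = float(np.log(33.0))
_SNV_LOG_SD = float((np.log(67.0) - np.log(22.0)) / (2 * 0.6745))


@dataclass
class SimConfig:
    """Parameters of one synthetic pooled-selection experiment.

    Any of the per-strain arrays may be left ``None`` to be drawn from the
    default laws by :func:`draw_parameters`:

    - ``unique_snv_counts``: log-normal, median 33, matched to the observed
      quartile spread, floored at 1;
    - ``initial_frequencies``: symmetric Dirichlet with concentration
      ``dirichlet_concentration`` (default 3, giving a day-1 coefficient of
      variation around 0.6 — substantial founder dispersion around the
      uniform 1/n);
    - ``mortality_rates`` (per day): log-normal, median
      ``mortality_log_median`` = 0.10/day, log-sd 0.6, spanning roughly
      0.03-0.3/day so the median strain declines strongly relative to the
      hardiest strains over a 24-day course;
    - ``recovery_weights``: log-normal with log-sd ``recovery_log_sd``
      (default 0.25) around 1.
    """

    n_strains: int = 96
    unique_snv_counts: np.ndarray | None = None
    initial_frequencies: np.ndarray | None = None
    dirichlet_concentration: float = 3.0
    mortality_rates: np.ndarray | None = None
    mortality_log_median: float = 0.10
    mortality_log_sd: float = 0.6
    recovery_weights: np.ndarray | None = None
    recovery_log_sd: float = 0.25
    sample_days_per_replicate: tuple = DEFAULT_SAMPLE_DAYS
    mean_total_coverage_per_snv: float = 1691.0
    read_noise_model: str = "poisson_split"
    seed: int = 0

    def strain_names(self) -> list[str]:
        width = max(3, len(str(self.n_strains)))
        return [f"S{i + 1:0{width}d}" for i in range(self.n_strains)]

    def validate(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if self.mean_total_coverage_per_snv <= 0:
            raise ValueError("coverage must be positive")
        if self.read_noise_model not in ("poisson_split", "binomial_given_total"):
            raise ValueError(f"unknown read_noise_model {self.read_noise_model!r}")
        for days in self.sample_days_per_replicate:
            if any(d < 0 for d in days):
                raise ValueError("sample days must be non-negative")
        if self.unique_snv_counts is not None:
            c = np.asarray(self.unique_snv_counts)
            if len(c) != self.n_strains or np.any(c < 1):
                raise ValueError("unique_snv_counts must have n_strains entries >= 1")
        if self.initial_frequencies is not None:
            f0 = np.asarray(self.initial_frequencies, dtype=float)
            if len(f0) != self.n_strains:
                raise ValueError("initial_frequencies must have n_strains entries")
            if np.any(f0 < 0) or abs(f0.sum() - 1.0) > 1e-12:
                raise ValueError("initial_frequencies must be >= 0 and sum to 1 (tol 1e-12)")
            if f0.sum() == 0:
                raise ValueError("all-zero pool")
        if self.mortality_rates is not None:
            m = np.asarray(self.mortality_rates, dtype=float)
            if len(m) != self.n_strains or np.any(m < 0):
                raise ValueError("mortality_rates must have n_strains entries >= 0")
        if self.recovery_weights is not None:
            w = np.asarray(self.recovery_weights, dtype=float)
            if len(w) != self.n_strains or np.any(w < 0):
                raise ValueError("recovery_weights must have n_strains entries >= 0")


def draw_parameters(config: SimConfig) -> SimConfig:
    """Fill any unspecified per-strain arrays from the default laws.

    Uses a dedicated stream derived from ``config.seed`` so parameter
    drawing and read sampling are independently reproducible.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_strains
    out = replace(config)
    if out.unique_snv_counts is None:
        counts = np.round(rng.lognormal(_SNV_LOG_MEDIAN, _SNV_LOG_SD, size=n))
        out.unique_snv_counts = np.maximum(counts, 1).astype(int)
    if out.initial_frequencies is None:
        f0 = rng.dirichlet(np.full(n, config.dirichlet_concentration))
        out.initial_frequencies = f0 / f0.sum()
    if out.mortality_rates is None:
        out.mortality_rates = rng.lognormal(
            np.log(config.mortality_log_median), config.mortality_log_sd, size=n
        )
    if out.recovery_weights is None:
        out.recovery_weights = rng.lognormal(0.0, config.recovery_log_sd, size=n)
    out.validate()
    return out


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``frequencies`` is strain x library (MultiIndex columns
    ``(replicate, day)``), each column summing to 1.  ``trait_values`` are
    the per-strain expected selection slopes, computed from the true
    frequencies with the same per-replicate regression the analysis
    pipeline applies.
    """

    config: SimConfig
    frequencies: pd.DataFrame
    trait_values: pd.Series

    @property
    def strains(self) -> list[str]:
        return list(self.frequencies.index)


def simulate_frequency_trajectories(config: SimConfig) -> SimTruth:
    """Deterministic strain-frequency trajectories under selection.

    Heterogeneous mortality inflates the cross-strain variance of the
    frequency distribution over time and pulls its median down, mirroring
    the qualitative behaviour of a starving pooled culture.
    """
    config = draw_parameters(config)
    f0 = np.asarray(config.initial_frequencies, dtype=float)
    m = np.asarray(config.mortality_rates, dtype=float)
    w = np.asarray(config.recovery_weights, dtype=float)

    cols = []
    data = []
    for r, days in enumerate(config.sample_days_per_replicate, start=1):
        for d in days:
            if d < 0:
                raise ValueError("negative day")
            raw = w * f0 * np.exp(-m * d)
            denom = raw.sum()
            if denom <= 0:
                raise ValueError("all-zero pool at day {}".format(d))
            cols.append((str(r), int(d)))
            data.append(raw / denom)
    freq = pd.DataFrame(
        np.column_stack(data),
        index=pd.Index(config.strain_names(), name="strain"),
        columns=pd.MultiIndex.from_tuples(cols, names=["replicate", "day"]),
    )

    trait = {}
    for strain in freq.index:
        slopes = []
        for r, days in enumerate(config.sample_days_per_replicate, start=1):
            vals = [freq.loc[strain, (str(r), int(d))] for d in days]
            if len(set(days)) >= 2:
                slopes.append(regression_slope(list(days), vals))
        trait[strain] = float(np.mean(slopes)) if slopes else np.nan
    return SimTruth(
        config=config,
        frequencies=freq,
        trait_values=pd.Series(trait, name="trait_value"),
    )


def _assign_variants(config: SimConfig) -> pd.DataFrame:
    """Synthetic variant records: one block of private SNVs per strain."""
    counts = np.asarray(config.unique_snv_counts, dtype=int)
    strains = np.repeat(config.strain_names(), counts)
    pos = np.arange(1, counts.sum() + 1) * 100
    return pd.DataFrame(
        {
            "chrom": "chrS",
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "strain": strains,
        }
    )


def simulate_count_table(
    truth: SimTruth,
    config: SimConfig | None = None,
    variants: pd.DataFrame | None = None,
    expected: bool = False,
) -> PooledCountTable:
    """Draw per-SNV ref/alt read counts for every library.

    Under ``poisson_split`` (default) the alternative and reference counts
    at a unique SNV of strain *s* in library *(r, d)* are independent
    ``Poisson(lam * f)`` and ``Poisson(lam * (1 - f))`` draws with
    ``lam = mean_total_coverage_per_snv`` and ``f = f_s(r, d)``.  Under
    ``binomial_given_total`` the total is ``Poisson(lam)`` and the
    alternative count binomial given that total.  With ``expected=True`` the
    draws are replaced by their expectations (non-integral counts), giving
    the noise-free oracle table for which downstream inference is exact.

    ``variants`` may supply explicit variant records (columns
    ``chrom, pos, ref, alt, strain``); by default one synthetic block of
    private SNVs per strain is created from ``unique_snv_counts``.
    Deterministic given ``config.seed``.
    """
    config = truth.config if config is None else config
    if variants is None:
        variants = _assign_variants(config)
    counts_per_strain = variants["strain"].value_counts()
    missing = [s for s in truth.strains if counts_per_strain.get(s, 0) < 1]
    if missing:
        raise ValueError(f"every strain needs >= 1 unique SNV; missing: {missing}")

    lam = config.mean_total_coverage_per_snv
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    f_by_strain = truth.frequencies.loc[variants["strain"].to_numpy()]

    out = variants.copy()
    for rep, day in truth.frequencies.columns:
        f = f_by_strain[(rep, day)].to_numpy(dtype=float)
        if expected:
            alt = lam * f
            ref = lam * (1.0 - f)
        elif config.read_noise_model == "poisson_split":
            alt = rng.poisson(lam * f)
            ref = rng.poisson(lam * (1.0 - f))
        else:  # binomial_given_total
            total = rng.poisson(lam, size=f.size)
            alt = rng.binomial(total, f)
            ref = total - alt
        out[f"{rep}_{day}_ref"] = ref
        out[f"{rep}_{day}_alt"] = alt
    return PooledCountTable(out)


def simulate_panel(
    n_strains: int,
    unique_snv_counts,
    n_background: int = 0,
    background_maf: float = 0.3,
    seed: int = 0,
) -> StrainPanel:
    """Synthetic genotype panel with known private markers.

    Each strain carries the alternative allele at exactly its own block of
    unique SNVs.  ``n_background`` extra biallelic markers with random
    genotypes (alt probability ``background_maf``, shared across strains)
    are appended for association-scan use; these are generally not unique.
    """
    counts = np.asarray(unique_snv_counts, dtype=int)
    if len(counts) != n_strains or np.any(counts < 1):
        raise ValueError("unique_snv_counts must have n_strains entries >= 1")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_strains)))
    strains = [f"S{i + 1:0{width}d}" for i in range(n_strains)]

    n_unique = int(counts.sum())
    gt = np.zeros((n_unique + n_background, n_strains), dtype=np.int8)
    row = 0
    for j, c in enumerate(counts):
        gt[row : row + c, j] = 1
        row += c
    if n_background:
        gt[n_unique:, :] = (
            rng.random((n_background, n_strains)) < background_maf
        ).astype(np.int8)

    variants = pd.DataFrame(
        {
            "chrom": ["chrS"] * n_unique + ["chrB"] * n_background,
            "pos": np.concatenate(
                [np.arange(1, n_unique + 1) * 100, np.arange(1, n_background + 1) * 100]
            ),
            "ref": "A",
            "alt": "T",
        }
    )
    return StrainPanel(strains=strains, variants=variants, genotypes=gt)


def simulate_survival_assay(
    median_days,
    steepness,
    days,
    plated_per_day: int = 150,
    seed: int = 0,
    n_replicates: int = 1,
    strains: list[str] | None = None,
) -> pd.DataFrame:
    """Binomial manual survival-assay observations from logistic truth.

    For each strain with median survival ``t50`` and steepness ``k``, the
    number alive out of ``plated_per_day`` worms on day *d* is
    ``Binomial(plated, S(d))`` with ``S(d) = 1 / (1 + exp(k * (d - t50)))``.

    Returns a long frame (strain, replicate, day, plated, alive).
    """
    t50 = np.atleast_1d(np.asarray(median_days, dtype=float))
    k = np.atleast_1d(np.asarray(steepness, dtype=float))
    if t50.shape != k.shape:
        raise ValueError("median_days and steepness must have equal length")
    if np.any(t50 <= 0) or np.any(k <= 0):
        raise ValueError("median_days and steepness must be positive")
    days = list(days)
    if any(d < 0 for d in days):
        raise ValueError("days must be non-negative")
    if strains is None:
        strains = [f"S{i + 1:03d}" for i in range(t50.size)]
    rng = np.random.default_rng(seed)
    records = []
    for i, strain in enumerate(strains):
        for rep in range(1, n_replicates + 1):
            for d in days:
                s = 1.0 / (1.0 + np.exp(k[i] * (d - t50[i])))
                alive = int(rng.binomial(plated_per_day, s))
                records.append((strain, str(rep), int(d), plated_per_day, alive))
    return pd.DataFrame(
        records, columns=["strain", "replicate", "day", "plated", "alive"]
    )


def truth_to_tsv(truth: SimTruth, path) -> None:
    """Write the ground-truth frequencies and trait values to TSV."""
    flat = truth.frequencies.copy()
    flat.columns = [f"{r}_{d}" for r, d in flat.columns]
    flat["true_trait_value"] = truth.trait_values
    flat.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")
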