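"""Theoretical measurement error of pooled strain-frequency estimates.

Read sampling at a unique SNV is modelled as Poisson: a strain at true
frequency ``f`` whose SNV attracts ``lam`` total reads on average yields
``Poisson(lam * f)`` alternative reads.  With ``n`` unique SNVs the
frequency estimate is the mean of the per-SNV fractions, and the precision
metric is the *mean proportional error*

    E|f_hat - f| / f,

estimated by Monte-Carlo simulation (4,000 replicates by default).  In the
normal regime the estimator is approximately ``Normal(f, f / (n * lam))``,
giving the half-normal closed form ``sqrt(2 / (pi * n * lam * f))`` used as
an analytic cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def analytic_proportional_error(coverage: float, n_snvs: int, true_frequency: float) -> float:
    """Half-normal approximation to the mean proportional error."""
    return float(np.sqrt(2.0 / (np.pi * n_snvs * coverage * true_frequency)))


def simulate_proportional_error(
    coverage: float,
    n_snvs: int,
    true_frequency: float,
    n_sim: int = 4000,
    seed: int | None = None,
    coverage_model: str = "fixed",
) -> float:
    """Monte-Carlo mean proportional error of the frequency estimator.

    Parameters
    ----------
    coverage
        Expected total reads per SNV (``lam``).
    n_snvs
        Number of unique SNVs averaged per estimate.
    true_frequency
        True strain frequency ``f`` in (0, 1].
    n_sim
        Number of simulated estimates to average.
    coverage_model
        ``"fixed"`` (default): per-SNV total reads are the constant ``lam``
        and only alternative reads are drawn, ``alt ~ Poisson(lam * f)``,
        estimating ``f_hat = mean(alt_i / lam)``.  ``"random_total"``: the
        per-SNV total is itself ``Poisson(lam)`` and alternative reads are
        binomial given the total; SNVs that draw zero total reads are
        excluded from that estimate.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if n_snvs < 1:
        raise ValueError("n_snvs must be >= 1")
    if not 0 < true_frequency <= 1:
        raise ValueError("true_frequency must be in (0, 1]; proportional error is undefined at 0")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    if coverage_model == "fixed":
        alt = rng.poisson(coverage * true_frequency, size=(n_sim, n_snvs))
        est = alt.mean(axis=1) / coverage
    elif coverage_model == "random_total":
        total = rng.poisson(coverage, size=(n_sim, n_snvs))
        alt = rng.binomial(total, true_frequency)
        with np.errstate(invalid="ignore"):
            frac = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
        est = np.nanmean(frac, axis=1)
    else:
        raise ValueError(f"unknown coverage_model {coverage_model!r}")
    return float(np.mean(np.abs(est - true_frequency)) / true_frequency)


@dataclass
class ErrorGridResult:
    """Complete error surface over (coverage, n_snvs, true_frequency)."""

    grid: pd.DataFrame  # columns: coverage, n_snvs, true_frequency, mean_prop_error
    n_simulations: int
    seed: int

    def lookup(self, coverage: float, n_snvs: int, true_frequency: float) -> float:
        g = self.grid
        row = g[
            (g["coverage"] == coverage)
            & (g["n_snvs"] == n_snvs)
            & (g["true_frequency"] == true_frequency)
        ]
        if row.empty:
            raise KeyError((coverage, n_snvs, true_frequency))
        return float(row["mean_prop_error"].iloc[0])


def error_grid(
    coverages,
    n_snvs_values,
    frequencies,
    n_sim: int = 4000,
    seed: int = 0,
    coverage_model: str = "fixed",
) -> ErrorGridResult:
    """Simulate the full cross-product error surface.

    Cell ``i`` (row-major over coverage x n_snvs x frequency) uses seed
    ``seed + i``, so a 1x1x1 grid reproduces a direct
    :func:`simulate_proportional_error` call with the same seed.
    """
    coverages = list(coverages)
    n_snvs_values = list(n_snvs_values)
    frequencies = list(frequencies)
    if not (coverages and n_snvs_values and frequencies):
        raise ValueError("all grid axes must be non-empty")
    rows = []
    i = 0
    for lam in coverages:
        for n in n_snvs_values:
            for f in frequencies:
                err = simulate_proportional_error(
                    lam, n, f, n_sim=n_sim, seed=seed + i, coverage_model=coverage_model
                )
                rows.append((lam, n, f, err))
                i += 1
    grid = pd.DataFrame(
        rows, columns=["coverage", "n_snvs", "true_frequency", "mean_prop_error"]
    )
    return ErrorGridResult(grid=grid, n_simulations=n_sim, seed=seed)


def minimum_requirements(
    target_error: float,
    coverage: float,
    true_frequency: float,
    n_snvs_candidates,
    n_sim: int = 4000,
    seed: int = 0,
) -> int | None:
    """Smallest candidate marker count meeting a proportional-error target.

    Candidates must be sorted ascending; returns ``None`` when no candidate
    achieves ``mean proportional error <= target_error``.
    """
    candidates = list(n_snvs_candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    if any(b < a for a, b in zip(candidates, candidates[1:])):
        raise ValueError("candidates must be sorted ascending")
    for i, n in enumerate(candidates):
        err = simulate_proportional_error(
            coverage, n, true_frequency, n_sim=n_sim, seed=seed + i
        )
        if err <= target_error:
            return int(n)
    return None
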