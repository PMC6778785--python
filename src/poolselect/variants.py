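"""Strain genotype panels, strain-unique SNV markers, and pooled count tables.

A pooled sequencing library contains reads from many isogenic strains at
once.  A SNV whose alternative allele is carried by exactly one strain in
the panel ("unique SNV") acts as a private marker: the alternative-allele
read fraction at that site estimates the owning strain's frequency in the
pool.  This module identifies unique SNVs from a multi-strain genotype
matrix, reads and writes the per-library read-count tables, and computes
the per-strain marker/coverage summaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# genotype codes in StrainPanel.genotypes
REF = 0
ALT = 1
MISSING = -1

#: columns that identify a variant record everywhere in this package
VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

_COUNT_COL = re.compile(r"^(?P<rep>[^_]+)_(?P<day>\d+)_(?P<kind>ref|alt)$")


def variant_ids(variants: pd.DataFrame) -> pd.Index:
    """Canonical ``chrom:pos:ref:alt`` string key for each variant row."""
    return pd.Index(
        variants["chrom"].astype(str)
        + ":"
        + variants["pos"].astype(str)
        + ":"
        + variants["ref"].astype(str)
        + ":"
        + variants["alt"].astype(str)
    )


@dataclass
class StrainPanel:
    """Biallelic-SNV genotype matrix for a panel of homozygous strains.

    Parameters
    ----------
    strains
        Ordered strain identifiers (unique).
    variants
        One row per SNV with columns ``chrom, pos, ref, alt``; ``pos`` is
        1-based. ``(chrom, pos, ref, alt)`` must be unique.
    genotypes
        ``(n_variants, n_strains)`` int8 array with entries ``REF`` (0),
        ``ALT`` (1) or ``MISSING`` (-1). Strains are homozygous, so a single
        allele call per strain suffices; heterozygous VCF calls are loaded
        as missing.
    """

    strains: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.strains = list(self.strains)
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("strain identifiers must be unique")
        self.variants = self.variants.reset_index(drop=True)
        missing_cols = [c for c in VARIANT_KEY if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.strains)):
            raise ValueError(
                "genotype matrix shape "
                f"{self.genotypes.shape} does not match "
                f"({len(self.variants)} variants, {len(self.strains)} strains)"
            )
        ids = variant_ids(self.variants)
        if ids.has_duplicates:
            raise ValueError("duplicate (chrom, pos, ref, alt) variant records")
        self._ids = ids

    @property
    def variant_ids(self) -> pd.Index:
        return self._ids

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @classmethod
    def from_vcf(cls, path: str) -> "StrainPanel":
        """Load a panel from a VCF with one genotype column per strain.

        Only biallelic SNV records are kept.  Homozygous-alt calls map to
        ``ALT``, homozygous-ref to ``REF``; heterozygous and uncalled
        genotypes map to ``MISSING``.
        """
        from cyvcf2 import VCF

        vcf = VCF(path, gts012=True)
        strains = list(vcf.samples)
        rows = []
        gts = []
        for rec in vcf:
            if len(rec.ALT) != 1:
                continue
            if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                continue
            rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
            g = rec.gt_types
            row = np.full(len(strains), MISSING, dtype=np.int8)
            row[g == 0] = REF
            row[g == 2] = ALT
            gts.append(row)
        vcf.close()
        variants = pd.DataFrame(rows, columns=VARIANT_KEY)
        genotypes = (
            np.array(gts, dtype=np.int8)
            if gts
            else np.empty((0, len(strains)), dtype=np.int8)
        )
        return cls(strains=strains, variants=variants, genotypes=genotypes)


@dataclass
class UniqueSNVMap:
    """Assignment of strain-unique SNVs to their owning strains.

    ``assignments`` maps variant id -> strain for every variant at which
    exactly one strain carries the alternative allele. ``per_strain_count``
    is indexed by every panel strain, zero-filled for strains that own no
    unique SNV.
    """

    assignments: pd.Series
    per_strain_count: pd.Series

    def __post_init__(self) -> None:
        if int(self.per_strain_count.sum()) != len(self.assignments):
            raise ValueError("per_strain_count does not sum to assigned variants")

    @property
    def variant_ids(self) -> pd.Index:
        return self.assignments.index

    def strains_of(self, ids: pd.Index) -> pd.Series:
        return self.assignments.reindex(ids)


def identify_unique_snvs(
    panel: StrainPanel, missing_policy: str = "strict"
) -> UniqueSNVMap:
    """Find SNVs whose alternative allele is private to a single strain.

    A variant is assigned to strain *s* iff *s* is the only strain with the
    alternative allele and every other strain is reference.  Missing calls
    are handled by ``missing_policy``:

    - ``"strict"`` (default): any missing call disqualifies the variant
      (ownership cannot be established);
    - ``"lenient"``: missing calls are treated as reference.
    """
    if panel.n_variants == 0 or not panel.strains:
        raise ValueError("empty strain panel")
    if missing_policy not in ("strict", "lenient"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    gt = panel.genotypes
    n_alt = (gt == ALT).sum(axis=1)
    n_missing = (gt == MISSING).sum(axis=1)
    unique = n_alt == 1
    if missing_policy == "strict":
        unique &= n_missing == 0
    owner_idx = np.argmax(gt == ALT, axis=1)

    ids = panel.variant_ids[unique]
    owners = pd.Series(
        np.array(panel.strains, dtype=object)[owner_idx[unique]],
        index=ids,
        name="strain",
        dtype=object,
    )
    counts = (
        owners.value_counts()
        .reindex(panel.strains, fill_value=0)
        .rename("n_unique_snvs")
        .astype(int)
    )
    return UniqueSNVMap(assignments=owners, per_strain_count=counts)


@dataclass
class PooledCountTable:
    """Ref/alt read counts per variant per pooled library.

    ``data`` has the variant key columns, an optional ``strain`` column (the
    owning strain, when known), then one ``<replicate>_<day>_ref`` and
    ``<replicate>_<day>_alt`` column pair per library.  Counts may be
    non-integral when the table holds expected (noise-free) counts.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_KEY if c not in self.data.columns]
        if missing:
            raise ValueError(f"count table lacks columns {missing}")
        if not self.libraries:
            raise ValueError("count table has no <replicate>_<day>_ref/alt columns")
        counts = self.data[self.count_columns()].to_numpy()
        if np.any(counts < 0) or np.any(~np.isfinite(counts)):
            raise ValueError("read counts must be finite and non-negative")
        self.data = self.data.reset_index(drop=True)

    @property
    def libraries(self) -> list[tuple[str, int]]:
        """Ordered (replicate, day) pairs present in the table."""
        seen: list[tuple[str, int]] = []
        for col in self.data.columns:
            m = _COUNT_COL.match(str(col))
            if m and m.group("kind") == "ref":
                seen.append((m.group("rep"), int(m.group("day"))))
        return seen

    def count_columns(self) -> list[str]:
        return [c for c in self.data.columns if _COUNT_COL.match(str(c))]

    @property
    def variant_ids(self) -> pd.Index:
        return variant_ids(self.data)

    def ref_alt(self, replicate: str, day: int) -> tuple[np.ndarray, np.ndarray]:
        base = f"{replicate}_{day}"
        return (
            self.data[f"{base}_ref"].to_numpy(dtype=float),
            self.data[f"{base}_alt"].to_numpy(dtype=float),
        )

    def filter_unique(self, snv_map: UniqueSNVMap) -> "PooledCountTable":
        """Restrict the table to unique SNVs and annotate the owning strain."""
        ids = self.variant_ids
        keep = ids.isin(snv_map.variant_ids)
        data = self.data.loc[keep].copy()
        data["strain"] = snv_map.assignments.reindex(ids[keep]).to_numpy()
        cols = VARIANT_KEY + ["strain"] + [
            c for c in data.columns if c not in VARIANT_KEY + ["strain"]
        ]
        return PooledCountTable(data[cols])

    def to_tsv(self, path) -> None:
        write_tsv(self.data, path)

    @classmethod
    def from_tsv(cls, path) -> "PooledCountTable":
        return cls(pd.read_csv(path, sep="\t"))


def write_tsv(df: pd.DataFrame, path) -> None:
    """Deterministic TSV output: UTF-8, tabs, '.' decimal, %.10g floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def strain_marker_summary(
    snv_map: UniqueSNVMap, counts: PooledCountTable
) -> pd.DataFrame:
    """Per-strain marker table: unique-SNV count and coverage statistics.

    Coverage of one SNV in one library is ``ref + alt``.  The mean and the
    standard error pool every owned SNV across every library (replicates
    included), so a strain with *k* SNVs observed in *L* libraries
    contributes ``k * L`` coverage observations.  Strains with no unique SNV
    get ``n_unique_snvs = 0`` and NaN coverage columns; a single observation
    yields NaN standard error.
    """
    ids = counts.variant_ids
    owners = snv_map.strains_of(ids)
    if owners.isna().any():
        raise ValueError(
            "count table contains variants outside the unique-SNV map; "
            "filter with PooledCountTable.filter_unique first"
        )
    cov_cols = []
    for rep, day in counts.libraries:
        ref, alt = counts.ref_alt(rep, day)
        cov_cols.append(ref + alt)
    coverage = np.column_stack(cov_cols)  # variants x libraries

    strains = snv_map.per_strain_count.index
    rows = []
    owner_arr = owners.to_numpy()
    for strain in strains:
        mask = owner_arr == strain
        obs = coverage[mask].ravel()
        n_snvs = int(snv_map.per_strain_count[strain])
        if obs.size == 0:
            rows.append((strain, n_snvs, np.nan, np.nan))
        else:
            mean = float(obs.mean())
            se = (
                float(obs.std(ddof=1) / np.sqrt(obs.size))
                if obs.size > 1
                else np.nan
            )
            rows.append((strain, n_snvs, mean, se))
    return pd.DataFrame(
        rows, columns=["strain", "n_unique_snvs", "avg_coverage", "se_coverage"]
    )


def summary_statistics(table: pd.DataFrame, min_snvs: int = 16) -> dict:
    """Headline statistics of a per-strain marker table.

    Quantiles use linear interpolation between order statistics (the
    ``(n - 1) * q + 1`` index convention shared by numpy's default and R
    type 7).

    Returns a dict with ``median_unique_snvs``, ``q25_unique_snvs``,
    ``q75_unique_snvs``, ``total_unique_snvs``, ``n_strains_min_snvs``
    (strains with at least ``min_snvs`` unique SNVs) and
    ``median_avg_coverage`` (median across strains of the per-strain mean
    coverage).
    """
    if len(table) == 0:
        raise ValueError("empty marker table")
    n = table["n_unique_snvs"].to_numpy(dtype=float)
    cov = table["avg_coverage"].to_numpy(dtype=float)
    return {
        "median_unique_snvs": float(np.percentile(n, 50)),
        "q25_unique_snvs": float(np.percentile(n, 25)),
        "q75_unique_snvs": float(np.percentile(n, 75)),
        "total_unique_snvs": int(n.sum()),
        "n_strains_min_snvs": int((n >= min_snvs).sum()),
        "median_avg_coverage": float(np.nanmedian(cov)),
    }
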