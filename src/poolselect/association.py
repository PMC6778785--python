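"""Simplified single-marker association scan for pooled-selection traits.

This is a *naive* marker-by-marker linear scan with no population-structure
(kinship) correction: at each biallelic marker the trait value is regressed
on the 0/1 allele indicator across homozygous strains, with a two-sided
t-test on the slope and a Bonferroni line at ``-log10(0.05 / M)`` over the
``M`` markers tested.  It is intended for synthetic benchmarks and quick
looks; results are not comparable to a mixed-model association study on
structured wild-isolate panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import ALT, MISSING, REF, StrainPanel

METHOD_NOTE = "naive linear scan, no population-structure correction"

_TINY_P = float(np.nextafter(0, 1))


@dataclass
class AssociationResult:
    results: pd.DataFrame  # chrom, pos, ref, alt, effect, t, pvalue, neg_log10_p
    n_markers_tested: int
    n_skipped_monomorphic: int
    n_skipped_maf: int
    bonferroni_line: float
    method: str = METHOD_NOTE


def marker_scan(
    panel: StrainPanel, traits: pd.DataFrame, maf_min: float = 0.05
) -> AssociationResult:
    """Per-marker linear association of trait values with allele counts.

    ``traits`` is the exported two-column (strain, trait_value) mapping.
    Markers whose minor-allele count among scored strains falls below
    ``maf_min * n`` are excluded; monomorphic markers are skipped and
    counted.  Requires >= 10 strains with both genotype and trait.
    """
    trait_by_strain = traits.set_index("strain")["trait_value"]
    common = [s for s in panel.strains if s in trait_by_strain.index]
    if len(common) < 10:
        raise ValueError("need >= 10 strains with both genotype and trait")
    col_idx = np.array([panel.strains.index(s) for s in common])
    y_all = trait_by_strain.loc[common].to_numpy(dtype=float)
    gt = panel.genotypes[:, col_idx]

    rows = []
    n_mono = n_maf = 0
    for i in range(panel.n_variants):
        g = gt[i]
        mask = g != MISSING
        x = (g[mask] == ALT).astype(float)
        y = y_all[mask]
        n = x.size
        if n < 3:
            n_mono += 1
            continue
        mac = int(min(x.sum(), n - x.sum()))
        if mac == 0:
            n_mono += 1
            continue
        if mac < maf_min * n:
            n_maf += 1
            continue
        xc = x - x.mean()
        yc = y - y.mean()
        sxx = float(xc @ xc)
        beta = float(xc @ yc) / sxx
        resid = yc - beta * xc
        ssr = float(resid @ resid)
        df = n - 2
        if ssr <= 0.0 or df <= 0:
            t = np.inf * np.sign(beta) if beta != 0 else 0.0
            p = _TINY_P if beta != 0 else 1.0
        else:
            se = np.sqrt(ssr / df / sxx)
            t = beta / se
            p = max(float(2.0 * stats.t.sf(abs(t), df)), _TINY_P)
        v = panel.variants.iloc[i]
        rows.append((v["chrom"], v["pos"], v["ref"], v["alt"], beta, t, p, -np.log10(p)))
    results = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "effect", "t", "pvalue", "neg_log10_p"],
    )
    m = len(results)
    return AssociationResult(
        results=results,
        n_markers_tested=m,
        n_skipped_monomorphic=n_mono,
        n_skipped_maf=n_maf,
        bonferroni_line=float(-np.log10(0.05 / m)) if m else np.nan,
    )


def genotype_phenotype_split(
    panel: StrainPanel, traits: pd.DataFrame, marker
) -> tuple[pd.DataFrame, pd.Series]:
    """Trait values split by REF/ALT allele at one marker.

    ``marker`` is a ``(chrom, pos)`` pair or a ``"chrom:pos"`` string.
    Returns one row per strain with a non-missing genotype and trait
    (columns ``strain, allele, trait_value``), plus the per-allele group
    mean trait values (NaN for an empty group).
    """
    if isinstance(marker, str):
        chrom, pos = marker.split(":")[:2]
        pos = int(pos)
    else:
        chrom, pos = marker[0], int(marker[1])
    hit = panel.variants.index[
        (panel.variants["chrom"] == chrom) & (panel.variants["pos"] == pos)
    ]
    if len(hit) == 0:
        raise KeyError(f"marker {chrom}:{pos} not in panel")
    g = panel.genotypes[hit[0]]
    trait_by_strain = traits.set_index("strain")["trait_value"]
    rows = []
    for j, strain in enumerate(panel.strains):
        if g[j] == MISSING or strain not in trait_by_strain.index:
            continue
        allele = "ALT" if g[j] == ALT else "REF"
        rows.append((strain, allele, float(trait_by_strain[strain])))
    table = pd.DataFrame(rows, columns=["strain", "allele", "trait_value"])
    means = table.groupby("allele")["trait_value"].mean().reindex(["REF", "ALT"])
    return table, means
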