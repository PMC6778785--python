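"""End-to-end orchestration and packaged reference fixtures.

``run_pipeline`` chains the stages — simulate a pooled experiment, identify
unique SNVs, infer strain frequencies, compute selection-slope trait
values, optionally run the naive marker scan — writing deterministic TSV
outputs plus a JSON manifest (package version, seeds, per-output SHA-256
checksums and row counts).  Outputs are a pure function of (config, seeds).

``load_table1_fixture`` returns the packaged 96-strain reference marker
table (unique-SNV counts, coverage statistics and published trait value per
strain), checksum-verified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import marker_scan
from .frequency import infer_frequencies
from .synthetic import (
    SimConfig,
    simulate_count_table,
    simulate_frequency_trajectories,
    simulate_panel,
    truth_to_tsv,
)
from .traits import compute_trait_values, export_gwas_traits
from .variants import (
    PooledCountTable,
    identify_unique_snvs,
    strain_marker_summary,
    write_tsv,
)

TABLE1_SHA256 = "7fafc9f6b027575678769e9b13fe8891899eccc2dec0c017774216dfc60cbdbb"

ALL_STAGES = ("simulate", "unique_snvs", "frequencies", "traits", "scan")


def load_table1_fixture() -> pd.DataFrame:
    """Packaged 96-strain reference marker table, checksum-verified.

    Columns: ``strain, n_unique_snvs, avg_coverage, se_coverage,
    trait_value``.
    """
    ref = resources.files("poolselect.data").joinpath("table1.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise ValueError(
            f"table1.tsv checksum mismatch: {digest} != {TABLE1_SHA256}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic run."""

    outdir: str = "poolselect_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    n_strains: int = 96
    n_background_markers: int = 200
    min_total_reads: int = 1
    maf_min: float = 0.05
    exclusions: tuple = ()
    replicate_day_map: dict | None = None
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "exclusions" in raw:
            raw["exclusions"] = tuple(raw["exclusions"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    outputs: dict[str, Path] = {}
    manifest: dict = {
        "poolselect_version": __version__,
        "seed": config.seed,
        "stages": stages,
        "outputs": {},
    }

    def record(name: str, path: Path, n_rows: int) -> None:
        outputs[name] = path
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
            "n_rows": int(n_rows),
        }

    state: dict = {}
    for stage in stages:
        try:
            if stage == "simulate":
                sim = SimConfig(
                    n_strains=config.n_strains, seed=config.seed, **config.sim_overrides
                )
                truth = simulate_frequency_trajectories(sim)
                sim = truth.config  # parameter arrays now realized
                panel = simulate_panel(
                    sim.n_strains,
                    sim.unique_snv_counts,
                    n_background=config.n_background_markers,
                    seed=config.seed,
                )
                unique_variants = panel.variants[panel.variants["chrom"] == "chrS"].copy()
                unique_variants["strain"] = np.repeat(
                    sim.strain_names(), sim.unique_snv_counts
                )
                counts = simulate_count_table(truth, sim, variants=unique_variants)
                state.update(truth=truth, panel=panel, counts=counts)
                counts.to_tsv(outdir / "counts.tsv")
                record("counts", outdir / "counts.tsv", len(counts.data))
                truth_to_tsv(truth, outdir / "truth.tsv")
                record("truth", outdir / "truth.tsv", len(truth.frequencies))
            elif stage == "unique_snvs":
                snv_map = identify_unique_snvs(state["panel"])
                state["snv_map"] = snv_map
                filtered = state["counts"].filter_unique(snv_map)
                state["counts"] = filtered
                summary = strain_marker_summary(snv_map, filtered)
                write_tsv(summary, outdir / "marker_summary.tsv")
                record("marker_summary", outdir / "marker_summary.tsv", len(summary))
            elif stage == "frequencies":
                freqs = infer_frequencies(
                    state["snv_map"],
                    state["counts"],
                    min_total_reads=config.min_total_reads,
                )
                state["freqs"] = freqs
                write_tsv(freqs, outdir / "frequencies.tsv")
                record("frequencies", outdir / "frequencies.tsv", len(freqs))
            elif stage == "traits":
                traits = compute_trait_values(
                    state["freqs"], replicate_day_map=config.replicate_day_map
                )
                state["traits"] = traits
                write_tsv(traits, outdir / "traits.tsv")
                record("traits", outdir / "traits.tsv", len(traits))
                exported = export_gwas_traits(traits, exclusions=config.exclusions)
                state["exported"] = exported
                write_tsv(exported, outdir / "gwas_traits.tsv")
                record("gwas_traits", outdir / "gwas_traits.tsv", len(exported))
            elif stage == "scan":
                scan = marker_scan(
                    state["panel"], state["exported"], maf_min=config.maf_min
                )
                state["scan"] = scan
                write_tsv(scan.results, outdir / "scan.tsv")
                record("scan", outdir / "scan.tsv", len(scan.results))
                manifest["scan"] = {
                    "method": scan.method,
                    "n_markers_tested": scan.n_markers_tested,
                    "bonferroni_line": scan.bonferroni_line,
                }
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["_state"] = state
    return manifest
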