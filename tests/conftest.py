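import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from poolselect.synthetic import (
    SimConfig,
    simulate_count_table,
    simulate_frequency_trajectories,
    simulate_panel,
)
from poolselect.variants import identify_unique_snvs

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def write_vcf(panel, path):
    """Serialize a StrainPanel as a minimal VCF for round-trip tests."""
    gt_str = {0: "0/0", 1: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.strains)
            + "\n"
        )
        for i, row in panel.variants.iterrows():
            calls = "\t".join(gt_str[int(g)] for g in panel.genotypes[i])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                f".\tPASS\t.\tGT\t{calls}\n"
            )


@pytest.fixture(scope="session")
def small_experiment():
    """A 12-strain simulated experiment with panel, truth and noisy counts."""
    config = SimConfig(n_strains=12, seed=7)
    truth = simulate_frequency_trajectories(config)
    config = truth.config
    panel = simulate_panel(config.n_strains, config.unique_snv_counts, seed=7)
    snv_map = identify_unique_snvs(panel)
    counts = simulate_count_table(truth).filter_unique(snv_map)
    expected = simulate_count_table(truth, expected=True).filter_unique(snv_map)
    return {
        "config": config,
        "truth": truth,
        "panel": panel,
        "snv_map": snv_map,
        "counts": counts,
        "expected_counts": expected,
    }


@pytest.fixture()
def tiny_panel():
    """3 strains x 4 variants with hand-set genotypes."""
    variants = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "pos": [100, 200, 50, 75],
            "ref": ["A", "C", "G", "T"],
            "alt": ["T", "G", "A", "C"],
        }
    )
    genotypes = np.array(
        [
            [1, 0, 0],  # unique to s1
            [1, 1, 0],  # shared -> not unique
            [0, 0, 1],  # unique to s3
            [0, -1, 1],  # unique to s3 only under lenient policy
        ],
        dtype=np.int8,
    )
    from poolselect.variants import StrainPanel

    return StrainPanel(strains=["s1", "s2", "s3"], variants=variants, genotypes=genotypes)
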