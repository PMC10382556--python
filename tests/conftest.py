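import numpy as np
import pandas as pd
import pytest

from driftscan.genotype_io import GenotypeMatrix, make_variant_table
from driftscan.synthetic_data import SimulationConfig, simulate


def build_matrix(dosage, populations=None, chrom=None, pos=None,
                 alleles=None, sample_ids=None):
    """Small helper to build a GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if populations is None:
        populations = ["pop1"] * n
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = list(range(1000, 1000 + 1000 * m, 1000))
    if alleles is None:
        alleles = [("A", "C")] * m
    variants = make_variant_table(
        [
            (f"snp{j}", chrom[j], pos[j], alleles[j][0], alleles[j][1])
            for j in range(m)
        ]
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    return GenotypeMatrix(samples, variants, dosage)


@pytest.fixture(scope="session")
def drift_dataset():
    """2 populations, Ne=100, t=20 — shared across read-only tests."""
    cfg = SimulationConfig(
        seed=7,
        n_populations=2,
        ne_per_population=100,
        generations_divergence=20,
        n_chromosomes=3,
        chrom_length_bp=40_000_000,
        n_snps_per_chrom=700,
        sample_sizes=[50, 50],
    )
    return simulate(cfg)
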