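import numpy as np
import pandas as pd
import pytest

from kdrkit.core_io import GenotypeMatrix, HaplotypeMatrix, SampleTable, VariantRecord
from kdrkit.diplotypes import default_kdr_config
from kdrkit.simgen import CohortGroupSpec, KdrCohortSpec, simulate_kdr_cohort


def make_genotypes(calls, n_alleles=None, chrom="2L"):
    """GenotypeMatrix from a nested list (sites × samples × 2)."""
    calls = np.asarray(calls, dtype=np.int16)
    alphabet = "ACGT"
    variants = []
    for i in range(calls.shape[0]):
        k = n_alleles[i] if n_alleles else max(2, int(calls[i].max()) + 1)
        variants.append(
            VariantRecord(chrom, 100 + i, alphabet[0], tuple(alphabet[1:k]))
        )
    sample_ids = [f"s{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(variants, calls, sample_ids)


def make_haplotypes(haps, chrom="2L"):
    """HaplotypeMatrix from a nested list (sites × 2·samples)."""
    haps = np.asarray(haps, dtype=np.int16)
    alphabet = "ACGT"
    variants = [
        VariantRecord(chrom, 100 + i, "A", tuple(alphabet[1: max(2, int(haps[i].max()) + 1)]))
        for i in range(haps.shape[0])
    ]
    sample_ids = [f"s{j}" for j in range(haps.shape[1] // 2)]
    return HaplotypeMatrix(variants, haps, sample_ids, phased=True)


def make_samples(rows):
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture
def kdr_cfg():
    return default_kdr_config()


@pytest.fixture
def two_background_cohort(kdr_cfg):
    """A coluzzii cohort dominated by the FL1T and LVI backgrounds plus a small
    near-fixed gambiae group — the structure of the field data."""
    spec = KdrCohortSpec(
        groups=[
            CohortGroupSpec("coluzzii", "Bana", 100, {"FL1T": 0.4, "LVI": 0.6}),
            CohortGroupSpec("gambiae_ss", "Nassan", 40, {"FVI": 0.95, "LVI": 0.05}),
        ],
        n_background_sites=30,
        seed=11,
    )
    return spec, simulate_kdr_cohort(spec)
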