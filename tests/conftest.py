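import numpy as np
import pytest

from paravar.conservation import CodonAlignment
from paravar.synthetic import FamilySimConfig, simulate_orthologs


@pytest.fixture
def toy_alignment():
    """4 sequences, 3 codons; column 2 has one syn (GCT->GCC) and one nonsyn
    (GCT->GTT) change relative to the reference."""
    return CodonAlignment(
        gene="toy",
        reference_id="human",
        sequences={
            "human": "ATGGCTAAA",
            "sp1": "ATGGCCAAA",  # GCT->GCC synonymous
            "sp2": "ATGGTTAAA",  # GCT->GTT nonsynonymous
            "sp3": "ATGGCTAAA",  # identical
        },
    )


@pytest.fixture
def small_config():
    return FamilySimConfig(
        n_genes=2,
        species_per_gene=12,
        protein_length=40,
        domain_start=11,
        domain_end=30,
        p_sub_domain=0.1,
        p_sub_flank=0.4,
        omega_domain=0.1,
        omega_flank=0.8,
        n_variants_per_source={s: 8 for s in ("gnomad", "clinvar", "geno2mp", "cosmic", "literature")},
        seed=11,
    )


@pytest.fixture
def small_family(small_config):
    return simulate_orthologs(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
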