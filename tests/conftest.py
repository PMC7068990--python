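import numpy as np
import pytest

from agtbarcode.simulate import SimParams, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Compact simulated dataset shared by read-only tests: 2 subfamilies x
    2 clades x 3 species, 2 accessions each, one planted hybrid."""
    params = SimParams(n_subfamilies=2, n_groups_per_subfamily=2,
                       n_species_per_group=3, accessions_per_species=2,
                       n_hybrids=1, het_fraction=0.2, seed=11)
    records, exon_msa, truth = simulate(params)
    return params, records, exon_msa, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
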