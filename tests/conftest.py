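import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from phycodelim import (conserved_columns, encode_barcode, extract_v4,
                        generate_its2_dataset, generate_v4_dataset)


@pytest.fixture(scope="session")
def its2_dataset():
    """Three planted species, one CBC + one hemi-CBC per split."""
    strains, truth = generate_its2_dataset(
        n_species=3, strains_per_species=3, core_width=24,
        cbc_per_split=1, hcbc_per_split=1, loop_noise_rate=0.1, seed=11)
    return strains, truth


@pytest.fixture(scope="session")
def its2_barcodes(its2_dataset):
    strains, truth = its2_dataset
    cols = conserved_columns(strains)
    return [encode_barcode(s, cols) for s in strains], cols, truth


@pytest.fixture(scope="session")
def v4_dataset():
    """Three planted species with two haplotypes each."""
    return generate_v4_dataset(
        n_species=3, haplotypes_per_species=2, steps_between=1,
        samples_per_haplotype=2, seed=7)


@pytest.fixture(scope="session")
def v4_slice(v4_dataset):
    alignment, metadata, template, truth = v4_dataset
    return extract_v4(alignment, template)
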