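import pytest

from pomedev import synthetic_data as sd


@pytest.fixture(scope="session")
def small_fixture():
    """Compact genome + gene models used across the variant-effect tests."""
    genome = sd.generate_genome(n_chrom=2, chrom_length=60_000, n_fraction=0.005, seed=11)
    genome, models = sd.generate_gene_models(
        genome, n_genes=16, seed=11, n_noncanonical_start=2
    )
    return genome, models


@pytest.fixture(scope="session")
def planted_fixture(small_fixture):
    genome, models = small_fixture
    spec = {c: 8 for c in range(13)}
    spec[10], spec[11] = 6, 2
    variants, truths = sd.plant_variants(genome, models, spec, seed=17)
    return genome, models, variants, truths


@pytest.fixture(scope="session")
def sample_sheet():
    return sd.make_sample_sheet()


@pytest.fixture(scope="session")
def counts_fixture(small_fixture, sample_sheet):
    genome, models = small_fixture
    em, truth = sd.simulate_counts(
        models,
        sample_sheet,
        profile_spec={"steady_decrease": 0.25, "steady_increase": 0.25, "flat": 0.5},
        noise=0.05,
        seed=23,
    )
    return em, truth
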