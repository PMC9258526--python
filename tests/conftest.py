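import pytest

from tecred import RunConfig, SimConfig, generate_genome, generate_tags, run_pipeline


@pytest.fixture(scope="session")
def default_sim():
    """Noiseless reference simulation: 60 genes, 10 operons, 3 paralog pairs."""
    config = SimConfig(seed=1)
    genome, genes, truth = generate_genome(config)
    tags = generate_tags(genome, truth, config)
    return config, genome, genes, truth, tags


@pytest.fixture(scope="session")
def default_run(default_sim):
    config, genome, genes, truth, tags = default_sim
    result = run_pipeline(RunConfig(), tags=tags, genome=genome, genes=genes,
                          write=False)
    return truth, result


@pytest.fixture(scope="session")
def noisy_sim():
    """Mixed tag origins: offsets, novel sites and unmappable tags."""
    config = SimConfig(
        seed=7,
        n_single_genes=30,
        fraction_at_annotated_start=0.5,
        fraction_minor_offset=0.15,
        fraction_major_offset=0.15,
        fraction_novel_site=0.1,
        fraction_unmappable=0.1,
    )
    genome, genes, truth = generate_genome(config)
    tags = generate_tags(genome, truth, config)
    return config, genome, genes, truth, tags


@pytest.fixture(scope="session")
def noisy_run(noisy_sim):
    config, genome, genes, truth, tags = noisy_sim
    result = run_pipeline(RunConfig(), tags=tags, genome=genome, genes=genes,
                          write=False)
    return truth, result
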