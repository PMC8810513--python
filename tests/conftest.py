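import pytest
from hypothesis import settings, HealthCheck

from comorbnet.simulate import SyntheticConfig, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """A small but fully structured synthetic study: 300-gene universe,
    two 30-gene disease sets sharing 10, 5 candidates wired to 6 shared
    genes, 12 pathways with 2 planted per disease."""
    return SyntheticConfig(
        seed=11,
        n_genes=300,
        mean_degree=4.0,
        n_a=30,
        n_b=30,
        n_shared=10,
        n_candidates=5,
        candidate_wiring=6,
        n_pathways=12,
        pathway_size_range=(5, 15),
        n_enriched_per_disease=2,
        enrichment_fraction=0.8,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path
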