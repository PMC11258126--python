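import numpy as np
import pandas as pd
import pytest

from methlink import genome, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(
        seed=11,
        n_genes=15,
        n_clusters=200,
        genome_length=8_000_000,
        n_cohorts=2,
        samples_per_cohort=120,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """A small simulated study shared by read-only tests."""
    genes, probes = simulate.simulate_genome(small_config)
    cluster_map = genome.cluster_probes(probes)
    adjacency = genome.build_adjacency(genes, cluster_map)
    adjacency = genome.annotate_distance_ranks(adjacency, cluster_map, genes)
    datasets, truth = simulate.simulate_cohorts(small_config, cluster_map, adjacency)
    return {
        "config": small_config,
        "genes": genes,
        "probes": probes,
        "cluster_map": cluster_map,
        "adjacency": adjacency,
        "datasets": datasets,
        "truth": truth,
    }


def random_manifest(rng, n_probes, span=50_000, n_chroms=1):
    chroms = rng.integers(0, n_chroms, n_probes)
    pos = rng.integers(0, span, n_probes)
    df = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n_probes)],
            "chrom": [f"chr{c + 1}" for c in chroms],
            "pos": pos,
            "in_cgi": rng.random(n_probes) < 0.3,
        }
    )
    return df.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
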