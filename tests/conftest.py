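import numpy as np
import pytest

import cnclone as cc
from cnclone.cnmatrix import ClusterProfile, round_half_up
from cnclone.cnmatrix import estimate_chromosome_number


@pytest.fixture(scope="session")
def demo_genome():
    return cc.default_demo_genome()


@pytest.fixture
def small_genome():
    """One 20 Mb chromosome in four 5 Mb bins."""
    return cc.make_binned_genome({"c1": 20_000_000}, 5_000_000)


def make_profile(genome, states, cluster_id=1, passage="", cell_count=10):
    """ClusterProfile straight from an integer state vector."""
    states = np.asarray(states, dtype=np.int64)
    return ClusterProfile(
        cluster_id=cluster_id,
        cell_count=cell_count,
        mean_cn=states.astype(float),
        state_cn=states,
        chromosome_estimate=estimate_chromosome_number(states.astype(float), genome),
        passage_label=passage,
        genome=genome,
    )


def random_state_profiles(genome, n_clusters, rng, low=0, high=5, passage=""):
    """Random integer-state cluster profiles over a genome."""
    return [
        make_profile(
            genome,
            rng.integers(low, high + 1, size=genome.n_bins),
            cluster_id=i + 1,
            passage=passage,
        )
        for i in range(n_clusters)
    ]


@pytest.fixture
def two_clone_population(demo_genome):
    """Two-clone mixture: the minor clone carries two whole-chromosome
    gains plus partial gains, and expands between passages."""
    clones = [
        cc.CloneSpec("A", None, []),
        cc.CloneSpec(
            "B",
            "A",
            [
                ("chr5", 0, 24, 1),
                ("chr6", 0, 20, 1),
                ("chr1", 0, 10, 1),
                ("chr3", 10, 20, 1),
            ],
        ),
    ]
    return cc.PopulationSpec(
        clones=clones,
        proportions_early={"A": 0.913, "B": 0.087},
        proportions_late={"A": 0.593, "B": 0.407},
        n_cells_early=705,
        n_cells_late=744,
        noise_rate=0.05,
        seed=7,
    )
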