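import numpy as np
import pytest

from faw_haplotyper.popgen_profiles import DistanceMatrix
from faw_haplotyper.references import coib_reference, tpi_reference
from faw_haplotyper.synthetic_data import (
    PopulationConfig,
    SimulationConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def coib_ref():
    return coib_reference()


@pytest.fixture(scope="session")
def tpi_ref():
    return tpi_reference()


def make_population(name="pop", n=50, **overrides) -> PopulationConfig:
    """A small single-population config with overridable rates."""
    params = dict(
        name=name,
        n_specimens=n,
        coib_category_profile={"CSh1": 0.2, "CSh2": 0.6, "CSh4": 0.2},
        coib_variant_profiles={
            "CSh1": [0.7, 0.3],
            "CSh2": [0.6, 0.25, 0.15],
            "CSh4": [1.0],
        },
        intron_haplotype_profile=[0.5, 0.3, 0.2],
        strain_profile={"C": 0.8, "R": 0.2},
        hybrid_rate=0.1,
        heterozygosity=0.4,
        indel_het_fraction=0.5,
        noise_rate=0.0,
    )
    params.update(overrides)
    return PopulationConfig(**params)


@pytest.fixture(scope="session")
def small_study():
    """One 60-specimen population with hybrids and heterozygotes."""
    config = SimulationConfig(seed=42, populations=[make_population(n=60)])
    return simulate_study(config)


def random_additive_matrix(rng, n_leaves) -> DistanceMatrix:
    """Leaf distances induced by a random tree with positive branch lengths.

    Independent oracle for NJ consistency: on an additive matrix NJ must
    reproduce the generating tree's distances exactly.
    """
    edges: dict[str, list[tuple[str, float]]] = {}

    def add_edge(u, v, w):
        edges.setdefault(u, []).append((v, w))
        edges.setdefault(v, []).append((u, w))

    def del_edge(u, v):
        edges[u] = [(x, w) for x, w in edges[u] if x != v]
        edges[v] = [(x, w) for x, w in edges[v] if x != u]

    def blen():
        return float(rng.uniform(0.1, 1.0))

    center = "int0"
    n_int = 1
    for leaf in ("L0", "L1", "L2"):
        add_edge(center, leaf, blen())
    for k in range(3, n_leaves):
        pairs = [(u, v) for u in edges for v, _ in edges[u] if u < v]
        u, v = pairs[rng.integers(len(pairs))]
        w = dict(edges[u])[v]
        mid = f"int{n_int}"
        n_int += 1
        del_edge(u, v)
        split = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, f"L{k}", blen())
    labels = [f"L{i}" for i in range(n_leaves)]
    dist = np.zeros((n_leaves, n_leaves))
    for i, leaf in enumerate(labels):
        seen = {leaf: 0.0}
        stack = [leaf]
        while stack:
            x = stack.pop()
            for y, w in edges[x]:
                if y not in seen:
                    seen[y] = seen[x] + w
                    stack.append(y)
        for j, other in enumerate(labels):
            dist[i, j] = seen[other]
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(labels, (dist + dist.T) / 2)
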