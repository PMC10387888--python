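import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

import pathnetgwas as pg

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition fixture bundle shared across the suite."""
    return pg.generate_bundle(pg.FixtureSpec(rng_seed=17))


@pytest.fixture(scope="session")
def fixture_dir(default_bundle, tmp_path_factory):
    """The default bundle written out as plain-text files."""
    out = tmp_path_factory.mktemp("fixtures")
    paths = pg.write_bundle(default_bundle, out)
    return paths


@pytest.fixture(scope="session")
def trio_config(fixture_dir):
    return pg.PipelineConfig(
        datasets={f"ds{i}": fixture_dir[f"dataset{i}"] for i in (1, 2, 3)},
        ppi=fixture_dir["ppi"],
        gene_bed=fixture_dir["genes"],
        gmt=fixture_dir["pathways"],
        rng_seed=17,
    )


@pytest.fixture(scope="session")
def trio_run(trio_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    return pg.run_all(trio_config, out), out


def two_cliques_with_bridge() -> nx.Graph:
    """Two 5-cliques joined by a single bridge edge a0-b0."""
    g = nx.Graph()
    for base in ("a", "b"):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(f"{base}{i}", f"{base}{j}")
    g.add_edge("a0", "b0")
    return g


def random_partition(rng: np.random.Generator, genes, n_blocks: int):
    """Partition a gene list into n non-empty blocks uniformly at random."""
    labels = rng.integers(0, n_blocks, size=len(genes))
    blocks = [set() for _ in range(n_blocks)]
    for g, lab in zip(genes, labels):
        blocks[lab].add(g)
    return [b for b in blocks if b]
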