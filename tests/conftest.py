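import numpy as np
import pytest

from rlkfam.synthetic_data import SimConfig, generate_dataset
from rlkfam.types import GenePlacement


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One default synthetic dataset shared across read-only tests."""
    out = tmp_path_factory.mktemp("synth")
    return generate_dataset(SimConfig(), seed=7, out_dir=str(out))


@pytest.fixture(scope="session")
def small_config():
    return SimConfig()


def random_placements(rng: np.random.Generator, n_genes: int = 20,
                      seq_id: str = "A01") -> list[GenePlacement]:
    """A random single-chromosome gene layout for TDE oracle checks."""
    placements = []
    pos = 1
    for rank in range(n_genes):
        length = int(rng.integers(500, 5000))
        placements.append(
            GenePlacement(
                gene_id=f"g{rank}",
                seq_id=seq_id,
                rank=rank,
                start=pos,
                end=pos + length - 1,
                is_family=bool(rng.random() < 0.4),
            )
        )
        gap = int(rng.choice([2_000, 30_000, 600_000, 1_500_000]))
        pos += length + gap
    return placements


def brute_force_tde(placements: list[GenePlacement], window_bp: int = 1_000_000):
    """Independent TDE oracle: all-pairs links + networkx components."""
    import networkx as nx

    fam = sorted((p for p in placements if p.is_family), key=lambda p: p.rank)
    g = nx.Graph()
    g.add_nodes_from(p.gene_id for p in fam)
    for i in range(len(fam)):
        for j in range(i + 1, len(fam)):
            a, b = fam[i], fam[j]
            between = b.rank - a.rank - 1
            if between <= 1 or (between == 2 and b.start - a.end <= window_bp):
                g.add_edge(a.gene_id, b.gene_id)
    return {
        frozenset(c) for c in nx.connected_components(g) if len(c) >= 2
    }
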