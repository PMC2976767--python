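import pandas as pd
import pytest

import barcomm as bc


@pytest.fixture
def small_taxonomy() -> bc.CommunityTaxonomy:
    """Two orders / three families / four genera / six species."""
    rows = [
        ("sp1", "g1", "f1", "o1"),
        ("sp2", "g1", "f1", "o1"),
        ("sp3", "g2", "f2", "o1"),
        ("sp4", "g3", "f3", "o2"),
        ("sp5", "g3", "f3", "o2"),
        ("sp6", "g4", "f3", "o2"),
    ]
    return bc.CommunityTaxonomy(
        pd.DataFrame(rows, columns=["species", "genus", "family", "order"]))


@pytest.fixture
def backbone() -> bc.Tree:
    return bc.Tree.from_newick("(o1,o2);")


@pytest.fixture(scope="session")
def sim_community():
    """One seeded 24-species community with sequences, reused across tests."""
    cfg = bc.SimulationConfig(orders=3, families_per_order=2,
                              genera_per_family=2, species_per_genus=2,
                              seed=7, dropout={})
    truth = bc.simulate_truth(cfg)
    records = {m: bc.evolve_sequences(truth, m) for m in cfg.loci}
    return truth, records


class FakeMatrix:
    """Minimal taxa/rows container accepted by the parsimony scorer."""

    def __init__(self, taxa, rows):
        self.taxa = list(taxa)
        self.rows = list(rows)


@pytest.fixture
def fake_matrix_cls():
    return FakeMatrix
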