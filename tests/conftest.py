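import pytest

from hsfkit import simulate


@pytest.fixture(scope="session")
def class_proteins():
    """One generated protein + truth per Hsf class."""
    out = {}
    for seed, klass in enumerate("ABC"):
        out[klass] = simulate.generate_hsf_protein(klass, f"{klass}1", seed=seed,
                                                   gene_id=f"gene_{klass}")
    return out


@pytest.fixture(scope="session")
def family_sim():
    """A small synthetic family genome with planted duplications and a
    4-gene tandem cluster."""
    return simulate.generate_family_genome(
        6, 3, dup_pairs=[(0.95, 0.95), (0.75, 0.90)],
        tandem_cluster_size=4, seed=7)
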