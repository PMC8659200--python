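import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cyclomine.io import load_cleavage_table, load_seed_set


@pytest.fixture(scope="session")
def seed_set():
    return load_seed_set()


@pytest.fixture(scope="session")
def cleavage_table():
    return load_cleavage_table()


@pytest.fixture(scope="session")
def small_simulation(seed_set):
    """3 genomes: one multi-copy cluster, one unannotated-precursor
    cluster, one decoy missing its precursor."""
    from cyclomine.simulate import ClusterSpec, SimConfig, generate_genomes

    cfg = SimConfig(
        seed=424242,
        n_genomes=3,
        background_genes=15,
        clusters=[
            ClusterSpec(0, "amylocyclicin", identity_pct=70.0,
                        n_precursor_copies=2, include_yip1=True),
            ClusterSpec(1, "gassericin A", identity_pct=65.0,
                        precursor_annotated=False),
            ClusterSpec(2, "pumilarin", identity_pct=75.0, omit_role="precursor"),
        ],
    )
    return generate_genomes(cfg, seed_set)
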