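import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fishdiv as fd

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


def make_checklist(rows):
    """rows: (species_id, genus, family, order, class, phylum) tuples."""
    return fd.checklist_from_records(
        dict(zip(("species_id", "genus", "family", "order", "class", "phylum"), r))
        for r in rows
    )


@pytest.fixture
def tiny_checklist():
    """8 species spanning two classes, three orders, four families."""
    return make_checklist([
        ("s1", "G1", "F1", "O1", "C1", "P1"),
        ("s2", "G1", "F1", "O1", "C1", "P1"),
        ("s3", "G2", "F1", "O1", "C1", "P1"),
        ("s4", "G3", "F2", "O1", "C1", "P1"),
        ("s5", "G4", "F3", "O2", "C1", "P1"),
        ("s6", "G5", "F3", "O2", "C1", "P1"),
        ("s7", "G6", "F4", "O3", "C2", "P1"),
        ("s8", "G7", "F4", "O3", "C2", "P1"),
    ])


@pytest.fixture
def nested_chain():
    """3 sites, richness (5, 3, 2), site3 strictly inside site2 inside site1."""
    frame = pd.DataFrame(
        {"siteA": [1, 1, 1, 1, 1], "siteB": [1, 1, 1, 0, 0], "siteC": [1, 1, 0, 0, 0]},
        index=pd.Index([f"s{i}" for i in range(1, 6)], name="species_id"),
    )
    return fd.OccurrenceMatrix(frame)


@pytest.fixture(scope="session")
def guangxi_data():
    cfg = fd.guangxi_preset(seed=2022)
    return fd.generate_dataset(cfg)


@pytest.fixture
def four_block_matrix():
    """8 sites in 4 blocks; within-block similarity 1, between-block < 0.5."""
    rng = np.random.default_rng(11)
    n_blocks, per_block, spp_per_block, shared = 4, 2, 10, 2
    n_spp = n_blocks * spp_per_block + shared
    cols = {}
    for b in range(n_blocks):
        vec = np.zeros(n_spp, dtype=int)
        vec[b * spp_per_block:(b + 1) * spp_per_block] = 1
        vec[-shared:] = 1  # small shared core keeps between-block sim > 0
        for k in range(per_block):
            cols[f"s{b}{k}"] = vec
    frame = pd.DataFrame(cols, index=pd.Index([f"sp{i}" for i in range(n_spp)],
                                              name="species_id"))
    return fd.OccurrenceMatrix(frame)
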