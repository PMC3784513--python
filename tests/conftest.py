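import numpy as np
import pandas as pd
import pytest

import mutmotif as mm


@pytest.fixture(scope="session")
def toy_genome():
    return mm.Genome({"chr1": "TTCGAA"})


@pytest.fixture(scope="session")
def random_sequences():
    """100 random 1 kb sequences for oracle-equivalence style checks."""
    rng = np.random.default_rng(2024)
    return [
        "".join(rng.choice(list("ACGT"), size=1000)) for _ in range(100)
    ]


@pytest.fixture(scope="session")
def sim_small():
    """One modest synthetic catalog shared by read-only tests."""
    cfg = mm.SyntheticConfig(
        genome_length=80_000, n_genes=8, n_samples=6, mu=3e-4
    )
    return mm.simulate_catalog(cfg, 101)


@pytest.fixture(scope="session")
def sim_small_fractions(sim_small):
    ds = mm.deduplicate(mm.from_dataframe(sim_small["records"]))
    m, _ = mm.annotate_contexts(ds, sim_small["genome"], sim_small["mask"])
    t = mm.count_genome_motifs(sim_small["genome"], sim_small["mask"])
    return mm.motif_fractions(m, t)
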