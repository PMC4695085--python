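import numpy as np
import pandas as pd
import pytest

from symcomm import synth
from symcomm.table import CountTable


@pytest.fixture(scope="session")
def toy_db():
    """Small synthetic reference database shared across tests."""
    db, truth = synth.make_reference_db(n_per_clade=4, seed=11)
    return db, truth


@pytest.fixture(scope="session")
def small_survey(toy_db):
    """A small simulated survey with reads (error rate 0.005)."""
    db, truth_db = toy_db
    scenario = synth.default_scenario()
    for g in scenario.groups:
        g.n_per_pool = 3
    scenario.depth_geometric_mean = 120
    scenario.depth_geometric_sd = 1.8
    table, truth_comm = synth.simulate_community(scenario, db, truth_db,
                                                 seed=21)
    reads, truth_reads = synth.simulate_reads(table, db, truth_db,
                                              error_rate=0.005, seed=22)
    return {"db": db, "truth_db": truth_db, "table": table,
            "truth_comm": truth_comm, "reads": reads,
            "truth_reads": truth_reads, "scenario": scenario}


def make_two_pool_table(rng, n_per_pool=10, taxa_props=None, depth_mean=1000,
                        fold=None, compartment="water"):
    """Multinomial two-pool count table with optional planted
    fold-changes (applied in pool 300)."""
    if taxa_props is None:
        taxa_props = np.full(12, 1 / 12)
    taxa_props = np.asarray(taxa_props, float)
    taxa = [f"T{j}" for j in range(len(taxa_props))]
    rows, meta = [], []
    for pool in (300, 400):
        p = taxa_props.copy()
        if fold is not None and pool == 300:
            p = p * np.asarray(fold, float)
        p = p / p.sum()
        for i in range(n_per_pool):
            depth = max(30, int(rng.lognormal(np.log(depth_mean), 0.3)))
            rows.append(rng.multinomial(depth, p))
            meta.append({"sample_id": f"s{pool}-{i}", "pool": pool,
                         "compartment": compartment, "species": None})
    counts = pd.DataFrame(rows, index=[m["sample_id"] for m in meta],
                          columns=taxa)
    return CountTable(counts, pd.DataFrame(meta).set_index("sample_id"))
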