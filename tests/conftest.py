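import numpy as np
import pandas as pd
import pytest

from famexpand import pipeline, simulate


def genome_with_ranks(ranks, chromosome="chr1", n_total=None, family="FAM1"):
    """A full gene table where only the genes at `ranks` carry `family`.

    The remaining ranks are filler genes without a family assignment, so
    adjacency rules see intervening ORFs.
    """
    n_total = n_total or (max(ranks) + 5)
    rows, fam_rows = [], []
    for r in range(n_total):
        gid = f"g{r:03d}"
        rows.append((gid, chromosome, 1 + r * 1000, 500 + r * 1000, "+"))
        if r in set(ranks):
            fam_rows.append((gid, family, "test"))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    )
    genes["rank"] = np.arange(n_total)
    families = pd.DataFrame(fam_rows, columns=["gene_id", "family", "species"])
    return genes, families


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(seed=11, n_chromosomes=3, genes_per_chromosome=100)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One simulated scenario analyzed end-to-end, shared across tests."""
    return pipeline.run_simulation_study(small_config)
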