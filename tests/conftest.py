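import numpy as np
import pandas as pd
import pytest

from wgdadapt import (
    AFTable,
    SimulationConfig,
    simulate_pool_reads,
    simulate_quartet_afs,
)

POPS = ["LUZ", "VKR", "CEZ", "PIC"]
PLOIDY = {"LUZ": 2, "VKR": 2, "CEZ": 4, "PIC": 4}


def make_af_table(af: np.ndarray, positions=None, scaffold="s1") -> AFTable:
    """AFTable from a raw (n_snps, 4) frequency matrix, for hand-built cases."""
    af = np.asarray(af, dtype=float)
    n = len(af)
    pos = np.arange(n) * 10 if positions is None else np.asarray(positions)
    sites = pd.DataFrame(
        {
            "scaffold": [scaffold] * n,
            "pos": pos,
            "ref": ["A"] * n,
            "alt": ["T"] * n,
        }
    )
    return AFTable(sites=sites, pops=list(POPS), ploidy=dict(PLOIDY), af=af)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_snps=600,
        n_scaffolds=2,
        scaffold_length=10_000,
        n_genes=10,
        n_sweeps_ploidy=2,
        n_sweeps_lineage=2,
        min_sweep_snps=5,
        mean_depth=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    afs, truth = simulate_quartet_afs(small_config)
    reads = simulate_pool_reads(afs, small_config)
    return afs, truth, reads
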