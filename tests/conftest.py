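import numpy as np
import pandas as pd
import pytest

from bsascan import GenomeMap, PoolCountTable, QtlSpec, SimConfig, simulate_experiment


@pytest.fixture
def small_counts() -> PoolCountTable:
    """Three SNPs x three pools, hand-written."""
    df = pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "pos": [100, 200, 50],
            "high_ref": [30, 20, 10],
            "high_tot": [40, 40, 40],
            "low_ref": [10, 20, 30],
            "low_tot": [40, 40, 40],
            "control_ref": [20, 21, 19],
            "control_tot": [40, 41, 39],
        }
    )
    return PoolCountTable(df)


def random_counts(rng: np.random.Generator, n_snps: int, pools=("high", "low")):
    """A random but valid count table on two chromosomes."""
    n1 = n_snps // 2
    pos1 = np.sort(rng.choice(np.arange(1, 10 * n_snps + 1), n1, replace=False))
    pos2 = np.sort(
        rng.choice(np.arange(1, 10 * n_snps + 1), n_snps - n1, replace=False)
    )
    df = pd.DataFrame(
        {
            "chrom": ["1"] * n1 + ["2"] * (n_snps - n1),
            "pos": np.concatenate([pos1, pos2]),
        }
    )
    for p in pools:
        tot = rng.poisson(40, n_snps)
        f = rng.uniform(0.05, 0.95, n_snps)
        df[f"{p}_ref"] = rng.binomial(tot, f)
        df[f"{p}_tot"] = tot
    return PoolCountTable(df)


@pytest.fixture(scope="session")
def qtl_experiment():
    """One moderately sized simulated experiment with a strong planted QTL,
    shared across tests (read-only)."""
    rng = np.random.default_rng(2024)
    genome = GenomeMap.uniform_random(2, 100_000_000, 3000, rng=rng)
    config = SimConfig(
        pop_size=1200, intermating_generations=10, n_selected=46, n_control=92,
        h2=0.4, mean_depth=40, seq_error=0.001, seed=11,
    )
    qtls = [QtlSpec("chr1", 50_000_000, a=1.0)]
    sim = simulate_experiment(genome, qtls, config)
    sim["genome"] = genome
    sim["config"] = config
    return sim
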