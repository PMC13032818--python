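import numpy as np
import pytest

import admixgeo as ag


def random_table(seed: int, n_snps: int = 100, n_pops: int = 8) -> ag.FrequencyTable:
    """A random frequency table with labelled populations P0..P{n-1}."""
    rng = np.random.default_rng(seed)
    pops = [f"P{i}" for i in range(n_pops)]
    return ag.FrequencyTable(rng.uniform(0.02, 0.98, size=(n_snps, n_pops)), pops)


@pytest.fixture(scope="session")
def exact_mix():
    """Exact-mixture table: Target = 0.3*SourceA + 0.7*SourceB, 6 auxiliaries."""
    return ag.exact_mixture_table(1000, 0.3, 6, seed=0)


@pytest.fixture(scope="session")
def sim_data():
    """One simulated dataset with missing data, plus its frequency table."""
    ds, truth = ag.simulate_triplet(
        ag.SimSpec(s=4000, seed=11, missing_rate=0.05)
    )
    ft = ag.compute_frequency_table(ds)
    return ds, truth, ft


@pytest.fixture()
def tiny_trio(tmp_path):
    """Write a 2-SNP x 3-individual EIGENSTRAT trio and return its paths."""
    geno = tmp_path / "t.geno"
    snp = tmp_path / "t.snp"
    ind = tmp_path / "t.ind"
    geno.write_text("029\n110\n")
    snp.write_text("rs1 1 0.0 100 A G\nrs2 1 0.0 200 C T\n")
    ind.write_text("I0 M Pop1\nI1 F Pop1\nI2 M Pop2\n")
    return geno, snp, ind
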