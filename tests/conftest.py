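import numpy as np
import pytest

import hiergst as hg


@pytest.fixture()
def tiny_table(tmp_path):
    """Hand-written genotype table: 4 individuals, 2 populations, 3 loci."""
    text = (
        "individual\tpopulation\tsnp1\tsnp2\tsnp3\n"
        "i1\tpopA\tAA\tAG\tCC\n"
        "i2\tpopA\tAG\tGG\tCT\n"
        "i3\tpopB\tGG\tAG\tTT\n"
        "i4\tpopB\tAG\t--\tCT\n"
    )
    path = tmp_path / "geno.tsv"
    path.write_text(text)
    return path


@pytest.fixture()
def tiny_ds(tiny_table):
    return hg.read_genotypes(tiny_table, format="table")


def make_two_pop_dataset(codes_a, codes_b, n_loci=None):
    """Build a dataset from per-population genotype-code row lists."""
    codes = np.array(codes_a + codes_b, dtype=np.int8)
    if codes.ndim == 1:
        codes = codes[:, None]
    loci = [f"L{j}" for j in range(codes.shape[1])]
    inds = [f"a{i}" for i in range(len(codes_a))] + [f"b{i}" for i in range(len(codes_b))]
    pop_of = {ind: ("A" if ind.startswith("a") else "B") for ind in inds}
    return hg.GenotypeDataset(loci, inds, codes, pop_of)


@pytest.fixture(scope="session")
def neutral_sim():
    """One neutral 16-population simulation under the default scenario."""
    return hg.simulate(hg.ScenarioConfig(L=60, seed=7))


@pytest.fixture(scope="session")
def hierarchy16():
    """Default 16-population hierarchy (2 clusters x 2 sub-clusters x 2
    sites x 2 elevations), without simulating genotypes."""
    return hg.simulate(hg.ScenarioConfig(L=2, N=4, generations=1, seed=0)).hierarchy
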