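import pytest

from c9quant import synthetic


@pytest.fixture(scope="session")
def wt_fixture():
    """WT-control diploid: alleles with 2 and 10 repeats, one phased SNP."""
    return synthetic.fixture_wt_2_10()


@pytest.fixture(scope="session")
def het_fixture():
    """Heterozygous clone: WT -20 nt, mutant retains 1491 repeats."""
    return synthetic.fixture_het_20nt_retained()


@pytest.fixture(scope="session")
def hom_fixture():
    """Homozygous clone: mutant -48 nt, WT -32 nt."""
    return synthetic.fixture_hom_48_32()


@pytest.fixture(scope="session")
def impure_fixture():
    """Impure pool: WT -27 (52%), mutant -17 (32%) / -19 (16%)."""
    return synthetic.fixture_impure_27_19_17()


@pytest.fixture
def noiseless_params():
    def make(n_reads, seed=0):
        return synthetic.ReadSimParams(
            n_reads=n_reads, sub_rate=0.0, ins_rate=0.0, del_rate=0.0, seed=seed
        )

    return make
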